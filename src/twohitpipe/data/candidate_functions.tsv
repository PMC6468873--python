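gene	protein_function
BRCA2	Double-strand break repair via homologous recombination, inherited predisposition to breast and ovarian cancer
BLM	DNA helicase, double-strand break repair via homologous recombination, regulation of cell cycle and apoptosis, DNA replication, telomere maintenance
ERCC2	DNA helicase, transcription-coupled nucleotide excision repair, regulation of cell cycle
FAT2	Regulation of cell proliferation, cell adhesion
IGF2R	Positive regulation of apoptosis
LATS2	Positive regulation of apoptosis, regulation of cell cycle
PARP2	Base excision repair, extrinsic apoptotic signaling pathway
PSMD9	Subunit of 26S proteasome, regulation of apoptosis and cell cycle, regulation of ubiquitin-protein ligase activity
RASSF6	Positive regulation of apoptosis
RECQL	DNA helicase, double-strand break repair via homologous recombination, DNA replication
RERGL	Unknown (closely related to RERG, which functions as a negative regulator of cell growth)
REV3L	DNA repair, translesion DNA synthesis
RIF1	Double-strand break repair via nonhomologous end joining, telomere maintenance
SEC23B	Intracellular protein transport, associated with inherited cancer predisposition Cowden Syndrome
SMARCA4	Regulation of cell growth, regulation of cell cycle, chromatin remodeling
STK11IP	Interaction with STK11 (serine/threonine kinase activity, negative regulation of cell growth, Peutz-Jeghers CRC predisposition syndrome)
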