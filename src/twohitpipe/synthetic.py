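"""Synthetic paired germline/tumor cohorts with recorded ground truth.

The generator emits, per sample, the same plain-text formats the pipeline
reads (variant TSVs, het-site allele depths, a germline coverage table and a
somatic SNV catalog with trinucleotide contexts), plus a cohort manifest,
gene intervals (BED), a reference signature matrix and a
``ground_truth.json``.  Everything is deterministic for a fixed seed.

Copy-neutral LOH is the simulated second-hit mechanism: at tumor purity
``p`` a germline-het site inside an LOH region has expected tumor VAF
``(1+p)/2`` (variant allele on the retained haplotype) or ``(1-p)/2``
(variant on the lost haplotype).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    Consequence,
    GeneInterval,
    Origin,
    SampleManifest,
    SiteAlleleDepth,
    VariantRecord,
    write_gene_intervals,
    write_manifest,
    write_site_depths,
    write_variant_table,
)
from .signatures import (
    CHANNELS,
    SignatureMatrix,
    SomaticSNV,
    channel_ref_alt_context,
    write_signature_matrix,
)

__all__ = [
    "PlantedGene",
    "CohortConfig",
    "GroundTruth",
    "make_reference_signatures",
    "loh_expected_vafs",
    "generate_cohort",
    "paper_shaped_fixture",
    "PAPER_SHAPED_BURDENS",
]

_PREDICTORS_ALL = dict.fromkeys(
    ("phylop", "sift", "polyphen2", "mutation_taster", "lrt", "cadd"), True
)


@dataclass(frozen=True)
class PlantedGene:
    """A gene planted with a germline first hit and a somatic second hit."""

    gene: str
    first_hit_type: str  # snv | indel
    second_hit_type: str  # somatic_snv | loh | both
    sample_id: str | None = None  # None -> round-robin over passing samples

    def __post_init__(self) -> None:
        if self.first_hit_type not in ("snv", "indel"):
            raise ValueError(f"bad first_hit_type {self.first_hit_type!r}")
        if self.second_hit_type not in ("somatic_snv", "loh", "both"):
            raise ValueError(f"bad second_hit_type {self.second_hit_type!r}")


@dataclass(frozen=True)
class CohortConfig:
    n_samples: int = 18
    n_genes: int = 40
    exome_mb: float = 30.0
    tumor_purity: float = 0.75
    mean_depth: int = 100
    planted_twohit_genes: tuple[PlantedGene, ...] = ()
    het_sites_per_gene: int = 10
    signature_mixtures: Mapping[str, Mapping[str, float]] | None = None
    default_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"sig_clock": 0.85, "sig_c2a": 0.10, "sig_t2g": 0.05}
    )
    burden_per_mb: Mapping[str, float] | float = 30.0
    n_lowqc_tumors: int = 2
    base_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.tumor_purity <= 1.0:
            raise ValueError("tumor_purity must be in (0, 1]")
        if self.n_lowqc_tumors > self.n_samples:
            raise ValueError("more low-QC tumors than samples")
        if len(self.planted_twohit_genes) > self.n_genes:
            raise ValueError("more planted genes than genes in the cohort")
        mixtures = list((self.signature_mixtures or {}).values()) + [self.default_mixture]
        for mix in mixtures:
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"signature mixture proportions must sum to 1, got {total}")

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def gene_names(self) -> list[str]:
        return [f"G{i + 1:03d}" for i in range(self.n_genes)]

    def burden_for(self, sample_id: str) -> float:
        if isinstance(self.burden_per_mb, Mapping):
            return float(self.burden_per_mb[sample_id])
        return float(self.burden_per_mb)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, keyed the way the pipeline reports results."""

    outdir: str
    seed: int
    tumor_purity: float
    qc_fail_samples: tuple[str, ...]
    planted: tuple[dict, ...]  # gene / sample_id / first_hit_type / second_hit_class
    burdens: dict[str, float]
    n_snv: dict[str, int]
    mixtures: dict[str, dict[str, float]]
    loh_genes: dict[str, tuple[str, ...]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "outdir": self.outdir,
                    "seed": self.seed,
                    "tumor_purity": self.tumor_purity,
                    "qc_fail_samples": list(self.qc_fail_samples),
                    "planted": list(self.planted),
                    "burdens": self.burdens,
                    "n_snv": self.n_snv,
                    "mixtures": self.mixtures,
                    "loh_genes": {k: list(v) for k, v in self.loh_genes.items()},
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def loh_expected_vafs(purity: float) -> tuple[float, float]:
    """Expected tumor VAF at a germline-het site under copy-neutral LOH.

    With tumor purity ``p``, tumor cells carry two copies of the retained
    haplotype and none of the lost one, so the alt allele averages
    ``2p + (1-p)`` copies (retained) or ``1-p`` copies (lost) out of two
    per cell: VAF = ``(1+p)/2`` or ``(1-p)/2`` (0.875 / 0.125 at p = 0.75).
    """
    return (1.0 + purity) / 2.0, (1.0 - purity) / 2.0


def make_reference_signatures(k: int = 5) -> SignatureMatrix:
    """Deterministic, well-separated synthetic reference signatures.

    ``sig_clock`` concentrates on C>T at NpCpG (clock-like); the others each
    concentrate on one substitution class, so mixtures are identifiable.
    """
    if not 2 <= k <= 5:
        raise ValueError("k must be in [2, 5]")
    names = ("sig_clock", "sig_c2a", "sig_t2g", "sig_c2g", "sig_t2a")[:k]
    blocks = {"sig_c2a": "[C>A]", "sig_t2g": "[T>G]", "sig_c2g": "[C>G]", "sig_t2a": "[T>A]"}
    matrix = np.full((96, k), 1e-4)
    for j, name in enumerate(names):
        if name == "sig_clock":
            for i, channel in enumerate(CHANNELS):
                if "[C>T]" in channel and channel.endswith("G"):
                    matrix[i, j] += 0.20
        else:
            token = blocks[name]
            for i, channel in enumerate(CHANNELS):
                if token in channel:
                    matrix[i, j] += 1.0 / 16.0
    matrix /= matrix.sum(axis=0, keepdims=True)
    return SignatureMatrix(tuple(names), matrix)


# gene layout constants: one synthetic contig per gene
_GENE_SPAN = 10_000
_FIRST_SITE = 1_000
_SITE_STEP = 500


def _gene_intervals(cfg: CohortConfig) -> list[GeneInterval]:
    return [
        GeneInterval(gene=gene, chrom=f"ctg{i + 1:03d}", start=_FIRST_SITE - 1,
                     end=_FIRST_SITE - 1 + _GENE_SPAN)
        for i, gene in enumerate(cfg.gene_names())
    ]


def _depth(rng: np.random.Generator, mean_depth: int) -> int:
    return max(int(rng.poisson(mean_depth)), 12)


def _het_alt(rng: np.random.Generator, depth: int, vaf: float) -> int:
    return int(rng.binomial(depth, vaf))


def _make_germline_hit(
    rng: np.random.Generator, sample_id: str, gene: str, chrom: str, pos: int,
    hit_type: str, mean_depth: int,
) -> VariantRecord:
    depth = _depth(rng, mean_depth)
    alt_depth = _het_alt(rng, depth, 0.5)
    if hit_type == "indel":
        ref, alt, consequence = "ACT", "A", Consequence.TRUNCATING
    else:
        ref, alt, consequence = "C", "T", Consequence.MISSENSE
    return VariantRecord(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
        origin=Origin.GERMLINE, gene=gene, consequence=consequence,
        depth=depth, alt_depth=alt_depth, predictor_calls=dict(_PREDICTORS_ALL),
        cadd_phred=28.0, pop_allele_count=0, pop_allele_number=60706,
    )


def _sample_catalog_snvs(
    rng: np.random.Generator, n_snv: int, S: SignatureMatrix, mixture: Mapping[str, float]
) -> list[SomaticSNV]:
    mix = np.zeros(S.k)
    for name, proportion in mixture.items():
        mix[S.names.index(name)] = proportion
    channel_p = S.matrix @ mix
    channel_p = channel_p / channel_p.sum()
    counts = rng.multinomial(n_snv, channel_p)
    snvs: list[SomaticSNV] = []
    pos = 0
    for i, n in enumerate(counts):
        ref, alt, context = channel_ref_alt_context(CHANNELS[i])
        for _ in range(int(n)):
            pos += 10
            snvs.append(SomaticSNV("ctg_cat", pos, ref, alt, context))
    return snvs


def _write_catalog_snvs(snvs: Sequence[SomaticSNV], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tcontext\n")
        for s in snvs:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.context}\n")


def read_catalog_snvs(path: str | Path) -> list[SomaticSNV]:
    snvs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            snvs.append(
                SomaticSNV(
                    fields[idx["chrom"]], int(fields[idx["pos"]]),
                    fields[idx["ref"]], fields[idx["alt"]], fields[idx["context"]],
                )
            )
    return snvs


def generate_cohort(cfg: CohortConfig, outdir: str | Path) -> GroundTruth:
    """Write a full synthetic cohort under ``outdir`` and return its truth.

    Layout::

        outdir/
          manifest.yaml  genes.bed  signatures.tsv  ground_truth.json
          samples/<sample_id>/{germline.tsv, somatic.tsv, het_sites.tsv,
                               germline_coverage.tsv, catalog_snvs.tsv}
    """
    outdir = Path(outdir)
    (outdir / "samples").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    sample_ids = cfg.sample_ids()
    genes = cfg.gene_names()
    intervals = _gene_intervals(cfg)
    by_gene = {iv.gene: iv for iv in intervals}
    purity = cfg.tumor_purity
    vaf_retained, vaf_lost = loh_expected_vafs(purity)

    # QC: plant n_lowqc_tumors below the 70% floor
    lowqc = sorted(rng.choice(cfg.n_samples, size=cfg.n_lowqc_tumors, replace=False))
    lowqc_ids = [sample_ids[i] for i in lowqc]
    qc_fraction = {}
    for sid in sample_ids:
        if sid in lowqc_ids:
            qc_fraction[sid] = round(0.30 + 0.30 * rng.random(), 4)
        else:
            qc_fraction[sid] = round(0.75 + 0.24 * rng.random(), 4)
    passing = [sid for sid in sample_ids if sid not in lowqc_ids]

    # assign planted genes to passing samples (round-robin when unassigned)
    planted: list[dict] = []
    for i, pg in enumerate(cfg.planted_twohit_genes):
        if pg.gene not in by_gene:
            raise ValueError(f"planted gene {pg.gene!r} not in the gene pool")
        sid = pg.sample_id or passing[i % len(passing)]
        planted.append(
            {
                "gene": pg.gene,
                "sample_id": sid,
                "first_hit_type": pg.first_hit_type,
                "second_hit_class": pg.second_hit_type,
            }
        )
    planted_by_sample: dict[str, list[dict]] = {}
    for entry in planted:
        planted_by_sample.setdefault(entry["sample_id"], []).append(entry)
    planted_genes = {entry["gene"] for entry in planted}

    # background role split: germline-only / somatic-only / quiet
    spare = [g for g in genes if g not in planted_genes]
    n_spare = len(spare)
    germline_only = spare[: n_spare // 3]
    somatic_only = spare[n_spare // 3 : 2 * n_spare // 3]

    S = make_reference_signatures()
    write_signature_matrix(S, outdir / "signatures.tsv")
    write_gene_intervals(intervals, outdir / "genes.bed")

    manifests = []
    burdens: dict[str, float] = {}
    n_snv_truth: dict[str, int] = {}
    mixtures_truth: dict[str, dict[str, float]] = {}
    loh_truth: dict[str, tuple[str, ...]] = {}

    for sid in sample_ids:
        sdir = outdir / "samples" / sid
        sdir.mkdir(parents=True, exist_ok=True)
        sample_planted = planted_by_sample.get(sid, [])
        loh_genes = tuple(
            sorted(
                e["gene"] for e in sample_planted if e["second_hit_class"] in ("loh", "both")
            )
        )
        loh_truth[sid] = loh_genes

        germline: list[VariantRecord] = []
        somatic: list[VariantRecord] = []
        coverage: dict[tuple[str, int], int] = {}

        for entry in sample_planted:
            iv = by_gene[entry["gene"]]
            first = _make_germline_hit(
                rng, sid, entry["gene"], iv.chrom, _FIRST_SITE,
                entry["first_hit_type"], cfg.mean_depth,
            )
            germline.append(first)
            if entry["second_hit_class"] in ("somatic_snv", "both"):
                depth = _depth(rng, cfg.mean_depth)
                somatic.append(
                    VariantRecord(
                        sample_id=sid, chrom=iv.chrom, pos=_FIRST_SITE + 7,
                        ref="G", alt="A", origin=Origin.SOMATIC, gene=entry["gene"],
                        consequence=Consequence.MISSENSE, depth=depth,
                        alt_depth=int(rng.binomial(depth, 0.45)),
                        predictor_calls={"phylop": True, "sift": True,
                                         "polyphen2": True, "cadd": True},
                        cadd_phred=24.0, pop_allele_count=0, pop_allele_number=0,
                    )
                )
                coverage[(iv.chrom, _FIRST_SITE + 7)] = _depth(rng, cfg.mean_depth)

        # germline-only background: rare deleterious first hits with no
        # somatic event, plus filter-fodder (common / synonymous / shallow)
        for gene in germline_only:
            iv = by_gene[gene]
            germline.append(
                _make_germline_hit(rng, sid, gene, iv.chrom, _FIRST_SITE + 20, "snv",
                                   cfg.mean_depth)
            )
        fodder_gene = germline_only[0] if germline_only else genes[-1]
        iv = by_gene[fodder_gene]
        germline.append(  # common missense: fails the rarity rule
            VariantRecord(
                sample_id=sid, chrom=iv.chrom, pos=_FIRST_SITE + 40, ref="A", alt="G",
                origin=Origin.GERMLINE, gene=fodder_gene,
                consequence=Consequence.MISSENSE, depth=_depth(rng, cfg.mean_depth),
                alt_depth=30, predictor_calls=dict(_PREDICTORS_ALL), cadd_phred=20.0,
                pop_allele_count=1200, pop_allele_number=60000,
            )
        )
        germline.append(  # synonymous: fails the consequence rule
            VariantRecord(
                sample_id=sid, chrom=iv.chrom, pos=_FIRST_SITE + 60, ref="T", alt="C",
                origin=Origin.GERMLINE, gene=fodder_gene,
                consequence=Consequence.SYNONYMOUS, depth=_depth(rng, cfg.mean_depth),
                alt_depth=40, cadd_phred=2.0, pop_allele_count=0, pop_allele_number=60706,
            )
        )

        # somatic-only background plus rule-exercising rejects
        for gene in somatic_only:
            iv = by_gene[gene]
            depth = _depth(rng, cfg.mean_depth)
            somatic.append(
                VariantRecord(
                    sample_id=sid, chrom=iv.chrom, pos=_FIRST_SITE + 80, ref="C",
                    alt="A", origin=Origin.SOMATIC, gene=gene,
                    consequence=Consequence.TRUNCATING, depth=depth,
                    alt_depth=int(rng.binomial(depth, 0.40)), cadd_phred=30.0,
                    pop_allele_count=0, pop_allele_number=0,
                )
            )
            coverage[(iv.chrom, _FIRST_SITE + 80)] = _depth(rng, cfg.mean_depth)
        if somatic_only:
            iv = by_gene[somatic_only[0]]
            depth = _depth(rng, cfg.mean_depth)
            somatic.append(  # subclonal: fails the VAF floor
                VariantRecord(
                    sample_id=sid, chrom=iv.chrom, pos=_FIRST_SITE + 95, ref="G",
                    alt="C", origin=Origin.SOMATIC, gene=somatic_only[0],
                    consequence=Consequence.TRUNCATING, depth=depth,
                    alt_depth=max(int(0.05 * depth), 1), cadd_phred=30.0,
                    pop_allele_count=0, pop_allele_number=0,
                )
            )
            coverage[(iv.chrom, _FIRST_SITE + 95)] = _depth(rng, cfg.mean_depth)
            somatic.append(  # no matched-normal coverage: fails the dual rule
                VariantRecord(
                    sample_id=sid, chrom=iv.chrom, pos=_FIRST_SITE + 97, ref="T",
                    alt="A", origin=Origin.SOMATIC, gene=somatic_only[0],
                    consequence=Consequence.TRUNCATING, depth=depth, alt_depth=depth // 2,
                    cadd_phred=30.0, pop_allele_count=0, pop_allele_number=0,
                )
            )
        if germline_only:
            # somatic record identical to a germline call: must be excluded
            iv = by_gene[germline_only[0]]
            depth = _depth(rng, cfg.mean_depth)
            somatic.append(
                VariantRecord(
                    sample_id=sid, chrom=iv.chrom, pos=_FIRST_SITE + 20, ref="C",
                    alt="T", origin=Origin.SOMATIC, gene=germline_only[0],
                    consequence=Consequence.MISSENSE, depth=depth,
                    alt_depth=int(rng.binomial(depth, 0.5)),
                    predictor_calls=dict(_PREDICTORS_ALL), cadd_phred=28.0,
                    pop_allele_count=0, pop_allele_number=0,
                )
            )
            coverage[(iv.chrom, _FIRST_SITE + 20)] = _depth(rng, cfg.mean_depth)

        # het sites: balanced everywhere except planted LOH genes
        sites: list[SiteAlleleDepth] = []
        loh_set = set(loh_genes)
        for iv in intervals:
            in_loh = iv.gene in loh_set
            for j in range(cfg.het_sites_per_gene):
                pos = _FIRST_SITE + j * _SITE_STEP
                gdepth = _depth(rng, cfg.mean_depth)
                galt = _het_alt(rng, gdepth, 0.5)
                tdepth = _depth(rng, cfg.mean_depth)
                if in_loh:
                    # first site carries the germline variant; wild type lost
                    if j == 0:
                        vaf = vaf_retained
                    else:
                        vaf = vaf_retained if rng.random() < 0.5 else vaf_lost
                else:
                    vaf = 0.5
                if cfg.base_error > 0:
                    vaf = vaf * (1 - cfg.base_error) + (1 - vaf) * cfg.base_error
                talt = int(rng.binomial(tdepth, vaf))
                sites.append(
                    SiteAlleleDepth(iv.chrom, pos, gdepth - galt, galt, tdepth - talt, talt)
                )

        # somatic catalog from the signature mixture
        burden = cfg.burden_for(sid)
        n_snv = int(round(burden * cfg.exome_mb))
        mixture = dict((cfg.signature_mixtures or {}).get(sid, cfg.default_mixture))
        snvs = _sample_catalog_snvs(rng, n_snv, S, mixture)

        germline.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
        somatic.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
        write_variant_table(germline, sdir / "germline.tsv")
        write_variant_table(somatic, sdir / "somatic.tsv")
        write_site_depths(sites, sdir / "het_sites.tsv")
        _write_catalog_snvs(snvs, sdir / "catalog_snvs.tsv")
        with open(sdir / "germline_coverage.tsv", "w") as fh:
            fh.write("chrom\tpos\tdepth\n")
            for (chrom, pos), depth in sorted(coverage.items()):
                fh.write(f"{chrom}\t{pos}\t{depth}\n")

        manifests.append(
            SampleManifest(
                sample_id=sid,
                germline_path=str(Path("samples") / sid / "germline.tsv"),
                tumor_path=str(Path("samples") / sid / "somatic.tsv"),
                qc_shared_ge10x_fraction=qc_fraction[sid],
            )
        )
        burdens[sid] = burden
        n_snv_truth[sid] = n_snv
        mixtures_truth[sid] = mixture

    write_manifest(manifests, outdir / "manifest.yaml")
    truth = GroundTruth(
        outdir=str(outdir),
        seed=cfg.seed,
        tumor_purity=purity,
        qc_fail_samples=tuple(lowqc_ids),
        planted=tuple(planted),
        burdens=burdens,
        n_snv=n_snv_truth,
        mixtures=mixtures_truth,
        loh_genes=loh_truth,
    )
    truth.to_json(outdir / "ground_truth.json")
    return truth


#: Burdens (mutations/Mb) for the 16 QC-passing samples of the default
#: cohort shape: median 58.8, five >= 90 (hypermutated), one > 500
#: (ultrahypermutated); 96.9, 61.0 and 30.8 appear as worked-example values.
PAPER_SHAPED_BURDENS: tuple[float, ...] = (
    20.0, 25.0, 30.8, 35.0, 40.0, 45.0, 50.0, 57.6,
    60.0, 61.0, 70.0, 92.0, 95.0, 96.9, 120.0, 550.0,
)


def paper_shaped_fixture(outdir: str | Path, seed: int = 7) -> tuple[CohortConfig, GroundTruth]:
    """The default cohort shape: 18 samples, 2 planted low-QC tumors, and
    per-sample burdens from :data:`PAPER_SHAPED_BURDENS` (5 hypermutated,
    1 ultrahypermutated among the 16 passing samples), with clock-dominated
    signature mixtures and six planted two-hit genes."""
    n_samples = 18
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    # peek at the QC assignment so burdens can target passing samples
    rng = np.random.default_rng(seed)
    lowqc = sorted(rng.choice(n_samples, size=2, replace=False))
    lowqc_ids = {sample_ids[i] for i in lowqc}
    passing = [sid for sid in sample_ids if sid not in lowqc_ids]
    burden_map = dict(zip(passing, PAPER_SHAPED_BURDENS))
    for sid in lowqc_ids:
        burden_map[sid] = 40.0  # discarded before burden analysis

    cfg = CohortConfig(
        n_samples=n_samples,
        n_genes=40,
        planted_twohit_genes=(
            PlantedGene("G001", "snv", "loh"),
            PlantedGene("G002", "snv", "somatic_snv"),
            PlantedGene("G003", "snv", "both"),
            PlantedGene("G004", "indel", "loh"),
            PlantedGene("G005", "snv", "loh"),
            PlantedGene("G006", "indel", "loh"),
        ),
        burden_per_mb=burden_map,
        n_lowqc_tumors=2,
        seed=seed,
    )
    truth = generate_cohort(cfg, outdir)
    assert set(truth.qc_fail_samples) == lowqc_ids  # same rng draw order
    return cfg, truth
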