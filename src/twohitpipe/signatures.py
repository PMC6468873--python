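"""96-channel somatic catalogs, mutational burden, and signature refitting.

Channels follow the standard pyrimidine-reference convention: 6 substitution
classes (C>A, C>G, C>T, T>A, T>C, T>G) x 16 flanking contexts, written
``X[R>A]Y``.  Substitutions reported on a purine reference are
reverse-complemented into their pyrimidine channel.  Refitting solves a
non-negative least-squares problem against a fixed reference signature
matrix and reports proportional contributions.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "CHANNELS",
    "CHANNEL_INDEX",
    "EXOME_MB",
    "HYPERMUTATED_PER_MB",
    "ULTRAHYPERMUTATED_PER_MB",
    "SomaticSNV",
    "MutationalCatalog",
    "SignatureMatrix",
    "ExposureVector",
    "BurdenReport",
    "EmptyCatalogError",
    "channel_for",
    "channel_ref_alt_context",
    "build_catalog",
    "compute_burden",
    "refit_signatures",
    "load_signature_matrix",
    "write_signature_matrix",
    "write_catalogs",
    "read_catalogs",
    "write_exposures",
    "plot_catalog",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Fixed channel order: substitution-major, then 5' base, then 3' base.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}

#: Exome footprint assumed when converting SNV counts to mutations/Mb.
EXOME_MB = 30.0
#: Burden classification boundaries (inclusive / strict respectively).
HYPERMUTATED_PER_MB = 90.0
ULTRAHYPERMUTATED_PER_MB = 500.0


class SomaticSNV(NamedTuple):
    """Minimal SNV for catalog building; ``context`` is the trinucleotide
    centered on the reference base."""

    chrom: str
    pos: int
    ref: str
    alt: str
    context: str


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_for(ref: str, alt: str, context: str) -> str:
    """Map a substitution plus trinucleotide context to its channel name.

    Purine-reference substitutions are strand-collapsed by reverse
    complementing both alleles and the context.  Raises ``ValueError`` for
    non-SNVs, ambiguous bases, or a context that contradicts ``ref``.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if len(context) != 3 or any(b not in _BASES for b in context):
        raise ValueError(f"ambiguous or malformed context {context!r}")
    if context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if ref in "AG":
        ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def channel_ref_alt_context(channel: str) -> tuple[str, str, str]:
    """Inverse of :func:`channel_for` for pyrimidine-reference channels."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, f"{five}{ref}{three}"


@dataclass(frozen=True)
class MutationalCatalog:
    """Per-sample 96-channel somatic SNV counts."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (96,):
            raise ValueError(f"catalog needs 96 channels, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("catalog counts must be >= 0")
        object.__setattr__(self, "counts", counts)

    @property
    def n_snv(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SignatureMatrix:
    """Reference signatures: 96 channel rows x K probability columns."""

    names: tuple[str, ...]
    matrix: np.ndarray  # (96, K)

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != 96:
            raise ValueError(f"signature matrix must be 96 x K, got {matrix.shape}")
        if matrix.shape[1] != len(self.names):
            raise ValueError("one name per signature column required")
        if (matrix < 0).any():
            raise ValueError("signature probabilities must be >= 0")
        sums = matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"signature columns must sum to 1, got {sums}")
        object.__setattr__(self, "matrix", matrix)

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ExposureVector:
    sample_id: str
    signature_names: tuple[str, ...]
    exposures: np.ndarray
    contributions: np.ndarray
    reconstruction_cosine: float


@dataclass(frozen=True)
class BurdenReport:
    sample_id: str
    n_snv: int
    mutations_per_mb: float
    burden_class: str  # normal | hypermutated | ultrahypermutated


class EmptyCatalogError(ValueError):
    """Refitting was requested for a catalog with zero SNVs."""


def build_catalog(
    sample_id: str, snvs: Iterable[SomaticSNV]
) -> tuple[MutationalCatalog, int]:
    """Accumulate SNVs into a catalog.

    Returns the catalog plus a tally of SNVs dropped for ambiguous (e.g. N)
    context bases; each drop is warned about.
    """
    counts = np.zeros(96, dtype=np.int64)
    dropped = 0
    for snv in snvs:
        try:
            channel = channel_for(snv.ref, snv.alt, snv.context)
        except ValueError as exc:
            dropped += 1
            warnings.warn(f"dropping SNV at {snv.chrom}:{snv.pos}: {exc}", stacklevel=2)
            continue
        counts[CHANNEL_INDEX[channel]] += 1
    return MutationalCatalog(sample_id, counts), dropped


def compute_burden(catalog: MutationalCatalog, exome_mb: float = EXOME_MB) -> BurdenReport:
    """Mutations/Mb under the fixed exome-size assumption, with the burden
    class (hypermutated at >= 90/Mb, ultrahypermutated at > 500/Mb)."""
    per_mb = catalog.n_snv / exome_mb
    if per_mb > ULTRAHYPERMUTATED_PER_MB:
        burden_class = "ultrahypermutated"
    elif per_mb >= HYPERMUTATED_PER_MB:
        burden_class = "hypermutated"
    else:
        burden_class = "normal"
    return BurdenReport(catalog.sample_id, catalog.n_snv, per_mb, burden_class)


def refit_signatures(catalog: MutationalCatalog, S: SignatureMatrix) -> ExposureVector:
    """Non-negative least-squares refit of the catalog onto ``S``.

    Solves ``argmin_{e >= 0} ||S e - counts||_2`` (Lawson-Hanson, via
    :func:`scipy.optimize.nnls`, deterministic), reports exposures, their
    normalized contributions and the cosine between the reconstruction and
    the observed counts.
    """
    if catalog.n_snv == 0:
        raise EmptyCatalogError("empty catalog: no SNVs to refit")
    counts = catalog.counts.astype(float)
    exposures, _ = nnls(S.matrix, counts)
    total = exposures.sum()
    contributions = exposures / total if total > 0 else np.zeros_like(exposures)
    recon = S.matrix @ exposures
    denom = np.linalg.norm(recon) * np.linalg.norm(counts)
    cosine = float(recon @ counts / denom) if denom > 0 else 0.0
    return ExposureVector(
        sample_id=catalog.sample_id,
        signature_names=S.names,
        exposures=exposures,
        contributions=contributions,
        reconstruction_cosine=min(cosine, 1.0),
    )


# ---------------------------------------------------------------------------
# I/O

_COSMIC_META_COLUMNS = {"Substitution Type", "Trinucleotide", "Somatic Mutation Type"}


def load_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a reference signature TSV.

    Two layouts are accepted: a generic one with a ``channel`` index column
    followed by one column per signature, and the COSMIC 30-signature layout
    (``Substitution Type`` / ``Trinucleotide`` / ``Somatic Mutation Type``
    metadata columns, channels keyed by ``Somatic Mutation Type``).
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        rows = list(reader)
    if _COSMIC_META_COLUMNS & set(header):
        key_col = "Somatic Mutation Type"
        sig_cols = [
            c for c in header
            if c not in _COSMIC_META_COLUMNS and c and not c.startswith("Unnamed")
        ]
    else:
        key_col = header[0]
        sig_cols = header[1:]
    matrix = np.zeros((96, len(sig_cols)))
    seen = set()
    for row in rows:
        channel = row[key_col].strip()
        if channel not in CHANNEL_INDEX:
            raise ValueError(f"unknown channel {channel!r} in {path}")
        i = CHANNEL_INDEX[channel]
        seen.add(channel)
        for j, col in enumerate(sig_cols):
            matrix[i, j] = float(row[col])
    if len(seen) != 96:
        raise ValueError(f"signature matrix in {path} has {len(seen)} channels, need 96")
    return SignatureMatrix(tuple(sig_cols), matrix)


def write_signature_matrix(S: SignatureMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["channel", *S.names])
        for i, channel in enumerate(CHANNELS):
            writer.writerow([channel, *(repr(float(x)) for x in S.matrix[i])])


def write_catalogs(catalogs: Sequence[MutationalCatalog], path: str | Path) -> None:
    """Catalog TSV: 96 channel rows x one column per sample."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["channel", *(c.sample_id for c in catalogs)])
        for i, channel in enumerate(CHANNELS):
            writer.writerow([channel, *(int(c.counts[i]) for c in catalogs)])


def read_catalogs(path: str | Path) -> list[MutationalCatalog]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        sample_ids = header[1:]
        counts = np.zeros((96, len(sample_ids)), dtype=np.int64)
        for row in reader:
            i = CHANNEL_INDEX[row[0]]
            counts[i] = [int(x) for x in row[1:]]
    return [MutationalCatalog(sid, counts[:, j]) for j, sid in enumerate(sample_ids)]


def write_exposures(exposures: Sequence[ExposureVector], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "signature", "exposure", "contribution",
                         "reconstruction_cosine"])
        for ev in exposures:
            for name, e, c in zip(ev.signature_names, ev.exposures, ev.contributions):
                writer.writerow(
                    [ev.sample_id, name, repr(float(e)), repr(float(c)),
                     repr(ev.reconstruction_cosine)]
                )


def plot_catalog(catalog: MutationalCatalog, path: str | Path) -> None:
    """Optional 96-channel bar chart of one sample's profile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = np.repeat(
        ["#03bcee", "#010101", "#e32926", "#cac9c9", "#a1ce63", "#ebc6c4"], 16
    )
    fig, ax = plt.subplots(figsize=(14, 3.2))
    ax.bar(range(96), catalog.counts, color=colors)
    ax.set_xticks(range(96))
    ax.set_xticklabels(CHANNELS, rotation=90, fontsize=4)
    ax.set_ylabel("SNV count")
    ax.set_title(catalog.sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
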