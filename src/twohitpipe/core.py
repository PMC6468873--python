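"""Domain types, coordinate conventions and I/O for annotated variant data.

Variants use 1-based inclusive positions (VCF convention); gene intervals are
stored 0-based half-open (BED convention on disk).  All coordinate conversion
lives in this module.

The on-disk variant table is a plain TSV with one row per (sample, variant)
and the columns listed in :data:`VARIANT_COLUMNS`.  VCF v4.2 input is read
through :mod:`pysam`; multi-allelic sites are split into one record per ALT.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "PREDICTOR_NAMES",
    "QC_MIN_SHARED_FRACTION",
    "Origin",
    "Consequence",
    "SchemaError",
    "RowError",
    "VariantRecord",
    "SiteAlleleDepth",
    "SampleManifest",
    "GeneInterval",
    "parse_allele_fraction",
    "format_allele_fraction",
    "read_variant_table",
    "write_variant_table",
    "read_vcf",
    "read_site_depths",
    "write_site_depths",
    "read_manifest",
    "write_manifest",
    "qc_pass",
    "read_gene_intervals",
    "write_gene_intervals",
]

#: The six pathogenicity predictors, in canonical column order.
PREDICTOR_NAMES: tuple[str, ...] = (
    "phylop",
    "sift",
    "polyphen2",
    "mutation_taster",
    "lrt",
    "cadd",
)

#: Minimum fraction of shared exome regions at >= 10x for a tumor to pass QC.
#: Boundary is inclusive.
QC_MIN_SHARED_FRACTION = 0.70


class Origin(str, enum.Enum):
    """Compartment a variant call was made in."""

    GERMLINE = "germline"
    SOMATIC = "somatic"


class Consequence(str, enum.Enum):
    """Coarse functional consequence class.

    ``TRUNCATING`` covers frameshift, nonsense and splice-disrupting calls;
    the label is consumed from the annotation input, never recomputed from
    transcripts.
    """

    MISSENSE = "missense"
    TRUNCATING = "truncating"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """A row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant call for one sample.

    ``predictor_calls`` maps each name in :data:`PREDICTOR_NAMES` to the
    boolean outcome of that predictor's pass rule (already thresholded
    upstream, e.g. PhyloP >= 1.6, CADD Phred >= 15).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    origin: Origin
    gene: str
    consequence: Consequence
    depth: int
    alt_depth: int
    predictor_calls: Mapping[str, bool] = field(default_factory=dict)
    cadd_phred: float = 0.0
    pop_allele_count: int = 0
    pop_allele_number: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, depth={self.depth}]"
            )
        if self.pop_allele_count > self.pop_allele_number:
            raise ValueError(
                f"pop_allele_count {self.pop_allele_count} > "
                f"pop_allele_number {self.pop_allele_number}"
            )
        unknown = set(self.predictor_calls) - set(PREDICTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown predictor name(s): {sorted(unknown)}")
        # canonicalize: every predictor present, absent tools count as fail
        object.__setattr__(
            self,
            "predictor_calls",
            {name: bool(self.predictor_calls.get(name, False)) for name in PREDICTOR_NAMES},
        )

    @property
    def vaf(self) -> float:
        """Variant allele fraction; 0 at zero depth."""
        return self.alt_depth / self.depth if self.depth else 0.0

    @property
    def pop_af(self) -> float:
        """Population allele frequency; 0 when the variant is absent (AN=0)."""
        if self.pop_allele_number == 0:
            return 0.0
        return self.pop_allele_count / self.pop_allele_number

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def site_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SiteAlleleDepth:
    """Paired germline/tumor ref and alt read counts at one site."""

    chrom: str
    pos: int
    germ_ref: int
    germ_alt: int
    tum_ref: int
    tum_alt: int

    def __post_init__(self) -> None:
        for name in ("germ_ref", "germ_alt", "tum_ref", "tum_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def germ_depth(self) -> int:
        return self.germ_ref + self.germ_alt

    @property
    def tum_depth(self) -> int:
        return self.tum_ref + self.tum_alt

    @property
    def germ_vaf(self) -> float:
        return self.germ_alt / self.germ_depth if self.germ_depth else 0.0

    @property
    def tum_vaf(self) -> float:
        return self.tum_alt / self.tum_depth if self.tum_depth else 0.0


@dataclass(frozen=True)
class SampleManifest:
    """One cohort entry: paths to the paired calls plus the tumor QC metric."""

    sample_id: str
    germline_path: str
    tumor_path: str
    qc_shared_ge10x_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.qc_shared_ge10x_fraction <= 1.0:
            raise ValueError("qc_shared_ge10x_fraction must be in [0, 1]")


def qc_pass(manifest: SampleManifest) -> bool:
    """True iff the tumor's shared >=10x fraction meets the 70% floor (inclusive)."""
    return manifest.qc_shared_ge10x_fraction >= QC_MIN_SHARED_FRACTION


@dataclass(frozen=True)
class GeneInterval:
    """Gene footprint, stored 0-based half-open (BED convention)."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")

    def contains_pos(self, pos: int) -> bool:
        """Whether a 1-based variant position falls inside the interval."""
        return self.start < pos <= self.end

    def overlaps_span(self, start1: int, end1: int) -> bool:
        """Overlap with a 1-based inclusive span [start1, end1]."""
        return self.start < end1 and start1 <= self.end


# ---------------------------------------------------------------------------
# allele-fraction strings ("1/60,570")


def parse_allele_fraction(text: str) -> tuple[int, int]:
    """Parse a ``count/number`` allele-frequency string.

    Thousands separators in either part are tolerated: ``"1/60,570"`` gives
    ``(1, 60570)``.
    """
    try:
        count_s, number_s = text.split("/")
        count = int(count_s.replace(",", "").strip())
        number = int(number_s.replace(",", "").strip())
    except ValueError as exc:
        raise ValueError(f"malformed allele fraction {text!r}") from exc
    return count, number


def format_allele_fraction(count: int, number: int) -> str:
    return f"{count}/{number}"


# ---------------------------------------------------------------------------
# variant table TSV

VARIANT_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "origin",
    "gene",
    "consequence",
    "depth",
    "alt_depth",
    *(f"pred_{name}" for name in PREDICTOR_NAMES),
    "cadd_phred",
    "pop_allele_count",
    "pop_allele_number",
)


def _record_to_row(v: VariantRecord) -> list[str]:
    row = [
        v.sample_id,
        v.chrom,
        str(v.pos),
        v.ref,
        v.alt,
        v.origin.value,
        v.gene,
        v.consequence.value,
        str(v.depth),
        str(v.alt_depth),
    ]
    row += ["1" if v.predictor_calls.get(name, False) else "0" for name in PREDICTOR_NAMES]
    row += [repr(v.cadd_phred), str(v.pop_allele_count), str(v.pop_allele_number)]
    return row


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as TSV; the float column uses ``repr`` so reads round-trip
    bit-exactly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for v in records:
            writer.writerow(_record_to_row(v))


def _parse_int(value: str, column: str, line_number: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise RowError(f"malformed integer in column {column!r}: {value!r}", line_number)


def read_variant_table(path: str | Path, origin: Origin | None = None) -> list[VariantRecord]:
    """Read a variant table.

    Dispatches on extension: ``.vcf`` goes through :func:`read_vcf` (where
    ``origin`` is required), anything else is parsed as the TSV layout of
    :data:`VARIANT_COLUMNS`.  For TSV, an ``origin`` argument overrides the
    column when given.

    Raises :class:`SchemaError` naming the first missing column, and
    :class:`RowError` with a line number for malformed counts.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        if origin is None:
            raise ValueError("origin is required when reading VCF input")
        return read_vcf(path, origin)

    records: list[VariantRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for column in VARIANT_COLUMNS:
            if column not in header:
                raise SchemaError(f"missing required column {column!r} in {path}")
        for line_number, row in enumerate(reader, start=2):
            rec_origin = origin if origin is not None else Origin(row["origin"])
            predictor_calls = {
                name: row[f"pred_{name}"].strip() in ("1", "true", "True")
                for name in PREDICTOR_NAMES
            }
            try:
                records.append(
                    VariantRecord(
                        sample_id=row["sample_id"],
                        chrom=row["chrom"],
                        pos=_parse_int(row["pos"], "pos", line_number),
                        ref=row["ref"],
                        alt=row["alt"],
                        origin=rec_origin,
                        gene=row["gene"],
                        consequence=Consequence(row["consequence"]),
                        depth=_parse_int(row["depth"], "depth", line_number),
                        alt_depth=_parse_int(row["alt_depth"], "alt_depth", line_number),
                        predictor_calls=predictor_calls,
                        cadd_phred=float(row["cadd_phred"]),
                        pop_allele_count=_parse_int(
                            row["pop_allele_count"], "pop_allele_count", line_number
                        ),
                        pop_allele_number=_parse_int(
                            row["pop_allele_number"], "pop_allele_number", line_number
                        ),
                    )
                )
            except ValueError as exc:
                if isinstance(exc, RowError):
                    raise
                raise RowError(str(exc), line_number) from exc
    return records


# ---------------------------------------------------------------------------
# VCF input (pysam)

#: INFO keys expected in annotated VCF input.  Per-ALT keys are Number=A.
VCF_INFO_KEYS = {
    "gene": "GENE",
    "consequence": "CSQCLS",
    "predictors": "PREDPASS",  # string of six 0/1 flags in PREDICTOR_NAMES order
    "cadd": "CADD",
    "pop_ac": "POP_AC",
    "pop_an": "POP_AN",
}


def _info_per_alt(value, index: int):
    if isinstance(value, (tuple, list)):
        return value[index] if index < len(value) else value[0]
    return value


def read_vcf(path: str | Path, origin: Origin) -> list[VariantRecord]:
    """Read an annotated single-sample VCF v4.2 into variant records.

    Multi-allelic sites are split into one record per ALT; the AD FORMAT
    field supplies per-allele depths (total depth = sum of AD).
    """
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        sample_names = list(vf.header.samples)
        if len(sample_names) != 1:
            raise SchemaError(f"expected a single-sample VCF, found {sample_names}")
        sample = sample_names[0]
        for rec in vf:
            ad = rec.samples[sample].get("AD")
            if ad is None:
                raise SchemaError(f"missing AD FORMAT field at {rec.chrom}:{rec.pos}")
            depth = int(sum(a for a in ad if a is not None))
            info = rec.info
            for key in VCF_INFO_KEYS.values():
                if key not in info:
                    raise SchemaError(
                        f"missing required INFO field {key!r} at {rec.chrom}:{rec.pos}"
                    )
            for i, alt in enumerate(rec.alts or ()):
                pred_flags = str(_info_per_alt(info[VCF_INFO_KEYS["predictors"]], i))
                predictor_calls = {
                    name: flag == "1"
                    for name, flag in zip(PREDICTOR_NAMES, pred_flags)
                }
                records.append(
                    VariantRecord(
                        sample_id=sample,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        origin=origin,
                        gene=str(_info_per_alt(info[VCF_INFO_KEYS["gene"]], i)),
                        consequence=Consequence(
                            str(_info_per_alt(info[VCF_INFO_KEYS["consequence"]], i))
                        ),
                        depth=depth,
                        alt_depth=int(ad[i + 1]),
                        predictor_calls=predictor_calls,
                        cadd_phred=float(_info_per_alt(info[VCF_INFO_KEYS["cadd"]], i)),
                        pop_allele_count=int(_info_per_alt(info[VCF_INFO_KEYS["pop_ac"]], i)),
                        pop_allele_number=int(info[VCF_INFO_KEYS["pop_an"]]),
                    )
                )
    return records


# ---------------------------------------------------------------------------
# site allele depths

SITE_COLUMNS = ("chrom", "pos", "germ_ref", "germ_alt", "tum_ref", "tum_alt")


def write_site_depths(sites: Iterable[SiteAlleleDepth], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_COLUMNS)
        for s in sites:
            writer.writerow(
                [s.chrom, s.pos, s.germ_ref, s.germ_alt, s.tum_ref, s.tum_alt]
            )


def read_site_depths(path: str | Path) -> list[SiteAlleleDepth]:
    sites: list[SiteAlleleDepth] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for column in SITE_COLUMNS:
            if column not in (reader.fieldnames or []):
                raise SchemaError(f"missing required column {column!r} in {path}")
        for line_number, row in enumerate(reader, start=2):
            sites.append(
                SiteAlleleDepth(
                    chrom=row["chrom"],
                    pos=_parse_int(row["pos"], "pos", line_number),
                    germ_ref=_parse_int(row["germ_ref"], "germ_ref", line_number),
                    germ_alt=_parse_int(row["germ_alt"], "germ_alt", line_number),
                    tum_ref=_parse_int(row["tum_ref"], "tum_ref", line_number),
                    tum_alt=_parse_int(row["tum_alt"], "tum_alt", line_number),
                )
            )
    return sites


# ---------------------------------------------------------------------------
# manifest (YAML or TSV)


def write_manifest(manifests: Sequence[SampleManifest], path: str | Path) -> None:
    path = Path(path)
    payload = [
        {
            "sample_id": m.sample_id,
            "germline_path": m.germline_path,
            "tumor_path": m.tumor_path,
            "qc_shared_ge10x_fraction": m.qc_shared_ge10x_fraction,
        }
        for m in manifests
    ]
    if path.suffix in (".yaml", ".yml"):
        with open(path, "w") as fh:
            yaml.safe_dump({"samples": payload}, fh, sort_keys=True)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=[
                    "sample_id",
                    "germline_path",
                    "tumor_path",
                    "qc_shared_ge10x_fraction",
                ],
                delimiter="\t",
                lineterminator="\n",
            )
            writer.writeheader()
            writer.writerows(payload)


def read_manifest(path: str | Path) -> list[SampleManifest]:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        rows = data["samples"] if isinstance(data, dict) else data
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    manifests = []
    for row in rows:
        try:
            manifests.append(
                SampleManifest(
                    sample_id=row["sample_id"],
                    germline_path=row["germline_path"],
                    tumor_path=row["tumor_path"],
                    qc_shared_ge10x_fraction=float(row["qc_shared_ge10x_fraction"]),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"missing manifest field {exc.args[0]!r} in {path}")
    return manifests


# ---------------------------------------------------------------------------
# gene intervals (BED)


def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """Read a 4-column BED (chrom, start, end, gene) into intervals."""
    intervals: list[GeneInterval] = []
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise RowError("BED line needs >= 4 columns (chrom start end name)", line_number)
            intervals.append(
                GeneInterval(
                    gene=fields[3],
                    chrom=fields[0],
                    start=_parse_int(fields[1], "start", line_number),
                    end=_parse_int(fields[2], "end", line_number),
                )
            )
    return intervals


def write_gene_intervals(intervals: Iterable[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene}\n")
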