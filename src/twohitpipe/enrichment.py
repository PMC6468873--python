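"""Per-gene rare-variant case-control enrichment via Fisher's exact test.

Variants are pre-filtered to rare (control AF strictly below 0.1%) and
potentially pathogenic (CADD Phred strictly above 15).  Each variant is
tested on a 2x2 allele-count table (case alt/ref vs control alt/ref) with a
two-sided exact test using the probability-ordering definition: the p-value
sums the hypergeometric probabilities of every table with the same margins
whose probability does not exceed the observed table's (relative tie
tolerance 1e-7).  Genes are highlighted when strictly more than half of
their tested variants are significant.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "EnrichmentConfig",
    "EnrichmentVariant",
    "EnrichmentResult",
    "GeneSummary",
    "select_enrichment_variants",
    "fisher_exact_2x2",
    "test_enrichment",
    "gene_level_summary",
    "read_enrichment_table",
    "write_enrichment_results",
    "write_gene_summaries",
]

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class EnrichmentConfig:
    max_control_af: float = 0.001  # strict <
    min_cadd: float = 15.0  # strict >
    alpha: float = 0.05
    bh_correction: bool = False


@dataclass(frozen=True)
class EnrichmentVariant:
    """Per-variant allele counts in the case cohort and the control
    repository, plus the rarity/pathogenicity annotations."""

    gene: str
    variant_id: str
    case_allele_count: int
    case_allele_number: int
    control_allele_count: int
    control_allele_number: int
    cadd_phred: float

    def __post_init__(self) -> None:
        if self.case_allele_count > self.case_allele_number:
            raise ValueError("case allele count exceeds allele number")
        if self.control_allele_count > self.control_allele_number:
            raise ValueError("control allele count exceeds allele number")

    @property
    def control_af(self) -> float:
        if self.control_allele_number == 0:
            return 0.0
        return self.control_allele_count / self.control_allele_number


@dataclass(frozen=True)
class EnrichmentResult:
    gene: str
    variant_id: str
    table: tuple[int, int, int, int]  # case alt, case ref, control alt, control ref
    odds_ratio: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class GeneSummary:
    gene: str
    n_tested: int
    n_significant: int
    fraction_significant: float
    highlighted: bool  # strictly more than half significant
    testable: bool = True


def select_enrichment_variants(
    variants: Iterable[EnrichmentVariant], cfg: EnrichmentConfig | None = None
) -> list[EnrichmentVariant]:
    """Keep rare (control AF < max_control_af) and potentially pathogenic
    (CADD > min_cadd) variants; both inequalities are strict."""
    cfg = cfg or EnrichmentConfig()
    return [
        v
        for v in variants
        if v.control_af < cfg.max_control_af and v.cadd_phred > cfg.min_cadd
    ]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test for the table ``[[a, b], [c, d]]``.

    Returns ``(odds_ratio, p)``.  The odds ratio is ``a*d / (b*c)``,
    ``inf`` when ``b*c == 0`` with ``a*d > 0``, and ``nan`` for the all-zero
    table (for which p = 1).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        return math.nan, 1.0
    if b * c == 0:
        odds_ratio = math.inf if a * d > 0 else math.nan
    else:
        odds_ratio = (a * d) / (b * c)

    row1 = a + b
    col1 = a + c
    # support of the hypergeometric count in cell (1,1) given the margins
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    mask = pmf <= p_obs * (1.0 + _TIE_RTOL)
    if mask.all():  # observed table is (tied for) the most probable one
        return odds_ratio, 1.0
    p = float(pmf[mask].sum())
    return odds_ratio, min(p, 1.0)


def test_enrichment(
    variants: Sequence[EnrichmentVariant], cfg: EnrichmentConfig | None = None
) -> list[EnrichmentResult]:
    """Fisher test per variant on allele-count 2x2 tables.

    With ``cfg.bh_correction`` the significance flag uses Benjamini-Hochberg
    adjusted p-values at ``cfg.alpha``; raw p-values are always reported.
    """
    cfg = cfg or EnrichmentConfig()
    results = []
    raw_p = []
    for v in variants:
        a = v.case_allele_count
        b = v.case_allele_number - v.case_allele_count
        c = v.control_allele_count
        d = v.control_allele_number - v.control_allele_count
        odds_ratio, p = fisher_exact_2x2(a, b, c, d)
        raw_p.append(p)
        results.append((v, (a, b, c, d), odds_ratio, p))
    if cfg.bh_correction and results:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(raw_p, alpha=cfg.alpha, method="fdr_bh")
    else:
        reject = [p < cfg.alpha for p in raw_p]
    return [
        EnrichmentResult(
            gene=v.gene,
            variant_id=v.variant_id,
            table=table,
            odds_ratio=odds_ratio,
            p_value=p,
            significant=bool(sig),
        )
        for (v, table, odds_ratio, p), sig in zip(results, reject)
    ]


def gene_level_summary(
    results: Sequence[EnrichmentResult], genes: Iterable[str] | None = None
) -> list[GeneSummary]:
    """Per-gene fraction of significant variants.

    A gene is highlighted when the fraction is strictly greater than 0.5.
    Genes passed in ``genes`` but absent from the results are reported
    untestable.
    """
    by_gene: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene, []).append(r)
    all_genes = sorted(set(genes) | set(by_gene)) if genes is not None else sorted(by_gene)
    summaries = []
    for gene in all_genes:
        tested = by_gene.get(gene, [])
        if not tested:
            summaries.append(GeneSummary(gene, 0, 0, 0.0, False, testable=False))
            continue
        n_sig = sum(r.significant for r in tested)
        fraction = n_sig / len(tested)
        summaries.append(
            GeneSummary(gene, len(tested), n_sig, fraction, fraction > 0.5)
        )
    return summaries


# ---------------------------------------------------------------------------
# I/O

_ENRICH_COLUMNS = (
    "gene",
    "variant_id",
    "case_allele_count",
    "case_allele_number",
    "control_allele_count",
    "control_allele_number",
    "cadd_phred",
)


def read_enrichment_table(path: str | Path) -> list[EnrichmentVariant]:
    from .core import SchemaError, _parse_int

    variants = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for column in _ENRICH_COLUMNS:
            if column not in (reader.fieldnames or []):
                raise SchemaError(f"missing required column {column!r} in {path}")
        for line_number, row in enumerate(reader, start=2):
            variants.append(
                EnrichmentVariant(
                    gene=row["gene"],
                    variant_id=row["variant_id"],
                    case_allele_count=_parse_int(
                        row["case_allele_count"], "case_allele_count", line_number
                    ),
                    case_allele_number=_parse_int(
                        row["case_allele_number"], "case_allele_number", line_number
                    ),
                    control_allele_count=_parse_int(
                        row["control_allele_count"], "control_allele_count", line_number
                    ),
                    control_allele_number=_parse_int(
                        row["control_allele_number"], "control_allele_number", line_number
                    ),
                    cadd_phred=float(row["cadd_phred"]),
                )
            )
    return variants


def write_enrichment_results(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene", "variant_id", "case_alt", "case_ref", "control_alt",
             "control_ref", "odds_ratio", "p_value", "significant"]
        )
        for r in results:
            writer.writerow(
                [r.gene, r.variant_id, *r.table, repr(r.odds_ratio),
                 repr(r.p_value), int(r.significant)]
            )


def write_gene_summaries(summaries: Sequence[GeneSummary], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene", "n_tested", "n_significant", "fraction_significant",
             "highlighted", "testable"]
        )
        for s in summaries:
            writer.writerow(
                [s.gene, s.n_tested, s.n_significant, repr(s.fraction_significant),
                 int(s.highlighted), int(s.testable)]
            )
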