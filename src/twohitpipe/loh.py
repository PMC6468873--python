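"""Loss-of-heterozygosity calling from allelic imbalance at germline-het sites.

The tumor VAF at each germline-heterozygous site is folded around 0.5
(``d_i = |VAF - 0.5|``) so the statistic is insensitive to which allele was
lost.  Per chromosome, sites are partitioned by recursive binary segmentation
with a seeded permutation max-t stopping rule; each segment is then tested
for imbalance with per-site two-sided exact binomial tests against
Binomial(depth, 0.5), combined by Fisher's method, plus an effect-size floor
on the mean folded shift.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import GeneInterval, SiteAlleleDepth, VariantRecord

__all__ = [
    "LOHParams",
    "LOHSegment",
    "LOHCall",
    "filter_het_sites",
    "segment_vaf",
    "test_segment_imbalance",
    "call_gene_loh",
    "write_segments_tsv",
    "write_segments_bed",
    "write_gene_calls",
]


@dataclass(frozen=True)
class LOHParams:
    """Tuning knobs; all defaults are package choices, not published values."""

    alpha_split: float = 0.01
    alpha_loh: float = 0.01
    shift_min: float = 0.15
    min_sites: int = 5
    n_perm: int = 1000
    seed: int = 0
    het_vaf_low: float = 0.30
    het_vaf_high: float = 0.70
    min_het_depth: int = 10


@dataclass(frozen=True)
class LOHSegment:
    """A run of consecutive het sites with a shared imbalance state.

    ``start``/``end`` are the 1-based positions of the first and last site.
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    mean_shift: float
    p_value: float
    is_loh: bool
    affected_allele: str = "unknown"  # ref_lost | alt_lost | unknown
    testable: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_shift <= 0.5 + 1e-12:
            raise ValueError(f"mean_shift {self.mean_shift} outside [0, 0.5]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    def overlaps(self, interval: GeneInterval) -> bool:
        return self.chrom == interval.chrom and interval.overlaps_span(self.start, self.end)


@dataclass(frozen=True)
class LOHCall:
    gene: str
    sample_id: str
    is_loh: bool
    supporting_segment: LOHSegment | None = None
    second_hit_allele_retains_germline_variant: bool | None = None


def filter_het_sites(
    sites: Iterable[SiteAlleleDepth], params: LOHParams | None = None
) -> list[SiteAlleleDepth]:
    """Keep germline-heterozygous, adequately covered sites: germline VAF in
    [het_vaf_low, het_vaf_high] and germline depth >= min_het_depth."""
    params = params or LOHParams()
    return [
        s
        for s in sites
        if s.germ_depth >= params.min_het_depth
        and params.het_vaf_low <= s.germ_vaf <= params.het_vaf_high
    ]


def _folded_shift(sites: Sequence[SiteAlleleDepth]) -> np.ndarray:
    vaf = np.array(
        [s.tum_alt / s.tum_depth if s.tum_depth else 0.5 for s in sites], dtype=float
    )
    return np.abs(vaf - 0.5)


def _split_t_stats(d: np.ndarray, min_sites: int) -> tuple[np.ndarray, np.ndarray]:
    """|t| for every admissible breakpoint.

    Breakpoint ``k`` splits ``d`` into ``d[:k]`` and ``d[k:]``; both children
    must have >= ``min_sites`` sites.  Returns (ks, |t| per k); empty when no
    admissible breakpoint exists.
    """
    n = len(d)
    ks = np.arange(min_sites, n - min_sites + 1)
    if ks.size == 0:
        return ks, np.array([])
    csum = np.concatenate([[0.0], np.cumsum(d)])
    csq = np.concatenate([[0.0], np.cumsum(d * d)])
    n1 = ks.astype(float)
    n2 = n - n1
    m1 = csum[ks] / n1
    m2 = (csum[n] - csum[ks]) / n2
    ss1 = csq[ks] - n1 * m1 * m1
    ss2 = (csq[n] - csq[ks]) - n2 * m2 * m2
    dof = n - 2
    pooled = (ss1 + ss2) / dof if dof > 0 else np.zeros_like(n1)
    se = np.sqrt(np.maximum(pooled, 0.0) * (1.0 / n1 + 1.0 / n2))
    diff = np.abs(m1 - m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        # cumsum round-off can make equal means differ in the last bit;
        # treat sub-1e-9 differences at zero variance as no signal
        t = np.where(se > 0, diff / se, np.where(diff > 1e-9, np.inf, 0.0))
    return ks, t


def best_breakpoint(d: np.ndarray, min_sites: int) -> tuple[int | None, float]:
    """Breakpoint maximizing |t| (exhaustive over admissible positions)."""
    ks, t = _split_t_stats(d, min_sites)
    if ks.size == 0:
        return None, 0.0
    i = int(np.argmax(t))
    return int(ks[i]), float(t[i])


def _max_t_permutation_p(
    d: np.ndarray, observed_t: float, min_sites: int, n_perm: int, rng: np.random.Generator
) -> float:
    """Permutation p-value for the max-|t| statistic (add-one estimator)."""
    if not np.isfinite(observed_t):
        return 1.0 / (n_perm + 1)
    perms = rng.permuted(np.tile(d, (n_perm, 1)), axis=1)
    n = len(d)
    ks = np.arange(min_sites, n - min_sites + 1)
    csum = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms, axis=1)], axis=1)
    csq = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms * perms, axis=1)], axis=1)
    n1 = ks.astype(float)
    n2 = n - n1
    m1 = csum[:, ks] / n1
    m2 = (csum[:, [n]] - csum[:, ks]) / n2
    ss1 = csq[:, ks] - n1 * m1 * m1
    ss2 = (csq[:, [n]] - csq[:, ks]) - n2 * m2 * m2
    dof = n - 2
    pooled = (ss1 + ss2) / dof
    se = np.sqrt(np.maximum(pooled, 0.0) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, np.abs(m1 - m2) / se, 0.0)
    max_t = t.max(axis=1)
    return float((1 + np.sum(max_t >= observed_t - 1e-12)) / (n_perm + 1))


def test_segment_imbalance(
    sites: Sequence[SiteAlleleDepth], params: LOHParams | None = None
) -> tuple[float, float]:
    """(mean folded shift, combined p) for one segment.

    Per site, a two-sided exact binomial test of ``tum_alt`` against
    Binomial(tum_depth, 0.5); segment p combines site p-values by Fisher's
    method.  Sites with zero tumor depth are skipped; if none are testable
    the segment gets p = 1.
    """
    params = params or LOHParams()
    covered = [s for s in sites if s.tum_depth > 0]
    if not covered:
        return 0.0, 1.0
    mean_shift = float(np.mean(np.abs([s.tum_vaf - 0.5 for s in covered])))
    pvals = [
        stats.binomtest(s.tum_alt, s.tum_depth, 0.5, alternative="two-sided").pvalue
        for s in covered
    ]
    if len(pvals) == 1:
        return mean_shift, float(min(pvals[0], 1.0))
    # Fisher's method; clip to avoid log(0) from astronomically small p
    clipped = np.clip(pvals, 1e-300, 1.0)
    _, p_combined = stats.combine_pvalues(clipped, method="fisher")
    return mean_shift, float(min(p_combined, 1.0))


def _make_segment(
    sites: Sequence[SiteAlleleDepth], params: LOHParams, testable: bool = True
) -> LOHSegment:
    mean_shift, p_value = test_segment_imbalance(sites, params)
    is_loh = testable and p_value < params.alpha_loh and mean_shift >= params.shift_min
    allele = "unknown"
    if is_loh:
        covered = [s for s in sites if s.tum_depth > 0]
        mean_vaf = float(np.mean([s.tum_vaf for s in covered]))
        if mean_vaf > 0.5:
            allele = "ref_lost"
        elif mean_vaf < 0.5:
            allele = "alt_lost"
    return LOHSegment(
        chrom=sites[0].chrom,
        start=sites[0].pos,
        end=sites[-1].pos,
        n_sites=len(sites),
        mean_shift=mean_shift,
        p_value=p_value,
        is_loh=is_loh,
        affected_allele=allele,
        testable=testable,
    )


def _segment_recursive(
    sites: Sequence[SiteAlleleDepth],
    params: LOHParams,
    rng: np.random.Generator,
) -> list[LOHSegment]:
    d = _folded_shift(sites)
    k, t_obs = best_breakpoint(d, params.min_sites)
    if k is None:
        return [_make_segment(sites, params)]
    p = _max_t_permutation_p(d, t_obs, params.min_sites, params.n_perm, rng)
    if p >= params.alpha_split:
        return [_make_segment(sites, params)]
    return _segment_recursive(sites[:k], params, rng) + _segment_recursive(
        sites[k:], params, rng
    )


def segment_vaf(
    sites: Sequence[SiteAlleleDepth], params: LOHParams | None = None
) -> list[LOHSegment]:
    """Partition het sites into imbalance segments, per chromosome.

    Input sites must already be restricted to germline-het calls (see
    :func:`filter_het_sites`).  Chromosomes with fewer than ``min_sites``
    sites yield a single untestable segment.  Deterministic for a fixed
    ``params.seed``.
    """
    params = params or LOHParams()
    if not sites:
        return []
    by_chrom: dict[str, list[SiteAlleleDepth]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    segments: list[LOHSegment] = []
    for chrom in sorted(by_chrom):
        chrom_sites = sorted(by_chrom[chrom], key=lambda s: s.pos)
        if len(chrom_sites) < params.min_sites:
            segments.append(_make_segment(chrom_sites, params, testable=False))
            continue
        # crc32 keeps the per-chromosome stream stable across processes
        rng = np.random.default_rng((params.seed, zlib.crc32(chrom.encode())))
        segments.extend(_segment_recursive(chrom_sites, params, rng))
    return segments


def call_gene_loh(
    segments: Sequence[LOHSegment],
    gene_intervals: Sequence[GeneInterval],
    germline_first_hits: Sequence[VariantRecord] = (),
    tumor_site_vaf: Mapping[tuple[str, int], float] | None = None,
) -> list[LOHCall]:
    """Per-gene LOH calls from overlap with imbalance segments.

    A gene is LOH when any ``is_loh`` segment overlaps its interval.  When a
    germline first-hit variant for the gene lies inside the supporting
    segment and its tumor VAF is known (``tumor_site_vaf``), the call records
    whether the surviving allele retains the germline variant (tumor VAF >
    0.5, i.e. the wild-type allele was lost).
    """
    tumor_site_vaf = tumor_site_vaf or {}
    hits_by_gene: dict[tuple[str, str], list[VariantRecord]] = {}
    for v in germline_first_hits:
        hits_by_gene.setdefault((v.sample_id, v.gene), []).append(v)
    sample_ids = sorted({v.sample_id for v in germline_first_hits}) or [""]

    calls: list[LOHCall] = []
    for interval in gene_intervals:
        overlapping = [seg for seg in segments if seg.overlaps(interval)]
        loh_segs = [seg for seg in overlapping if seg.is_loh]
        support = loh_segs[0] if loh_segs else (overlapping[0] if overlapping else None)
        for sample_id in sample_ids:
            retains: bool | None = None
            if loh_segs:
                for v in hits_by_gene.get((sample_id, interval.gene), []):
                    for seg in loh_segs:
                        if (
                            seg.chrom == v.chrom
                            and seg.start <= v.pos <= seg.end
                            and v.site_key in tumor_site_vaf
                        ):
                            retains = tumor_site_vaf[v.site_key] > 0.5
                            break
                    if retains is not None:
                        break
            calls.append(
                LOHCall(
                    gene=interval.gene,
                    sample_id=sample_id,
                    is_loh=bool(loh_segs),
                    supporting_segment=support,
                    second_hit_allele_retains_germline_variant=retains,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# output


def write_segments_tsv(segments: Iterable[LOHSegment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["chrom", "start", "end", "n_sites", "mean_shift", "p_value", "is_loh",
             "affected_allele", "testable"]
        )
        for s in segments:
            writer.writerow(
                [s.chrom, s.start, s.end, s.n_sites, repr(s.mean_shift),
                 repr(s.p_value), int(s.is_loh), s.affected_allele, int(s.testable)]
            )


def write_segments_bed(segments: Iterable[LOHSegment], path: str | Path) -> None:
    """BED output (0-based half-open; name column carries the call)."""
    with open(path, "w") as fh:
        for s in segments:
            name = "LOH" if s.is_loh else "balanced"
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{name}\t{s.n_sites}\n")


def write_gene_calls(calls: Iterable[LOHCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene", "sample_id", "is_loh", "segment_p", "segment_mean_shift",
             "retains_germline_variant"]
        )
        for c in calls:
            seg = c.supporting_segment
            writer.writerow(
                [
                    c.gene,
                    c.sample_id,
                    int(c.is_loh),
                    repr(seg.p_value) if seg else "",
                    repr(seg.mean_shift) if seg else "",
                    ""
                    if c.second_hit_allele_retains_germline_variant is None
                    else int(c.second_hit_allele_retains_germline_variant),
                ]
            )
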