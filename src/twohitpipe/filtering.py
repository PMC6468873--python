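"""Germline and somatic SNV/indel filter cascades.

Each cascade keeps truncating variants unconditionally past the predictor
rule and requires missense variants to satisfy a minimum number of the six
pathogenicity predictors.  The somatic cascade additionally enforces dual
coverage (tumor and matched germline both >= 10x), a tumor VAF floor, and
exact-match exclusion of germline calls.

The production path is vectorized over a pandas frame; tests compare it
against a naive per-record oracle.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    PREDICTOR_NAMES,
    Consequence,
    Origin,
    VariantRecord,
)

__all__ = [
    "FilterConfig",
    "PathogenicityScore",
    "score_pathogenicity",
    "filter_germline",
    "filter_somatic",
    "germline_filter_trace",
    "somatic_filter_trace",
    "germline_site_depths",
    "write_filter_trace",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for both cascades.  All boundaries are inclusive except
    the population-AF caps, which are strict upper bounds."""

    min_depth: int = 10
    min_tumor_vaf: float = 0.20
    min_predictors: int = 3
    max_pop_af_germline: float = 0.001
    max_pop_af_enrichment: float = 0.001
    min_cadd_enrichment: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_tumor_vaf <= 1.0:
            raise ValueError("min_tumor_vaf must be in [0, 1]")
        if not 0 <= self.min_predictors <= 6:
            raise ValueError("min_predictors must be in [0, 6]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "min_depth": self.min_depth,
                    "min_tumor_vaf": self.min_tumor_vaf,
                    "min_predictors": self.min_predictors,
                    "max_pop_af_germline": self.max_pop_af_germline,
                    "max_pop_af_enrichment": self.max_pop_af_enrichment,
                    "min_cadd_enrichment": self.min_cadd_enrichment,
                },
                fh,
                sort_keys=True,
            )


@dataclass(frozen=True)
class PathogenicityScore:
    """Outcome of the six-predictor vote for one missense variant."""

    variant_key: tuple[str, int, str, str]
    n_pass: int
    passing_tools: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_pass != len(self.passing_tools):
            raise ValueError("n_pass must equal |passing_tools|")


_warned_missing: set[str] = set()


def score_pathogenicity(v: VariantRecord) -> PathogenicityScore:
    """Count predictor passes for a missense variant.

    A predictor missing from ``predictor_calls`` counts as a fail and is
    logged once per tool.
    """
    if v.consequence is not Consequence.MISSENSE:
        raise ValueError(
            f"pathogenicity scoring applies to missense variants, got {v.consequence.value}"
        )
    passing = set()
    for name in PREDICTOR_NAMES:
        if name not in v.predictor_calls and name not in _warned_missing:
            _warned_missing.add(name)
            logger.warning("predictor %r missing from input; counted as fail", name)
        if v.predictor_calls.get(name, False):
            passing.add(name)
    return PathogenicityScore(v.variant_key, len(passing), frozenset(passing))


def _n_predictor_pass(v: VariantRecord) -> int:
    return sum(bool(v.predictor_calls.get(name, False)) for name in PREDICTOR_NAMES)


# ---------------------------------------------------------------------------
# vectorized cascades

_GERMLINE_RULES = ("min_depth", "pop_af", "consequence_class")
_SOMATIC_RULES = (
    "tumor_depth",
    "germline_depth",
    "tumor_vaf",
    "consequence_class",
    "germline_match",
)


def _frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "depth": np.array([v.depth for v in records], dtype=np.int64),
            "alt_depth": np.array([v.alt_depth for v in records], dtype=np.int64),
            "pop_af": np.array([v.pop_af for v in records], dtype=float),
            "truncating": np.array(
                [v.consequence is Consequence.TRUNCATING for v in records], dtype=bool
            ),
            "missense": np.array(
                [v.consequence is Consequence.MISSENSE for v in records], dtype=bool
            ),
            "n_pass": np.array([_n_predictor_pass(v) for v in records], dtype=np.int64),
        }
    )


def germline_filter_trace(
    records: Sequence[VariantRecord], cfg: FilterConfig | None = None
) -> list[tuple[VariantRecord, tuple[str, ...]]]:
    """Evaluate the germline cascade, returning each record with the tuple of
    rule names it failed (empty tuple = kept)."""
    cfg = cfg or FilterConfig()
    if not records:
        return []
    df = _frame(records)
    fails = {
        "min_depth": (df["depth"] < cfg.min_depth).to_numpy(),
        "pop_af": (df["pop_af"] >= cfg.max_pop_af_germline).to_numpy(),
        "consequence_class": ~(
            df["truncating"] | (df["missense"] & (df["n_pass"] >= cfg.min_predictors))
        ).to_numpy(),
    }
    return [
        (v, tuple(rule for rule in _GERMLINE_RULES if fails[rule][i]))
        for i, v in enumerate(records)
    ]


def filter_germline(
    records: Sequence[VariantRecord], cfg: FilterConfig | None = None
) -> list[VariantRecord]:
    """Germline first-hit cascade.

    Keeps records with depth >= ``min_depth``, population AF strictly below
    ``max_pop_af_germline`` (absent-from-repository variants count as AF 0),
    and a consequence of truncating, or missense passing >= ``min_predictors``
    of the six predictors.
    """
    for v in records:
        if v.origin is not Origin.GERMLINE:
            raise ValueError(f"filter_germline got a {v.origin.value} record")
    return [v for v, failed in germline_filter_trace(records, cfg) if not failed]


def germline_site_depths(
    germline_records: Iterable[VariantRecord],
) -> dict[tuple[str, int], int]:
    """Map (chrom, pos) -> germline read depth, for the somatic dual-coverage
    rule.  When several records share a site the maximum depth is used."""
    depths: dict[tuple[str, int], int] = {}
    for v in germline_records:
        key = v.site_key
        depths[key] = max(depths.get(key, 0), v.depth)
    return depths


def somatic_filter_trace(
    records: Sequence[VariantRecord],
    germline_records: Sequence[VariantRecord] = (),
    cfg: FilterConfig | None = None,
    germline_depths: Mapping[tuple[str, int], int] | None = None,
) -> list[tuple[VariantRecord, tuple[str, ...]]]:
    """Evaluate the somatic cascade with a per-rule failure trace.

    ``germline_depths`` supplies matched-normal coverage per site; when not
    given it is derived from ``germline_records``.  A site absent from both
    is treated as germline depth 0 (fails the dual-coverage rule).
    """
    cfg = cfg or FilterConfig()
    if not records:
        return []
    if germline_depths is None:
        germline_depths = germline_site_depths(germline_records)
    germline_keys = {v.variant_key for v in germline_records}

    df = _frame(records)
    gdepth = np.array(
        [germline_depths.get(v.site_key, 0) for v in records], dtype=np.int64
    )
    vaf = np.where(df["depth"] > 0, df["alt_depth"] / df["depth"].clip(lower=1), 0.0)
    fails = {
        "tumor_depth": (df["depth"] < cfg.min_depth).to_numpy(),
        "germline_depth": gdepth < cfg.min_depth,
        "tumor_vaf": vaf < cfg.min_tumor_vaf,
        "consequence_class": ~(
            df["truncating"] | (df["missense"] & (df["n_pass"] >= cfg.min_predictors))
        ).to_numpy(),
        "germline_match": np.array(
            [v.variant_key in germline_keys for v in records], dtype=bool
        ),
    }
    return [
        (v, tuple(rule for rule in _SOMATIC_RULES if fails[rule][i]))
        for i, v in enumerate(records)
    ]


def filter_somatic(
    records: Sequence[VariantRecord],
    germline_records: Sequence[VariantRecord] = (),
    cfg: FilterConfig | None = None,
    germline_depths: Mapping[tuple[str, int], int] | None = None,
) -> list[VariantRecord]:
    """Somatic second-hit cascade.

    Keeps records with tumor depth >= 10x and matched germline depth >= 10x,
    tumor VAF >= 20% (inclusive), a truncating consequence or missense with
    >= 3/6 predictor passes, and no exact germline match at the same
    chrom/pos/ref/alt (those are non-somatic).
    """
    for v in records:
        if v.origin is not Origin.SOMATIC:
            raise ValueError(f"filter_somatic got a {v.origin.value} record")
    return [
        v
        for v, failed in somatic_filter_trace(records, germline_records, cfg, germline_depths)
        if not failed
    ]


def write_filter_trace(
    traced: Sequence[tuple[VariantRecord, tuple[str, ...]]], path: str | Path
) -> None:
    """Audit TSV: one row per input record with a ``filter_trace`` column
    listing the failed rules (semicolon-joined; empty means kept)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["sample_id", "chrom", "pos", "ref", "alt", "gene", "kept", "filter_trace"]
        )
        for v, failed in traced:
            writer.writerow(
                [
                    v.sample_id,
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.gene,
                    "1" if not failed else "0",
                    ";".join(failed),
                ]
            )
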