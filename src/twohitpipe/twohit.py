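"""Two-hit pairing of germline first hits with somatic second hits.

A gene becomes a candidate in a sample when it carries at least one filtered
germline variant (first hit) and at least one somatic second hit: a distinct
somatic SNV/indel (different chrom/pos/ref/alt), a gene-level LOH call, or
both.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import VariantRecord, format_allele_fraction
from .filtering import _n_predictor_pass
from .loh import LOHCall

__all__ = [
    "DEFAULT_PRIORITY_KEYWORDS",
    "DNA_REPAIR_KEYWORDS",
    "CandidateGene",
    "pair_two_hits",
    "summarize_candidates",
    "match_function_keywords",
    "apply_function_prioritization",
    "flag_gene_functions",
    "load_bundled_function_map",
    "write_candidate_table",
]

logger = logging.getLogger(__name__)

#: Default functional-priority keyword list (gene-function text is matched
#: case-insensitively against these substrings).
DEFAULT_PRIORITY_KEYWORDS: tuple[str, ...] = (
    "dna repair",
    "repair",
    "apoptosis",
    "apoptotic",
    "autophagy",
    "cell growth",
    "cell proliferation",
    "inflammatory response",
    "cell cycle",
    "angiogenesis",
    "cell differentiation",
    "cell adhesion",
    "chromatin",
)

#: Keywords defining the DNA-repair functional category.
DNA_REPAIR_KEYWORDS: tuple[str, ...] = ("repair",)


@dataclass(frozen=True)
class CandidateGene:
    """A (gene, sample) pair satisfying the two-hit requirement."""

    gene: str
    sample_id: str
    first_hit: VariantRecord
    second_hit_class: str  # somatic_snv | loh | both
    second_hit_variant: VariantRecord | None = None
    loh_call: LOHCall | None = None
    priority_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.second_hit_class not in ("somatic_snv", "loh", "both"):
            raise ValueError(f"bad second_hit_class {self.second_hit_class!r}")
        if self.second_hit_class in ("somatic_snv", "both"):
            if self.second_hit_variant is None:
                raise ValueError("somatic_snv class requires second_hit_variant")
            if self.second_hit_variant.variant_key == self.first_hit.variant_key:
                raise ValueError("second hit must differ from first hit")
        if self.second_hit_class in ("loh", "both"):
            if self.loh_call is None or not self.loh_call.is_loh:
                raise ValueError("loh class requires a positive LOHCall")


def pair_two_hits(
    germline_hits: Sequence[VariantRecord],
    somatic_hits: Sequence[VariantRecord],
    loh_calls: Sequence[LOHCall],
) -> list[CandidateGene]:
    """Assemble one candidate per (gene, sample) with both hits present.

    The first hit is the lexicographically first filtered germline variant in
    the gene; a somatic second hit must be a distinct variant key.  Output is
    sorted by (gene, sample).
    """
    germ_by_key: dict[tuple[str, str], list[VariantRecord]] = {}
    for v in germline_hits:
        germ_by_key.setdefault((v.gene, v.sample_id), []).append(v)
    som_by_key: dict[tuple[str, str], list[VariantRecord]] = {}
    for v in somatic_hits:
        som_by_key.setdefault((v.gene, v.sample_id), []).append(v)
    loh_by_key: dict[tuple[str, str], LOHCall] = {
        (c.gene, c.sample_id): c for c in loh_calls if c.is_loh
    }

    candidates: list[CandidateGene] = []
    for (gene, sample_id) in sorted(germ_by_key):
        firsts = sorted(germ_by_key[(gene, sample_id)], key=lambda v: v.variant_key)
        first = firsts[0]
        first_keys = {v.variant_key for v in firsts}
        distinct_som = sorted(
            (
                v
                for v in som_by_key.get((gene, sample_id), [])
                if v.variant_key not in first_keys
            ),
            key=lambda v: v.variant_key,
        )
        loh = loh_by_key.get((gene, sample_id))
        if distinct_som and loh:
            cls = "both"
        elif distinct_som:
            cls = "somatic_snv"
        elif loh:
            cls = "loh"
        else:
            continue
        candidates.append(
            CandidateGene(
                gene=gene,
                sample_id=sample_id,
                first_hit=first,
                second_hit_class=cls,
                second_hit_variant=distinct_som[0] if distinct_som else None,
                loh_call=loh,
            )
        )
    return candidates


def summarize_candidates(candidates: Sequence[CandidateGene]) -> dict:
    """Counts per second-hit class, first-hit type and sample.

    ``union`` is the total number of candidates and satisfies
    inclusion-exclusion over the (disjoint) classes:
    ``snv_any + loh_any - both == union``.
    """
    by_class = {"somatic_snv": 0, "loh": 0, "both": 0}
    by_first_hit = {"snv": 0, "indel": 0}
    by_sample: dict[str, int] = {}
    for c in candidates:
        by_class[c.second_hit_class] += 1
        by_first_hit["indel" if c.first_hit.is_indel else "snv"] += 1
        by_sample[c.sample_id] = by_sample.get(c.sample_id, 0) + 1
    snv_any = by_class["somatic_snv"] + by_class["both"]
    loh_any = by_class["loh"] + by_class["both"]
    return {
        "by_class": by_class,
        "by_first_hit": by_first_hit,
        "by_sample": dict(sorted(by_sample.items())),
        "snv_second_hit_any": snv_any,
        "loh_second_hit_any": loh_any,
        "union": len(candidates),
    }


def match_function_keywords(text: str, keywords: Iterable[str]) -> frozenset[str]:
    """Case-insensitive substring match; returns the keywords that hit."""
    lowered = text.lower()
    return frozenset(k for k in keywords if k.lower() in lowered)


def apply_function_prioritization(
    candidates: Sequence[CandidateGene],
    keyword_map: Mapping[str, str],
    keywords: Iterable[str] = DEFAULT_PRIORITY_KEYWORDS,
    include: Iterable[str] = (),
    exclude: Iterable[str] = (),
) -> list[CandidateGene]:
    """Annotate candidates with function-keyword priority flags.

    Nothing is removed: candidates whose gene's function text (from
    ``keyword_map``) matches any keyword gain a ``function:<keyword>`` flag;
    user ``include``/``exclude`` lists add ``user_include``/``user_exclude``
    flags.  Output is sorted flagged-first, then (gene, sample).
    """
    include = set(include)
    exclude = set(exclude)
    keywords = tuple(keywords)
    out: list[CandidateGene] = []
    for c in candidates:
        flags = set(c.priority_flags)
        if c.gene in keyword_map:
            matched = match_function_keywords(keyword_map[c.gene], keywords)
            flags.update(f"function:{k}" for k in matched)
        else:
            logger.info("gene %s absent from function map; no flag", c.gene)
        if c.gene in include:
            flags.add("user_include")
        if c.gene in exclude:
            flags.add("user_exclude")
        if (
            c.loh_call is not None
            and c.loh_call.second_hit_allele_retains_germline_variant
        ):
            flags.add("wild_type_allele_lost")
        out.append(replace(c, priority_flags=frozenset(flags)))
    return sorted(
        out,
        key=lambda c: (not any(f.startswith("function:") for f in c.priority_flags),
                       c.gene, c.sample_id),
    )


def flag_gene_functions(
    keyword_map: Mapping[str, str], keywords: Iterable[str]
) -> dict[str, bool]:
    """Per-gene keyword match over a gene -> function-text map."""
    return {
        gene: bool(match_function_keywords(text, keywords))
        for gene, text in keyword_map.items()
    }


def load_bundled_function_map() -> dict[str, str]:
    """Bundled example gene -> protein-function annotation map (16 genes)."""
    ref = resources.files("twohitpipe").joinpath("data/candidate_functions.tsv")
    mapping: dict[str, str] = {}
    with ref.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            mapping[row["gene"]] = row["protein_function"]
    return mapping


def write_candidate_table(
    candidates: Sequence[CandidateGene], path: str | Path
) -> None:
    """Candidate TSV: gene, sample, HGVS-like variant string, predictor vote
    as ``n/6``, population frequency as ``k/N``, second-hit class, flags."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene", "sample_id", "first_hit", "path_tools", "pop_freq",
             "second_hit_class", "second_hit", "priority_flags"]
        )
        for c in candidates:
            v = c.first_hit
            hgvs_like = f"{v.chrom}:g.{v.pos}{v.ref}>{v.alt}"
            path_tools = (
                "FS" if v.consequence.value == "truncating"
                else f"{_n_predictor_pass(v)}/6"
            )
            second = ""
            if c.second_hit_variant is not None:
                sv = c.second_hit_variant
                second = f"{sv.chrom}:g.{sv.pos}{sv.ref}>{sv.alt}"
            writer.writerow(
                [
                    c.gene,
                    c.sample_id,
                    hgvs_like,
                    path_tools,
                    format_allele_fraction(v.pop_allele_count, v.pop_allele_number),
                    c.second_hit_class,
                    second,
                    ";".join(sorted(c.priority_flags)),
                ]
            )
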