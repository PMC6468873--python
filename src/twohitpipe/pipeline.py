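"""End-to-end orchestration over a cohort directory.

The cohort layout is the one :func:`twohitpipe.synthetic.generate_cohort`
emits (and that real inputs can be arranged into): a manifest, a gene BED,
a reference signature matrix and per-sample variant/het-site/coverage
tables.  Every stage writes plain TSV/BED/JSON so runs are resumable and
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .core import (
    Origin,
    qc_pass,
    read_gene_intervals,
    read_manifest,
    read_site_depths,
    read_variant_table,
)
from .filtering import (
    FilterConfig,
    germline_filter_trace,
    germline_site_depths,
    somatic_filter_trace,
    write_filter_trace,
)
from .loh import (
    LOHParams,
    call_gene_loh,
    filter_het_sites,
    segment_vaf,
    write_gene_calls,
    write_segments_bed,
    write_segments_tsv,
)
from .signatures import (
    build_catalog,
    compute_burden,
    load_signature_matrix,
    refit_signatures,
    write_catalogs,
    write_exposures,
)
from .synthetic import read_catalog_snvs
from .twohit import (
    DEFAULT_PRIORITY_KEYWORDS,
    apply_function_prioritization,
    pair_two_hits,
    summarize_candidates,
    write_candidate_table,
)

__all__ = ["RunConfig", "PipelineError", "StageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Configuration problem detected before any compute."""


class StageError(RuntimeError):
    """A stage failed; names the stage and the offending sample."""

    def __init__(self, stage: str, sample_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample_id!r}: {cause}")
        self.stage = stage
        self.sample_id = sample_id


@dataclass
class RunConfig:
    cohort_dir: Path
    outdir: Path
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    loh_params: LOHParams = field(default_factory=LOHParams)
    keyword_map: dict[str, str] = field(default_factory=dict)
    keywords: tuple[str, ...] = DEFAULT_PRIORITY_KEYWORDS
    with_signatures: bool = True
    seed: int = 0

    def validate(self) -> None:
        self.cohort_dir = Path(self.cohort_dir)
        self.outdir = Path(self.outdir)
        for name in ("manifest.yaml", "genes.bed"):
            if not (self.cohort_dir / name).exists():
                raise PipelineError(f"missing cohort input {name!r} in {self.cohort_dir}")
        if self.with_signatures and not (self.cohort_dir / "signatures.tsv").exists():
            raise PipelineError(
                "signatures stage enabled but signatures.tsv is missing "
                f"from {self.cohort_dir}"
            )


def _read_coverage(path: Path) -> dict[tuple[str, int], int]:
    coverage: dict[tuple[str, int], int] = {}
    if not path.exists():
        return coverage
    with open(path) as fh:
        next(fh)
        for line in fh:
            chrom, pos, depth = line.rstrip("\n").split("\t")
            coverage[(chrom, int(pos))] = int(depth)
    return coverage


def run_pipeline(config: RunConfig) -> dict:
    """qc -> filter -> loh -> twohit -> signatures, writing per-stage TSVs
    and a machine-readable run manifest; returns the summary report dict."""
    config.validate()
    config.outdir.mkdir(parents=True, exist_ok=True)
    cohort = config.cohort_dir

    manifests = read_manifest(cohort / "manifest.yaml")
    intervals = read_gene_intervals(cohort / "genes.bed")
    passing = [m for m in manifests if qc_pass(m)]
    failed_qc = [m.sample_id for m in manifests if not qc_pass(m)]
    logger.info("QC: %d/%d samples pass", len(passing), len(manifests))

    loh_params = LOHParams(
        **{**config.loh_params.__dict__, "seed": config.seed}
    )

    all_candidates = []
    burden_rows = []
    exposures = []
    catalogs = []
    S = (
        load_signature_matrix(cohort / "signatures.tsv")
        if config.with_signatures
        else None
    )

    for m in passing:
        sid = m.sample_id
        sdir = config.outdir / "samples" / sid
        sdir.mkdir(parents=True, exist_ok=True)
        try:
            germline = read_variant_table(cohort / m.germline_path, Origin.GERMLINE)
            somatic = read_variant_table(cohort / m.tumor_path, Origin.SOMATIC)
            sites = read_site_depths(cohort / "samples" / sid / "het_sites.tsv")
            coverage = _read_coverage(cohort / "samples" / sid / "germline_coverage.tsv")
        except Exception as exc:  # noqa: BLE001 - surfaced with stage context
            raise StageError("read", sid, exc) from exc

        try:
            germ_trace = germline_filter_trace(germline, config.filter_config)
            germ_hits = [v for v, fails in germ_trace if not fails]
            depths = germline_site_depths(germline)
            for s in sites:
                key = (s.chrom, s.pos)
                depths[key] = max(depths.get(key, 0), s.germ_depth)
            for key, depth in coverage.items():
                depths[key] = max(depths.get(key, 0), depth)
            som_trace = somatic_filter_trace(
                somatic, germline, config.filter_config, germline_depths=depths
            )
            som_hits = [v for v, fails in som_trace if not fails]
            write_filter_trace(germ_trace, sdir / "germline_filter_trace.tsv")
            write_filter_trace(som_trace, sdir / "somatic_filter_trace.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("filter", sid, exc) from exc

        try:
            het = filter_het_sites(sites, loh_params)
            segments = segment_vaf(het, loh_params)
            tumor_vaf = {(s.chrom, s.pos): s.tum_vaf for s in het if s.tum_depth > 0}
            loh_calls = call_gene_loh(segments, intervals, germ_hits, tumor_vaf)
            loh_calls = [c for c in loh_calls if c.sample_id in ("", sid)]
            loh_calls = [
                type(c)(c.gene, sid, c.is_loh, c.supporting_segment,
                        c.second_hit_allele_retains_germline_variant)
                for c in loh_calls
            ]
            write_segments_tsv(segments, sdir / "loh_segments.tsv")
            write_segments_bed(segments, sdir / "loh_segments.bed")
            write_gene_calls(loh_calls, sdir / "loh_gene_calls.tsv")
        except Exception as exc:
            raise StageError("loh", sid, exc) from exc

        try:
            candidates = pair_two_hits(germ_hits, som_hits, loh_calls)
            candidates = apply_function_prioritization(
                candidates, config.keyword_map, config.keywords
            )
            all_candidates.extend(candidates)
        except Exception as exc:
            raise StageError("twohit", sid, exc) from exc

        if config.with_signatures:
            try:
                snvs = read_catalog_snvs(cohort / "samples" / sid / "catalog_snvs.tsv")
                catalog, _dropped = build_catalog(sid, snvs)
                catalogs.append(catalog)
                burden = compute_burden(catalog)
                burden_rows.append(burden)
                if catalog.n_snv > 0:
                    exposures.append(refit_signatures(catalog, S))
            except Exception as exc:
                raise StageError("signatures", sid, exc) from exc

    write_candidate_table(all_candidates, config.outdir / "candidates.tsv")
    summary = summarize_candidates(all_candidates)
    if catalogs:
        write_catalogs(catalogs, config.outdir / "catalogs.tsv")
        write_exposures(exposures, config.outdir / "exposures.tsv")
    with open(config.outdir / "burden.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "n_snv", "mutations_per_mb", "class"])
        for b in burden_rows:
            writer.writerow([b.sample_id, b.n_snv, repr(b.mutations_per_mb), b.burden_class])

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_samples": len(manifests),
        "n_samples_analyzed": len(passing),
        "qc_failed_samples": failed_qc,
        "candidate_summary": summary,
        "n_hypermutated": sum(b.burden_class != "normal" for b in burden_rows),
        "n_ultrahypermutated": sum(
            b.burden_class == "ultrahypermutated" for b in burden_rows
        ),
        "thresholds": {
            "filter": config.filter_config.__dict__,
            "loh": loh_params.__dict__,
        },
    }
    with open(config.outdir / "run_manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
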