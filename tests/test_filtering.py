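import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twohitpipe.core import Consequence, Origin, PREDICTOR_NAMES
from twohitpipe.filtering import (
    FilterConfig,
    filter_germline,
    filter_somatic,
    germline_filter_trace,
    germline_site_depths,
    score_pathogenicity,
    somatic_filter_trace,
    write_filter_trace,
)

from .conftest import make_variant


# ---------------------------------------------------------------------------
# independent per-record oracles (deliberately naive, no shared code path)


def oracle_germline_keep(v, cfg):
    if v.depth < cfg.min_depth:
        return False
    af = v.pop_allele_count / v.pop_allele_number if v.pop_allele_number else 0.0
    if af >= cfg.max_pop_af_germline:
        return False
    if v.consequence is Consequence.TRUNCATING:
        return True
    if v.consequence is Consequence.MISSENSE:
        n = sum(1 for name in PREDICTOR_NAMES if v.predictor_calls.get(name))
        return n >= cfg.min_predictors
    return False


def oracle_somatic_keep(v, germline, cfg):
    if v.depth < cfg.min_depth:
        return False
    gdepth = max(
        (g.depth for g in germline if (g.chrom, g.pos) == (v.chrom, v.pos)), default=0
    )
    if gdepth < cfg.min_depth:
        return False
    if v.depth == 0 or v.alt_depth / v.depth < cfg.min_tumor_vaf:
        return False
    if any((g.chrom, g.pos, g.ref, g.alt) == (v.chrom, v.pos, v.ref, v.alt) for g in germline):
        return False
    if v.consequence is Consequence.TRUNCATING:
        return True
    if v.consequence is Consequence.MISSENSE:
        n = sum(1 for name in PREDICTOR_NAMES if v.predictor_calls.get(name))
        return n >= cfg.min_predictors
    return False


class TestScorePathogenicity:
    def test_all_six(self):
        assert score_pathogenicity(make_variant()).n_pass == 6

    def test_three_of_six_passes_default(self):
        v = make_variant(predictors=("phylop", "cadd", "sift"))
        score = score_pathogenicity(v)
        assert score.n_pass == 3
        assert score.passing_tools == frozenset({"phylop", "cadd", "sift"})
        assert score.n_pass >= FilterConfig().min_predictors

    def test_all_false(self):
        score = score_pathogenicity(make_variant(predictors=()))
        assert score.n_pass == 0
        assert score.n_pass < FilterConfig().min_predictors

    def test_rejects_non_missense(self):
        with pytest.raises(ValueError):
            score_pathogenicity(make_variant(consequence=Consequence.TRUNCATING))


class TestGermlineCascade:
    def test_truncating_rare_kept(self):
        # frameshift, deep coverage, absent from the control repository
        v = make_variant(ref="ACTT", alt="A", consequence=Consequence.TRUNCATING,
                         depth=95, predictors=(), pop_allele_count=0,
                         pop_allele_number=60706)
        assert filter_germline([v]) == [v]

    def test_missense_6of6_rare_kept(self):
        # AF 1/60570 ~ 1.7e-5 < 0.1%
        v = make_variant(pop_allele_count=1, pop_allele_number=60570)
        assert filter_germline([v]) == [v]

    def test_synonymous_removed(self):
        v = make_variant(consequence=Consequence.SYNONYMOUS)
        assert filter_germline([v]) == []

    def test_common_removed(self):
        v = make_variant(pop_allele_count=600, pop_allele_number=60000)  # AF 1%
        assert filter_germline([v]) == []

    def test_af_boundary_strict(self):
        v = make_variant(pop_allele_count=60, pop_allele_number=60000)  # exactly 0.1%
        assert filter_germline([v]) == []

    def test_low_depth_removed(self):
        assert filter_germline([make_variant(depth=9, alt_depth=4)]) == []

    def test_origin_checked(self):
        with pytest.raises(ValueError):
            filter_germline([make_variant(origin=Origin.SOMATIC)])

    def test_trace_names_failed_rules(self):
        v = make_variant(consequence=Consequence.SYNONYMOUS, depth=5, alt_depth=2)
        ((_, failed),) = germline_filter_trace([v])
        assert set(failed) == {"min_depth", "consequence_class"}


class TestSomaticCascade:
    def _germ(self, depth=100):
        return make_variant(pos=1000, depth=depth)

    def test_vaf_boundary_inclusive(self):
        # VAF exactly 20% with both depths >= 10x, missense 4/6
        v = make_variant(origin=Origin.SOMATIC, pos=1000, ref="G", alt="A",
                         depth=100, alt_depth=20,
                         predictors=("phylop", "sift", "polyphen2", "cadd"))
        assert filter_somatic([v], [self._germ()]) == [v]

    def test_low_vaf_removed(self):
        v = make_variant(origin=Origin.SOMATIC, pos=1000, ref="G", alt="A",
                         depth=100, alt_depth=5)
        assert filter_somatic([v], [self._germ()]) == []

    def test_low_germline_depth_removed(self):
        # VAF 0.5 but matched normal at 6x fails the dual >=10x rule
        v = make_variant(origin=Origin.SOMATIC, pos=1000, ref="G", alt="A",
                         depth=100, alt_depth=50)
        assert filter_somatic([v], [self._germ(depth=6)]) == []

    def test_absent_germline_coverage_is_depth_zero(self):
        v = make_variant(origin=Origin.SOMATIC, pos=999, ref="G", alt="A",
                         depth=100, alt_depth=50)
        assert filter_somatic([v], [self._germ()]) == []

    def test_exact_germline_match_excluded(self):
        germ = self._germ()
        v = make_variant(origin=Origin.SOMATIC, pos=1000, depth=100, alt_depth=50)
        assert v.variant_key == germ.variant_key
        assert filter_somatic([v], [germ]) == []

    def test_explicit_depth_map(self):
        v = make_variant(origin=Origin.SOMATIC, pos=55, ref="G", alt="A",
                         depth=100, alt_depth=50)
        kept = filter_somatic([v], [], germline_depths={("ctg001", 55): 30})
        assert kept == [v]

    def test_site_depth_map_from_records(self):
        depths = germline_site_depths([self._germ(depth=80), self._germ(depth=90)])
        assert depths == {("ctg001", 1000): 90}


def _variant_pool(origin):
    """Deterministic grid of records covering every rule combination."""
    pool = []
    i = 0
    for consequence in Consequence:
        for depth in (5, 10, 60):
            for alt_frac in (0.05, 0.20, 0.5):
                for n_pred in (0, 3, 6):
                    for pop in ((0, 0), (1, 60570), (900, 60000)):
                        i += 1
                        pool.append(
                            make_variant(
                                pos=i * 10,
                                ref="C",
                                alt="T",
                                origin=origin,
                                consequence=consequence,
                                depth=depth,
                                alt_depth=int(depth * alt_frac),
                                predictors=PREDICTOR_NAMES[:n_pred],
                                pop_allele_count=pop[0],
                                pop_allele_number=pop[1],
                            )
                        )
    return pool


class TestOracleEquivalence:
    def test_germline_matches_naive_oracle(self):
        pool = _variant_pool(Origin.GERMLINE)
        assert len(pool) <= 200 * 2  # small cohort regime
        cfg = FilterConfig()
        expected = [v for v in pool if oracle_germline_keep(v, cfg)]
        assert filter_germline(pool, cfg) == expected

    def test_somatic_matches_naive_oracle(self):
        som = _variant_pool(Origin.SOMATIC)
        germ = [make_variant(pos=v.pos, ref="A", alt="G", depth=d)
                for v, d in zip(som[::2], itertools.cycle((5, 50)))]
        # plus one exact germline match
        germ.append(make_variant(pos=som[0].pos, ref=som[0].ref, alt=som[0].alt,
                                 consequence=som[0].consequence, depth=100))
        cfg = FilterConfig()
        expected = [v for v in som if oracle_somatic_keep(v, germ, cfg)]
        assert filter_somatic(som, germ, cfg) == expected

    @settings(max_examples=30, deadline=None)
    @given(
        min_depth=st.integers(0, 80),
        min_vaf=st.floats(0.0, 1.0),
        min_predictors=st.integers(0, 6),
        max_af=st.floats(0.0, 0.05),
    )
    def test_monotone_in_every_threshold(self, min_depth, min_vaf, min_predictors, max_af):
        """Raising any threshold never enlarges the surviving set."""
        som = _variant_pool(Origin.SOMATIC)
        germ = [make_variant(pos=v.pos, ref="A", alt="G", depth=50) for v in som]
        base = FilterConfig()
        tighter = FilterConfig(
            min_depth=max(base.min_depth, min_depth),
            min_tumor_vaf=max(base.min_tumor_vaf, min_vaf),
            min_predictors=max(base.min_predictors, min_predictors),
            max_pop_af_germline=min(base.max_pop_af_germline, max_af),
        )
        assert set(v.variant_key for v in filter_somatic(som, germ, tighter)) <= set(
            v.variant_key for v in filter_somatic(som, germ, base)
        )
        germ_pool = _variant_pool(Origin.GERMLINE)
        assert set(v.variant_key for v in filter_germline(germ_pool, tighter)) <= set(
            v.variant_key for v in filter_germline(germ_pool, base)
        )


class TestConfigAndTrace:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = FilterConfig(min_depth=15, min_tumor_vaf=0.25)
        path = tmp_path / "filter.yaml"
        cfg.to_yaml(path)
        assert FilterConfig.from_yaml(path) == cfg

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            FilterConfig(min_predictors=7)
        with pytest.raises(ValueError):
            FilterConfig(min_tumor_vaf=1.5)

    def test_trace_file(self, tmp_path):
        traced = somatic_filter_trace(
            [make_variant(origin=Origin.SOMATIC, depth=100, alt_depth=5)], []
        )
        path = tmp_path / "trace.tsv"
        write_filter_trace(traced, path)
        lines = path.read_text().splitlines()
        assert "filter_trace" in lines[0]
        assert "tumor_vaf" in lines[1] and "germline_depth" in lines[1]
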