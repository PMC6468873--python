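import numpy as np
import pytest

from twohitpipe.signatures import (
    CHANNELS,
    EmptyCatalogError,
    MutationalCatalog,
    SignatureMatrix,
    SomaticSNV,
    build_catalog,
    channel_for,
    channel_ref_alt_context,
    compute_burden,
    load_signature_matrix,
    read_catalogs,
    refit_signatures,
    write_catalogs,
    write_signature_matrix,
)
from twohitpipe.synthetic import make_reference_signatures


def catalog_of(n, sample_id="s"):
    counts = np.zeros(96, dtype=int)
    counts[: min(n, 96)] = n // 96 if n >= 96 else 0
    counts = np.full(96, n // 96, dtype=int)
    counts[0] += n - counts.sum()
    return MutationalCatalog(sample_id, counts)


class TestChannels:
    def test_96_fixed_order(self):
        assert len(CHANNELS) == 96
        assert CHANNELS[0] == "A[C>A]A"
        assert CHANNELS[-1] == "T[T>G]T"
        assert len(set(CHANNELS)) == 96

    def test_pyrimidine_direct(self):
        assert channel_for("C", "A", "ACA") == "A[C>A]A"

    def test_purine_reverse_complement(self):
        # G>T at TGT: complement strand reads A[C>A]A
        assert channel_for("G", "T", "TGT") == "A[C>A]A"

    def test_every_channel_roundtrips(self):
        for channel in CHANNELS:
            ref, alt, context = channel_ref_alt_context(channel)
            assert channel_for(ref, alt, context) == channel

    def test_rejects_ambiguous(self):
        with pytest.raises(ValueError):
            channel_for("C", "A", "NCA")
        with pytest.raises(ValueError):
            channel_for("C", "A", "AAA")  # context contradicts ref


class TestBuildCatalog:
    def test_counts_and_total(self):
        snvs = [
            SomaticSNV("c", 1, "C", "A", "ACA"),
            SomaticSNV("c", 2, "G", "T", "TGT"),  # same channel, via revcomp
            SomaticSNV("c", 3, "T", "C", "ATG"),
        ]
        catalog, dropped = build_catalog("s", snvs)
        assert dropped == 0
        assert catalog.n_snv == 3
        assert catalog.counts[CHANNELS.index("A[C>A]A")] == 2

    def test_ambiguous_context_dropped_with_tally(self):
        snvs = [SomaticSNV("c", 1, "C", "A", "NCA"), SomaticSNV("c", 2, "C", "A", "ACA")]
        with pytest.warns(UserWarning, match="dropping"):
            catalog, dropped = build_catalog("s", snvs)
        assert dropped == 1
        assert catalog.n_snv == 1

    def test_empty_input_zero_catalog(self):
        catalog, dropped = build_catalog("s", [])
        assert catalog.n_snv == 0 and dropped == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MutationalCatalog("s", np.full(96, -1))


class TestBurden:
    def test_2907_snvs_hypermutated(self):
        report = compute_burden(catalog_of(2907))
        assert report.mutations_per_mb == pytest.approx(96.9)
        assert report.burden_class == "hypermutated"

    def test_1830_snvs_normal(self):
        report = compute_burden(catalog_of(1830))
        assert report.mutations_per_mb == pytest.approx(61.0)
        assert report.burden_class == "normal"

    def test_zero(self):
        report = compute_burden(catalog_of(0))
        assert report.mutations_per_mb == 0.0
        assert report.burden_class == "normal"

    @pytest.mark.parametrize(
        "n,cls",
        [
            (2699, "normal"),          # 89.97/Mb
            (2700, "hypermutated"),    # exactly 90/Mb: boundary inclusive
            (15000, "hypermutated"),   # exactly 500/Mb: ultra is strict
            (15001, "ultrahypermutated"),
        ],
    )
    def test_class_boundaries(self, n, cls):
        assert compute_burden(catalog_of(n)).burden_class == cls


class TestRefit:
    S = make_reference_signatures()

    def test_exact_two_signature_mixture(self):
        # disjoint uniform signatures give integer-exact combinations:
        # counts = 1600*s1 + 800*s2 -> contributions (2/3, 1/3, 0), cosine 1
        matrix = np.zeros((96, 3))
        matrix[0:16, 0] = 1 / 16
        matrix[16:32, 1] = 1 / 16
        matrix[32:48, 2] = 1 / 16
        S = SignatureMatrix(("s1", "s2", "s3"), matrix)
        counts = (1600 * matrix[:, 0] + 800 * matrix[:, 1]).astype(int)
        ev = refit_signatures(MutationalCatalog("s", counts), S)
        assert ev.reconstruction_cosine == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(ev.exposures, [1600.0, 800.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(ev.contributions, [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_single_signature(self):
        counts = np.round(self.S.matrix[:, 2] * 20000).astype(int)
        ev = refit_signatures(MutationalCatalog("s", counts), self.S)
        assert ev.contributions[2] == pytest.approx(1.0, abs=1e-3)
        assert ev.reconstruction_cosine == pytest.approx(1.0, abs=1e-5)

    def test_empty_catalog_error(self):
        with pytest.raises(EmptyCatalogError):
            refit_signatures(catalog_of(0), self.S)

    def test_sampled_mixture_recovery(self):
        """n=5000 draws from a 0.8/0.2 mixture of well-separated signatures:
        recovered contributions within +/- 0.03 of planted."""
        rng = np.random.default_rng(2024)
        mix = 0.8 * self.S.matrix[:, 0] + 0.2 * self.S.matrix[:, 1]
        counts = rng.multinomial(5000, mix)
        ev = refit_signatures(MutationalCatalog("s", counts), self.S)
        assert ev.contributions[0] == pytest.approx(0.8, abs=0.03)
        assert ev.contributions[1] == pytest.approx(0.2, abs=0.03)

    def test_nnls_optimality_vs_random_perturbations(self):
        """Returned exposures beat 1000 random non-negative perturbations."""
        rng = np.random.default_rng(7)
        counts = rng.multinomial(3000, (self.S.matrix @ np.array([0.5, 0.2, 0.1, 0.1, 0.1])))
        catalog = MutationalCatalog("s", counts)
        ev = refit_signatures(catalog, self.S)
        residual = np.linalg.norm(self.S.matrix @ ev.exposures - counts)
        for _ in range(1000):
            perturbed = np.maximum(ev.exposures + rng.normal(0, 10, self.S.k), 0)
            assert np.linalg.norm(self.S.matrix @ perturbed - counts) >= residual - 1e-9

    def test_kkt_active_gradient_zero(self):
        rng = np.random.default_rng(8)
        counts = rng.multinomial(4000, (self.S.matrix @ np.array([0.6, 0.4, 0, 0, 0])))
        ev = refit_signatures(MutationalCatalog("s", counts), self.S)
        gradient = self.S.matrix.T @ (self.S.matrix @ ev.exposures - counts)
        active = ev.exposures > 0
        assert np.all(np.abs(gradient[active]) < 1e-6 * max(1.0, np.abs(gradient).max()))

    def test_scale_invariance_of_contributions(self):
        rng = np.random.default_rng(9)
        counts = rng.multinomial(900, self.S.matrix @ np.array([0.7, 0.1, 0.1, 0.05, 0.05]))
        ev1 = refit_signatures(MutationalCatalog("s", counts), self.S)
        ev5 = refit_signatures(MutationalCatalog("s", counts * 5), self.S)
        assert ev5.contributions == pytest.approx(ev1.contributions, abs=1e-9)

    def test_error_shrinks_with_sample_size(self):
        """Mean |contribution error| at n=500 >= at n=5000, over 20 seeds."""
        planted = np.array([0.8, 0.2, 0.0, 0.0, 0.0])
        mix = self.S.matrix @ planted

        def mean_error(n):
            errors = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                counts = rng.multinomial(n, mix)
                ev = refit_signatures(MutationalCatalog("s", counts), self.S)
                errors.append(np.abs(ev.contributions - planted).mean())
            return np.mean(errors)

        assert mean_error(500) >= mean_error(5000)


class TestSignatureMatrixValidation:
    def test_columns_must_sum_to_one(self):
        bad = np.full((96, 2), 1.0 / 96)
        bad[:, 1] *= 2
        with pytest.raises(ValueError, match="sum to 1"):
            SignatureMatrix(("a", "b"), bad)

    def test_negative_rejected(self):
        bad = np.full((96, 1), 1.0 / 96)
        bad[0] = -bad[0]
        with pytest.raises(ValueError):
            SignatureMatrix(("a",), bad)


class TestIO:
    def test_signature_matrix_roundtrip(self, tmp_path):
        S = make_reference_signatures()
        path = tmp_path / "sig.tsv"
        write_signature_matrix(S, path)
        back = load_signature_matrix(path)
        assert back.names == S.names
        np.testing.assert_allclose(back.matrix, S.matrix, atol=1e-12)

    def test_cosmic_layout(self, tmp_path):
        S = make_reference_signatures(k=2)
        path = tmp_path / "cosmic.tsv"
        with open(path, "w") as fh:
            fh.write("Substitution Type\tTrinucleotide\tSomatic Mutation Type\t"
                     "Signature 1\tSignature 2\n")
            for i, channel in enumerate(CHANNELS):
                sub = channel[2:5]
                tri = channel[0] + channel[2] + channel[6]
                fh.write(
                    f"{sub}\t{tri}\t{channel}\t"
                    f"{float(S.matrix[i, 0])!r}\t{float(S.matrix[i, 1])!r}\n"
                )
        back = load_signature_matrix(path)
        assert back.names == ("Signature 1", "Signature 2")
        np.testing.assert_allclose(back.matrix, S.matrix, atol=1e-12)

    def test_catalog_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        catalogs = [
            MutationalCatalog("a", rng.integers(0, 50, 96)),
            MutationalCatalog("b", rng.integers(0, 50, 96)),
        ]
        path = tmp_path / "catalogs.tsv"
        write_catalogs(catalogs, path)
        back = read_catalogs(path)
        assert [c.sample_id for c in back] == ["a", "b"]
        for orig, rt in zip(catalogs, back):
            np.testing.assert_array_equal(orig.counts, rt.counts)
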