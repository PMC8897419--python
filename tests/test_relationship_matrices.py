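import numpy as np
import pytest

import domgblup as dg
from domgblup.data_io import MISSING
from domgblup.errors import ConditioningError, DataError
from domgblup.relationship_matrices import RelationshipMatrix
from domgblup.simulate import preset

from conftest import make_genotypes


def freqs(locus_ids, p):
    return dg.AlleleFrequencies(list(locus_ids), np.asarray(p, dtype=float))


class TestAdditiveG:
    def test_single_locus_hand_computation(self):
        g = make_genotypes([[0], [2]])
        G = dg.build_additive_G(g, freqs(["L0"], [0.5]))
        assert G.denominator == pytest.approx(0.5)
        np.testing.assert_allclose(G.values, [[2, -2], [-2, 2]])

    def test_centered_heterozygotes_vanish(self):
        g = make_genotypes([[1], [1]])
        G = dg.build_additive_G(g, freqs(["L0"], [0.5]))
        np.testing.assert_allclose(G.values, 0.0)

    def test_duplicate_individuals_identical_rows(self, rng):
        codes = rng.integers(0, 3, size=(4, 10))
        codes[3] = codes[0]
        g = make_genotypes(codes)
        G = dg.build_additive_G(g, dg.allele_frequencies(g))
        np.testing.assert_allclose(G.values[0], G.values[3])

    def test_monomorphic_denominator_error(self):
        g = make_genotypes([[2], [2]])
        with pytest.raises(DataError):
            dg.build_additive_G(g, freqs(["L0"], [1.0]))

    def test_column_centering_property(self, rng):
        codes = rng.integers(0, 3, size=(40, 15)).astype(np.int8)
        g = make_genotypes(codes)
        f = dg.allele_frequencies(g)
        M = dg.impute_missing(g, f) - 2.0 * f.p
        assert np.abs(M.mean(axis=0)).max() < 1e-10


class TestDominanceD:
    def test_two_heterozygotes(self):
        g = make_genotypes([[1], [1]])
        D = dg.build_dominance_D(g, freqs(["L0"], [0.5]))
        np.testing.assert_allclose(D.values, [[1, 1], [1, 1]])

    def test_homozygote_vs_heterozygote(self):
        m = 6
        codes = np.vstack([np.zeros(m), np.ones(m)]).astype(np.int8)
        g = make_genotypes(codes)
        D = dg.build_dominance_D(g, freqs(g.locus_ids, [0.5] * m))
        assert D.values[0, 1] == pytest.approx(-1.0)

    def test_rare_locus_limit(self):
        # p -> 0 contributes ~0 to numerator and denominator
        g = make_genotypes([[0, 1], [0, 1], [1, 1], [0, 1]])
        f = freqs(["L0", "L1"], [1e-4, 0.5])
        D = dg.build_dominance_D(g, f)
        assert D.denominator == pytest.approx((2 * 0.5 * 0.5) ** 2, rel=1e-3)

    def test_exact_hwe_columns_have_zero_mean(self):
        # counts (4, 8, 4) at p = 0.5: H column mean is exactly 0
        codes = np.repeat([0, 1, 2], [4, 8, 4]).astype(np.int8)[:, None]
        g = make_genotypes(codes)
        f = freqs(["L0"], [0.5])
        p = 0.5
        coef = {0: -2 * p**2, 1: 2 * p * (1 - p), 2: -2 * (1 - p) ** 2}
        H = np.array([coef[c] for c in codes[:, 0]])
        assert abs(H.mean()) < 1e-14
        D = dg.build_dominance_D(g, f)
        assert np.isfinite(D.values).all()


class TestCombinedGad:
    def test_reduces_to_additive_when_weights_are_one(self, rng):
        codes = rng.integers(0, 3, size=(25, 12)).astype(np.int8)
        codes[2, 3] = MISSING
        g = make_genotypes(codes)
        f = dg.allele_frequencies(g)
        coding = dg.DominanceCoding(
            list(g.locus_ids),
            np.full(g.m, np.nan),
            np.ones(g.m),
            np.zeros(g.m, bool),
            np.ones(g.m, bool),
        )
        coded = dg.apply_coding(g, coding)
        Gad = dg.build_combined_Gad(coded, f, list(g.individual_ids), flip=coding.flip)
        G = dg.build_additive_G(g, f)
        np.testing.assert_allclose(Gad.values, G.values, atol=1e-12)

    def test_complete_dominance_hand_computation(self):
        g = make_genotypes([[1], [0]])
        coding = dg.DominanceCoding(
            ["L0"], np.array([2.0]), np.array([2.0]),
            np.array([False]), np.array([False]),
        )
        coded = dg.apply_coding(g, coding)
        Gad = dg.build_combined_Gad(coded, freqs(["L0"], [0.5]),
                                    list(g.individual_ids), flip=coding.flip)
        np.testing.assert_allclose(Gad.values, [[2, -2], [-2, 2]])

    def test_zero_weight_merges_het_with_low_homozygote(self):
        g = make_genotypes([[0], [1], [2]])
        coding = dg.DominanceCoding(
            ["L0"], np.array([0.0]), np.array([0.0]),
            np.array([False]), np.array([False]),
        )
        coded = dg.apply_coding(g, coding)
        Gad = dg.build_combined_Gad(coded, freqs(["L0"], [1.0 / 3]),
                                    list(g.individual_ids), flip=coding.flip)
        np.testing.assert_allclose(Gad.values[0], Gad.values[1])

    def test_flip_centering_uses_coded2_allele(self):
        # flipped locus: code 2 tags the former A1 allele, frequency 1 - p
        g = make_genotypes([[0], [2], [2], [2]])
        p = dg.allele_frequencies(g)  # p = 0.75
        coding = dg.DominanceCoding(
            ["L0"], np.array([1.5]), np.array([1.5]),
            np.array([True]), np.array([False]),
        )
        coded = dg.apply_coding(g, coding)
        Gad = dg.build_combined_Gad(coded, p, list(g.individual_ids), flip=coding.flip)
        M = coded[:, 0] - 2 * 0.25
        expected = np.outer(M, M) / (2 * 0.75 * 0.25)
        np.testing.assert_allclose(Gad.values, expected)


class TestBruteForceOracle:
    def brute(self, coded, centre, denom):
        n = coded.shape[0]
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for l in range(coded.shape[1]):
                    acc += (coded[i, l] - centre[l]) * (coded[j, l] - centre[l])
                out[i, j] = acc / denom
        return out

    def test_additive_matches_double_sum(self, rng):
        for _ in range(3):
            n, m = rng.integers(3, 10), rng.integers(2, 20)
            codes = rng.integers(0, 3, size=(n, m)).astype(np.int8)
            g = make_genotypes(codes)
            f = dg.allele_frequencies(g)
            if not (2 * f.p * (1 - f.p)).sum() > 0:
                continue
            G = dg.build_additive_G(g, f)
            expected = self.brute(codes.astype(float), 2 * f.p,
                                  (2 * f.p * (1 - f.p)).sum())
            np.testing.assert_allclose(G.values, expected, atol=1e-10)

    def test_dominance_matches_double_sum(self, rng):
        n, m = 8, 10
        codes = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        g = make_genotypes(codes)
        f = dg.allele_frequencies(g)
        p, q = f.p, 1 - f.p
        coef = np.stack([-2 * p**2, 2 * p * q, -2 * q**2])
        H = np.choose(codes, coef)
        expected = self.brute(H, np.zeros(m), ((2 * p * q) ** 2).sum())
        D = dg.build_dominance_D(g, f)
        np.testing.assert_allclose(D.values, expected, atol=1e-10)


class TestEnsureInvertible:
    def test_generic_simulated_matrix_needs_no_ridge(self, rng):
        # centring by the generating frequencies keeps G positive definite;
        # sample-frequency centring makes G exactly singular (ones-vector
        # null space), which the ridge test below covers
        n, m = 50, 500
        p = rng.uniform(0.1, 0.5, size=m)
        codes = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        g = make_genotypes(codes)
        G = dg.build_additive_G(g, freqs(g.locus_ids, p))
        out = dg.ensure_invertible(G)
        assert out.ridge_added == 0.0

    def test_sample_centred_matrix_is_singular(self, rng):
        codes = rng.integers(0, 3, size=(30, 200)).astype(np.int8)
        g = make_genotypes(codes)
        G = dg.build_additive_G(g, dg.allele_frequencies(g))
        # exact column centring puts the ones-vector in the null space
        assert np.abs(G.values @ np.ones(G.n)).max() < 1e-8

    def test_singular_matrix_gets_ridge(self):
        vals = np.ones((3, 3))
        R = RelationshipMatrix("G_additive", vals, ["a", "b", "c"], 1.0)
        out = dg.ensure_invertible(R)
        assert out.ridge_added > 0.0
        np.linalg.cholesky(out.values)

    def test_identity_untouched(self):
        R = RelationshipMatrix("G_additive", np.eye(4), list("abcd"), 1.0)
        out = dg.ensure_invertible(R)
        assert out.ridge_added == 0.0
        np.testing.assert_array_equal(out.values, np.eye(4))

    def test_hopeless_matrix_raises(self):
        R = RelationshipMatrix("G_additive", -1e4 * np.eye(3), list("abc"), 1.0)
        with pytest.raises(ConditioningError):
            dg.ensure_invertible(R)


class TestHWEScale:
    def test_mean_diagonal_near_one(self):
        ds = dg.simulate_dataset(
            preset("additive", n_individuals=500, n_loci=2000), seed=9
        )
        g = ds.genotypes
        f = dg.allele_frequencies(g)
        G = dg.build_additive_G(g, f)
        assert 0.9 < np.mean(np.diag(G.values)) < 1.1
        off = G.values[~np.eye(G.n, dtype=bool)]
        assert -0.05 < off.mean() < 0.05
        # purely additive trait with weights forced to 1: same bounds for G_ad
        y = dg.correct_fixed_effects(ds.phenotypes)
        cm = dg.genotype_class_means(g, y)
        coding = dg.estimate_dominance(cm, min_class_count=np.inf)
        Gad = dg.build_combined_Gad(dg.apply_coding(g, coding), f,
                                    list(g.individual_ids), flip=coding.flip)
        assert 0.9 < np.mean(np.diag(Gad.values)) < 1.1
        offad = Gad.values[~np.eye(Gad.n, dtype=bool)]
        assert -0.05 < offad.mean() < 0.05


class TestSerialization:
    def test_text_export(self, tmp_path, rng):
        codes = rng.integers(0, 3, size=(5, 8)).astype(np.int8)
        g = make_genotypes(codes)
        G = dg.build_additive_G(g, dg.allele_frequencies(g))
        path = tmp_path / "G.txt"
        G.to_text(path)
        lines = path.read_text().splitlines()
        assert lines[1].split("\t") == g.individual_ids
        assert len(lines) == 2 + g.n
        last = [float(v) for v in lines[-1].split("\t")]
        np.testing.assert_allclose(last, G.values[-1], rtol=1e-12)
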