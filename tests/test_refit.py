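import numpy as np
import pytest

from sigstrat import (
    SignatureMatrix,
    attribute_with_ci,
    decompose_denovo,
    flat_signature,
    nnls_fit,
    synthetic_signatures,
)
from sigstrat.schemas import SBS96


def _with_flat(pool):
    flat = flat_signature(pool.schema)
    return SignatureMatrix(pool.schema, pool.signature_ids + ["FLAT"],
                           np.vstack([pool.profiles, flat.profiles]))


class TestNnlsFit:
    def test_exact_member_recovers_scale(self, pool96):
        spectrum = 100.0 * pool96.profiles[1]
        act = nnls_fit(spectrum, pool96)
        expected = np.zeros(4)
        expected[1] = 100.0
        np.testing.assert_allclose(act, expected, atol=1e-8)

    def test_orthogonal_spectrum_gets_zero(self):
        # references supported on the first half, spectrum on the second
        profiles = np.zeros((2, 96))
        profiles[0, :10] = 0.1
        profiles[1, 10:20] = 0.1
        ref = SignatureMatrix(SBS96, ["a", "b"], profiles)
        spectrum = np.zeros(96)
        spectrum[50:60] = 30.0
        assert nnls_fit(spectrum, ref) == pytest.approx(np.zeros(2))

    def test_scale_equivariance(self, pool96):
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(4))
        y = rng.multinomial(500, w @ pool96.profiles).astype(float)
        a1 = nnls_fit(y, pool96)
        a7 = nnls_fit(7 * y, pool96)
        np.testing.assert_allclose(a7, 7 * a1, rtol=1e-9, atol=1e-9)

    def test_schema_mismatch_raises(self, pool96):
        with pytest.raises(ValueError, match="channels"):
            nnls_fit(np.ones(384), pool96)


class TestDecomposeDenovo:
    def test_pure_reference_is_100_percent(self, pool96):
        denovo = SignatureMatrix(SBS96, ["D1"], pool96.profiles[:1])
        df = decompose_denovo(denovo, pool96)
        top = df.set_index("reference").loc[pool96.signature_ids[0]]
        assert top["weight_pct"] == pytest.approx(100.0, abs=1e-6)
        assert top["reconstruction_cosine"] == pytest.approx(1.0)

    def test_exact_mixture_of_disjoint_references(self):
        profiles = np.zeros((2, 96))
        profiles[0, :48] = 1 / 48
        profiles[1, 48:] = 1 / 48
        ref = SignatureMatrix(SBS96, ["A", "B"], profiles)
        mix = 0.7 * profiles[0] + 0.3 * profiles[1]
        denovo = SignatureMatrix(SBS96, ["D"], mix[None, :])
        df = decompose_denovo(denovo, ref).set_index("reference")
        assert df.loc["A", "weight_pct"] == pytest.approx(70.0, abs=1e-6)
        assert df.loc["B", "weight_pct"] == pytest.approx(30.0, abs=1e-6)

    def test_noisy_three_way_mixture_recovered_within_two_points(self):
        pool = synthetic_signatures(3, "SBS96", seed=9)
        rng = np.random.default_rng(9)
        w = rng.dirichlet(np.ones(3) * 5)
        noisy = rng.multinomial(50_000, w @ pool.profiles).astype(float)
        denovo = SignatureMatrix(SBS96, ["D"], (noisy / noisy.sum())[None, :])
        df = decompose_denovo(denovo, pool).set_index("reference")
        for sig, true_w in zip(pool.signature_ids, w):
            assert df.loc[sig, "weight_pct"] == pytest.approx(
                100 * true_w, abs=2.0)


class TestAttributeWithCi:
    def test_planted_single_signature_prunes_the_decoy(self):
        pool = synthetic_signatures(2, "SBS96", seed=30,
                                    max_pairwise_cosine=0.4)
        rng = np.random.default_rng(30)
        y = rng.multinomial(1000, pool.profiles[0])
        fit = attribute_with_ci(y, pool, n_bootstrap=200, seed=1)
        a_id, b_id = pool.signature_ids
        assert fit.pruned == [b_id]
        assert fit.retained == [a_id]
        i = fit.signature_ids.index(a_id)
        assert fit.ci_low[i] <= 1000 <= fit.ci_high[i]
        assert fit.residual_cosine > 0.95

    def test_low_burden_flat_spectrum_is_mostly_pruned(self):
        pool = synthetic_signatures(10, "SBS96", seed=12)
        rng = np.random.default_rng(12)
        y = rng.multinomial(20, np.full(96, 1 / 96))
        fit = attribute_with_ci(y, pool, n_bootstrap=100, seed=2)
        assert len(fit.pruned) >= 8

    def test_sparsity_increases_as_burden_decreases(self):
        pool = synthetic_signatures(6, "SBS96", seed=14)
        rng = np.random.default_rng(14)
        w = rng.dirichlet(np.ones(6))
        p = w @ pool.profiles
        retained = {}
        for burden in (30, 3000):
            y = rng.multinomial(burden, p)
            fit = attribute_with_ci(y, pool, n_bootstrap=100, seed=3)
            retained[burden] = len(fit.retained)
        assert retained[30] <= retained[3000]

    def test_invariants_of_the_fit_result(self, pool96):
        rng = np.random.default_rng(5)
        y = rng.multinomial(800, pool96.profiles[2])
        fit = attribute_with_ci(y, pool96, n_bootstrap=100, seed=4)
        pruned = set(fit.pruned)
        for i, sig in enumerate(fit.signature_ids):
            if sig in pruned:
                assert fit.activities[i] == 0.0
            else:
                assert fit.ci_low[i] <= fit.activities[i] <= fit.ci_high[i]
                assert fit.ci_low[i] > 0
        assert (fit.activities >= 0).all()

    def test_pruning_barely_degrades_reconstruction(self):
        pool = synthetic_signatures(5, "SBS96", seed=18)
        rng = np.random.default_rng(18)
        for _ in range(10):
            w = rng.dirichlet(np.ones(3))
            sub = pool.profiles[:3]
            y = rng.multinomial(800, w @ sub).astype(float)
            initial = nnls_fit(y, pool)
            recon0 = initial @ pool.profiles
            cos0 = y @ recon0 / (np.linalg.norm(y) * np.linalg.norm(recon0))
            fit = attribute_with_ci(y, pool, n_bootstrap=100, seed=6)
            assert fit.residual_cosine >= cos0 - 0.02

    def test_input_validation(self, pool96):
        with pytest.raises(ValueError, match="positive"):
            attribute_with_ci(np.zeros(96), pool96)
        with pytest.raises(ValueError, match="n_bootstrap"):
            attribute_with_ci(np.ones(96), pool96, n_bootstrap=10)

    def test_grid_search_oracle_small(self):
        # NNLS residual is never beaten by an integer-step grid search
        pool = synthetic_signatures(3, "SBS96", seed=25)
        rng = np.random.default_rng(25)
        for _ in range(5):
            w = rng.dirichlet(np.ones(3))
            y = rng.multinomial(500, w @ pool.profiles).astype(float)
            act = nnls_fit(y, pool)
            S = pool.profiles  # 3 x 96
            G = S @ S.T
            c = S @ y
            yy = y @ y
            best = np.inf
            a1 = np.arange(0, 700)
            a2 = np.arange(0, 700)
            A1, A2 = np.meshgrid(a1, a2, indexing="ij")
            a3 = np.clip((c[2] - A1 * G[0, 2] - A2 * G[1, 2]) / G[2, 2],
                         0, None)
            obj = (yy + A1**2 * G[0, 0] + A2**2 * G[1, 1] + a3**2 * G[2, 2]
                   + 2 * A1 * A2 * G[0, 1] + 2 * A1 * a3 * G[0, 2]
                   + 2 * A2 * a3 * G[1, 2]
                   - 2 * (A1 * c[0] + A2 * c[1] + a3 * c[2]))
            best = obj.min()
            res_nnls = np.sum((y - act @ S) ** 2)
            assert res_nnls <= best + 1e-6
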