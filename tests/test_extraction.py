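from types import SimpleNamespace

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from sigstrat import MutationCatalog, bootstrap_catalog, extract, nmf_kl
from sigstrat.extraction import select_k_from_records
from sigstrat.schemas import SBS96
from sigstrat.synthetic import synthetic_signatures


def _matched_cosines(A, B):
    An = A / np.linalg.norm(A, axis=1, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=1, keepdims=True)
    cos = An @ Bn.T
    r, c = linear_sum_assignment(-cos)
    return cos[r, c]


class TestBootstrap:
    def test_degenerate_and_zero_rows(self):
        counts = np.zeros((2, 96), dtype=int)
        counts[0, 7] = 123  # all mass in one channel: resample is identity
        cat = MutationCatalog(SBS96, ["one", "zero"], counts)
        boot = bootstrap_catalog(cat, 5)
        assert np.array_equal(boot.counts, counts)

    def test_totals_conserved_and_moments(self):
        rng = np.random.default_rng(1)
        base = np.zeros(96, dtype=int)
        base[:3] = (60, 30, 10)
        cat = MutationCatalog(SBS96, [f"S{i}" for i in range(10_000)],
                              np.tile(base, (10_000, 1)))
        boot = bootstrap_catalog(cat, 123)
        assert np.array_equal(boot.totals(), cat.totals())
        # multinomial moment oracle: mean count within 3 SE of expectation
        for j, n_exp in [(0, 60), (1, 30), (2, 10)]:
            p = n_exp / 100
            se = np.sqrt(100 * p * (1 - p) / 10_000)
            assert abs(boot.counts[:, j].mean() - n_exp) < 3 * se

    def test_keyed_by_sample_id_not_position(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 40, size=(4, 96))
        cat = MutationCatalog(SBS96, ["a", "b", "c", "d"], counts)
        flipped = MutationCatalog(SBS96, ["d", "c", "b", "a"], counts[::-1])
        b1 = bootstrap_catalog(cat, 9)
        b2 = bootstrap_catalog(flipped, 9)
        assert np.array_equal(b1.counts, b2.counts[::-1])


class TestNmfKl:
    def test_rank1_closed_form(self):
        rng = np.random.default_rng(0)
        V = rng.integers(0, 25, size=(96, 12)).astype(float)
        W, H = nmf_kl(V, 1, max_iter=500)
        np.testing.assert_allclose(W[:, 0], V.sum(axis=1) / V.sum(),
                                   atol=1e-6)
        np.testing.assert_allclose(H[0], V.sum(axis=0), rtol=1e-6)

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(3)
        V = rng.integers(0, 50, size=(96, 30)).astype(float)
        for init in ("nndsvda", "random"):
            _, _, hist = nmf_kl(V, 4, seed=7, init=init, max_iter=300,
                                return_objective=True)
            assert np.all(np.diff(hist) <= 1e-8 * np.abs(hist[:-1]) + 1e-6)

    def test_planted_factor_recovery(self):
        pool = synthetic_signatures(3, "SBS96", seed=5)
        rng = np.random.default_rng(5)
        # dominance structure makes the exact factorization identifiable
        H0 = rng.uniform(5, 50, size=(3, 40))
        for j in range(40):
            H0[j % 3, j] += 300
        V = pool.profiles.T @ H0  # exactly rank 3
        W, H = nmf_kl(V, 3, seed=1, max_iter=5000, tol=1e-10)
        recon = W @ H
        cos = (V * recon).sum(axis=0) / (
            np.linalg.norm(V, axis=0) * np.linalg.norm(recon, axis=0))
        assert cos.min() >= 0.999
        assert _matched_cosines(W.T, pool.profiles).min() >= 0.99

    def test_input_validation(self):
        V = np.abs(np.random.default_rng(0).normal(size=(96, 5)))
        with pytest.raises(ValueError, match="k="):
            nmf_kl(V, 6)
        with pytest.raises(ValueError, match="nonnegative"):
            nmf_kl(-V, 2)
        V2 = V.copy()
        V2[:, 0] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            nmf_kl(V2, 2)


def _fake_records(sils, coss):
    return {k: SimpleNamespace(mean_silhouette=s, mean_sample_cosine=c)
            for k, s, c in zip(range(2, 2 + len(sils)), sils, coss)}


class TestSelectK:
    def test_rule_applied_by_hand(self):
        # silhouettes and cumulative cosines chosen so gains are
        # (base, 0.05, 0.02, 0.001): the largest stable k with gain > 0.01
        records = _fake_records([0.95, 0.93, 0.92, 0.60],
                                [0.90, 0.95, 0.97, 0.971])
        assert select_k_from_records(records) == 4

    def test_single_candidate(self):
        records = _fake_records([0.5], [0.9])
        with pytest.warns(UserWarning):
            assert select_k_from_records(records) == 2
        records = _fake_records([0.9], [0.9])
        assert select_k_from_records(records) == 2

    def test_all_below_floor_falls_back_to_argmax(self):
        records = _fake_records([0.5, 0.7, 0.6], [0.9, 0.95, 0.96])
        with pytest.warns(UserWarning, match="falling back"):
            assert select_k_from_records(records) == 3


@pytest.fixture(scope="module")
def planted():
    pool = synthetic_signatures(3, "SBS96", seed=31)
    rng = np.random.default_rng(31)
    counts = []
    for lab in range(3):
        for _ in range(25):
            w = rng.uniform(0, 1, 3)
            w[lab] = 0.0
            w = 0.25 * w / w.sum()
            w[lab] = 0.75
            counts.append(rng.multinomial(400, w @ pool.profiles))
    cat = MutationCatalog(SBS96, [f"S{i:02d}" for i in range(75)],
                          np.array(counts))
    return pool, cat


class TestExtract:

    def test_recovers_planted_signatures_and_k(self, planted):
        pool, cat = planted
        report = extract(cat, range(2, 5), n_replicates=8, seed=17)
        assert report.chosen_k == 3
        rec = report.records[3]
        assert _matched_cosines(rec.signatures.profiles,
                                pool.profiles).min() >= 0.95
        assert rec.mean_sample_cosine > 0.95
        # relative exposures sum to one; activities stay near sample totals
        rel = rec.exposures.relative
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-9)
        fitted = rec.exposures.activities.sum(axis=1)
        assert np.all(fitted <= cat.totals() * 1.1)

    def test_seeded_determinism(self, planted):
        _, cat = planted
        r1 = extract(cat, [3], n_replicates=4, seed=99)
        r2 = extract(cat, [3], n_replicates=4, seed=99)
        assert np.array_equal(r1.records[3].signatures.profiles,
                              r2.records[3].signatures.profiles)
        assert np.array_equal(r1.records[3].exposures.activities,
                              r2.records[3].exposures.activities)

    def test_sample_permutation_equivariance(self, planted):
        _, cat = planted
        perm = np.random.default_rng(1).permutation(cat.n_samples)
        permuted = MutationCatalog(
            cat.schema, [cat.sample_ids[i] for i in perm], cat.counts[perm])
        r1 = extract(cat, [3], n_replicates=4, seed=7)
        r2 = extract(permuted, [3], n_replicates=4, seed=7)
        cos = _matched_cosines(r1.records[3].signatures.profiles,
                               r2.records[3].signatures.profiles)
        assert cos.min() >= 0.999

    def test_single_signature_cohort_is_most_stable_at_k1(self):
        pool = synthetic_signatures(1, "SBS96", seed=41)
        rng = np.random.default_rng(41)
        counts = np.array([rng.multinomial(300, pool.profiles[0])
                           for _ in range(30)])
        cat = MutationCatalog(SBS96, [f"S{i}" for i in range(30)], counts)
        report = extract(cat, [1, 2], n_replicates=6, seed=3)
        sils = {k: r.mean_silhouette for k, r in report.records.items()}
        assert sils[1] == 1.0  # sentinel: stability undefined at k=1
        assert sils[2] < sils[1]

    def test_single_replicate_reports_sentinel_silhouette(self, planted):
        _, cat = planted
        report = extract(cat, [3], n_replicates=1, seed=5)
        assert report.records[3].mean_silhouette == 1.0
        assert report.records[3].n_replicates_used == 1
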