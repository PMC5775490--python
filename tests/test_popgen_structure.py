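import itertools

import numpy as np
import pandas as pd
import pytest

import landgen
from landgen import GenotypeMatrix
from landgen.io_formats import LandgenError

from conftest import make_sample_table


def matrix(d, prefix="s"):
    d = np.asarray(d, dtype=float)
    return GenotypeMatrix(
        [f"{prefix}{i}" for i in range(d.shape[0])],
        [f"l{j}" for j in range(d.shape[1])],
        d,
    )


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------


class TestDiversity:
    def test_single_locus_closed_form(self):
        # n=10, p=0.5 -> h = (20/19) * 0.5
        d = np.array([[0.0]] * 5 + [[1.0]] * 5)
        gm = matrix(d)
        st = make_sample_table(gm.sample_ids, ["A"] * 10)
        stats = landgen.diversity_stats(gm, st, locus_length=87)
        assert stats.table.loc["A", "H"] == pytest.approx((20 / 19) * 0.5)
        assert stats.table.loc["A", "pi"] == pytest.approx((20 / 19) * 0.5 / 87)

    def test_monomorphic_group_zero(self):
        gm = matrix(np.zeros((4, 5)))
        st = make_sample_table(gm.sample_ids, ["A"] * 4)
        stats = landgen.diversity_stats(gm, st)
        assert stats.table.loc["A", "H"] == 0.0
        assert stats.table.loc["A", "pi"] == 0.0

    def test_simulated_H_matches_analytic_expectation(self):
        # genotypes drawn from known frequencies: E[h_j] per locus is known
        rng = np.random.default_rng(4)
        freqs = rng.uniform(0.1, 0.9, 100)
        n = 40
        d = rng.binomial(2, np.tile(freqs, (n, 1))) / 2.0
        gm = matrix(d)
        st = make_sample_table(gm.sample_ids, ["A"] * n)
        stats = landgen.diversity_stats(gm, st)
        exp_H = float(np.mean(2 * freqs * (1 - freqs)))
        row = stats.table.loc["A"]
        assert abs(row["H"] - exp_H) < 2 * row["SE_H"] + 0.01

    def test_small_group_excluded(self):
        gm = matrix(np.tile([0.0, 0.5, 1.0], (3, 1)).T)
        st = make_sample_table(gm.sample_ids, ["A", "A", "B"])
        with pytest.warns(UserWarning, match="excluded"):
            stats = landgen.diversity_stats(gm, st)
        assert list(stats.table.index) == ["A"]


# ---------------------------------------------------------------------------
# F_ST: brute-force Weir-Cockerham oracle
# ---------------------------------------------------------------------------


def wc_fst_brute(d1, d2):
    """Scalar, loop-based two-population Weir-Cockerham ratio of sums."""
    num = den = 0.0
    any_used = False
    for j in range(d1.shape[1]):
        g1 = d1[:, j][np.isfinite(d1[:, j])]
        g2 = d2[:, j][np.isfinite(d2[:, j])]
        n1, n2 = len(g1), len(g2)
        r = 2.0
        nbar = (n1 + n2) / r
        if n1 < 1 or n2 < 1 or nbar <= 1:
            continue
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        p1, p2 = g1.mean(), g2.mean()
        h1, h2 = np.mean(g1 == 0.5), np.mean(g2 == 0.5)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        if a + b + c == 0:
            continue
        num += a
        den += a + b + c
        any_used = True
    return num / den if any_used else np.nan


class TestFst:
    def test_fixed_alternate_alleles_fst_one(self):
        d1, d2 = np.zeros((10, 50)), np.ones((10, 50))
        gm = matrix(np.vstack([d1, d2]))
        st = make_sample_table(gm.sample_ids, ["A"] * 10 + ["B"] * 10)
        fst = landgen.pairwise_fst(gm, st)
        assert fst.values[0, 1] == pytest.approx(1.0)

    def test_identical_balanced_hets_fst_nonpositive(self):
        # both groups p=0.5 with identical genotype composition
        block = np.array([[0.0], [1.0], [0.5], [0.5]])
        d = np.tile(block, (2, 30))
        gm = matrix(d)
        st = make_sample_table(gm.sample_ids, ["A"] * 4 + ["B"] * 4)
        fst = landgen.pairwise_fst(gm, st)
        assert fst.values[0, 1] <= 1e-12

    def test_matches_brute_force_on_enumerated_toys(self):
        """Exhaustive 3+3-sample, 2-locus configurations vs the oracle."""
        levels = [0.0, 0.5, 1.0]
        st = make_sample_table([f"s{i}" for i in range(6)], ["A"] * 3 + ["B"] * 3)
        rng = np.random.default_rng(7)
        # full enumeration of one-locus patterns x sampled second locus
        combos = list(itertools.product(levels, repeat=6))
        worst = 0.0
        for k, combo in enumerate(combos):
            col1 = np.array(combo)
            col2 = rng.choice(levels, size=6)
            d = np.column_stack([col1, col2])
            gm = matrix(d)
            mine = landgen.pairwise_fst(gm, st).values[0, 1]
            oracle = wc_fst_brute(d[:3], d[3:])
            if np.isnan(oracle):
                assert np.isnan(mine)
            else:
                worst = max(worst, abs(mine - oracle))
        assert worst < 1e-12

    def test_matches_brute_force_with_missing_data(self):
        rng = np.random.default_rng(2)
        d = rng.choice([0.0, 0.5, 1.0, np.nan], size=(20, 30), p=[0.3, 0.3, 0.3, 0.1])
        gm = matrix(d)
        st = make_sample_table(gm.sample_ids, ["A"] * 10 + ["B"] * 10)
        mine = landgen.pairwise_fst(gm, st).values[0, 1]
        assert mine == pytest.approx(wc_fst_brute(d[:10], d[10:]), abs=1e-12)

    def test_simulated_divergence_increases_fst(self):
        """Realized F_ST grows with planted cluster frequency divergence."""
        vals = []
        for div in (0.1, 0.3, 0.5):
            cfg = landgen.SimConfig(
                seed=13, K_true=2, n_individuals=60, n_neutral_loci=300,
                n_adaptive_loci=0, cluster_divergence=div, cluster_tau=0.02,
            )
            gm, truth, table = landgen.simulate_genotypes(cfg)
            groups = np.where(truth.Q_true[:, 0] > 0.5, "A", "B")
            st = make_sample_table(gm.sample_ids, groups)
            vals.append(landgen.pairwise_fst(gm, st).values[0, 1])
        assert vals[0] < vals[1] < vals[2]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPca:
    def test_two_fixed_clusters_separate_on_pc1(self):
        d = np.vstack([np.zeros((5, 20)), np.ones((5, 20))])
        res = landgen.pca(matrix(d), n_axes=2)
        pc1 = res.scores[:, 0]
        assert np.std(pc1[:5]) < 1e-8 and np.std(pc1[5:]) < 1e-8
        assert abs(pc1[:5].mean() - pc1[5:].mean()) > 1.0

    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(1)
        d = rng.choice([0.0, 0.5, 1.0], size=(8, 40))
        dd = np.vstack([d, d])
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(8)] + [f"dup{i}" for i in range(8)],
            [f"l{j}" for j in range(40)],
            dd,
        )
        res = landgen.pca(gm, n_axes=3)
        np.testing.assert_allclose(res.scores[:8], res.scores[8:], atol=1e-8)

    def test_locus_permutation_invariance_up_to_sign(self):
        rng = np.random.default_rng(3)
        d = rng.choice([0.0, 0.5, 1.0], size=(15, 50))
        gm = matrix(d)
        perm = rng.permutation(50)
        gm_p = GenotypeMatrix(
            gm.sample_ids, [gm.locus_ids[j] for j in perm], d[:, perm]
        )
        a = landgen.pca(gm, n_axes=4).scores
        b = landgen.pca(gm_p, n_axes=4).scores
        for k in range(4):
            assert min(
                np.abs(a[:, k] - b[:, k]).max(), np.abs(a[:, k] + b[:, k]).max()
            ) < 1e-8

    def test_k3_clusters_recovered_by_nearest_centroid(self):
        cfg = landgen.SimConfig(
            seed=6, K_true=3, n_individuals=120, n_neutral_loci=400,
            n_adaptive_loci=0, cluster_divergence=0.4, cluster_tau=0.05,
        )
        gm, truth, _ = landgen.simulate_genotypes(cfg)
        labels = truth.Q_true.argmax(axis=1)
        res = landgen.pca(gm, n_axes=2)
        cents = np.array([res.scores[labels == k].mean(axis=0) for k in range(3)])
        pred = np.argmin(
            ((res.scores[:, None, :] - cents[None]) ** 2).sum(axis=2), axis=1
        )
        assert (pred == labels).mean() >= 0.95

    def test_all_monomorphic_raises(self):
        with pytest.raises(LandgenError, match="monomorphic"):
            landgen.pca(matrix(np.ones((5, 4))))

    def test_eigenvalues_nonincreasing(self):
        rng = np.random.default_rng(9)
        gm = matrix(rng.choice([0.0, 0.5, 1.0], size=(20, 60)))
        res = landgen.pca(gm, n_axes=10)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------


class TestAdmixture:
    def test_k1_recovers_mean_dosage_and_binomial_loglik(self):
        rng = np.random.default_rng(0)
        d = rng.choice([0.0, 0.5, 1.0], size=(30, 50))
        gm = matrix(d)
        fit = landgen.admixture_em(gm, 1, seed=0, tol=1e-12)
        p_hat = d.mean(axis=0)
        np.testing.assert_allclose(fit.F[0], p_hat, atol=1e-4)
        g = 2 * d
        p = np.clip(p_hat, 1e-6, 1 - 1e-6)
        ll = np.sum(g * np.log(p) + (2 - g) * np.log(1 - p))
        assert fit.loglik == pytest.approx(ll, abs=1e-3)

    def test_loglik_trace_nondecreasing(self):
        cfg = landgen.SimConfig(seed=8, K_true=2, n_individuals=40,
                                n_neutral_loci=100, n_adaptive_loci=0)
        gm, _, _ = landgen.simulate_genotypes(cfg)
        fit = landgen.admixture_em(gm, 3, seed=1, max_iter=200)
        tr = np.array(fit.loglik_trace)
        assert (np.diff(tr) >= -1e-6).all()

    def test_reproducible_with_seed(self):
        cfg = landgen.SimConfig(seed=8, K_true=2, n_individuals=30,
                                n_neutral_loci=80, n_adaptive_loci=0)
        gm, _, _ = landgen.simulate_genotypes(cfg)
        a = landgen.admixture_em(gm, 2, seed=5, max_iter=100)
        b = landgen.admixture_em(gm, 2, seed=5, max_iter=100)
        np.testing.assert_array_equal(a.Q, b.Q)

    def test_k_exceeding_samples_raises(self):
        gm = matrix(np.zeros((3, 4)) + 0.5)
        with pytest.raises(LandgenError):
            landgen.admixture_em(gm, 4, seed=0)

    def test_q_rows_sum_to_one(self):
        cfg = landgen.SimConfig(seed=8, K_true=2, n_individuals=30,
                                n_neutral_loci=80, n_adaptive_loci=0,
                                missing_rate=0.2)
        gm, _, _ = landgen.simulate_genotypes(cfg)
        fit = landgen.admixture_em(gm, 2, seed=2, max_iter=300)
        np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-8)


class TestCvChooseK:
    def test_single_k(self):
        rng = np.random.default_rng(0)
        gm = matrix(rng.choice([0.0, 0.5, 1.0], size=(20, 40)))
        curve = landgen.cv_choose_k(gm, [1], folds=2, seed=0, n_restarts=1,
                                    max_iter=200)
        assert curve.argmin_k == 1
        assert len(curve.table) == 1

    def test_unstructured_data_prefers_small_k(self):
        """Without structure, K=1 should beat K=3 in most seeded runs."""
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            freqs = rng.uniform(0.2, 0.8, 120)
            d = rng.binomial(2, np.tile(freqs, (40, 1))) / 2.0
            curve = landgen.cv_choose_k(
                matrix(d), [1, 3], folds=2, seed=s, n_restarts=1, max_iter=300
            )
            t = curve.table["mean_error"]
            hits += t.loc[1] <= t.loc[3]
        assert hits >= 8


class TestMembershipMissingness:
    def test_planted_biased_missingness_flagged(self):
        cfg = landgen.SimConfig(
            seed=14, K_true=2, n_individuals=80, n_neutral_loci=300,
            n_adaptive_loci=0, missing_rate=0.25, missing_mode="sample_biased",
        )
        gm, truth, _ = landgen.simulate_genotypes(cfg)
        fit = landgen.AdmixtureFit(
            2, gm.sample_ids, gm.locus_ids, truth.Q_true,
            np.full((2, gm.n_loci), 0.5), [0.0], True,
        )
        res = landgen.membership_missingness_check(fit, gm)
        assert res.loc[1, "p_adj"] < 0.05
        assert res.loc[1, "r"] > 0.3

    def test_mcar_mostly_null(self):
        flags = 0
        for s in range(10):
            cfg = landgen.SimConfig(
                seed=200 + s, K_true=2, n_individuals=60, n_neutral_loci=200,
                n_adaptive_loci=0, missing_rate=0.15,
            )
            gm, truth, _ = landgen.simulate_genotypes(cfg)
            fit = landgen.AdmixtureFit(
                2, gm.sample_ids, gm.locus_ids, truth.Q_true,
                np.full((2, gm.n_loci), 0.5), [0.0], True,
            )
            res = landgen.membership_missingness_check(fit, gm)
            flags += int((res["p_adj"] < 0.05).any())
        assert flags <= 1

    def test_constant_missingness_reports_zero(self):
        rng = np.random.default_rng(1)
        d = rng.choice([0.0, 0.5, 1.0], size=(20, 50))
        gm = matrix(d)  # no missing data at all
        fit = landgen.admixture_em(gm, 2, seed=0, max_iter=50)
        res = landgen.membership_missingness_check(fit, gm)
        assert (res["r"] == 0.0).all()
        assert (res["note"] == "zero variance").all()
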