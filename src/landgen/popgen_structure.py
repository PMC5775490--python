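"""Population-genetic structure: diversity, differentiation, PCA, admixture.

Estimators operate on the dosage matrix (0/0.5/1 diploid calls, nan
missing).  Pairwise F_ST follows Weir & Cockerham's (1984) variance
components for two populations — the genotype-based formulation including
the within-individual (heterozygosity) term — aggregated over loci as a
ratio of sums, which is what PLINK reports.  The admixture model is the
standard binomial mixture: individual i carries fraction q_ik of its genome
from cluster k with allele frequency f_kj at locus j, so its alt-allele
count at j is Binomial(2, sum_k q_ik f_kj).  It is fitted by EM with
restarts; K is chosen by masked-entry cross-validation (lowest held-out
squared prediction error).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, LandgenError, SampleTable

__all__ = [
    "DiversityStats",
    "FstMatrix",
    "PcaResult",
    "AdmixtureFit",
    "CvCurve",
    "diversity_stats",
    "pairwise_fst",
    "wc_fst_components",
    "pca",
    "admixture_em",
    "cv_choose_k",
    "align_clusters",
    "membership_missingness_check",
]


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversityStats:
    """Per-group expected heterozygosity and per-base nucleotide diversity."""

    table: pd.DataFrame  # index group; columns H, SE_H, pi, SE_pi, ...
    locus_length: int


def diversity_stats(
    gm: GenotypeMatrix,
    samples: SampleTable,
    locus_length: int = 87,
    groupby: str = "group",
) -> DiversityStats:
    """Unbiased gene diversity per locus, averaged within groups.

    h_j = (2n_j / (2n_j - 1)) * 2 p_j (1 - p_j) on non-missing calls;
    H is the mean of h over loci and pi spreads the same heterozygosity
    over ``locus_length`` assayed bases per locus (one variant site per
    sequenced tag).  Groups with fewer than 2 samples are excluded.
    """
    meta = samples.df.set_index("sample_id").loc[gm.sample_ids]
    rows = []
    for grp, sub in meta.groupby(groupby, sort=True):
        idx = gm.sample_index(sub.index)
        if len(idx) < 2:
            warnings.warn(f"group {grp!r} has < 2 samples; excluded")
            continue
        d = gm.dosage[idx]
        n = np.sum(np.isfinite(d), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0)
        ok = n >= 2
        nj, pj = n[ok], p[ok]
        h = (2 * nj / (2 * nj - 1)) * 2 * pj * (1 - pj)
        L = h.size
        if L == 0:
            warnings.warn(f"group {grp!r}: no loci with >= 2 calls; excluded")
            continue
        H = float(h.mean())
        se = float(h.std(ddof=1) / np.sqrt(L)) if L > 1 else 0.0
        rows.append(
            {
                "group": grp,
                "H": H,
                "SE_H": se,
                "pi": float(h.sum() / (L * locus_length)),
                "SE_pi": se / locus_length,
                "n_samples": len(idx),
                "n_loci": L,
                "total_bases": L * locus_length,
            }
        )
    return DiversityStats(pd.DataFrame(rows).set_index("group"), locus_length)


# ---------------------------------------------------------------------------
# Weir-Cockerham pairwise F_ST
# ---------------------------------------------------------------------------


def wc_fst_components(
    d1: np.ndarray, d2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components a, b, c for two groups.

    ``d1``/``d2`` are dosage matrices of the two groups (nan missing).
    Returns (a, b, c, usable) with ``usable`` marking loci where both
    groups have >= 1 call and the mean sample size exceeds 1.
    """
    r = 2.0
    n1 = np.sum(np.isfinite(d1), axis=0).astype(float)
    n2 = np.sum(np.isfinite(d2), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p1 = np.nanmean(d1, axis=0)
        p2 = np.nanmean(d2, axis=0)
        h1 = np.nansum(np.where(np.isfinite(d1), d1 == 0.5, np.nan), axis=0) / n1
        h2 = np.nansum(np.where(np.isfinite(d2), d2 == 0.5, np.nan), axis=0) / n2
    nbar = (n1 + n2) / r
    usable = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    return a, b, c, usable


@dataclass
class FstMatrix:
    groups: list[str]
    values: np.ndarray  # symmetric, nan where not estimable
    n_loci_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.groups, columns=self.groups)


def pairwise_fst(gm: GenotypeMatrix, samples: SampleTable) -> FstMatrix:
    """Pairwise Weir-Cockerham F_ST as a ratio of summed components.

    Loci whose total component sum is zero (e.g. monomorphic across the
    pair) are skipped and counted out of the per-pair locus totals.
    """
    meta = samples.df.set_index("sample_id").loc[gm.sample_ids]
    groups = sorted(g for g, s in meta.groupby("group") if len(s) >= 2)
    if len(groups) < 2:
        raise LandgenError("need >= 2 groups with >= 2 samples each")
    idx = {
        g: gm.sample_index(meta.index[meta["group"] == g]) for g in groups
    }
    G = len(groups)
    vals = np.full((G, G), np.nan)
    np.fill_diagonal(vals, 0.0)
    used = np.zeros((G, G), dtype=int)
    for i, j in itertools.combinations(range(G), 2):
        a, b, c, ok = wc_fst_components(
            gm.dosage[idx[groups[i]]], gm.dosage[idx[groups[j]]]
        )
        denom = a + b + c
        ok = ok & np.isfinite(denom) & (np.abs(denom) > 0)
        if not ok.any():
            warnings.warn(
                f"no informative loci for pair ({groups[i]}, {groups[j]})"
            )
            continue
        vals[i, j] = vals[j, i] = float(a[ok].sum() / denom[ok].sum())
        used[i, j] = used[j, i] = int(ok.sum())
    return FstMatrix(groups, vals, used)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    sample_ids: list[str]
    scores: np.ndarray  # (n, n_axes)
    eigenvalues: np.ndarray
    explained: np.ndarray  # variance fractions

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def pca(
    gm: GenotypeMatrix, n_axes: int = 10, standardize: bool = True
) -> PcaResult:
    """Genotype PCA with per-locus mean imputation.

    Works on allele counts g = 2 * dosage: missing entries are imputed at
    2 p_j, loci centered at 2 p_j and (optionally) scaled by
    sqrt(p_j (1 - p_j)); monomorphic loci are dropped; scores are the
    projections onto the eigenvectors of the sample covariance.
    """
    if gm.n_samples < 2:
        raise LandgenError("PCA needs >= 2 samples")
    g = 2.0 * gm.dosage
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise LandgenError("all loci monomorphic; PCA undefined")
    g = g[:, poly]
    p = p[poly]
    X = np.where(np.isfinite(g), g, 2 * p) - 2 * p
    if standardize:
        X = X / np.sqrt(p * (1 - p))
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    lam = S**2 / (gm.n_samples - 1)
    k = min(n_axes, len(lam))
    # deterministic sign: largest-|loading| sample coordinate positive
    scores = U[:, :k] * S[:k]
    for a in range(k):
        imax = np.argmax(np.abs(scores[:, a]))
        if scores[imax, a] < 0:
            scores[:, a] = -scores[:, a]
    return PcaResult(
        list(gm.sample_ids), scores, lam[:k], lam[:k] / lam.sum()
    )


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureFit:
    K: int
    sample_ids: list[str]
    locus_ids: list[str]
    Q: np.ndarray  # (n, K)
    F: np.ndarray  # (K, L)
    loglik_trace: list[float] = field(repr=False)
    converged: bool = False

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


_F_EPS = 1e-6


def _em_run(
    g: np.ndarray,
    ok: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    n, L = g.shape
    L_i = ok.sum(axis=1).astype(float)
    g0 = np.where(ok, g, 0.0)
    g2 = np.where(ok, 2.0 - g, 0.0)
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.05, 0.95, size=(K, L))
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
        ll = float(np.sum(g0 * np.log(P) + g2 * np.log1p(-P)))
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        W1 = g0 / P
        W0 = g2 / (1.0 - P)
        SA = W1 @ F.T  # (n, K): sum_j a / q
        SB = W0 @ (1.0 - F).T
        Qn = Q * (SA + SB) / (2.0 * L_i[:, None])
        Qn = Qn / Qn.sum(axis=1, keepdims=True)
        NA = F * (Q.T @ W1)  # (K, L): sum_i a
        NB = (1.0 - F) * (Q.T @ W0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Fn = NA / (NA + NB)
        Fn[~np.isfinite(Fn)] = 0.5
        Q, F = Qn, np.clip(Fn, _F_EPS, 1.0 - _F_EPS)
    return Q, F, trace, converged


def admixture_em(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 3,
) -> AdmixtureFit:
    """Maximum-likelihood admixture fit by EM with random restarts.

    log L = sum over non-missing (i, j) of
    g_ij ln(sum_k q_ik f_kj) + (2 - g_ij) ln(sum_k q_ik (1 - f_kj)) with
    g = 2 * dosage.  The best of ``n_restarts`` seeded runs is returned.
    """
    if K < 1:
        raise LandgenError("K must be >= 1")
    if K > gm.n_samples:
        raise LandgenError(f"K={K} exceeds the {gm.n_samples} samples")
    g = 2.0 * gm.dosage
    ok = np.isfinite(g)
    best = None
    root = np.random.default_rng(seed)
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(root.integers(2**31))
        Q, F, trace, conv = _em_run(g, ok, K, rng, max_iter, tol)
        if best is None or trace[-1] > best[2][-1]:
            best = (Q, F, trace, conv)
    Q, F, trace, conv = best
    return AdmixtureFit(K, list(gm.sample_ids), list(gm.locus_ids), Q, F, trace, conv)


def align_clusters(
    Q_est: np.ndarray, Q_ref: np.ndarray
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Permute estimated cluster labels to best match a reference Q."""
    K = Q_est.shape[1]
    best_perm, best_err = None, np.inf
    for perm in itertools.permutations(range(K)):
        err = np.abs(Q_est[:, perm] - Q_ref).mean()
        if err < best_err:
            best_perm, best_err = perm, err
    return Q_est[:, best_perm], best_perm


# ---------------------------------------------------------------------------
# Cross-validation for K
# ---------------------------------------------------------------------------


@dataclass
class CvCurve:
    table: pd.DataFrame  # index K; columns mean_error, sd_error
    argmin_k: int


def cv_choose_k(
    gm: GenotypeMatrix,
    K_range,
    folds: int = 5,
    mask_frac: float = 0.1,
    seed: int = 0,
    **em_kwargs,
) -> CvCurve:
    """Choose K by masked-genotype cross-validation.

    Per fold, ``mask_frac`` of the non-missing entries are hidden, the
    model is fitted on the rest, and the error is the mean squared
    difference (g - g_hat)^2 / 4 over the hidden entries with
    g_hat = 2 sum_k q_ik f_kj.  The reported argmin is the smallest K
    attaining the minimum mean error.
    """
    K_list = sorted(set(int(k) for k in K_range))
    if not K_list:
        raise LandgenError("K_range is empty")
    rng = np.random.default_rng(seed)
    ok = np.isfinite(gm.dosage)
    nz = np.argwhere(ok)
    fold_masks = []
    for _ in range(folds):
        pick = rng.choice(len(nz), size=max(1, int(mask_frac * len(nz))), replace=False)
        fold_masks.append(nz[pick])
    errors = {k: [] for k in K_list}
    for fold in fold_masks:
        d = gm.dosage.copy()
        d[fold[:, 0], fold[:, 1]] = np.nan
        masked_gm = GenotypeMatrix(gm.sample_ids, gm.locus_ids, d)
        g_true = 2.0 * gm.dosage[fold[:, 0], fold[:, 1]]
        for k in K_list:
            fit = admixture_em(
                masked_gm, k, seed=int(rng.integers(2**31)), **em_kwargs
            )
            g_hat = 2.0 * (fit.Q @ fit.F)[fold[:, 0], fold[:, 1]]
            errors[k].append(float(np.mean((g_true - g_hat) ** 2) / 4.0))
    tbl = pd.DataFrame(
        {
            "mean_error": [np.mean(errors[k]) for k in K_list],
            "sd_error": [np.std(errors[k], ddof=1) if folds > 1 else 0.0 for k in K_list],
        },
        index=pd.Index(K_list, name="K"),
    )
    argmin = int(tbl.index[np.argmin(tbl["mean_error"].to_numpy())])
    return CvCurve(tbl, argmin)


# ---------------------------------------------------------------------------
# Membership vs missingness
# ---------------------------------------------------------------------------


def membership_missingness_check(
    fit: AdmixtureFit, gm: GenotypeMatrix
) -> pd.DataFrame:
    """Pearson r of each cluster's membership against per-sample missingness.

    p-values are Bonferroni-adjusted over the K tests; zero-variance inputs
    report r = 0 with a note instead of failing.
    """
    if fit.sample_ids != gm.sample_ids:
        raise LandgenError("fit and matrix sample ids differ")
    miss = np.isnan(gm.dosage).mean(axis=1)
    rows = []
    for k in range(fit.K):
        q = fit.Q[:, k]
        if np.std(miss) < 1e-15 or np.std(q) < 1e-15:
            rows.append(
                {"cluster": k + 1, "r": 0.0, "p_adj": 1.0, "note": "zero variance"}
            )
            continue
        r, p = stats.pearsonr(q, miss)
        rows.append(
            {
                "cluster": k + 1,
                "r": float(r),
                "p_adj": float(min(1.0, p * fit.K)),
                "note": "",
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
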