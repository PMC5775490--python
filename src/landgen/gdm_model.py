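"""Generalized dissimilarity modeling of genetic distances.

GDM regresses pairwise compositional dissimilarity d_ij on monotone
I-spline transforms of the predictor differences between the two sites,

    eta_ij = alpha + sum_p sum_k a_pk |I_pk(x_ip) - I_pk(x_jp)|,
    mu_ij  = 1 - exp(-eta_ij),

with all coefficients constrained non-negative so each fitted turnover
function f_p(x) = sum_k a_pk I_pk(x) is non-decreasing along its gradient.
Geographic distance enters as one extra predictor splined on the distance
value itself (lower knot pinned at zero).  The fit minimizes the
binomial-form deviance; the per-predictor spline height sum_k a_pk is the
predictor's importance, and 100 (1 - D/D_0) is the percent deviance
explained relative to an intercept-only model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io_formats import EnvRaster, GenotypeMatrix, LandgenError, SampleTable
from .gradient_forest import TransformedGrid, _check_aligned

logger = logging.getLogger("landgen")

__all__ = [
    "SitePairTable",
    "IsplineBasis",
    "GdmModel",
    "build_site_pairs",
    "fit_gdm",
    "gdm_importance",
    "gdm_transform",
    "gdm_predict",
]

_D_EPS = 1e-6
GEO_NAME = "geographic"


# ---------------------------------------------------------------------------
# Site pairs
# ---------------------------------------------------------------------------


@dataclass
class SitePairTable:
    """One row per unordered pair of individuals ("sites")."""

    sample_ids: list[str]
    pairs: np.ndarray  # (n_pairs, 2) integer indices, i < j
    d: np.ndarray  # observed dissimilarity in [0, 1]
    geo: np.ndarray  # geographic distance >= 0
    predictor_names: list[str]
    Xi: np.ndarray  # (n_pairs, P) predictor values at end i
    Xj: np.ndarray
    scale_denominator: float = 1.0

    @property
    def n_pairs(self) -> int:
        return len(self.d)


def _pairwise_complete_euclidean(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair Euclidean distance over shared non-missing loci and the
    shared-locus counts, via masked matrix products."""
    M = np.isfinite(d).astype(float)
    A = np.where(np.isfinite(d), d, 0.0)
    A2M = (A * A) * M
    shared = M @ M.T
    sq = A2M @ M.T + M @ A2M.T - 2.0 * (A @ A.T)
    return np.clip(sq, 0.0, None), shared


def build_site_pairs(
    gm: GenotypeMatrix,
    samples: SampleTable,
    predictors: pd.DataFrame,
    scale: str = "max",
    scale_denominator: float | None = None,
) -> SitePairTable:
    """Genetic, geographic and environmental values for every pair.

    Genetic dissimilarity is the Euclidean distance between dosage vectors
    over pairwise-complete loci, divided by sqrt(shared locus count), then
    mapped into [0, 1] by the observed maximum (``scale="max"``) or by a
    caller-supplied denominator (``scale="given"``).
    """
    n = gm.n_samples
    if n < 3:
        raise LandgenError("need >= 3 samples for site pairs")
    missing_pred = set(gm.sample_ids) - set(map(str, predictors.index))
    if missing_pred:
        raise LandgenError(f"predictors missing for samples {sorted(missing_pred)[:5]}")
    sq, shared = _pairwise_complete_euclidean(gm.dosage)
    iu, ju = np.triu_indices(n, k=1)
    if (shared[iu, ju] == 0).any():
        bad = np.argwhere(shared == 0)
        i, j = bad[bad[:, 0] < bad[:, 1]][0]
        raise LandgenError(
            f"no shared loci for pair ({gm.sample_ids[i]}, {gm.sample_ids[j]})"
        )
    d_raw = np.sqrt(sq[iu, ju] / shared[iu, ju])
    if scale == "max":
        denom = float(d_raw.max()) or 1.0
    elif scale == "given":
        if scale_denominator is None or scale_denominator <= 0:
            raise LandgenError('scale="given" needs a positive scale_denominator')
        denom = float(scale_denominator)
    else:
        raise LandgenError(f"unknown scale {scale!r}")
    d01 = np.clip(d_raw / denom, 0.0, 1.0)
    coords = samples.coords(gm.sample_ids)
    geo = np.sqrt(((coords[iu] - coords[ju]) ** 2).sum(axis=1))
    X = predictors.loc[gm.sample_ids].to_numpy(dtype=float)
    return SitePairTable(
        sample_ids=list(gm.sample_ids),
        pairs=np.column_stack([iu, ju]),
        d=d01,
        geo=geo,
        predictor_names=list(predictors.columns),
        Xi=X[iu],
        Xj=X[ju],
        scale_denominator=denom,
    )


# ---------------------------------------------------------------------------
# I-spline basis
# ---------------------------------------------------------------------------


def _ispline_eval(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Order-2 I-splines (integrated linear M-splines) on quantile knots.

    ``knots`` are the base knots (length = number of splines); each basis
    function rises from 0 to 1 over a local knot triple taken from the
    boundary-padded knot vector.  A degenerate (zero-width) triple yields
    the all-zero function.
    """
    x = np.asarray(x, dtype=float)
    T = np.concatenate([[knots[0]], knots, [knots[-1]]])
    out = np.zeros(x.shape + (len(knots),))
    for s in range(len(knots)):
        a, b, c = T[s], T[s + 1], T[s + 2]
        if c <= a:
            continue
        v = np.zeros_like(x)
        if b > a:
            seg = (x > a) & (x <= b)
            v[seg] = (x[seg] - a) ** 2 / ((b - a) * (c - a))
        if c > b:
            seg = (x > b) & (x <= c)
            v[seg] = 1.0 - (c - x[seg]) ** 2 / ((c - b) * (c - a))
        v[x > c] = 1.0
        out[..., s] = v
    return out


@dataclass
class IsplineBasis:
    """Per-predictor monotone spline basis with quantile knots."""

    knots: dict[str, np.ndarray]
    n_splines: int = 3

    @classmethod
    def from_values(
        cls,
        values: dict[str, np.ndarray],
        n_splines: int = 3,
        pin_zero: tuple[str, ...] = (GEO_NAME,),
    ) -> "IsplineBasis":
        """Knots at evenly spaced percentiles (min/median/max for three
        splines); predictors in ``pin_zero`` get their lower knot at 0."""
        if n_splines < 2:
            raise LandgenError("n_splines must be >= 2")
        qs = np.linspace(0.0, 100.0, n_splines)
        knots = {}
        for name, v in values.items():
            k = np.percentile(np.asarray(v, dtype=float), qs)
            if name in pin_zero:
                k[0] = 0.0
            knots[name] = np.maximum.accumulate(k)
        return cls(knots, n_splines)

    @classmethod
    def from_site_pairs(cls, spt: SitePairTable, n_splines: int = 3) -> "IsplineBasis":
        vals = {
            name: np.concatenate([spt.Xi[:, p], spt.Xj[:, p]])
            for p, name in enumerate(spt.predictor_names)
        }
        vals[GEO_NAME] = spt.geo
        return cls.from_values(vals, n_splines)

    def evaluate(self, name: str, x: np.ndarray) -> np.ndarray:
        return _ispline_eval(np.asarray(x, dtype=float), self.knots[name])

    def evaluate_clamped(self, name: str, x: np.ndarray) -> tuple[np.ndarray, int]:
        k = self.knots[name]
        x = np.asarray(x, dtype=float)
        n_clamped = int(((x < k[0]) | (x > k[-1])).sum())
        return _ispline_eval(np.clip(x, k[0], k[-1]), k), n_clamped


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class GdmModel:
    intercept: float
    coefs: dict[str, np.ndarray]  # per predictor (incl. geographic), >= 0
    basis: IsplineBasis
    deviance: float
    null_deviance: float
    converged: bool
    deviance_trace: list[float] = field(repr=False, default_factory=list)
    n_pairs: int = 0
    include_geo: bool = True

    @property
    def pct_deviance_explained(self) -> float:
        return 100.0 * (1.0 - self.deviance / self.null_deviance)

    def to_json(self, path) -> None:
        obj = {
            "intercept": self.intercept,
            "coefs": {k: v.tolist() for k, v in self.coefs.items()},
            "knots": {k: v.tolist() for k, v in self.basis.knots.items()},
            "n_splines": self.basis.n_splines,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "converged": self.converged,
            "n_pairs": self.n_pairs,
            "include_geo": self.include_geo,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GdmModel":
        with open(path) as fh:
            obj = json.load(fh)
        basis = IsplineBasis(
            {k: np.array(v) for k, v in obj["knots"].items()}, obj["n_splines"]
        )
        return cls(
            intercept=obj["intercept"],
            coefs={k: np.array(v) for k, v in obj["coefs"].items()},
            basis=basis,
            deviance=obj["deviance"],
            null_deviance=obj["null_deviance"],
            converged=obj["converged"],
            n_pairs=obj["n_pairs"],
            include_geo=obj["include_geo"],
        )


def _deviance(d: np.ndarray, mu: np.ndarray) -> float:
    dc = np.clip(d, _D_EPS, 1.0 - _D_EPS)
    mc = np.clip(mu, _D_EPS, 1.0 - _D_EPS)
    return float(
        2.0
        * np.sum(dc * np.log(dc / mc) + (1.0 - dc) * np.log((1.0 - dc) / (1.0 - mc)))
    )


def _design_matrix(
    spt: SitePairTable, basis: IsplineBasis, include_geo: bool
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    blocks, labels = [], []
    for p, name in enumerate(spt.predictor_names):
        Zi = basis.evaluate(name, spt.Xi[:, p])
        Zj = basis.evaluate(name, spt.Xj[:, p])
        blocks.append(np.abs(Zi - Zj))
        labels += [(name, k) for k in range(basis.n_splines)]
    if include_geo:
        blocks.append(basis.evaluate(GEO_NAME, spt.geo))
        labels += [(GEO_NAME, k) for k in range(basis.n_splines)]
    return np.concatenate(blocks, axis=1), labels


def fit_gdm(
    spt: SitePairTable,
    basis: IsplineBasis | None = None,
    include_geo: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> GdmModel:
    """Non-negative deviance-minimizing GDM fit.

    Bound-constrained quasi-Newton (L-BFGS-B) minimization of the binomial
    deviance over [alpha, a_pk] >= 0; the deviance at each accepted iterate
    is recorded.  Non-convergence returns the best iterate with
    ``converged=False`` and a warning.
    """
    if np.ptp(spt.d) <= 0:
        raise LandgenError("site-pair dissimilarities are constant; nothing to fit")
    basis = basis or IsplineBasis.from_site_pairs(spt)
    Z, labels = _design_matrix(spt, basis, include_geo)
    d = np.clip(spt.d, _D_EPS, 1.0 - _D_EPS)

    def unpack(theta):
        return theta[0], theta[1:]

    def fg(theta):
        alpha, a = unpack(theta)
        eta = alpha + Z @ a
        mu = 1.0 - np.exp(-eta)
        mc = np.clip(mu, _D_EPS, 1.0 - _D_EPS)
        dev = 2.0 * np.sum(
            d * np.log(d / mc) + (1.0 - d) * np.log((1.0 - d) / (1.0 - mc))
        )
        # d(dev)/d(eta) = 2 [ (1 - d) - d (1 - mu) / mu ]
        live = (mu > _D_EPS) & (mu < 1.0 - _D_EPS)
        g_eta = np.where(live, 2.0 * ((1.0 - d) - d * (1.0 - mu) / mc), 0.0)
        grad = np.concatenate([[g_eta.sum()], g_eta @ Z])
        return dev, grad

    theta0 = np.zeros(1 + Z.shape[1])
    theta0[0] = max(-np.log(1.0 - d.mean()), _D_EPS)
    trace: list[float] = [fg(theta0)[0]]

    def cb(theta):
        trace.append(fg(theta)[0])

    res = optimize.minimize(
        fg,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * len(theta0),
        callback=cb,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    if not res.success:
        warnings.warn(f"GDM fit did not converge: {res.message}")
    alpha, a = unpack(res.x)
    coefs: dict[str, np.ndarray] = {}
    for (name, k), val in zip(labels, a):
        coefs.setdefault(name, np.zeros(basis.n_splines))[k] = val

    # intercept-only null deviance
    def f0(al):
        return _deviance(d, np.full_like(d, 1.0 - np.exp(-al)))

    r0 = optimize.minimize_scalar(f0, bounds=(0.0, 20.0), method="bounded")
    D0 = float(r0.fun)
    return GdmModel(
        intercept=float(alpha),
        coefs=coefs,
        basis=basis,
        deviance=float(res.fun),
        null_deviance=D0,
        converged=bool(res.success),
        deviance_trace=trace,
        n_pairs=spt.n_pairs,
        include_geo=include_geo,
    )


def gdm_importance(model: GdmModel) -> pd.Series:
    """Predictor importances as spline-coefficient sums, ranked descending."""
    imp = {name: float(c.sum()) for name, c in model.coefs.items()}
    return pd.Series(imp).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Transform / predict
# ---------------------------------------------------------------------------


def _eta_between(
    model: GdmModel, env_i: pd.DataFrame, env_j: pd.DataFrame, geo: np.ndarray
) -> np.ndarray:
    eta = np.full(len(env_i), model.intercept)
    for name, a in model.coefs.items():
        if name == GEO_NAME:
            Zg, nc = model.basis.evaluate_clamped(name, np.asarray(geo, float))
            eta += Zg @ a
            continue
        Zi, ni = model.basis.evaluate_clamped(name, env_i[name].to_numpy(float))
        Zj, nj = model.basis.evaluate_clamped(name, env_j[name].to_numpy(float))
        if ni or nj:
            logger.info("gdm predict: %d values clamped for %s", ni + nj, name)
        eta += np.abs(Zi - Zj) @ a
    return eta


def gdm_predict(
    model: GdmModel,
    env_i: pd.DataFrame,
    env_j: pd.DataFrame,
    geo: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Predicted dissimilarity mu for supplied environment pairs."""
    geo = np.broadcast_to(np.asarray(geo, dtype=float), (len(env_i),))
    return 1.0 - np.exp(-_eta_between(model, env_i, env_j, geo))


def gdm_transform(
    model: GdmModel, rasters: dict[str, EnvRaster], mask: EnvRaster
) -> TransformedGrid:
    """Fitted turnover value f_p(x) = sum_k a_pk I_pk(x) per cell and predictor.

    Values outside the knot range are clamped (count logged per raster).
    """
    _check_aligned(rasters, mask)
    rows, cols = np.nonzero(mask.values > 0)
    names = [n for n in model.coefs if n != GEO_NAME]
    vecs = np.empty((len(rows), len(names)))
    for p, name in enumerate(names):
        if name not in rasters:
            raise LandgenError(f"no raster supplied for predictor {name!r}")
        Z, nc = model.basis.evaluate_clamped(name, rasters[name].values[rows, cols])
        if nc:
            logger.info("gdm transform: %d cells clamped for %s", nc, name)
        vecs[:, p] = Z @ model.coefs[name]
    return TransformedGrid(mask, rows, cols, vecs, names)
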