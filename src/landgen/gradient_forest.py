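"""Gradient forest: forest-based genotype-environment turnover functions.

Each locus's dosage is regressed on the predictor set with a random forest.
Every split in every tree partitions one predictor at a threshold; the
impurity (variance) reduction of that split is credited to the bin of the
predictor's gradient containing the threshold.  Per locus the binned split
importance is normalized to sum one and weighted by the locus's out-of-bag
R^2, so only loci the forest can predict contribute, in proportion to how
predictable they are.  Averaging the per-locus cumulative curves over loci
yields, per predictor p, a non-decreasing step function F_p along the
gradient whose total height W_p = F_p(max) is the predictor's overall
importance: steep stretches of F_p mark zones of rapid allelic turnover.

Transforming an environmental grid through the F_p functions maps each cell
into "genetic composition" units, the common scale used for mapping and for
the genetic-offset computation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.ensemble import RandomForestRegressor

from .io_formats import EnvRaster, GenotypeMatrix, LandgenError

__all__ = [
    "ForestConfig",
    "GfModel",
    "TransformedGrid",
    "fit_gf",
    "gf_importance_split",
    "gf_transform",
    "idw_raster",
]


@dataclass
class ForestConfig:
    """Forest and importance-curve settings.

    ``mtry`` defaults to ceil(P/3) predictors per split; ``n_bins`` controls
    the resolution of the cumulative-importance curves; density
    standardization divides binned importance by a kernel-density estimate
    of the predictor's sampled values so densely sampled stretches of a
    gradient are not over-credited.
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int = 5
    n_bins: int = 200
    density_standardize: bool = True
    importance: str = "split"  # or "permutation"
    min_samples_per_locus: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 50:
            raise LandgenError("n_trees >= 50 required for stable importances")
        if self.n_bins < 10:
            raise LandgenError("n_bins must be >= 10")
        if self.importance not in ("split", "permutation"):
            raise LandgenError(f"unknown importance mode {self.importance!r}")


@dataclass
class GfModel:
    """Aggregated gradient-forest fit.

    ``cum_curves[p]`` holds the cumulative importance at the upper edge of
    each of the ``n_bins`` bins spanning ``ranges[p]``; F_p is the step
    function that jumps to ``cum_curves[p][b]`` at ``bin_edges[p][b]``,
    with F_p(min) = 0 and F_p(max) = importance W_p.
    """

    predictor_names: list[str]
    bin_edges: dict[str, np.ndarray] = field(repr=False)  # upper edges
    cum_curves: dict[str, np.ndarray] = field(repr=False)
    importance: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    r2: pd.Series = field(repr=False)  # per-locus OOB R^2 (all fitted loci)
    n_included: int = 0
    config: ForestConfig | None = None

    def curve_value(self, name: str, x: np.ndarray) -> np.ndarray:
        """Evaluate F_p at x (clamped to the training range)."""
        lo, hi = self.ranges[name]
        xc = np.clip(np.asarray(x, dtype=float), lo, hi)
        edges = self.bin_edges[name]
        cum = np.concatenate([[0.0], self.cum_curves[name]])
        return cum[np.searchsorted(edges, xc, side="right")]

    def to_json(self, path) -> None:
        obj = {
            "predictor_names": self.predictor_names,
            "bin_edges": {k: v.tolist() for k, v in self.bin_edges.items()},
            "cum_curves": {k: v.tolist() for k, v in self.cum_curves.items()},
            "importance": self.importance,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "r2": self.r2.to_dict(),
            "n_included": self.n_included,
            "config": asdict(self.config) if self.config else None,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GfModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            predictor_names=obj["predictor_names"],
            bin_edges={k: np.array(v) for k, v in obj["bin_edges"].items()},
            cum_curves={k: np.array(v) for k, v in obj["cum_curves"].items()},
            importance=obj["importance"],
            ranges={k: tuple(v) for k, v in obj["ranges"].items()},
            r2=pd.Series(obj["r2"]),
            n_included=obj["n_included"],
            config=ForestConfig(**obj["config"]) if obj["config"] else None,
        )


def _split_importance_matrix(
    forest: RandomForestRegressor, P: int, lows: np.ndarray, widths: np.ndarray,
    n_bins: int,
) -> np.ndarray:
    """Sum impurity decreases of every split into (predictor, bin) cells."""
    M = np.zeros((P, n_bins))
    for est in forest.estimators_:
        t = est.tree_
        internal = t.feature >= 0
        if not internal.any():
            continue
        feat = t.feature[internal]
        thr = t.threshold[internal]
        wi = t.weighted_n_node_samples * t.impurity
        delta = (
            wi[internal]
            - wi[t.children_left[internal]]
            - wi[t.children_right[internal]]
        )
        delta = np.clip(delta, 0.0, None)
        bins = np.floor((thr - lows[feat]) / widths[feat]).astype(int)
        np.add.at(M, (feat, np.clip(bins, 0, n_bins - 1)), delta)
    return M


def fit_gf(
    gm: GenotypeMatrix, predictors: pd.DataFrame, config: ForestConfig | None = None
) -> GfModel:
    """Fit per-locus random forests and aggregate importance curves.

    ``predictors`` is indexed by sample id and must cover every sample in
    the genotype matrix.  Loci with non-positive out-of-bag R^2 (or too few
    non-missing calls) are excluded from the aggregation.
    """
    cfg = config or ForestConfig()
    if predictors.shape[1] < 2:
        raise LandgenError("need >= 2 predictors")
    X_all = predictors.loc[gm.sample_ids].to_numpy(dtype=float)
    names = list(predictors.columns)
    P = len(names)
    n_bins = cfg.n_bins
    lows = X_all.min(axis=0)
    highs = X_all.max(axis=0)
    spans = np.where(highs > lows, highs - lows, 1.0)
    widths = spans / n_bins
    mtry = cfg.mtry or int(np.ceil(P / 3))

    density = np.ones((P, n_bins))
    if cfg.density_standardize:
        centers = lows[:, None] + (np.arange(n_bins) + 0.5) * widths[:, None]
        for p in range(P):
            col = X_all[:, p]
            if np.ptp(col) <= 0:
                continue
            kde = gaussian_kde(col, bw_method="silverman")
            d = kde(centers[p])
            density[p] = np.maximum(d, 1e-3 * d.max())

    rng = np.random.default_rng(cfg.seed)
    r2_list: dict[str, float] = {}
    sum_curves = np.zeros((P, n_bins))
    n_included = 0
    for j, lid in enumerate(gm.locus_ids):
        y = gm.dosage[:, j]
        ok = np.isfinite(y)
        if ok.sum() < cfg.min_samples_per_locus or np.ptp(y[ok]) <= 0:
            r2_list[lid] = np.nan
            continue
        forest = RandomForestRegressor(
            n_estimators=cfg.n_trees,
            max_features=mtry,
            min_samples_leaf=cfg.min_node_size,
            bootstrap=True,
            oob_score=True,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse OOB coverage warnings
            forest.fit(X_all[ok], y[ok])
        r2 = float(forest.oob_score_)
        r2_list[lid] = r2
        if r2 <= 0:
            continue
        M = _split_importance_matrix(forest, P, lows, widths, n_bins)
        if cfg.importance == "permutation":
            # per-predictor totals from permutation importance; split bins
            # only shape the curves within each predictor
            from sklearn.inspection import permutation_importance

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pi = permutation_importance(
                    forest, X_all[ok], y[ok], n_repeats=5,
                    random_state=int(rng.integers(2**31)),
                )
            totals = np.clip(pi.importances_mean, 0.0, None)
            shape = M / np.maximum(M.sum(axis=1, keepdims=True), 1e-300)
            M = shape * totals[:, None]
        M = M / density
        tot = M.sum()
        if tot <= 0:
            continue
        sum_curves += np.cumsum(M / tot, axis=1) * r2
        n_included += 1
    if n_included == 0:
        raise LandgenError(
            "no locus had positive out-of-bag R^2; increase effect sizes, "
            "sample size or tree count"
        )
    mean_curves = sum_curves / n_included
    bin_edges = {
        names[p]: lows[p] + widths[p] * np.arange(1, n_bins + 1) for p in range(P)
    }
    # pin the last edge to the exact observed max
    for p, nm in enumerate(names):
        bin_edges[nm][-1] = highs[p]
    cum = {names[p]: mean_curves[p] for p in range(P)}
    W = {names[p]: float(mean_curves[p][-1]) for p in range(P)}
    if sum(W.values()) <= 0:
        raise LandgenError("all predictor importances zero")
    return GfModel(
        predictor_names=names,
        bin_edges=bin_edges,
        cum_curves=cum,
        importance=W,
        ranges={names[p]: (float(lows[p]), float(highs[p])) for p in range(P)},
        r2=pd.Series(r2_list),
        n_included=n_included,
        config=cfg,
    )


def gf_importance_split(model: GfModel, spatial_prefix: str = "PCNM") -> dict:
    """Share of total importance carried by spatial vs environment predictors."""
    spat = sum(
        w for p, w in model.importance.items() if p.startswith(spatial_prefix)
    )
    env = sum(
        w for p, w in model.importance.items() if not p.startswith(spatial_prefix)
    )
    total = spat + env
    if total <= 0:
        raise LandgenError("model has zero total importance")
    return {"spatial_share": spat / total, "environment_share": env / total}


# ---------------------------------------------------------------------------
# Grid transforms
# ---------------------------------------------------------------------------


@dataclass
class TransformedGrid:
    """Predictor grids mapped into genetic-composition space.

    ``vectors[c, p]`` is F_p evaluated at mask cell c; cells are addressed
    by the parallel ``rows``/``cols`` index arrays into the mask raster.
    """

    mask: EnvRaster
    rows: np.ndarray
    cols: np.ndarray
    vectors: np.ndarray  # (n_cells, P)
    predictor_names: list[str]

    def to_rasters(self) -> dict[str, EnvRaster]:
        out = {}
        for p, name in enumerate(self.predictor_names):
            vals = np.full((self.mask.nrows, self.mask.ncols), np.nan)
            vals[self.rows, self.cols] = self.vectors[:, p]
            out[name] = self.mask.copy_with(vals)
        return out


def idw_raster(
    coords: np.ndarray,
    values: np.ndarray,
    mask: EnvRaster,
    power: float = 2.0,
    k: int = 8,
) -> EnvRaster:
    """Inverse-distance-weighted interpolation of point values to mask cells."""
    rows, cols = np.nonzero(mask.values > 0)
    gx = mask.x_centers()[cols]
    gy = mask.y_centers()[rows]
    out = np.full((mask.nrows, mask.ncols), np.nan)
    pts = np.asarray(coords, dtype=float)
    vals = np.asarray(values, dtype=float)
    kk = min(k, len(pts))
    d = np.sqrt(
        (gx[:, None] - pts[None, :, 0]) ** 2 + (gy[:, None] - pts[None, :, 1]) ** 2
    )
    idx = np.argpartition(d, kk - 1, axis=1)[:, :kk]
    dn = np.take_along_axis(d, idx, axis=1)
    w = 1.0 / np.maximum(dn, 1e-12) ** power
    est = (w * vals[idx]).sum(axis=1) / w.sum(axis=1)
    # exact hit: use the point's value
    hit = dn[:, 0] < 1e-12
    if hit.any():
        est[hit] = vals[idx[hit, 0]]
    out[rows, cols] = est
    return mask.copy_with(out)


def _check_aligned(rasters: dict[str, EnvRaster], mask: EnvRaster) -> None:
    for name, r in rasters.items():
        if not r.same_grid(mask):
            raise LandgenError(
                f"raster {name!r} not aligned with mask: "
                f"({r.ncols}x{r.nrows} @ {r.xll},{r.yll},{r.cellsize}) vs "
                f"({mask.ncols}x{mask.nrows} @ {mask.xll},{mask.yll},{mask.cellsize})"
            )


def gf_transform(
    model: GfModel,
    rasters: dict[str, EnvRaster],
    mask: EnvRaster,
    include_pcnm: bool = True,
    pcnm_table: pd.DataFrame | None = None,
    coords: np.ndarray | None = None,
    spatial_prefix: str = "PCNM",
    exclude: tuple[str, ...] = (),
) -> TransformedGrid:
    """Map every mask cell's predictor vector through the F_p functions.

    Spatial (PCNM-prefixed) predictors have no natural raster; when
    ``include_pcnm`` they are interpolated to the grid by inverse-distance
    weighting of the sample scores (``pcnm_table`` + ``coords``), otherwise
    they are dropped from the transform.  Predictors named in ``exclude``
    are left out of the output vector entirely.
    """
    _check_aligned(rasters, mask)
    use_names = []
    grids: dict[str, EnvRaster] = {}
    for name in model.predictor_names:
        if name in exclude:
            continue
        if name in rasters:
            grids[name] = rasters[name]
            use_names.append(name)
        elif name.startswith(spatial_prefix):
            if not include_pcnm:
                continue
            if pcnm_table is None or coords is None:
                raise LandgenError(
                    f"no raster for spatial predictor {name!r}; pass "
                    "pcnm_table and coords or set include_pcnm=False"
                )
            grids[name] = idw_raster(coords, pcnm_table[name].to_numpy(), mask)
            use_names.append(name)
        else:
            raise LandgenError(f"no raster supplied for predictor {name!r}")
    rows, cols = np.nonzero(mask.values > 0)
    vecs = np.empty((len(rows), len(use_names)))
    for p, name in enumerate(use_names):
        vecs[:, p] = model.curve_value(name, grids[name].values[rows, cols])
    return TransformedGrid(mask, rows, cols, vecs, use_names)
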