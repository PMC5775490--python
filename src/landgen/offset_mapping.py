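"""Genetic-offset maps and RGB landscape projections.

Genetic offset measures, per grid cell, how far the genetic composition
predicted under future environment lies from the composition predicted
under current environment — the magnitude of genetic change implied by the
environmental change if today's genotype-environment relationship is to be
maintained.  For the gradient-forest model it is the Euclidean distance
between the transformed current and future predictor vectors; for GDM it is
the predicted dissimilarity between a cell's current and future environment
with geographic distance zero.  Spatial (PCNM) terms are held fixed by
default: geography does not change between now and the future scenario, so
only changing environmental variables contribute.  Substrate-style
predictors that should not enter the offset are named in a drop list.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import EnvRaster, LandgenError
from .gradient_forest import GfModel, TransformedGrid, _check_aligned, gf_transform
from .gdm_model import GEO_NAME, GdmModel, gdm_predict

__all__ = ["OffsetGrid", "RgbMap", "gf_offset", "gdm_offset", "rgb_map"]


@dataclass
class OffsetGrid:
    raster: EnvRaster  # offsets on mask cells, nan elsewhere
    method: str  # "gf" | "gdm"
    model_fingerprint: str

    @property
    def values(self) -> np.ndarray:
        return self.raster.values


def _fingerprint(obj: dict) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _drop_rasters(
    rasters: dict[str, EnvRaster], drop: tuple[str, ...]
) -> dict[str, EnvRaster]:
    return {k: v for k, v in rasters.items() if k not in drop}


def gf_offset(
    model: GfModel,
    current: dict[str, EnvRaster],
    future: dict[str, EnvRaster],
    mask: EnvRaster,
    include_pcnm: bool = False,
    weight_by_importance: bool = False,
    drop: tuple[str, ...] = ("substrate_age",),
    **transform_kwargs,
) -> OffsetGrid:
    """Per-cell Euclidean distance between current and future GF transforms.

    The cumulative-importance functions already scale each dimension by its
    importance (F_p tops out at W_p); ``weight_by_importance`` applies an
    additional per-dimension W_p weighting for sensitivity analysis.
    Predictors in ``drop`` and (by default) PCNM dimensions are excluded —
    they do not change between the two scenarios.
    """
    cur = _drop_rasters(current, drop)
    fut = _drop_rasters(future, drop)
    _check_aligned(cur, mask)
    _check_aligned(fut, mask)
    tg_cur = gf_transform(
        model, cur, mask, include_pcnm=include_pcnm, exclude=drop, **transform_kwargs
    )
    tg_fut = gf_transform(
        model, fut, mask, include_pcnm=include_pcnm, exclude=drop, **transform_kwargs
    )
    diff = tg_cur.vectors - tg_fut.vectors
    if weight_by_importance:
        w = np.array([model.importance[p] for p in tg_cur.predictor_names])
        diff = diff * w[None, :]
    off = np.sqrt((diff**2).sum(axis=1))
    vals = np.full((mask.nrows, mask.ncols), np.nan)
    vals[tg_cur.rows, tg_cur.cols] = off
    fp = _fingerprint({"method": "gf", "importance": model.importance})
    return OffsetGrid(mask.copy_with(vals), "gf", fp)


def gdm_offset(
    model: GdmModel,
    current: dict[str, EnvRaster],
    future: dict[str, EnvRaster],
    mask: EnvRaster,
    drop: tuple[str, ...] = ("substrate_age",),
) -> OffsetGrid:
    """Predicted GDM dissimilarity between each cell's current and future
    environment, with the geographic-distance term set to zero."""
    cur = _drop_rasters(current, drop)
    fut = _drop_rasters(future, drop)
    _check_aligned(cur, mask)
    _check_aligned(fut, mask)
    names = [n for n in model.coefs if n != GEO_NAME and n not in drop]
    for n in names:
        if n not in cur or n not in fut:
            raise LandgenError(f"no current/future raster for predictor {n!r}")
    rows, cols = np.nonzero(mask.values > 0)
    env_i = pd.DataFrame({n: cur[n].values[rows, cols] for n in names})
    env_j = pd.DataFrame({n: fut[n].values[rows, cols] for n in names})
    # restrict the model to the offset predictors: dropped/geo terms are
    # identical between scenarios and the intercept is kept as the floor
    sub = GdmModel(
        intercept=model.intercept,
        coefs={n: model.coefs[n] for n in names},
        basis=model.basis,
        deviance=model.deviance,
        null_deviance=model.null_deviance,
        converged=model.converged,
        n_pairs=model.n_pairs,
        include_geo=False,
    )
    mu = gdm_predict(sub, env_i, env_j, geo=0.0)
    vals = np.full((mask.nrows, mask.ncols), np.nan)
    vals[rows, cols] = mu
    fp = _fingerprint(
        {"method": "gdm", "intercept": model.intercept,
         "coefs": {k: v.tolist() for k, v in model.coefs.items()}}
    )
    return OffsetGrid(mask.copy_with(vals), "gdm", fp)


# ---------------------------------------------------------------------------
# RGB projection
# ---------------------------------------------------------------------------


@dataclass
class RgbMap:
    """First three PCs of the transformed grid, min-max scaled to [0, 255]."""

    mask: EnvRaster
    rows: np.ndarray
    cols: np.ndarray
    rgb: np.ndarray  # (n_cells, 3)
    loadings: np.ndarray = field(repr=False, default=None)
    explained: np.ndarray = None

    def to_rasters(self) -> dict[str, EnvRaster]:
        out = {}
        for i, ch in enumerate(("red", "green", "blue")):
            vals = np.full((self.mask.nrows, self.mask.ncols), np.nan)
            vals[self.rows, self.cols] = self.rgb[:, i]
            out[ch] = self.mask.copy_with(vals)
        return out

    def to_png(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        img = np.ones((self.mask.nrows, self.mask.ncols, 3))
        img[self.rows, self.cols] = self.rgb / 255.0
        plt.imsave(path, img)


def rgb_map(tg: TransformedGrid) -> RgbMap:
    """Color mask cells by the first three PCs of their transformed vectors."""
    if tg.vectors.shape[0] < 3:
        raise LandgenError("need >= 3 mask cells for an RGB map")
    X = tg.vectors - tg.vectors.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    nz = int((S > 1e-12).sum())
    scores = U[:, :3] * S[:3] if X.shape[1] >= 3 else U * S
    if scores.shape[1] < 3 or nz < 3:
        pad = np.zeros((scores.shape[0], 3 - min(3, nz)))
        scores = np.column_stack([scores[:, :nz], pad])[:, :3]
    rgb = np.zeros_like(scores)
    for i in range(3):
        lo, hi = scores[:, i].min(), scores[:, i].max()
        rgb[:, i] = 0.0 if hi <= lo else (scores[:, i] - lo) / (hi - lo) * 255.0
    lam = S**2
    explained = lam[:3] / lam.sum() if lam.sum() > 0 else np.zeros(3)
    return RgbMap(tg.mask, tg.rows, tg.cols, rgb, Vt[:3], explained)
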