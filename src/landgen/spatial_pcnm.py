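"""Spatial eigenvector predictors (PCNM / Moran's eigenvector maps).

The classical construction: truncate the Euclidean distance matrix at the
longest edge of its minimum spanning tree (so the graph stays connected),
replace larger distances by four times the truncation threshold, Gower
double-center the squared distances, and eigen-decompose.  Positive-
eigenvalue eigenvectors, scaled by the square root of their eigenvalue,
form orthogonal spatial predictors ordered broad-scale to fine-scale.
Retaining half of the positive-eigenvalue vectors is a common screening
rule for genotype-environment models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from .io_formats import LandgenError

__all__ = ["PcnmBasis", "pcnm", "retain_half"]

_EIG_REL_TOL = 1e-10


@dataclass
class PcnmBasis:
    truncation: float
    eigenvalues: np.ndarray  # descending, candidates only (lambda > tol)
    vectors: np.ndarray  # (n, m), columns scaled by sqrt(eigenvalue)
    n_positive: int
    sample_ids: list[str] | None = None
    retained: np.ndarray | None = field(default=None, repr=False)


def pcnm(coords: np.ndarray, sample_ids=None, truncation: float | None = None) -> PcnmBasis:
    """Build the PCNM basis from ``(n, 2)`` point coordinates.

    Duplicate coordinate pairs are jittered (deterministically) with a
    warning; the truncation threshold defaults to the longest minimum-
    spanning-tree edge of the Euclidean distance matrix.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 3:
        raise LandgenError("need an (n >= 3, 2) coordinate array")
    n = coords.shape[0]
    if np.ptp(coords[:, 0]) == 0 and np.ptp(coords[:, 1]) == 0:
        raise LandgenError("all points coincident; PCNM undefined")
    if len(np.unique(coords.round(12), axis=0)) < n:
        warnings.warn("duplicate coordinates jittered before PCNM")
        rng = np.random.default_rng(0)
        span = max(np.ptp(coords[:, 0]), np.ptp(coords[:, 1]), 1.0)
        coords = coords + rng.normal(0.0, 1e-9 * span, size=coords.shape)
    D = squareform(pdist(coords))
    if D.max() <= 0:
        raise LandgenError("all points coincident; PCNM undefined")
    if truncation is None:
        mst = minimum_spanning_tree(D).toarray()
        truncation = float(mst.max())
    Dp = np.where(D > truncation, 4.0 * truncation, D)
    np.fill_diagonal(Dp, 0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dp * Dp) @ J
    w, v = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    tol = _EIG_REL_TOL * max(abs(w[0]), abs(w[-1]))
    keep = w > tol
    w, v = w[keep], v[:, keep]
    vecs = v * np.sqrt(w)
    # sign convention: largest-magnitude loading positive
    for a in range(vecs.shape[1]):
        imax = np.argmax(np.abs(vecs[:, a]))
        if vecs[imax, a] < 0:
            vecs[:, a] = -vecs[:, a]
    return PcnmBasis(
        truncation=truncation,
        eigenvalues=w,
        vectors=vecs,
        n_positive=int(keep.sum()),
        sample_ids=list(sample_ids) if sample_ids is not None else None,
    )


def retain_half(basis: PcnmBasis, rounding: str = "ceil") -> pd.DataFrame:
    """Keep the first half of positive-eigenvalue vectors as predictors.

    Returns a table with columns PCNM1..PCNMm (broad to fine scale),
    indexed by sample id when the basis carries ids.  ``rounding`` decides
    how an odd count is halved (default: keep the extra one).
    """
    if basis.n_positive < 1:
        raise LandgenError("no positive-eigenvalue vectors to retain")
    half = basis.n_positive / 2.0
    m = int(np.ceil(half)) if rounding == "ceil" else int(np.floor(half))
    m = max(m, 1)
    basis.retained = np.arange(m)
    cols = [f"PCNM{i + 1}" for i in range(m)]
    idx = basis.sample_ids if basis.sample_ids is not None else None
    return pd.DataFrame(basis.vectors[:, :m], columns=cols, index=idx)
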