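"""Synthetic island landscapes with known genotype-environment structure.

The generator emulates the data-generating situation the analysis modules
assume: a volcanic island with a steep windward (wet, east) / leeward (dry,
west) rainfall gradient, K admixed genetic clusters with geographic
structure, a set of adaptive loci whose allele frequency follows a logistic
cline in rainfall centered near 3,500 mm/yr, negative-binomial read depths
for the ploidy diagnostic, and a future rainfall surface with reduced
windward rainfall.  Every draw is reproducible from (config, seed); the
ground truth (cluster frequencies, admixture proportions, cline parameters)
is returned so downstream estimators can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import (
    DIPLOID_DOSAGES,
    TETRAPLOID_DOSAGES,
    EnvRaster,
    GenotypeMatrix,
    LandgenError,
    SampleTable,
)
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "ReadDepthTable",
    "make_env_rasters",
    "simulate_genotypes",
    "simulate_reads",
    "simulate_tetraploid_dosages",
    "simulate_replicates",
    "stack_replicates",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic landscape and population.

    Rainfall runs west (dry) to east (wet) as a logistic in easting whose
    value at the transition midpoint is ``rain_center_mm``; the cline of
    each adaptive locus is logistic in rainfall with center ``cline_center``
    (mm/yr) and slope ``cline_slope`` (per mm).
    """

    # grid geometry (decimal degrees, Hawaii-island sized)
    ncols: int = 60
    nrows: int = 48
    cellsize: float = 0.02
    xll: float = -156.1
    yll: float = 19.0
    # rainfall field (mm/yr)
    rain_west: float = 800.0
    rain_east: float = 6200.0
    rain_center_mm: float = 3500.0
    rain_steepness: float = 12.0  # per degree of easting
    # auxiliary environmental variables: name -> (target r with rainfall, lo, hi)
    aux_vars: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "temp_min": (-0.55, 5.0, 20.0),
            "isothermality": (0.45, 0.5, 0.8),
            "temp_seasonality": (-0.35, 100.0, 300.0),
            "rain_seasonality": (0.55, 0.3, 1.0),
        }
    )
    max_abs_corr: float = 0.8
    aux_noise_sigma: float = 4.0  # smoothing length (cells) of the noise fields
    # future scenario: rainfall declines on the wet side
    future_rain_delta_wet: float = -1500.0
    # population
    n_individuals: int = 200
    K_true: int = 3
    n_neutral_loci: int = 450
    n_adaptive_loci: int = 50
    cline_center: float = 3500.0
    cline_slope: float = 0.004
    cluster_divergence: float = 0.3
    cluster_tau: float = 0.3  # degrees; distance decay of cluster membership
    admix_gamma_shape: float = 2.0
    missing_rate: float = 0.0
    missing_mode: str = "mcar"  # or "sample_biased"
    # read-depth model
    depth_mean: float = 20.0
    depth_overdispersion: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (
            ("ncols", self.ncols), ("nrows", self.nrows),
            ("n_individuals", self.n_individuals), ("K_true", self.K_true),
            ("n_neutral_loci", self.n_neutral_loci),
        ):
            if val < 1:
                raise LandgenError(f"{name} must be positive")
        if self.n_adaptive_loci < 0:
            raise LandgenError("n_adaptive_loci must be >= 0")
        for name, (r, lo, hi) in self.aux_vars.items():
            if abs(r) >= self.max_abs_corr:
                raise LandgenError(
                    f"target correlation for {name} must satisfy |r| < "
                    f"{self.max_abs_corr}"
                )
            if hi <= lo:
                raise LandgenError(f"aux var {name}: hi must exceed lo")


@dataclass
class SimTruth:
    """Ground truth of one simulated data set."""

    F_true: np.ndarray  # (K, n_neutral) cluster allele frequencies
    Q_true: np.ndarray  # (n, K) admixture proportions
    cline_center: float
    cline_slope: float
    adaptive_locus_ids: list[str]
    neutral_locus_ids: list[str]
    env_at_samples: pd.DataFrame  # per-sample predictor values (incl. rainfall)

    def __post_init__(self) -> None:
        if not np.allclose(self.Q_true.sum(axis=1), 1.0):
            raise LandgenError("Q_true rows must sum to 1")
        if self.F_true.size and (
            self.F_true.min() < 0.02 - 1e-12 or self.F_true.max() > 0.98 + 1e-12
        ):
            raise LandgenError("F_true outside [0.02, 0.98]")


@dataclass
class ReadDepthTable:
    """Per (sample, locus) total and alternate read counts."""

    sample_ids: list[str]
    locus_ids: list[str]
    total: np.ndarray  # (n, L) ints
    alt: np.ndarray  # (n, L) ints

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=int)
        self.alt = np.asarray(self.alt, dtype=int)
        if (self.alt < 0).any() or (self.alt > self.total).any():
            raise LandgenError("need 0 <= alt <= total")

    def to_frame(self) -> pd.DataFrame:
        n, L = self.total.shape
        return pd.DataFrame(
            {
                "sample": np.repeat(self.sample_ids, L),
                "locus": np.tile(self.locus_ids, n),
                "total": self.total.ravel(),
                "alt": self.alt.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReadDepthTable":
        wide_t = df.pivot(index="sample", columns="locus", values="total").fillna(0)
        wide_a = df.pivot(index="sample", columns="locus", values="alt").fillna(0)
        wide_a = wide_a[wide_t.columns].loc[wide_t.index]
        return cls(
            [str(s) for s in wide_t.index],
            [str(l) for l in wide_t.columns],
            wide_t.to_numpy(),
            wide_a.to_numpy(),
        )


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------


def _island_mask(cfg: SimConfig) -> np.ndarray:
    """Elliptical island inscribed in the grid (1 = land)."""
    r = (np.arange(cfg.nrows) + 0.5) / cfg.nrows - 0.5
    c = (np.arange(cfg.ncols) + 0.5) / cfg.ncols - 0.5
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return ((rr / 0.48) ** 2 + (cc / 0.48) ** 2 <= 1.0).astype(float)


def _smooth_field(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Standardized spatially autocorrelated noise field."""
    f = gaussian_filter(
        rng.standard_normal((cfg.nrows, cfg.ncols)), cfg.aux_noise_sigma,
        mode="reflect",
    )
    return (f - f.mean()) / f.std()


def _rainfall_values(cfg: SimConfig) -> np.ndarray:
    x = cfg.xll + (np.arange(cfg.ncols) + 0.5) * cfg.cellsize
    x_c = cfg.xll + cfg.ncols * cfg.cellsize / 2.0
    sig = 1.0 / (1.0 + np.exp(-cfg.rain_steepness * (x - x_c)))
    mid = (cfg.rain_west + cfg.rain_east) / 2.0
    # shift so the field passes through rain_center_mm at the midpoint
    row = cfg.rain_west + (cfg.rain_east - cfg.rain_west) * sig
    row = row + (cfg.rain_center_mm - mid)
    return np.tile(row, (cfg.nrows, 1))


def make_env_rasters(
    cfg: SimConfig, seed: int | None = None
) -> tuple[dict[str, tuple[EnvRaster, EnvRaster]], EnvRaster]:
    """Build current/future rasters for every variable plus a 0/1 mask.

    Rainfall is a west-east logistic through ``rain_center_mm``; each
    auxiliary variable mixes the standardized rainfall field with an
    independent smooth noise field to hit its target correlation (checked
    empirically over mask cells, |r| < ``max_abs_corr``).  The future
    rainfall subtracts ``|future_rain_delta_wet|`` on the wet side (same
    logistic shape); other variables are held at current values.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mask_vals = _island_mask(cfg)
    rain = _rainfall_values(cfg)
    on = mask_vals > 0

    def raster(values: np.ndarray) -> EnvRaster:
        return EnvRaster(
            cfg.ncols, cfg.nrows, cfg.xll, cfg.yll, cfg.cellsize, -9999.0,
            np.asarray(values, dtype=float),
        )

    rain_std = (rain - rain[on].mean()) / rain[on].std()
    out: dict[str, tuple[EnvRaster, EnvRaster]] = {}
    # future rainfall: decline proportional to the wet-side logistic
    wet_frac = (rain - rain.min()) / (rain.max() - rain.min())
    future_rain = rain + cfg.future_rain_delta_wet * wet_frac
    out["rainfall"] = (raster(rain), raster(future_rain))
    for name, (target_r, lo, hi) in cfg.aux_vars.items():
        noise = _smooth_field(rng, cfg)
        # residualize on rainfall over mask cells so the achieved
        # correlation equals the target instead of drifting with the
        # (few) effective degrees of freedom of the smoothed noise
        rm = rain_std[on] - rain_std[on].mean()
        nm = noise[on] - noise[on].mean()
        perp = noise - (nm @ rm) / (rm @ rm) * rain_std
        perp = (perp - perp[on].mean()) / perp[on].std()
        mixed = target_r * rain_std + np.sqrt(1.0 - target_r**2) * perp
        r_emp = np.corrcoef(mixed[on], rain[on])[0, 1]
        if abs(r_emp) >= cfg.max_abs_corr:
            raise LandgenError(
                f"{name}: empirical |r|={abs(r_emp):.2f} with rainfall exceeds "
                f"{cfg.max_abs_corr}; increase aux_noise_sigma or lower the target"
            )
        lo_m, hi_m = mixed[on].min(), mixed[on].max()
        scaled = lo + (mixed - lo_m) / (hi_m - lo_m) * (hi - lo)
        out[name] = (raster(scaled), raster(scaled.copy()))
    return out, raster(mask_vals)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _auto_samples(
    cfg: SimConfig, mask: EnvRaster, rng: np.random.Generator
) -> SampleTable:
    rows, cols = np.nonzero(mask.values > 0)
    pick = rng.choice(len(rows), size=cfg.n_individuals, replace=True)
    # jitter within the cell so no two trees share exact coordinates
    jx = rng.uniform(-0.4, 0.4, cfg.n_individuals) * cfg.cellsize
    jy = rng.uniform(-0.4, 0.4, cfg.n_individuals) * cfg.cellsize
    x = mask.x_centers()[cols[pick]] + jx
    y = mask.y_centers()[rows[pick]] + jy
    df = pd.DataFrame(
        {
            "sample_id": [f"ind{i:04d}" for i in range(cfg.n_individuals)],
            "group": "island",
            "x": x,
            "y": y,
        }
    )
    return SampleTable(df)


def _cluster_frequencies(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Cluster allele frequencies with mean divergence ``cluster_divergence``.

    Each locus gets an ancestral frequency and each cluster is pushed half
    the divergence up or down.  With K=2 the two clusters always take
    opposite signs, so E|F1 - F2| equals the configured divergence exactly.
    """
    L = cfg.n_neutral_loci
    d = cfg.cluster_divergence / 2.0
    p = rng.uniform(0.2, 0.8, size=L)
    if cfg.K_true == 1:
        signs = np.zeros((1, L))
    elif cfg.K_true == 2:
        signs = np.vstack([-np.ones(L), np.ones(L)])
    else:
        signs = rng.choice([-1.0, 1.0], size=(cfg.K_true, L))
    return np.clip(p[None, :] + signs * d, 0.02, 0.98)


def _admixture_proportions(
    cfg: SimConfig, coords: np.ndarray, mask: EnvRaster, rng: np.random.Generator
) -> np.ndarray:
    """Distance-decayed, Gamma-weighted membership to K cluster centers."""
    rows, cols = np.nonzero(mask.values > 0)
    pick = rng.choice(len(rows), size=cfg.K_true, replace=False)
    centers = np.column_stack(
        [mask.x_centers()[cols[pick]], mask.y_centers()[rows[pick]]]
    )
    d = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
    w = np.exp(-d / cfg.cluster_tau) * rng.gamma(
        cfg.admix_gamma_shape, 1.0, size=d.shape
    )
    return w / w.sum(axis=1, keepdims=True)


def simulate_genotypes(
    cfg: SimConfig,
    samples: SampleTable | None = None,
    rasters: dict[str, tuple[EnvRaster, EnvRaster]] | None = None,
    mask: EnvRaster | None = None,
) -> tuple[GenotypeMatrix, SimTruth, SampleTable]:
    """Draw genotypes for neutral (admixture-structured) and adaptive loci.

    Neutral locus j of individual i: p_ij = sum_k Q_ik F_kj; adaptive locus:
    p_i = logistic(slope * (rain_i - center)); genotype ~ Binomial(2, p)/2.
    """
    rng = np.random.default_rng(cfg.seed)
    if rasters is None or mask is None:
        rasters, mask = make_env_rasters(cfg, seed=rng.integers(2**31))
    if samples is None:
        samples = _auto_samples(cfg, mask, rng)
    coords = samples.coords(samples.df["sample_id"])
    env = {
        name: np.array([cur.value_at(x, y) for x, y in coords])
        for name, (cur, _fut) in rasters.items()
    }
    rain = env["rainfall"]
    if cfg.n_adaptive_loci > 0 and np.ptp(rain) < 1e-9:
        import warnings

        warnings.warn("constant rainfall over samples: cline unidentifiable")

    F = _cluster_frequencies(cfg, rng)
    Q = _admixture_proportions(cfg, coords, mask, rng)
    p_neutral = Q @ F
    probs = [p_neutral]
    if cfg.n_adaptive_loci > 0:
        p_ad = 1.0 / (1.0 + np.exp(-cfg.cline_slope * (rain - cfg.cline_center)))
        probs.append(np.tile(p_ad[:, None], (1, cfg.n_adaptive_loci)))
    p = np.clip(np.concatenate(probs, axis=1), 0.0, 1.0)
    dosage = rng.binomial(2, p) / 2.0

    if cfg.missing_rate > 0:
        if cfg.missing_mode == "mcar":
            miss = rng.random(dosage.shape) < cfg.missing_rate
        elif cfg.missing_mode == "sample_biased":
            rate = np.clip(cfg.missing_rate * 2.0 * Q[:, 0], 0.0, 0.9)
            miss = rng.random(dosage.shape) < rate[:, None]
        else:
            raise LandgenError(f"unknown missing_mode {cfg.missing_mode!r}")
        dosage = dosage.astype(float)
        dosage[miss] = np.nan

    neutral_ids = [f"neut{j:05d}" for j in range(cfg.n_neutral_loci)]
    adaptive_ids = [f"adap{j:05d}" for j in range(cfg.n_adaptive_loci)]
    gm = GenotypeMatrix(
        list(samples.df["sample_id"]), neutral_ids + adaptive_ids, dosage
    )
    truth = SimTruth(
        F_true=F,
        Q_true=Q,
        cline_center=cfg.cline_center,
        cline_slope=cfg.cline_slope,
        adaptive_locus_ids=adaptive_ids,
        neutral_locus_ids=neutral_ids,
        env_at_samples=pd.DataFrame(env, index=list(samples.df["sample_id"])),
    )
    return gm, truth, samples


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def simulate_tetraploid_dosages(
    freqs: np.ndarray, n_individuals: int, seed: int
) -> np.ndarray:
    """Hardy-Weinberg dosages on four chromosome copies: Binomial(4, p)/4."""
    rng = np.random.default_rng(seed)
    return rng.binomial(4, np.tile(freqs, (n_individuals, 1))) / 4.0


def simulate_reads(
    dosage: np.ndarray | GenotypeMatrix,
    depth_mean: float = 20.0,
    overdispersion: float = 3.0,
    ploidy: str = "diploid",
    seed: int = 0,
    sample_ids: list[str] | None = None,
    locus_ids: list[str] | None = None,
) -> ReadDepthTable:
    """Negative-binomial total depth, binomial alt reads at the true dosage."""
    if ploidy == "diploid":
        allowed = DIPLOID_DOSAGES
    elif ploidy == "autotetraploid":
        allowed = TETRAPLOID_DOSAGES
    else:
        raise LandgenError(f"unknown ploidy {ploidy!r}")
    if depth_mean < 1:
        raise LandgenError("depth_mean must be >= 1")
    if isinstance(dosage, GenotypeMatrix):
        sample_ids = sample_ids or dosage.sample_ids
        locus_ids = locus_ids or dosage.locus_ids
        dosage = dosage.dosage
    dosage = np.asarray(dosage, dtype=float)
    ok = np.isfinite(dosage)
    if not np.isin(dosage[ok], allowed).all():
        raise LandgenError(f"dosages outside the {ploidy} set {allowed}")
    n, L = dosage.shape
    rng = np.random.default_rng(seed)
    # gamma-poisson mixture == negative binomial with mean m, size theta
    lam = rng.gamma(overdispersion, depth_mean / overdispersion, size=(n, L))
    total = rng.poisson(lam)
    total[~ok] = 0
    alt = rng.binomial(total, np.where(ok, dosage, 0.0))
    return ReadDepthTable(
        sample_ids or [f"ind{i:04d}" for i in range(n)],
        locus_ids or [f"loc{j:05d}" for j in range(L)],
        total,
        alt,
    )


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------


def simulate_replicates(
    gm: GenotypeMatrix, error_rate: float, n_replicates: int, seed: int
) -> tuple[list[GenotypeMatrix], dict[str, list[str]]]:
    """Copy every individual ``n_replicates`` times with genotype-call noise.

    Each non-missing entry is independently flipped to one of the other two
    valid diploid dosages with probability ``error_rate``.
    """
    if not 0 <= error_rate < 0.5:
        raise LandgenError("need 0 <= error_rate < 0.5")
    rng = np.random.default_rng(seed)
    levels = np.array(DIPLOID_DOSAGES)
    reps: list[GenotypeMatrix] = []
    rep_map: dict[str, list[str]] = {s: [] for s in gm.sample_ids}
    for r in range(n_replicates):
        d = gm.dosage.copy()
        ok = np.isfinite(d)
        flip = ok & (rng.random(d.shape) < error_rate)
        if flip.any():
            cur = d[flip]
            # pick uniformly among the two other dosage levels
            offs = rng.integers(1, 3, size=cur.size)
            idx = (np.searchsorted(levels, cur) + offs) % 3
            d[flip] = levels[idx]
        ids = [f"{s}~rep{r + 1}" for s in gm.sample_ids]
        for s, rid in zip(gm.sample_ids, ids):
            rep_map[s].append(rid)
        reps.append(GenotypeMatrix(ids, list(gm.locus_ids), d))
    return reps, rep_map


def stack_replicates(reps: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Concatenate replicate matrices (shared loci) into one call set."""
    loci = reps[0].locus_ids
    for r in reps[1:]:
        if r.locus_ids != loci:
            raise LandgenError("replicates must share locus ids")
    return GenotypeMatrix(
        [s for r in reps for s in r.sample_ids],
        list(loci),
        np.vstack([r.dosage for r in reps]),
    )
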