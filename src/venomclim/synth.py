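"""Synthetic climate grids, sampling sites, and venom activities.

Everything downstream of raw data acquisition is testable against known
ground truth with this module: it fabricates smooth monthly climate
surfaces (trend + seeded Gaussian bumps + a seasonal cycle), places
sampling locations with within-location replication mimicking pooled
venom samples, and draws activities from a (possibly transformed)
linear model of the bioclim covariates with configurable noise.

The default scenario mirrors the sampling structure of the study this
package models: 115 venom samples pooled at 34 point locations, with
identity-scale activities of phospholipase-like magnitude (order 1e2
nmol/min/mg) and a linear signal explaining roughly half the variance.
Presets vary one failure mode at a time so that every diagnostic gate
fires on the data built to violate it:

========== ==========================================================
preset     what it exercises
========== ==========================================================
basic      Gaussian, homoscedastic, linear truth (all gates pass)
highsnr    like basic with a stronger signal (support recovery)
lognormal  truth on the ln scale (transform-cell downselection)
hetero     error SD proportional to a covariate (Breusch-Pagan), n=200
collinear  temperature indices from one shared latent field (VIF)
spatial    spatially correlated errors + a longitude-drifting slope
           (geographically weighted regression)
========== ==========================================================

Noise is parameterised by the population R^2 the linear signal should
attain at the sampled sites, which fixes sigma from the realised spread
of the noise-free linear predictor; an absolute ``sigma`` can be given
instead.  All randomness flows from one mandatory integer seed;
identical (config, seed) reproduce grids and tables bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .climate import compute_bioclim_grid, BIOCLIM_NAMES
from .geo import RasterGrid, GridTransform, extract_at_points
from .regression import back_transform

MONTH = np.arange(12)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic study."""

    seed: int
    nrow: int = 40
    ncol: int = 40
    px: float = 0.25                    # pixel size, degrees
    west: float = 70.0
    north: float = 30.0
    n_locations: int = 34
    n_samples: int = 115
    response: str = "activity"
    transform: str = "identity"         # scale on which the truth is linear
    intercept: float = 150.0            # transformed scale
    effect_sizes: dict = field(
        default_factory=lambda: {"TS": 30.0, "APN": 30.0, "AMDTR": 30.0}
    )                                   # per-SD effects on the transformed scale
    target_r2: float | None = 0.5       # fixes sigma unless sigma is given
    sigma: float | None = None
    hetero_covariate: str | None = None  # error SD proportional to this index
    hetero_strength: float = 2.0         # SD spans sigma .. (1+strength)*sigma
    spatial_error_range: float = 0.0     # degrees; 0 = independent errors
    beta_lon_gradient: dict = field(default_factory=dict)
    # ^ per-SD effect change per degree of longitude (spatially varying slope)
    collinear_climate: bool = False
    seasonal_amplitude: tuple[float, float] = (2.0, 9.0)   # deg C, across grid
    diurnal_range: tuple[float, float] = (6.0, 16.0)       # deg C
    base_temp: tuple[float, float] = (12.0, 28.0)          # deg C
    annual_ppt: tuple[float, float] = (300.0, 2800.0)      # mm
    n_bumps: int = 6

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_locations > self.n_samples:
            raise ValueError("n_locations cannot exceed n_samples")


@dataclass
class GroundTruth:
    """What the generator actually used, in raw-covariate units."""

    transform: str
    intercept: float
    beta: dict[str, float]              # raw units (per covariate unit)
    sigma: float
    noise_free_transformed: np.ndarray  # per sample
    noise_free_activity: np.ndarray
    redraw_count: int = 0
    beta_lon_gradient: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "transform": self.transform,
            "intercept": self.intercept,
            "beta": self.beta,
            "sigma": self.sigma,
            "redraw_count": self.redraw_count,
            "beta_lon_gradient": self.beta_lon_gradient,
            "noise_free_activity": [float(v) for v in self.noise_free_activity],
        }


def _smooth_field(rng, nrow, ncol, lo, hi, n_bumps, trend_axis=None):
    """Low-order trend + Gaussian bumps, rescaled into [lo, hi]."""
    rows, cols = np.mgrid[0:nrow, 0:ncol].astype(float)
    u, v = rows / max(nrow - 1, 1), cols / max(ncol - 1, 1)
    if trend_axis == "lon":
        f = v.copy()
    elif trend_axis == "lat":
        f = 1.0 - u
    else:
        a, b = rng.normal(size=2)
        f = a * u + b * v
    for _ in range(n_bumps):
        cu, cv = rng.uniform(0, 1, size=2)
        width = rng.uniform(0.1, 0.35)
        amp = rng.normal(0, 1)
        f = f + amp * np.exp(-(((u - cu) ** 2 + (v - cv) ** 2) / (2 * width**2)))
    fmin, fmax = f.min(), f.max()
    if fmax - fmin < 1e-12:
        return np.full((nrow, ncol), 0.5 * (lo + hi))
    return lo + (hi - lo) * (f - fmin) / (fmax - fmin)


def simulate_monthly_climate(cfg: ScenarioConfig) -> dict[str, RasterGrid]:
    """48 aligned grids: tmin/tmax/tavg/ppt for months 01..12.

    Construction guarantees tmax >= tavg >= tmin and ppt >= 0 at every
    pixel.  With ``collinear_climate`` the seasonal amplitude and the
    diurnal range are driven by the same latent field as the annual mean
    temperature, which makes AMT/TAR/AMDTR/TS strongly collinear.
    """
    rng = np.random.default_rng(cfg.seed)
    nrow, ncol = cfg.nrow, cfg.ncol
    t = GridTransform(west=cfg.west, north=cfg.north, px=cfg.px, py=cfg.px)

    base = _smooth_field(rng, nrow, ncol, *cfg.base_temp, cfg.n_bumps)
    if cfg.collinear_climate:
        z = (base - base.min()) / max(np.ptp(base), 1e-12)
        eps_a = _smooth_field(rng, nrow, ncol, 0.0, 1.0, cfg.n_bumps)
        eps_d = _smooth_field(rng, nrow, ncol, 0.0, 1.0, cfg.n_bumps)
        a_lo, a_hi = cfg.seasonal_amplitude
        d_lo, d_hi = cfg.diurnal_range
        amp = a_lo + (a_hi - a_lo) * np.clip(0.95 * z + 0.05 * eps_a, 0, 1)
        diurnal = d_lo + (d_hi - d_lo) * np.clip(0.95 * z + 0.05 * eps_d, 0, 1)
    else:
        amp = _smooth_field(rng, nrow, ncol, *cfg.seasonal_amplitude, cfg.n_bumps)
        diurnal = _smooth_field(rng, nrow, ncol, *cfg.diurnal_range, cfg.n_bumps)

    apn = _smooth_field(rng, nrow, ncol, *cfg.annual_ppt, cfg.n_bumps)
    # precipitation concentration: 0 -> uniform months, 1 -> monsoonal peak
    conc = _smooth_field(rng, nrow, ncol, 0.05, 0.95, cfg.n_bumps)
    peak = rng.integers(0, 12)

    grids: dict[str, RasterGrid] = {}
    cycle = np.cos(2 * np.pi * (MONTH[:, None, None] - 6) / 12.0)
    tavg = base[None] + amp[None] * cycle
    tmax = tavg + diurnal[None] / 2.0
    tmin = tavg - diurnal[None] / 2.0
    season = np.exp(
        conc[None] * 6.0 * np.cos(2 * np.pi * (MONTH[:, None, None] - peak) / 12.0)
    )
    ppt = apn[None] * season / season.sum(axis=0, keepdims=True)

    for i in range(12):
        m = f"{i + 1:02d}"
        for name, stack in (
            ("tmin", tmin), ("tmax", tmax), ("tavg", tavg), ("ppt", ppt)
        ):
            grids[f"{name}_{m}"] = RasterGrid(
                values=stack[i], transform=t, band_name=f"{name}_{m}"
            )
    return grids


def bioclim_grids(monthly: dict[str, RasterGrid]) -> dict[str, RasterGrid]:
    """Per-pixel bioclim indices from the 48 monthly grids."""
    ref = next(iter(monthly.values()))

    def stack(prefix):
        return np.stack(
            [monthly[f"{prefix}_{m + 1:02d}"].values for m in range(12)]
        ).astype(float)

    out = compute_bioclim_grid(
        stack("tmin"), stack("tmax"), stack("ppt"), stack("tavg")
    )
    return {
        name: RasterGrid(
            values=arr, transform=ref.transform, band_name=name, nodata=ref.nodata
        )
        for name, arr in out.items()
    }


def sample_sites(cfg: ScenarioConfig) -> pd.DataFrame:
    """Sites with pooled replication: n_samples rows, n_locations points.

    Each location's reported coordinate is its latent grid point plus a
    sub-pixel jitter drawn once and shared by all samples pooled there,
    so the table holds exactly ``n_locations`` unique (lon, lat) pairs.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    margin = cfg.px
    lon = rng.uniform(
        cfg.west + margin, cfg.west + cfg.ncol * cfg.px - margin, cfg.n_locations
    )
    lat = rng.uniform(
        cfg.north - cfg.nrow * cfg.px + margin, cfg.north - margin, cfg.n_locations
    )
    jitter = rng.uniform(-0.45, 0.45, size=(cfg.n_locations, 2)) * cfg.px
    lon = lon + jitter[:, 0]
    lat = lat + jitter[:, 1]

    base, extra = divmod(cfg.n_samples, cfg.n_locations)
    counts = np.full(cfg.n_locations, base)
    counts[:extra] += 1
    rows = []
    sid = 0
    for loc in range(cfg.n_locations):
        for _ in range(counts[loc]):
            rows.append(
                {
                    "sample_id": f"S{sid:03d}",
                    "location_id": loc,
                    "longitude": float(lon[loc]),
                    "latitude": float(lat[loc]),
                }
            )
            sid += 1
    return pd.DataFrame(rows)


def extract_covariates(
    sites: pd.DataFrame, bgrids: dict[str, RasterGrid]
) -> pd.DataFrame:
    """Bioclim index values at each sample's coordinates."""
    pts = list(zip(sites["longitude"], sites["latitude"]))
    data = {name: extract_at_points(bgrids[name], pts) for name in BIOCLIM_NAMES}
    return pd.DataFrame(data, index=sites.index)


def simulate_activities(
    sites: pd.DataFrame, X: pd.DataFrame, cfg: ScenarioConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw activities from the configured linear model of the covariates.

    tau(activity) = intercept + sum_j beta_j x_j [+ lon-gradient terms]
    + eps.  Effect sizes are specified per SD of each covariate at the
    sampled sites and converted to raw-unit betas here; sigma comes from
    ``target_r2`` unless given absolutely.  Samples whose back-
    transformed activity is not positive are redrawn (fresh noise);
    a redraw fraction above 10% warns that the scenario fights tau.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n = len(sites)
    predictors = list(cfg.effect_sizes)
    missing = [p for p in predictors if p not in X.columns]
    if missing:
        raise ValueError(f"covariate frame lacks {missing}")

    beta = {}
    for name, per_sd in cfg.effect_sizes.items():
        sd = float(np.std(X[name], ddof=1))
        if sd <= 0:
            raise ValueError(f"covariate {name} is constant at the sites")
        beta[name] = per_sd / sd

    grad_raw = {}
    lin = np.full(n, cfg.intercept, dtype=float)
    for name in predictors:
        b = np.full(n, beta[name])
        if cfg.beta_lon_gradient.get(name):
            sd = float(np.std(X[name], ddof=1))
            g = cfg.beta_lon_gradient[name] / sd
            grad_raw[name] = g
            lon0 = float(sites["longitude"].mean())
            b = b + g * (sites["longitude"].to_numpy() - lon0)
        lin += b * X[name].to_numpy(dtype=float)

    if cfg.sigma is not None:
        sigma = float(cfg.sigma)
    else:
        r2 = cfg.target_r2 if cfg.target_r2 is not None else 0.5
        if not (0 < r2 < 1):
            raise ValueError("target_r2 must lie in (0, 1)")
        s_lin = float(np.std(lin, ddof=1))
        sigma = s_lin * np.sqrt((1 - r2) / r2)

    sd_i = np.full(n, sigma)
    if cfg.hetero_covariate is not None:
        # SD increases monotonically in the covariate, spanning
        # sigma .. (1+strength)*sigma uniformly over its empirical CDF so
        # the violation is felt at every site regardless of the covariate's
        # marginal shape.
        h = X[cfg.hetero_covariate].to_numpy(dtype=float)
        z = stats.rankdata(h, method="average")
        z = (z - z.min()) / max(z.max() - z.min(), 1.0)
        sd_i = sigma * (1.0 + cfg.hetero_strength * z)

    def draw_noise(idx=None):
        if cfg.spatial_error_range > 0:
            coords = sites[["longitude", "latitude"]].to_numpy(dtype=float)
            d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
            corr = np.exp(-d / cfg.spatial_error_range)
            L = np.linalg.cholesky(corr + 1e-10 * np.eye(n))
            eps = sd_i * (L @ rng.standard_normal(n))
            return eps if idx is None else eps[idx]
        if idx is None:
            return sd_i * rng.standard_normal(n)
        return sd_i[idx] * rng.standard_normal(len(idx))

    y_t = lin + draw_noise()
    activity = back_transform(y_t, cfg.transform)
    redraws = 0
    for _ in range(100):
        bad = np.flatnonzero(~(activity > 0) | ~np.isfinite(activity))
        if bad.size == 0:
            break
        redraws += bad.size
        y_t[bad] = lin[bad] + draw_noise(bad)
        activity = back_transform(y_t, cfg.transform)
    else:
        raise RuntimeError("could not draw positive activities; scenario inconsistent")
    if redraws > 0.1 * n:
        warnings.warn(
            f"{redraws} redraws for {n} samples: scenario is inconsistent "
            f"with transform {cfg.transform!r}",
            stacklevel=2,
        )

    table = sites.copy()
    table[cfg.response] = activity
    truth = GroundTruth(
        transform=cfg.transform,
        intercept=cfg.intercept,
        beta=beta,
        sigma=sigma,
        noise_free_transformed=lin,
        noise_free_activity=np.asarray(back_transform(lin, cfg.transform)),
        redraw_count=redraws,
        beta_lon_gradient=grad_raw,
    )
    return table, truth


@dataclass
class Scenario:
    """A fully generated synthetic study."""

    config: ScenarioConfig
    monthly: dict[str, RasterGrid]
    bioclim: dict[str, RasterGrid]
    sites: pd.DataFrame
    covariates: pd.DataFrame
    table: pd.DataFrame
    truth: GroundTruth


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Run the whole generator: climate -> indices -> sites -> activities."""
    monthly = simulate_monthly_climate(cfg)
    bgrids = bioclim_grids(monthly)
    sites = sample_sites(cfg)
    X = extract_covariates(sites, bgrids)
    table, truth = simulate_activities(sites, X, cfg)
    return Scenario(
        config=cfg,
        monthly=monthly,
        bioclim=bgrids,
        sites=sites,
        covariates=X,
        table=table,
        truth=truth,
    )


PRESETS = ("basic", "highsnr", "lognormal", "hetero", "collinear", "spatial")


def preset_config(name: str, seed: int, **overrides) -> ScenarioConfig:
    """Named scenario variants; see the module docstring for intent."""
    if name == "basic":
        cfg = ScenarioConfig(seed=seed)
    elif name == "highsnr":
        cfg = ScenarioConfig(seed=seed, target_r2=0.75)
    elif name == "lognormal":
        cfg = ScenarioConfig(
            seed=seed,
            transform="ln",
            intercept=4.6,
            effect_sizes={"TS": 0.5, "APN": 0.5, "AMDTR": 0.5},
            target_r2=0.75,
        )
    elif name == "hetero":
        cfg = ScenarioConfig(
            seed=seed,
            n_locations=50,
            n_samples=200,
            hetero_covariate="TS",
            target_r2=0.5,
        )
    elif name == "collinear":
        cfg = ScenarioConfig(
            seed=seed,
            collinear_climate=True,
            effect_sizes={"TAR": 30.0, "AMDTR": 30.0, "APN": 30.0},
            intercept=200.0,
        )
    elif name == "spatial":
        cfg = ScenarioConfig(
            seed=seed,
            spatial_error_range=1.5,
            beta_lon_gradient={"TS": 8.0},
            target_r2=0.6,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    return replace(cfg, **overrides) if overrides else cfg
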