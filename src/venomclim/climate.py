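"""Bioclimatic indices from monthly climate normals.

Seven summary indices of a 12-month temperature/precipitation climatology
are used as regression predictors throughout the package:

====== =============================================== =========
name   definition                                      units
====== =============================================== =========
AMT    annual mean temperature, mean(Tavg)             deg C
TAR    temperature annual range, max(Tmax) - min(Tmin) deg C
AMDTR  annual mean diurnal range, mean(Tmax - Tmin)    deg C
I      isothermality, 100 * AMDTR / TAR                percent
TS     temperature seasonality, 100 * SD(Tavg) /
       (AMT + 273.15)                                  CV x 100
APN    annual precipitation, sum(PPT)                  mm
PS     precipitation seasonality, 100 * SD(PPT) /
       (1 + APN/12)                                    CV x 100
====== =============================================== =========

TS and PS are coefficient-of-variation forms (temperature in kelvin so
the CV is scale-meaningful; precipitation offset by 1 mm to keep arid
pixels finite).  The WorldClim rasters ship BIO4 as plain SD(Tavg)x100
instead; a ``worldclim_bio4`` compatibility switch reproduces that.
The standard deviation defaults to the sample (n-1) convention of R's
``sd``; ``sd_denominator="n"`` selects the population convention used
by WorldClim's own generation code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BIOCLIM_NAMES = ("AMT", "TAR", "AMDTR", "I", "TS", "APN", "PS")


class MissingDataError(ValueError):
    """A monthly climate vector contains non-finite values."""


@dataclass(frozen=True)
class MonthlyClimate:
    """Twelve monthly values of Tmin/Tmax/Tavg (deg C) and PPT (mm).

    ``tavg`` defaults to ``(tmax + tmin) / 2`` when not supplied.
    """

    tmin: np.ndarray
    tmax: np.ndarray
    ppt: np.ndarray
    tavg: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        for name in ("tmin", "tmax", "ppt"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (12,):
                raise ValueError(f"{name} must have length 12, got shape {v.shape}")
            object.__setattr__(self, name, v)
        if self.tavg is None:
            object.__setattr__(self, "tavg", (self.tmax + self.tmin) / 2.0)
        else:
            v = np.asarray(self.tavg, dtype=float)
            if v.shape != (12,):
                raise ValueError(f"tavg must have length 12, got shape {v.shape}")
            object.__setattr__(self, "tavg", v)
        for name in ("tmin", "tmax", "tavg", "ppt"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise MissingDataError(f"non-finite values in monthly {name}")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin in at least one month")
        if np.any(self.ppt < 0):
            raise ValueError("negative monthly precipitation")


@dataclass(frozen=True)
class BioclimVector:
    """The seven indices for one site or pixel; ``iso`` is NaN when TAR=0."""

    amt: float
    tar: float
    amdtr: float
    iso: float
    ts: float
    apn: float
    ps: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.amt, self.tar, self.amdtr, self.iso, self.ts, self.apn, self.ps]
        )


def _sd(x: np.ndarray, axis=None, *, sd_denominator: str = "n-1") -> np.ndarray:
    if sd_denominator == "n-1":
        return np.std(x, axis=axis, ddof=1)
    if sd_denominator == "n":
        return np.std(x, axis=axis, ddof=0)
    raise ValueError(f"sd_denominator must be 'n' or 'n-1', got {sd_denominator!r}")


def temperature_seasonality(
    tavg, *, sd_denominator: str = "n-1", worldclim_bio4: bool = False
):
    """CV-form temperature seasonality, 100*SD(Tavg)/(AMT+273.15).

    With ``worldclim_bio4=True`` returns WorldClim's BIO4 = 100*SD(Tavg).
    """
    tavg = np.asarray(tavg, dtype=float)
    if tavg.shape[-1] != 12:
        raise ValueError("tavg must have 12 months on the last axis")
    if not np.all(np.isfinite(tavg)):
        raise MissingDataError("non-finite values in tavg")
    sd = _sd(tavg, axis=-1, sd_denominator=sd_denominator)
    if worldclim_bio4:
        return 100.0 * sd
    amt = tavg.mean(axis=-1)
    return 100.0 * sd / (amt + 273.15)


def precipitation_seasonality(ppt, *, sd_denominator: str = "n-1"):
    """CV-form precipitation seasonality, 100*SD(PPT)/(1 + APN/12)."""
    ppt = np.asarray(ppt, dtype=float)
    if ppt.shape[-1] != 12:
        raise ValueError("ppt must have 12 months on the last axis")
    if not np.all(np.isfinite(ppt)):
        raise MissingDataError("non-finite values in ppt")
    if np.any(ppt < 0):
        raise ValueError("negative monthly precipitation")
    sd = _sd(ppt, axis=-1, sd_denominator=sd_denominator)
    apn = ppt.sum(axis=-1)
    return 100.0 * sd / (1.0 + apn / 12.0)


def compute_bioclim(
    mc: MonthlyClimate,
    *,
    sd_denominator: str = "n-1",
    worldclim_bio4: bool = False,
) -> BioclimVector:
    """Compute the seven indices for one site.

    Isothermality is undefined (NaN) when the annual range is zero.
    """
    amt = float(mc.tavg.mean())
    tar = float(mc.tmax.max() - mc.tmin.min())
    amdtr = float((mc.tmax - mc.tmin).mean())
    iso = float(100.0 * amdtr / tar) if tar > 0 else float("nan")
    ts = float(
        temperature_seasonality(
            mc.tavg, sd_denominator=sd_denominator, worldclim_bio4=worldclim_bio4
        )
    )
    apn = float(mc.ppt.sum())
    ps = float(precipitation_seasonality(mc.ppt, sd_denominator=sd_denominator))
    return BioclimVector(amt=amt, tar=tar, amdtr=amdtr, iso=iso, ts=ts, apn=apn, ps=ps)


def compute_bioclim_grid(
    tmin: np.ndarray,
    tmax: np.ndarray,
    ppt: np.ndarray,
    tavg: np.ndarray | None = None,
    *,
    sd_denominator: str = "n-1",
    worldclim_bio4: bool = False,
) -> dict[str, np.ndarray]:
    """Vectorised per-pixel indices from (12, nrow, ncol) monthly stacks.

    NaN pixels (NoData) propagate to NaN in every index.  Returns a dict
    keyed by the names in :data:`BIOCLIM_NAMES`.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    ppt = np.asarray(ppt, dtype=float)
    if tmin.shape != tmax.shape or tmin.shape != ppt.shape or tmin.shape[0] != 12:
        raise ValueError("monthly stacks must share a (12, nrow, ncol) shape")
    if tavg is None:
        tavg = (tmax + tmin) / 2.0
    else:
        tavg = np.asarray(tavg, dtype=float)
        if tavg.shape != tmin.shape:
            raise ValueError("tavg stack shape mismatch")

    # months on the last axis for the seasonality helpers
    tavg_m = np.moveaxis(tavg, 0, -1)
    ppt_m = np.moveaxis(ppt, 0, -1)

    amt = tavg.mean(axis=0)
    tar = tmax.max(axis=0) - tmin.min(axis=0)
    amdtr = (tmax - tmin).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        iso = np.where(tar > 0, 100.0 * amdtr / tar, np.nan)
        sd_t = _sd(tavg_m, axis=-1, sd_denominator=sd_denominator)
        ts = 100.0 * sd_t if worldclim_bio4 else 100.0 * sd_t / (amt + 273.15)
        apn = ppt.sum(axis=0)
        ps = 100.0 * _sd(ppt_m, axis=-1, sd_denominator=sd_denominator) / (1.0 + apn / 12.0)

    nodata = ~(
        np.all(np.isfinite(tmin), axis=0)
        & np.all(np.isfinite(tmax), axis=0)
        & np.all(np.isfinite(ppt), axis=0)
    )
    out = {}
    for name, arr in zip(
        BIOCLIM_NAMES, (amt, tar, amdtr, iso, ts, apn, ps), strict=True
    ):
        arr = np.asarray(arr, dtype=float).copy()
        arr[nodata] = np.nan
        out[name] = arr
    return out


class BioclimFeatures:
    """Transformer: monthly-climate columns -> the seven index columns.

    Accepts a DataFrame with columns ``tmin_01..tmin_12``, ``tmax_01..``,
    ``ppt_01..`` (and optionally ``tavg_01..``) and returns a DataFrame
    with the :data:`BIOCLIM_NAMES` columns, one row per input row.
    Stateless; ``fit`` exists for pipeline compatibility.
    """

    def __init__(self, sd_denominator: str = "n-1", worldclim_bio4: bool = False):
        self.sd_denominator = sd_denominator
        self.worldclim_bio4 = worldclim_bio4

    def get_params(self, deep: bool = True) -> dict:
        return {
            "sd_denominator": self.sd_denominator,
            "worldclim_bio4": self.worldclim_bio4,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        import pandas as pd

        months = [f"{m:02d}" for m in range(1, 13)]

        def block(prefix):
            cols = [f"{prefix}_{m}" for m in months]
            missing = [c for c in cols if c not in X.columns]
            if missing:
                raise ValueError(f"missing monthly columns: {missing}")
            return X[cols].to_numpy(dtype=float)

        tmin, tmax, ppt = block("tmin"), block("tmax"), block("ppt")
        has_tavg = all(f"tavg_{m}" in X.columns for m in months)
        tavg = block("tavg") if has_tavg else None
        rows = []
        for i in range(len(X)):
            mc = MonthlyClimate(
                tmin=tmin[i],
                tmax=tmax[i],
                ppt=ppt[i],
                tavg=None if tavg is None else tavg[i],
            )
            rows.append(
                compute_bioclim(
                    mc,
                    sd_denominator=self.sd_denominator,
                    worldclim_bio4=self.worldclim_bio4,
                ).as_array()
            )
        return pd.DataFrame(rows, columns=list(BIOCLIM_NAMES), index=X.index)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
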