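"""Reduction of raw enzymatic assay readouts to per-sample activities.

Chromogenic venom assays report absorbance kinetics; a parallel standard
curve converts absorbance to analyte amount.  Specific activity is

    rate (AU/min)  /  curve slope (AU/nmol)  /  venom mass (mg)
        ->  nmol substrate turned over per minute per mg venom,

the unit used for phospholipase A2 and L-amino acid oxidase.  Protease
(azocasein) activity is instead reported relative to a purified bovine
protease standard, as a percentage.  Replicates (typically triplicates)
are averaged before modelling; the replicate SD is carried for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class DegenerateCurveError(ValueError):
    """Standard curve has no usable positive slope."""


@dataclass(frozen=True)
class StandardCurve:
    """OLS line through (known amount, absorbance) pairs."""

    levels: np.ndarray    # nmol
    responses: np.ndarray  # AU
    slope: float          # AU per nmol
    intercept: float      # AU
    r2: float


@dataclass(frozen=True)
class KineticSeries:
    """Absorbance time course for one reaction well."""

    times: np.ndarray        # minutes
    absorbances: np.ndarray  # AU
    venom_mass: float        # mg protein in the reaction

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if t.size < 2 or t.size != a.size:
            raise ValueError("need >= 2 matched (time, absorbance) points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.venom_mass <= 0:
            raise ValueError("venom_mass must be positive (mg)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbances", a)


@dataclass(frozen=True)
class ActivityRecord:
    enzyme: str
    value: float          # nmol/min/mg, or percent for protease
    replicate_sd: float = float("nan")
    flags: tuple[str, ...] = field(default=())


def fit_standard_curve(levels, responses) -> StandardCurve:
    """Least-squares calibration line; errors if all levels coincide."""
    levels = np.asarray(levels, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if levels.size < 2 or levels.size != responses.size:
        raise ValueError("need >= 2 matched (level, response) points")
    if np.ptp(levels) == 0:
        raise DegenerateCurveError("all standard levels identical")
    res = stats.linregress(levels, responses)
    return StandardCurve(
        levels=levels,
        responses=responses,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def specific_activity(
    k: KineticSeries, sc: StandardCurve, enzyme: str = "PLA2"
) -> ActivityRecord:
    """Kinetic rate in nmol/min/mg via the standard curve.

    A negative fitted rate (photobleaching, pipetting noise) is clipped to
    zero and flagged rather than reported as a negative activity.
    """
    if sc.slope <= 0:
        raise DegenerateCurveError(
            f"standard curve slope {sc.slope} is not positive"
        )
    rate = float(stats.linregress(k.times, k.absorbances).slope)  # AU/min
    flags: tuple[str, ...] = ()
    if rate < 0:
        rate = 0.0
        flags = ("negative_rate_clipped",)
    value = rate / sc.slope / k.venom_mass
    return ActivityRecord(enzyme=enzyme, value=value, flags=flags)


def relative_activity(sample_abs: float, standard_abs: float) -> float:
    """Percent activity relative to the reference standard."""
    if standard_abs <= 0:
        raise ValueError("standard absorbance must be positive")
    return 100.0 * sample_abs / standard_abs


def average_replicates(values, enzyme: str) -> ActivityRecord:
    """Mean of replicate activities; SD (n-1) carried for reporting."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("no replicate values")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    return ActivityRecord(enzyme=enzyme, value=float(values.mean()), replicate_sd=sd)


def oneway_anova(groups) -> tuple[float, float, int, int]:
    """Classical one-way ANOVA.

    Returns ``(F, p, df_between, df_within)``.  With zero within-group
    variance and unequal means the statistic is infinite and p is 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n - k
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0, dfb, dfw
        return float("inf"), 0.0, dfb, dfw
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return float(f), p, dfb, dfw
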