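"""Per-generation HAC loss rates from retained-reporter fractions.

All three measurement channels — imaging (%GFP− among QC-passing
nuclei), flow cytometry (GFP gating among live, dye-negative events) and
FISH (HAC-bearing metaphase spreads) — yield a fraction of cells that
retained the reporter.  Under the exponential retention model the
treated fraction after N generations is

    P_t = P_c * (1 - R) ** N

where ``P_c`` is the matched negative-control (scrambled siRNA) fraction
— so background GFP− cells present in the control are absorbed — and R
is the per-generation loss rate.  Inverting,

    R = 1 - (P_t / P_c) ** (1 / N)

clamped to [0, 1]: a treated fraction above the control's is reported as
R = 0.  N comes from the treatment duration and a doubling time fitted
to a growth curve by log-linear least squares.

The model inversion is isolated in :func:`estimate_loss_rate` so an
alternative rate dialect can be swapped in one place.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthCurve",
    "LossRateEstimate",
    "fit_doubling_time",
    "generations_elapsed",
    "estimate_loss_rate",
    "fraction_from_facs",
    "fraction_from_fish",
]


@dataclass
class GrowthCurve:
    """A fitted exponential growth curve.

    ``doubling_time_hours`` = 1/slope of the log2(count)-vs-time fit.
    """

    time_hours: np.ndarray
    counts: np.ndarray
    doubling_time_hours: float
    slope: float
    intercept: float
    r_squared: float


@dataclass
class LossRateEstimate:
    """A per-generation HAC loss rate with a delta-method CI.

    ``loss_rate_per_generation`` lies in [0, 1]; ``clamped`` records
    whether the raw estimate fell outside and was clipped (e.g. the
    treated fraction exceeded the control's).  The CI propagates the
    binomial standard errors of both input fractions and is ``None``
    when the denominators were not supplied.
    """

    fraction_retained_sample: float
    fraction_retained_control: float
    n_generations: float
    loss_rate_per_generation: float
    ci_low: float | None = None
    ci_high: float | None = None
    clamped: bool = False

    @property
    def pct_per_generation(self) -> float:
        return 100.0 * self.loss_rate_per_generation


def fit_doubling_time(curve: pd.DataFrame) -> GrowthCurve:
    """Fit a doubling time by least squares on log2(count) vs time.

    ``curve`` needs ``time_hours`` and ``count`` columns with >= 3
    strictly positive counts.  A non-positive fitted slope (no growth)
    is an error.
    """
    t = np.asarray(curve["time_hours"], dtype=float)
    n = np.asarray(curve["count"], dtype=float)
    if len(t) < 3:
        raise ValueError("growth-curve fit needs >= 3 time points")
    if np.any(n <= 0):
        raise ValueError("counts must be strictly positive")
    res = stats.linregress(t, np.log2(n))
    if res.slope <= 0:
        raise ValueError(
            f"fitted slope {res.slope:.4g}/h is non-positive: no growth detected"
        )
    return GrowthCurve(
        time_hours=t,
        counts=n,
        doubling_time_hours=1.0 / res.slope,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def generations_elapsed(duration_hours: float, doubling_time_hours: float) -> float:
    """Generations elapsed in ``duration_hours``; fractional values allowed
    (96 h at a 24 h doubling time gives 4)."""
    if duration_hours <= 0 or doubling_time_hours <= 0:
        raise ValueError("duration and doubling time must be positive")
    return duration_hours / doubling_time_hours


def estimate_loss_rate(
    sample_fraction_retained: float,
    control_fraction_retained: float,
    n_generations: float,
    n_sample: int | None = None,
    n_control: int | None = None,
    ci_level: float = 0.95,
) -> LossRateEstimate:
    """Invert the exponential retention model for the per-generation rate.

    R = 1 - (P_sample / P_control) ** (1/N), clamped to [0, 1].  When
    the counts behind the two proportions are given (``n_sample``,
    ``n_control``), a delta-method CI propagates their independent
    binomial standard errors; the CI bounds are clipped to [0, 1].
    """
    ps, pc, n = sample_fraction_retained, control_fraction_retained, n_generations
    if not 0.0 <= ps <= 1.0 or not 0.0 <= pc <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    if pc == 0.0:
        raise ValueError("control fraction retained is 0: loss rate undefined")
    if ps == 0.0:
        # complete loss: rate is 1 regardless of N
        return LossRateEstimate(ps, pc, n, 1.0)
    if n <= 0:
        raise ValueError("n_generations must be positive")

    ratio = ps / pc
    raw = 1.0 - ratio ** (1.0 / n)
    clamped = raw < 0.0
    if clamped:
        logger.warning(
            "sample fraction %.4g exceeds control %.4g; loss rate clamped to 0",
            ps, pc,
        )
    rate = min(max(raw, 0.0), 1.0)

    ci_low = ci_high = None
    if n_sample is not None and n_control is not None:
        if n_sample < 1 or n_control < 1:
            raise ValueError("sample sizes must be >= 1")
        # delta method on R(ps, pc) with independent binomial variances
        d_ps = -(1.0 / n) * ratio ** (1.0 / n - 1.0) / pc
        d_pc = (1.0 / n) * ratio ** (1.0 / n - 1.0) * ps / pc**2
        var = (d_ps**2) * ps * (1 - ps) / n_sample + (d_pc**2) * pc * (1 - pc) / n_control
        se = math.sqrt(max(var, 0.0))
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        ci_low = max(raw - z * se, 0.0)
        ci_high = min(raw + z * se, 1.0)
    return LossRateEstimate(ps, pc, n, rate, ci_low, ci_high, clamped)


def fraction_from_facs(
    events: pd.DataFrame,
    dye_threshold: float,
    gfp_threshold: float,
) -> float:
    """GFP+ fraction among live flow-cytometry events.

    Events with viability-dye intensity at or above ``dye_threshold``
    are gated out as dead; among the remainder the fraction with GFP
    intensity at or above ``gfp_threshold`` is returned.
    """
    live = events[events["viability_dye_intensity"] < dye_threshold]
    if len(live) == 0:
        raise ValueError("no live events after viability-dye gating")
    return float((live["gfp_intensity"] >= gfp_threshold).mean())


def fraction_from_fish(
    n_spreads_with_hac: int,
    n_spreads_total: int,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """HAC-retained fraction from metaphase-spread counts, with a
    Clopper–Pearson binomial CI (exact, sensible at 0 or n successes)."""
    if n_spreads_total < 1:
        raise ValueError("total spread count must be >= 1")
    if not 0 <= n_spreads_with_hac <= n_spreads_total:
        raise ValueError("HAC-positive spreads must lie in [0, total]")
    frac = n_spreads_with_hac / n_spreads_total
    low, high = proportion_confint(
        n_spreads_with_hac, n_spreads_total, alpha=1 - ci_level, method="beta"
    )
    return frac, (float(low), float(high))
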