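"""Three-parameter sigmoidal growth model for microplate OD600 curves.

The model is a logistic curve anchored to zero at t = 0:

    dOD(t) = dOD_asym * [ 1/(1 + exp(k*(tc - t))) - 1/(1 + exp(k*tc)) ]

with ``dOD_asym`` the growth level at stationary phase, ``k`` the growth
rate (1/h) and ``tc`` the inflection time (h, time of maximal growth rate).
Note the plateau is dOD_asym * (1 - 1/(1 + exp(k*tc))), slightly below
dOD_asym; the reported asymptote is the fitted dOD_asym parameter itself,
matching common usage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GrowthCurve",
    "GrowthParameters",
    "eval_growth_model",
    "blank_correct",
    "drop_replicate_outlier",
    "fit_growth",
    "summarize_kinetics",
]

NO_GROWTH_FLOOR = 0.05  # max dOD below this -> "no growth", no fit attempted


@dataclass(frozen=True)
class GrowthCurve:
    """One blank-corrected OD600 time series."""

    strain: str
    substrate: str
    replicate_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if t.ndim != 1 or t.shape != y.shape or t.size < 5:
            raise ValueError("times and od must be equal-length 1-D arrays, n >= 5")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)


@dataclass(frozen=True)
class GrowthParameters:
    od_asym: float | None
    k: float | None
    tc: float | None
    rss: float | None = None
    converged: bool = False
    no_growth: bool = False

    @property
    def accepted(self) -> bool:
        return self.converged and not self.no_growth


def eval_growth_model(od_asym: float, k: float, tc: float, t) -> np.ndarray:
    """Evaluate the growth model; vectorized over t, exact zero at t = 0."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        term = 1.0 / (1.0 + np.exp(k * (tc - t)))
        offset = 1.0 / (1.0 + np.exp(k * tc))
    return od_asym * (term - offset)


def blank_correct(od, blank_mean: float) -> np.ndarray:
    """Subtract the negative-control (no-carbohydrate) mean; clip at 0."""
    return np.clip(np.asarray(od, dtype=float) - blank_mean, 0.0, None)


def drop_replicate_outlier(
    values: np.ndarray, min_replicates: int = 3, sd_factor: float = 3.0
) -> tuple[np.ndarray, int | None]:
    """Remove the single farthest-from-mean replicate if it deviates by
    more than ``sd_factor`` times the SD of the remaining replicates, and
    at least ``min_replicates`` would remain.

    Returns the retained values and the dropped index (or None).
    """
    values = np.asarray(values, dtype=float)
    if values.size <= min_replicates:
        return values, None
    dev = np.abs(values - values.mean())
    idx = int(np.argmax(dev))
    rest = np.delete(values, idx)
    sd_rest = rest.std(ddof=1)
    if sd_rest > 0 and dev[idx] > sd_factor * sd_rest:
        return rest, idx
    return values, None


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    od0 = float(y.max())
    slopes = np.diff(y) / np.diff(t)
    i = int(np.argmax(slopes))
    tc0 = float(0.5 * (t[i] + t[i + 1]))
    # logistic max slope = od_asym*k/4
    k0 = max(4.0 * float(slopes[i]) / max(od0, 1e-12), 1e-3)
    return np.array([od0, k0, max(tc0, 1e-3)])


def fit_growth(
    curve: GrowthCurve, no_growth_floor: float = NO_GROWTH_FLOOR
) -> GrowthParameters:
    """Nonlinear least-squares fit of the growth model to one curve.

    Initialization: od_asym from max(od), tc from the time of steepest
    finite-difference slope, k from that slope.  A small multi-start over
    perturbed initial values guards against bad starts.  Flat curves (range
    below ``no_growth_floor``) return a "no growth" result rather than a fit.
    """
    # time is measured from the first observation (inoculation), so the fit
    # is invariant to a uniform time-axis offset; tc is reported in the
    # original coordinates
    t0 = float(curve.times[0])
    t, y = curve.times - t0, curve.od
    if float(y.max() - y.min()) < no_growth_floor:
        return GrowthParameters(None, None, None, None, converged=False, no_growth=True)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return eval_growth_model(*theta, t) - y

    x0 = _initial_guess(t, y)
    starts = [x0]
    for mult in (0.5, 2.0):
        starts.append(x0 * np.array([1.0, mult, 1.0]))
        starts.append(x0 * np.array([1.0, 1.0, mult]))
    best = None
    lb = np.array([1e-6, 1e-6, 1e-6])
    ub = np.array([np.inf, np.inf, np.inf])
    for s in starts:
        try:
            sol = least_squares(
                residuals, np.clip(s, lb, None), bounds=(lb, ub),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        return GrowthParameters(None, None, None, None, converged=False)
    od_asym, k, tc = (float(v) for v in best.x)
    rss = float(2.0 * best.cost)
    return GrowthParameters(od_asym, k, tc + t0, rss, converged=True)


def summarize_kinetics(fits: pd.DataFrame) -> pd.DataFrame:
    """Per strain x substrate mean and sample SD of od_asym and k.

    Parameters
    ----------
    fits : DataFrame
        Columns strain, substrate, od_asym, k (one row per accepted fit).
        Groups with a single fit report SD as NaN (undefined); empty groups
        are excluded with a warning.
    """
    required = {"strain", "substrate", "od_asym", "k"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fits table missing columns: {sorted(missing)}")
    fits = fits.dropna(subset=["od_asym", "k"])
    rows = []
    for (strain, substrate), grp in fits.groupby(["strain", "substrate"], sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empties
            warnings.warn(f"empty group {strain}/{substrate} excluded")
            continue
        rows.append(
            {
                "strain": strain,
                "substrate": substrate,
                "n": len(grp),
                "od_asym_mean": grp["od_asym"].mean(),
                "od_asym_sd": grp["od_asym"].std(ddof=1),
                "k_mean": grp["k"].mean(),
                "k_sd": grp["k"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)
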