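"""Decay-curve fitting and half-life extraction.

Three fitted families cover every readout in the package:

* single exponentials for receptor association/dissociation phases,
* gamma survival functions over an integer shape grid for the cascade
  step-off response (k = 1 recovers the plain exponential),
* exponential fits to light/dark mRNA ratio series.

All fits are deterministic: nonlinear least squares with a fixed multi-start
list of rate guesses, and bootstrap confidence intervals driven by an explicit
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core_model import CascadeParams, gamma_survival, survival_quantile

__all__ = [
    "DecayTrace",
    "ExpFit",
    "GammaSurvivalFit",
    "RatioDecay",
    "FitError",
    "normalize_trace",
    "fit_exponential",
    "time_to_fraction",
    "fit_gamma_survival",
    "bootstrap_ci",
    "ratio_decay_halflife",
    "time_to_half_max",
]


class FitError(RuntimeError):
    """Raised when a fit fails to converge or is degenerate; never silent."""


@dataclass(frozen=True)
class DecayTrace:
    """A time series around a perturbation at ``t_zero`` (illumination onset)."""

    times: np.ndarray
    values: np.ndarray
    t_zero: float = 0.0
    unit: str = "s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape:
            raise ValueError("times and values must have the same shape")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def window(self, start: float, end: float) -> "DecayTrace":
        """Sub-trace with start <= t <= end (t_zero unchanged)."""
        sel = (self.times >= start) & (self.times <= end)
        return replace(self, times=self.times[sel], values=self.values[sel])

    @property
    def post(self) -> tuple[np.ndarray, np.ndarray]:
        sel = self.times >= self.t_zero
        return self.times[sel], self.values[sel]


@dataclass(frozen=True)
class ExpFit:
    rate: float  # 1/time-unit
    amplitude: float
    baseline: float
    direction: str  # "decay" | "rise"
    ci95: tuple[float, float]
    sse: float

    @property
    def half_life(self) -> float:
        return np.log(2) / self.rate


@dataclass(frozen=True)
class GammaSurvivalFit:
    shape: int
    scale: float
    half_life: float
    onset_time: float  # time to a 1% decrease of the fitted survival curve
    sse: float
    ci95_half_life: tuple[float, float]

    @property
    def params(self) -> CascadeParams:
        return CascadeParams(self.shape, self.scale)


@dataclass(frozen=True)
class RatioDecay:
    half_life: float  # from exponential fit, minutes
    rate: float  # 1/min
    half_crossing: float | None  # first linear-interpolated crossing of R = 0.5
    finite: bool


def normalize_trace(
    trace: DecayTrace,
    mode: str = "pre_mean_to_unit_min_to_zero",
    baseline_window: tuple[float, float] | None = None,
) -> DecayTrace:
    """Rescale a trace by one of the two conventions used for raw readouts.

    ``pre_mean_to_unit_min_to_zero``
        mean of the pre-``t_zero`` values maps to 1, the global minimum to 0
        (membrane-ratio convention).
    ``baseline_subtract_scale_max``
        baseline subtracted, then scaled so the maximum is 1 (relative
        calcium convention).  ``baseline_window`` overrides where the baseline
        is measured (default: everything before ``t_zero``).
    """
    if baseline_window is None:
        pre = trace.values[trace.times < trace.t_zero]
    else:
        sel = (trace.times >= baseline_window[0]) & (trace.times <= baseline_window[1])
        pre = trace.values[sel]
    if pre.size < 3:
        raise ValueError("need at least 3 baseline points before t_zero")
    baseline = float(np.mean(pre))

    meta = dict(trace.meta)
    if mode == "pre_mean_to_unit_min_to_zero":
        lo = float(np.min(trace.values))
        span = baseline - lo
        if span <= 0:
            meta["degenerate"] = True
            return replace(trace, values=np.zeros_like(trace.values), meta=meta)
        vals = (trace.values - lo) / span
    elif mode == "baseline_subtract_scale_max":
        shifted = trace.values - baseline
        hi = float(np.max(shifted))
        if hi <= 0:
            meta["degenerate"] = True
            return replace(trace, values=np.zeros_like(trace.values), meta=meta)
        vals = shifted / hi
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    meta["normalized"] = mode
    return replace(trace, values=vals, meta=meta)


def _exp_model(direction: str):
    if direction == "decay":
        return lambda t, rate, amp, base: base + amp * np.exp(-rate * t)
    if direction == "rise":
        return lambda t, rate, amp, base: base + amp * (1.0 - np.exp(-rate * t))
    raise ValueError("direction must be 'decay' or 'rise'")


def fit_exponential(trace: DecayTrace, direction: str = "decay") -> ExpFit:
    """Least-squares single-exponential fit to the post-``t_zero`` phase.

    Three deterministic starts with log-spaced rate guesses guard against
    local minima; non-convergence of all starts raises :class:`FitError`.
    """
    t, y = trace.post
    if t.size < 5:
        raise ValueError("need at least 5 points after t_zero")
    t = t - trace.t_zero
    model = _exp_model(direction)
    span = max(t[-1], np.finfo(float).tiny)
    amp0 = y[0] - y[-1] if direction == "decay" else y[-1] - y[0]
    base0 = y[-1] if direction == "decay" else y[0]
    best = None
    for rate0 in (8.0 / span, 2.0 / span, 0.4 / span):
        try:
            popt, pcov = curve_fit(
                model,
                t,
                y,
                p0=[rate0, amp0 if amp0 != 0 else 1.0, base0],
                bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise FitError(f"exponential {direction} fit did not converge")
    popt, pcov, sse = best
    rate_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    ci = (popt[0] - 1.96 * rate_se, popt[0] + 1.96 * rate_se)
    return ExpFit(rate=float(popt[0]), amplitude=float(popt[1]), baseline=float(popt[2]), direction=direction, ci95=ci, sse=sse)


def time_to_fraction(fit: ExpFit, remaining: float) -> float:
    """Time until only ``remaining`` of the transient amplitude is left.

    For a decay this is the time to (1 - remaining) completion of
    dissociation; for a rise, the time to come within ``remaining`` of the
    plateau.  Both are ln(1/remaining)/rate.
    """
    if not 0.0 < remaining < 1.0:
        raise ValueError("remaining must lie in (0, 1)")
    return float(np.log(1.0 / remaining) / fit.rate)


def fit_gamma_survival(trace: DecayTrace, shape_grid=range(1, 11)) -> GammaSurvivalFit:
    """Fit a normalized decay trace with gamma survival functions.

    For each integer shape k the scale theta is estimated by least squares;
    the (k, theta) pair with minimal SSE wins.  Half-life and onset time come
    from the fitted survival quantiles at 0.5 and 0.99.
    """
    t, y = trace.post
    if t.size < 4:
        raise ValueError("need at least 4 points after t_zero")
    t = t - trace.t_zero
    # data-driven scale guess from the observed half-crossing
    below = np.nonzero(y <= 0.5)[0]
    t_half_guess = t[below[0]] if below.size else t[-1]
    best = None
    for k in shape_grid:
        ref_median = survival_quantile(CascadeParams(k, 1.0), 0.5)
        theta0 = max(t_half_guess / ref_median, 1e-9)

        def model(tt, theta, _k=k):
            return gamma_survival(tt, CascadeParams(_k, theta))

        try:
            popt, pcov = curve_fit(model, t, y, p0=[theta0], bounds=(1e-12, np.inf), maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((model(t, popt[0]) - y) ** 2))
        if best is None or sse < best[2] - 1e-15:
            best = (k, float(popt[0]), sse, pcov)
    if best is None:
        raise FitError("all gamma-survival fits failed")
    k, theta, sse, pcov = best
    params = CascadeParams(k, theta)
    half = survival_quantile(params, 0.5)
    onset = survival_quantile(params, 0.99)
    theta_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    rel = 1.96 * theta_se / theta if theta > 0 else np.inf
    ci = (half * (1 - rel), half * (1 + rel))
    return GammaSurvivalFit(shape=k, scale=theta, half_life=half, onset_time=onset, sse=sse, ci95_half_life=ci)


def bootstrap_ci(traces, fit_op, n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Percentile 95% interval over replicate-trace resamples.

    ``fit_op`` maps a (mean) trace to a scalar statistic.  Replicates must
    share a time grid; each bootstrap draw resamples them with replacement,
    averages, and refits.  Deterministic for a given seed.
    """
    traces = list(traces)
    if len(traces) < 3:
        raise ValueError("need at least 3 replicate traces")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; intervals will be unstable", stacklevel=2)
    grid = traces[0].times
    for tr in traces[1:]:
        if not np.allclose(tr.times, grid):
            raise ValueError("replicate traces must share a time grid")
    stack = np.stack([tr.values for tr in traces])
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(traces), size=len(traces))
        mean_vals = stack[idx].mean(axis=0)
        resampled = replace(traces[0], values=mean_vals)
        try:
            stats.append(float(fit_op(resampled)))
        except (FitError, ValueError):
            continue
    if not stats:
        raise FitError("no bootstrap resample could be fit")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def ratio_decay_halflife(light: pd.Series, dark: pd.Series, delay: float = 5.0) -> RatioDecay:
    """Half-life of the light/dark relative-mRNA ratio, in the time unit of the
    series index (minutes by convention, measured from illumination onset).

    The ratio R(t) = light/dark is fit with A*exp(-rate*t) on points at
    t >= ``delay`` (the transcription shutoff lag); the first linear-
    interpolated crossing of R = 0.5 is reported alongside.  A flat ratio has
    no finite half-life and is flagged rather than fit.
    """
    light = pd.Series(light).sort_index()
    dark = pd.Series(dark).sort_index()
    if not np.array_equal(light.index.values, dark.index.values):
        raise ValueError("light and dark series must share time points")
    if np.any(dark.values <= 0):
        raise ValueError("dark values must be positive")
    t = light.index.values.astype(float)
    ratio = light.values / dark.values
    if t[-1] - max(t[0], 0.0) < 30.0:
        raise ValueError("need paired points covering at least 30 time units after onset")

    crossing = None
    for i in range(1, t.size):
        if ratio[i - 1] > 0.5 >= ratio[i]:
            frac = (ratio[i - 1] - 0.5) / (ratio[i - 1] - ratio[i])
            crossing = float(t[i - 1] + frac * (t[i] - t[i - 1]))
            break

    sel = t >= delay
    tt, rr = t[sel], ratio[sel]
    if tt.size < 3:
        raise ValueError("need at least 3 points after the shutoff delay")
    try:
        popt, _ = curve_fit(
            lambda x, amp, rate: amp * np.exp(-rate * x),
            tt,
            rr,
            p0=[1.0, np.log(2) / max(tt[-1] - tt[0], 1e-9)],
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as err:
        raise FitError("ratio decay fit did not converge") from err
    rate = float(popt[1])
    if rate <= 1e-6:
        return RatioDecay(half_life=np.inf, rate=rate, half_crossing=crossing, finite=False)
    return RatioDecay(half_life=float(np.log(2) / rate), rate=rate, half_crossing=crossing, finite=True)


def time_to_half_max(times: np.ndarray, values: np.ndarray, t_start: float | None = None) -> float:
    """Time after ``t_start`` (default: time of maximum) for ``values`` to fall
    to 50% of maximum, by linear interpolation between samples."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    i_max = int(np.argmax(values))
    peak = values[i_max]
    if peak <= 0:
        raise ValueError("series has no positive maximum")
    t0 = times[i_max] if t_start is None else t_start
    target = 0.5 * peak
    sel = times >= t0
    tt, vv = times[sel], values[sel]
    for i in range(1, tt.size):
        if vv[i - 1] > target >= vv[i]:
            frac = (vv[i - 1] - target) / (vv[i - 1] - vv[i])
            return float(tt[i - 1] + frac * (tt[i] - tt[i - 1]) - t0)
    raise FitError("series never falls to 50% of maximum")
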