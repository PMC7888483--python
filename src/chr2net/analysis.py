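"""Measurement layer: firing-rate estimation, steady-state pulse statistics
and the spatial Gaussian fit to per-neuron activity.

The steady-state response to a periodic light protocol is summarized by
three numbers read off the trial- and cycle-averaged response cycle: the
response minimum (trough of the mean cycle), the response maximum (its
peak) and the response pulse duration, i.e. the full width at the level
halfway between minimum and maximum.  The spatial network response is
summarized by weighted nonlinear least squares of a Gaussian-plus-baseline
profile to per-neuron time-averaged rates against their (signed) distance
to the stimulus center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RateTrace",
    "PulseStats",
    "SpatialFit",
    "boxcar_rate",
    "fold_cycles",
    "pulse_statistics",
    "open_state_pulse_statistics",
    "spatial_gaussian_fit",
    "population_activity",
    "pulse_locked_fraction",
]


@dataclass
class RateTrace:
    """Instantaneous firing rate on a uniform time grid (boxcar estimate)."""

    times: np.ndarray
    rate: np.ndarray
    window: float
    n_trials: int


@dataclass
class PulseStats:
    """Steady-state response statistics of one periodic stimulation.

    Units are Hz for firing-rate input or probability for open-state
    input; ``fwhm`` is NaN (and ``fwhm_defined`` False) for a flat cycle,
    where the width at half maximum has no meaning.
    """

    resp_min: float
    resp_max: float
    fwhm: float
    n_cycles: int
    onset_skip: float
    fwhm_defined: bool = True


@dataclass
class SpatialFit:
    """Gaussian fit nu(r) = (nu_max - nu_base) exp(-r^2/(2 sigma_FR^2)) + nu_base."""

    sigma_FR: float
    nu_max: float
    nu_base: float
    pop_activity: float
    r_squared: float
    ok: bool = True
    message: str = ""


def boxcar_rate(spike_trains, window: float, grid: np.ndarray) -> RateTrace:
    """Trial-averaged sliding-window rate estimate.

    At each grid time t the rate is the spike count in
    ``[t - window/2, t + window/2)`` over all trials, divided by
    ``window * n_trials``.  Insensitive to bin placement, unlike a
    peristimulus time histogram.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    trains = list(spike_trains)
    if len(trains) == 0:
        raise ValueError("need at least one trial")
    grid = np.asarray(grid, dtype=float)
    allspikes = np.sort(np.concatenate([np.asarray(t, dtype=float)
                                        for t in trains]))
    hi = np.searchsorted(allspikes, grid + window / 2, side="left")
    lo = np.searchsorted(allspikes, grid - window / 2, side="left")
    rate = (hi - lo) / (window * len(trains))
    return RateTrace(times=grid, rate=rate, window=window, n_trials=len(trains))


def fold_cycles(times: np.ndarray, values: np.ndarray, f: float,
                onset_skip: float, t_align: float = 0.0,
                t_max: float | None = None) -> tuple[np.ndarray, np.ndarray, int]:
    """Phase-align complete cycles after the onset transient and average them.

    Phase zero is anchored at pulse onsets (``t_align + k/f``).  Returns
    ``(phase_grid, mean_cycle, n_cycles)``; values are linearly
    interpolated from the input grid, so the period need not be a
    multiple of the sampling step.
    """
    if f <= 0:
        raise ValueError("f must be > 0")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    period = 1.0 / f
    t_end = times[-1] if t_max is None else min(t_max, times[-1])
    dt_g = times[1] - times[0]
    k0 = int(np.ceil((onset_skip - t_align) / period - 1e-9))
    k1 = int(np.floor((t_end - t_align) / period + 1e-9))
    starts = t_align + np.arange(k0, k1) * period
    starts = starts[starts + period <= t_end + 1e-9]
    if starts.size < 2:
        raise ValueError("need at least 2 complete cycles after onset_skip")
    n_phase = max(int(round(period / dt_g)), 8)
    phase = np.arange(n_phase) * (period / n_phase)
    sample_t = starts[:, None] + phase[None, :]
    cycles = np.interp(sample_t.ravel(), times, values).reshape(sample_t.shape)
    return phase, cycles.mean(axis=0), starts.size


def _fwhm_circular(phase: np.ndarray, cycle: np.ndarray) -> float:
    """Width of the mean cycle at half height, with linear interpolation.

    The cycle is treated as periodic: it is rotated so the minimum leads,
    and the widest contiguous above-half region containing the maximum is
    measured.  Crossings between samples are interpolated linearly.
    """
    n = cycle.size
    dp = phase[1] - phase[0]
    lo, hi = cycle.min(), cycle.max()
    half = lo + 0.5 * (hi - lo)
    shift = int(np.argmin(cycle))
    y = np.roll(cycle, -shift)
    above = y >= half
    imax = int(np.argmax(y))
    # contiguous run of `above` containing imax (no wrap: index 0 is a minimum)
    left = imax
    while left > 0 and above[left - 1]:
        left -= 1
    right = imax
    while right < n - 1 and above[right + 1]:
        right += 1
    width = (right - left) * dp
    if left > 0 and y[left - 1] != y[left]:
        width += dp * (y[left] - half) / (y[left] - y[left - 1])
    if right < n - 1 and y[right + 1] != y[right]:
        width += dp * (y[right] - half) / (y[right] - y[right + 1])
    return width


def _stats_from_cycle(phase, cycle, n_cycles, onset_skip, flat_tol) -> PulseStats:
    resp_min = float(cycle.min())
    resp_max = float(cycle.max())
    if resp_max - resp_min <= flat_tol * max(abs(resp_max), 1e-300):
        warnings.warn("flat response cycle: FWHM undefined", RuntimeWarning)
        return PulseStats(resp_min, resp_max, float("nan"), n_cycles,
                          onset_skip, fwhm_defined=False)
    return PulseStats(resp_min, resp_max, _fwhm_circular(phase, cycle),
                      n_cycles, onset_skip)


def pulse_statistics(rate: RateTrace, f: float, onset_skip: float = 0.1,
                     t_max: float | None = None, t_align: float = 0.0,
                     flat_tol: float = 1e-9) -> PulseStats:
    """Steady-state response min/max/FWHM of a periodically stimulated rate.

    Cycles after ``onset_skip`` (the ~100 ms onset transient) are
    phase-aligned at pulse onsets and averaged into one mean cycle; the
    statistics are read off that cycle.
    """
    phase, cycle, n_cycles = fold_cycles(rate.times, rate.rate, f,
                                         onset_skip, t_align, t_max)
    return _stats_from_cycle(phase, cycle, n_cycles, onset_skip, flat_tol)


def open_state_pulse_statistics(times: np.ndarray, O_trace: np.ndarray,
                                f: float, onset_skip: float = 0.1,
                                t_max: float | None = None,
                                t_align: float = 0.0,
                                flat_tol: float = 1e-9) -> PulseStats:
    """As :func:`pulse_statistics`, applied to the open-state probability."""
    phase, cycle, n_cycles = fold_cycles(times, O_trace, f, onset_skip,
                                         t_align, t_max)
    return _stats_from_cycle(phase, cycle, n_cycles, onset_skip, flat_tol)


def _gaussian_profile(r, sigma, nu_max, nu_base):
    return (nu_max - nu_base) * np.exp(-r**2 / (2.0 * sigma**2)) + nu_base


def spatial_gaussian_fit(signed_r, rates, sigma_tol: float = 0.2,
                         sigma0: float = 8.0, n_restarts: int = 5,
                         seed: int = 0) -> SpatialFit:
    """Fit the radial Gaussian activity profile to per-neuron mean rates.

    Weighted nonlinear least squares with a uniform rate tolerance
    ``sigma_tol`` (Hz) on every neuron.  Initialized at
    ``(sigma0, max(rates), min(rates))`` with up to ``n_restarts``
    jittered restarts; a flat profile or persistent non-convergence is
    returned flagged rather than raised.
    """
    r = np.asarray(signed_r, dtype=float)
    y = np.asarray(rates, dtype=float)
    if r.size < 10:
        raise ValueError("need at least 10 neurons for the spatial fit")
    if not np.all(np.isfinite(y)):
        raise ValueError("rates must be finite")
    pop = float(np.mean(y))
    if np.ptp(y) < 1e-12:
        return SpatialFit(float("nan"), pop, pop, pop, float("nan"),
                          ok=False, message="flat profile: width unidentifiable")
    r_span = max(2.0 * np.max(np.abs(r)), 1.0)
    p0 = np.array([sigma0, float(np.max(y)), float(np.min(y))])
    bounds = ([1e-6, 0.0, 0.0], [r_span, np.inf, np.inf])
    rng = np.random.default_rng(seed)
    last_err = ""
    for attempt in range(n_restarts + 1):
        try:
            popt, _ = curve_fit(
                _gaussian_profile, r, y, p0=p0,
                sigma=np.full(y.size, sigma_tol), absolute_sigma=True,
                bounds=bounds, maxfev=20000)
            resid = y - _gaussian_profile(r, *popt)
            ss_tot = float(np.sum((y - pop) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
            return SpatialFit(float(popt[0]), float(popt[1]), float(popt[2]),
                              pop, r2)
        except RuntimeError as err:  # non-convergence
            last_err = str(err)
            p0 = np.array([
                sigma0 * rng.uniform(0.3, 3.0),
                np.max(y) * rng.uniform(0.5, 1.5),
                max(np.min(y), 1e-6) * rng.uniform(0.5, 1.5),
            ])
    return SpatialFit(float("nan"), float("nan"), float("nan"), pop,
                      float("nan"), ok=False,
                      message=f"fit failed after restarts: {last_err}")


def population_activity(rates) -> float:
    """Mean of per-neuron time-averaged rates, Hz."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("need at least one neuron")
    return float(np.mean(rates))


def pulse_locked_fraction(spike_trains, onsets, window: float) -> float:
    """Fraction of (trial, pulse) pairs with >= 1 spike within ``window`` of onset.

    Quantifies locking of firing to the light pulses; for an unstimulated
    neuron it reduces to the chance probability of a spike falling in a
    window of that length.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one pulse onset")
    hits = 0
    total = 0
    for train in spike_trains:
        t = np.asarray(train, dtype=float)
        lo = np.searchsorted(t, onsets, side="left")
        hi = np.searchsorted(t, onsets + window, side="left")
        hits += int(np.sum(hi > lo))
        total += onsets.size
    return hits / total
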