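"""Quantification of EPSP traces: summation linearity, directional
selectivity, kinetics, spike counting, resolution fits and tail-current
I-V curves.

Conventions shared by all operations:

* the baseline (Vrest) of a trace is the mean over the 100 ms preceding
  the first annotated stimulus onset (falling back to the stored
  ``vrest``);
* "charge" is the baseline-subtracted trapezoidal integral of the trace
  from the first stimulus onset over a response window (default 550 ms,
  about five decay time constants), in mV*ms for voltage traces or
  pA*ms for current traces;
* directional selectivity (DS) is signed so that positive values mean a
  centrifugal (away-from-soma) preference:

      DS_amp    = (Vpeak_away - Vpeak_toward) / (Vpeak_toward - Vrest) * 100
      DS_charge = (Q_away - Q_toward) / Q_toward * 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .engine import Trace

__all__ = [
    "SummationStats",
    "KineticsStats",
    "peak_amplitude",
    "charge",
    "summation_ratio",
    "directional_selectivity",
    "epsp_kinetics",
    "spike_probability",
    "gaussian_resolution_fit",
    "tail_current_iv",
]

DEFAULT_RESPONSE_WINDOW = 550.0  # ms, ~5 decay time constants


def _response_slice(trace: Trace, window: float):
    """Samples from the first stimulus onset to ``window`` ms after the
    last onset, so multi-pulse responses are never truncated relative to
    their single-pulse reference."""
    onsets = trace.annotations.get("stimulus_onsets")
    t0 = min(onsets) if onsets else float(trace.times[0])
    t1 = (max(onsets) if onsets else t0) + window
    mask = (trace.times >= t0) & (trace.times <= t1)
    return trace.times[mask], trace.values[mask]


def peak_amplitude(trace: Trace, *, baseline: float | None = None,
                   window: float = DEFAULT_RESPONSE_WINDOW,
                   smooth_ms: float = 2.0) -> float:
    """Baseline-subtracted peak depolarization within the response window.

    The trace is lightly boxcar-smoothed (``smooth_ms``) before taking the
    maximum so that recording noise does not bias the peak upward; for the
    slow EPSPs considered here the smoothing is far below the rise time
    and leaves noiseless traces essentially untouched.
    """
    base = trace.baseline() if baseline is None else baseline
    _, v = _response_slice(trace, window)
    n = max(1, int(round(smooth_ms / trace.dt)))
    if n > 1:
        kernel = np.ones(n) / n
        v = np.convolve(v, kernel, mode="valid")
    return float(v.max() - base)


def charge(trace: Trace, *, baseline: float | None = None,
           window: float = DEFAULT_RESPONSE_WINDOW) -> float:
    """Baseline-subtracted trapezoidal integral over the response window."""
    base = trace.baseline() if baseline is None else baseline
    t, v = _response_slice(trace, window)
    return float(np.trapezoid(v - base, t))


@dataclass(frozen=True)
class SummationStats:
    amplitude_ratio: float
    charge_ratio: float
    n_pulses: int


def summation_ratio(
    summed: Trace,
    single: Trace,
    n_pulses: int = 3,
    mode: str = "charge",
    *,
    window: float = DEFAULT_RESPONSE_WINDOW,
) -> float:
    """Linearity of summation: summed response / (n_pulses x single).

    A ratio of 1 is linear; >1 supralinear.  ``mode`` selects peak
    amplitude or charge as the response measure.
    """
    if n_pulses < 2:
        raise ValueError("n_pulses must be at least 2")
    measure = {"amplitude": peak_amplitude, "charge": charge}[mode]
    denom = measure(single, window=window)
    if abs(denom) < 1e-12:
        raise ValueError("single response is ~0; summation ratio undefined")
    return measure(summed, window=window) / (n_pulses * denom)


def summation_stats(summed: Trace, single: Trace, n_pulses: int = 3,
                    window: float = DEFAULT_RESPONSE_WINDOW) -> SummationStats:
    return SummationStats(
        summation_ratio(summed, single, n_pulses, "amplitude", window=window),
        summation_ratio(summed, single, n_pulses, "charge", window=window),
        n_pulses,
    )


def directional_selectivity(
    away: Trace,
    toward: Trace,
    mode: str = "charge",
    *,
    vrest: float | None = None,
    window: float = DEFAULT_RESPONSE_WINDOW,
) -> float:
    """Signed percent preference for the centrifugal (away) direction."""
    if mode == "amplitude":
        rest = toward.baseline() if vrest is None else vrest
        vpeak_away = rest + peak_amplitude(away, baseline=rest, window=window)
        vpeak_toward = rest + peak_amplitude(toward, baseline=rest, window=window)
        denom = vpeak_toward - rest
        if abs(denom) < 1e-12:
            raise ValueError("toward peak equals Vrest; amplitude DS undefined")
        return (vpeak_away - vpeak_toward) / denom * 100.0
    if mode == "charge":
        base = vrest
        q_away = charge(away, baseline=base, window=window)
        q_toward = charge(toward, baseline=base, window=window)
        if abs(q_toward) < 1e-12:
            raise ValueError("toward charge is 0; charge DS undefined")
        return (q_away - q_toward) / q_toward * 100.0
    raise ValueError(f"unknown DS mode {mode!r}")


@dataclass(frozen=True)
class KineticsStats:
    rise_10_90: float  # ms
    decay_time: float  # ms, mono-exponential tau of the falling phase
    peak: float  # mV above baseline


def epsp_kinetics(trace: Trace, *, window: float = DEFAULT_RESPONSE_WINDOW) -> KineticsStats:
    """10-90% rise time and mono-exponential decay tau of a single EPSP.

    The decay constant is fitted (log-linear least squares) on the falling
    phase between 90% and 10% of the peak; both measures are invariant to
    amplitude rescaling and baseline offset.
    """
    base = trace.baseline()
    t, v = _response_slice(trace, window)
    y = v - base
    i_peak = int(np.argmax(y))
    peak = float(y[i_peak])
    if peak <= 0:
        raise ValueError("no positive peak above baseline")

    def crossing(level: float, rising: bool) -> float:
        seg = y[: i_peak + 1] if rising else y[i_peak:]
        ts = t[: i_peak + 1] if rising else t[i_peak:]
        above = seg >= level
        idx = np.argmax(above) if rising else np.argmax(~above)
        if rising and not above.any():
            raise ValueError(f"trace never reaches {level:.3g} on the rise")
        if not rising and above.all():
            raise ValueError("trace never decays to the requested level")
        if idx == 0:
            return float(ts[0])
        t1, t2 = ts[idx - 1], ts[idx]
        y1, y2 = seg[idx - 1], seg[idx]
        return float(t1 + (level - y1) / (y2 - y1) * (t2 - t1))

    t10 = crossing(0.1 * peak, rising=True)
    t90 = crossing(0.9 * peak, rising=True)
    rise = t90 - t10

    fall = y[i_peak:]
    t_fall = t[i_peak:]
    mask = (fall <= 0.9 * peak) & (fall >= 0.1 * peak)
    if mask.sum() < 3:
        # no falling phase in the window (e.g. a sustained step)
        return KineticsStats(rise_10_90=rise, decay_time=math.nan, peak=peak)
    slope, _ = np.polyfit(t_fall[mask], np.log(fall[mask]), 1)
    if slope >= 0:
        raise ValueError("falling phase does not decay")
    return KineticsStats(rise_10_90=rise, decay_time=-1.0 / slope, peak=peak)


def spike_probability(
    trials: list[Trace],
    *,
    v_threshold: float = -20.0,
    dvdt_threshold: float | None = 20.0,
) -> float:
    """Fraction of trials with at least one threshold crossing.

    A trial is suprathreshold if the voltage crosses ``v_threshold`` or
    (when enabled) dV/dt exceeds ``dvdt_threshold`` mV/ms.
    """
    if not trials:
        raise ValueError("need at least one trial")
    n_supra = 0
    for tr in trials:
        crossed = bool(np.any(tr.values >= v_threshold))
        if not crossed and dvdt_threshold is not None:
            dvdt = np.diff(tr.values) / np.diff(tr.times)
            crossed = bool(np.any(dvdt >= dvdt_threshold))
        n_supra += crossed
    return n_supra / len(trials)


def gaussian_resolution_fit(distances, amplitudes) -> float:
    """Half-maximal (full) width of a Gaussian fit to amplitude vs distance.

    Least-squares fit of a * exp(-(x-x0)^2 / (2 sigma^2)); returns the
    full width at half maximum, 2*sqrt(2 ln 2)*sigma.
    """
    x = np.asarray(distances, dtype=float)
    yv = np.asarray(amplitudes, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points spanning the peak")
    if np.ptp(yv) < 1e-12:
        raise ValueError("amplitudes are constant; Gaussian fit is degenerate")

    def gauss(xx, a, x0, sigma):
        return a * np.exp(-((xx - x0) ** 2) / (2.0 * sigma**2))

    p0 = (yv.max(), x[np.argmax(yv)], max(np.ptp(x) / 4.0, 1e-6))
    try:
        import warnings

        from scipy.optimize import OptimizeWarning

        with warnings.catch_warnings():
            # exact fits have a singular covariance; only the widths matter
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(gauss, x, yv, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        resid = float(np.sum((yv - gauss(x, *p0)) ** 2))
        raise ValueError(f"Gaussian fit failed to converge (residual {resid:.3g})") from exc
    sigma = abs(popt[2])
    return 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma


def tail_current_iv(
    control: list[Trace],
    blocked: list[Trace],
    steps,
    *,
    tail_window: float = 5.0,
) -> "pandas.DataFrame":  # noqa: F821
    """Normalized activation curve from subtraction tail currents.

    For each voltage step the blocked-condition current trace is
    subtracted from the control trace; the tail amplitude is the mean
    difference current over the first ``tail_window`` ms after step-off
    (annotation ``step_off_ms``), minus the pre-step holding difference
    (annotation ``holding_current``).  Amplitudes are normalized to the
    largest magnitude across steps.
    """
    import pandas as pd

    steps = list(steps)
    if not (len(control) == len(blocked) == len(steps)):
        raise ValueError("control, blocked and steps must have matching lengths")
    tails = []
    for ctl, blk, step in zip(control, blocked, steps):
        if ctl.annotations.get("step_mV") != blk.annotations.get("step_mV"):
            raise ValueError("mismatched step voltages between conditions")
        off = ctl.annotations["step_off_ms"]
        diff_hold = ctl.annotations.get("holding_current", 0.0) - blk.annotations.get(
            "holding_current", 0.0
        )
        mask = (ctl.times >= off) & (ctl.times <= off + tail_window)
        diff = ctl.values[mask] - blk.values[mask]
        tails.append(float(diff.mean()) - diff_hold)
    tails = np.asarray(tails)
    peak = np.abs(tails).max()
    norm = tails / peak if peak > 0 else tails
    return pd.DataFrame(
        {"step_mV": steps, "tail_pA": tails, "normalized": np.abs(norm)}
    ).sort_values("step_mV", ignore_index=True)
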