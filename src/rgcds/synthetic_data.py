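"""Synthetic EPSP traces with known ground truth.

Generates bi-exponential EPSP waveforms with the amplitude (1-4 mV) and
kinetics of subthreshold uncaging responses, plus additive white
Gaussian recording noise, so every analysis operation can be exercised
against constructions whose true summation ratios and directional-
selectivity values are known by direct arithmetic on the noiseless
waveforms.  Each fixture self-describes its ground truth in the trace
annotations; nothing downstream needs magic numbers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .engine import Trace

__all__ = [
    "SyntheticEPSPSpec",
    "SyntheticProtocolSpec",
    "make_epsp",
    "make_summation_fixture",
    "make_direction_fixture",
]


@dataclass(frozen=True)
class SyntheticEPSPSpec:
    """Parameters of one synthetic EPSP trace."""

    amplitude: float = 2.0  # mV, subthreshold range 1-4
    tau_rise: float = 25.0  # ms, waveform rise constant
    tau_fall: float = 109.0  # ms, matches measured uncaging decay
    noise_sd: float = 0.05  # mV
    sample_rate: float = 10.0  # kHz
    vrest: float = -65.0  # mV
    pre_time: float = 150.0  # ms of baseline before the (first) onset
    post_time: float = 700.0  # ms after the (first) onset
    seed: int = 0


@dataclass(frozen=True)
class SyntheticProtocolSpec:
    """Multi-pulse fixture layout (delays in ms, scales per pulse)."""

    n_pulses: int = 3
    delay: float = 50.0
    epsp: SyntheticEPSPSpec = field(default_factory=SyntheticEPSPSpec)


def _biexp_peak_time(tau_rise: float, tau_fall: float) -> float:
    return (
        math.log(tau_fall / tau_rise)
        * tau_rise
        * tau_fall
        / (tau_fall - tau_rise)
    )


def biexp_waveform(t, amplitude: float, tau_rise: float, tau_fall: float):
    """a*(exp(-t/tau_fall) - exp(-t/tau_rise)), normalized to peak ``amplitude``.

    The analytic maximum sits at t* = ln(tau_fall/tau_rise) *
    tau_rise*tau_fall/(tau_fall - tau_rise).
    """
    t = np.asarray(t, dtype=float)
    t_peak = _biexp_peak_time(tau_rise, tau_fall)
    norm = math.exp(-t_peak / tau_fall) - math.exp(-t_peak / tau_rise)
    shape = np.where(
        t >= 0, np.exp(-np.maximum(t, 0) / tau_fall) - np.exp(-np.maximum(t, 0) / tau_rise), 0.0
    )
    return amplitude * shape / norm


def _grid(spec: SyntheticEPSPSpec, extra: float = 0.0):
    dt = 1.0 / spec.sample_rate  # ms
    n = int(round((spec.pre_time + spec.post_time + extra) / dt))
    return np.arange(n) * dt, dt


def make_epsp(spec: SyntheticEPSPSpec = SyntheticEPSPSpec()) -> Trace:
    """One noisy synthetic EPSP; annotations carry the true parameters."""
    if spec.tau_rise >= spec.tau_fall:
        warnings.warn(
            "tau_rise >= tau_fall gives a degenerate bi-exponential shape",
            stacklevel=2,
        )
    t, _ = _grid(spec)
    onset = spec.pre_time
    wave = biexp_waveform(t - onset, spec.amplitude, spec.tau_rise, spec.tau_fall)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, t.shape) if spec.noise_sd > 0 else 0.0
    return Trace(
        t,
        spec.vrest + wave + noise,
        annotations={
            "stimulus_onsets": [onset],
            "truth": {
                "amplitude": spec.amplitude,
                "tau_rise": spec.tau_rise,
                "tau_fall": spec.tau_fall,
                "vrest": spec.vrest,
            },
        },
        vrest=spec.vrest,
    )


def _superposition(t, onsets, scales, spec: SyntheticEPSPSpec):
    out = np.zeros_like(t)
    for onset, s in zip(onsets, scales):
        out += s * biexp_waveform(t - onset, spec.amplitude, spec.tau_rise, spec.tau_fall)
    return out


def make_summation_fixture(
    proto: SyntheticProtocolSpec,
    target_ratio: float,
    mode: str = "charge",
) -> tuple[Trace, Trace]:
    """(summed, single) traces whose true summation ratio is ``target_ratio``.

    The summed trace is a scaled superposition of n shifted copies of the
    single waveform.  For charge the required scale is target_ratio
    exactly (integration is linear); for amplitude it is solved from the
    peak of the unscaled superposition.  Ground truth is computed by
    direct arithmetic on the noiseless waveforms.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    spec = proto.epsp
    extra = (proto.n_pulses - 1) * proto.delay
    t, _ = _grid(spec, extra)
    onsets = [spec.pre_time + k * proto.delay for k in range(proto.n_pulses)]
    single_wave = biexp_waveform(t - onsets[0], spec.amplitude, spec.tau_rise, spec.tau_fall)
    base_sum = _superposition(t, onsets, np.ones(proto.n_pulses), spec)

    if mode == "charge":
        scale = target_ratio  # integral is linear in the per-pulse scale
    elif mode == "amplitude":
        scale = target_ratio * proto.n_pulses * single_wave.max() / base_sum.max()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(spec.seed)

    def noisy(w):
        n = rng.normal(0.0, spec.noise_sd, t.shape) if spec.noise_sd > 0 else 0.0
        return spec.vrest + w + n

    truth = {"target_ratio": target_ratio, "mode": mode, "scale": scale,
             "n_pulses": proto.n_pulses}
    summed = Trace(t, noisy(scale * base_sum),
                   annotations={"stimulus_onsets": onsets, "truth": truth},
                   vrest=spec.vrest)
    single = Trace(t, noisy(single_wave),
                   annotations={"stimulus_onsets": onsets[:1], "truth": truth},
                   vrest=spec.vrest)
    return summed, single


def make_direction_fixture(
    proto: SyntheticProtocolSpec,
    target_ds_amplitude: float,
    target_ds_charge: float,
) -> tuple[Trace, Trace]:
    """(away, toward) traces with imposed DS percentages.

    The toward trace is the plain superposition; the away trace is a
    linear combination alpha*base + beta*bump, where the bump is a
    Gaussian at the base peak time.  alpha and beta are solved from the
    2x2 linear system pinning the charge and peak of the away trace to
    the targets (exact for the noiseless construction, up to the tiny
    peak-time shift introduced by the bump, which the solve accounts for
    iteratively).
    """
    spec = proto.epsp
    extra = (proto.n_pulses - 1) * proto.delay
    t, dt = _grid(spec, extra)
    onsets = [spec.pre_time + k * proto.delay for k in range(proto.n_pulses)]
    base = _superposition(t, onsets, np.ones(proto.n_pulses), spec)
    t_peak = t[np.argmax(base)]
    bump = np.exp(-((t - t_peak) ** 2) / (2.0 * 15.0**2))

    q_base = np.trapezoid(base, t)
    q_bump = np.trapezoid(bump, t)
    p_base = base.max()
    want_q = (1.0 + target_ds_charge / 100.0) * q_base
    want_p = (1.0 + target_ds_amplitude / 100.0) * p_base

    alpha, beta = 1.0, 0.0
    for _ in range(8):  # fixed-point refinement for the peak-time shift
        away = alpha * base + beta * bump
        a_mat = np.array(
            [[q_base, q_bump], [base[np.argmax(away)], bump[np.argmax(away)]]]
        )
        try:
            alpha, beta = np.linalg.solve(a_mat, [want_q, want_p])
        except np.linalg.LinAlgError:
            raise ValueError(
                "contradictory amplitude/charge targets for this waveform family"
            ) from None
    away_wave = alpha * base + beta * bump
    if away_wave.max() <= 0 or np.trapezoid(away_wave, t) <= 0:
        raise ValueError("infeasible DS targets: away waveform not a depolarization")

    rng = np.random.default_rng(spec.seed)

    def noisy(w):
        n = rng.normal(0.0, spec.noise_sd, t.shape) if spec.noise_sd > 0 else 0.0
        return spec.vrest + w + n

    truth = {
        "target_ds_amplitude": target_ds_amplitude,
        "target_ds_charge": target_ds_charge,
        "alpha": float(alpha),
        "beta": float(beta),
    }
    away = Trace(t, noisy(away_wave),
                 annotations={"stimulus_onsets": onsets, "truth": truth},
                 vrest=spec.vrest)
    toward = Trace(t, noisy(base),
                   annotations={"stimulus_onsets": onsets, "truth": truth},
                   vrest=spec.vrest)
    return away, toward
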