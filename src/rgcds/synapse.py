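"""The uncaging-surrogate synapse.

Photolysis of caged glutamate is emulated by a voltage-clamped
presynaptic compartment driving a small release->filter->receptor chain:

1. an exponential release function of presynaptic voltage with a 2 mV
   e-fold gain (release is relative to the baseline rate r0, which is an
   arbitrary unit absorbed into the postsynaptic g_max);
2. a first-order temporal filter with separate rise (75 ms) and fall
   (125 ms) time constants, approximating the time course of the real
   photolytic responses -- this filter, not the receptor scheme, is the
   kinetic bottleneck of the chain;
3. an occupancy-conserving AMPA-receptor kinetic scheme (default
   closed <-> open <-> desensitized) whose open fraction scales a peak
   conductance g_max with reversal potential 0 mV.

A stimulus "contrast" depolarizes the presynaptic clamp by a few mV for
the pulse duration (default 3 ms), so EPSP amplitude is controlled by
contrast exactly as laser intensity controls uncaging response size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .morphology import SynapseSite

__all__ = [
    "Transition",
    "KineticScheme",
    "default_ampa_scheme",
    "SynapseModel",
    "StimulusPulse",
    "release_rate",
    "relative_release_drive",
    "filter_release",
    "AsymmetricFilter",
    "ampa_conductance",
]


@dataclass(frozen=True)
class Transition:
    """One directed edge of a kinetic scheme.

    ``rate`` is in 1/ms; if ``glu_coupled`` the effective rate is
    rate * [glutamate] (glutamate in the filter's arbitrary units).
    """

    source: int
    target: int
    rate: float
    glu_coupled: bool = False


@dataclass(frozen=True)
class KineticScheme:
    """A first-order Markov scheme with glutamate-coupled transitions."""

    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    open_state: int

    @property
    def n_states(self) -> int:
        return len(self.states)

    def generator(self, glu: float) -> np.ndarray:
        """Generator matrix Q (columns sum to zero): dp/dt = Q p."""
        n = self.n_states
        q = np.zeros((n, n))
        for t in self.transitions:
            k = t.rate * glu if t.glu_coupled else t.rate
            q[t.target, t.source] += k
            q[t.source, t.source] -= k
        return q

    def steady_state(self, glu: float) -> np.ndarray:
        """Equilibrium occupancy at fixed glutamate (nullspace of Q)."""
        q = self.generator(glu)
        # replace one balance equation with the conservation constraint
        a = np.vstack([q[:-1, :], np.ones(self.n_states)])
        b = np.zeros(self.n_states)
        b[-1] = 1.0
        return np.linalg.lstsq(a, b, rcond=None)[0]

    def resting_occupancy(self) -> np.ndarray:
        return self.steady_state(0.0)


def default_ampa_scheme(
    k_on: float = 0.3,
    k_off: float = 0.2,
    k_conf: float = 0.03,
    k_desens: float = 0.02,
    k_recover: float = 0.002,
) -> KineticScheme:
    """Four-state AMPA scheme: unbound <-> bound <-> open -> desensitized.

    Glutamate binding (C1 <-> C2, rate k_on per unit of filtered
    glutamate) is fast relative to the 75/125 ms release filter; the
    conformational opening step (C2 <-> O, rate k_conf) adds the tens-of-
    milliseconds lag that shapes the measured EPSP rise; slow
    desensitization (O -> D, recovery D -> C1) trims the late tail of
    long transients.  Rates in 1/ms.  A richer literature scheme can be
    dropped in by constructing a KineticScheme directly.
    """
    return KineticScheme(
        states=("C1", "C2", "O", "D"),
        transitions=(
            Transition(0, 1, k_on, glu_coupled=True),
            Transition(1, 0, k_off),
            Transition(1, 2, k_conf),
            Transition(2, 1, k_conf),
            Transition(2, 3, k_desens),
            Transition(3, 0, k_recover),
        ),
        open_state=2,
    )


@dataclass(frozen=True)
class SynapseModel:
    """Parameters of the presynaptic-drive -> AMPA conductance chain."""

    e_fold_voltage: float = 2.0  # mV per e-fold of release
    baseline_presyn_v: float = -45.0  # mV, presynaptic resting clamp
    contrast_depolarization: float = 6.0  # mV, default stimulus contrast
    tau_rise: float = 75.0  # ms
    tau_fall: float = 125.0  # ms
    e_ampa: float = 0.0  # mV
    g_max: float = 0.13  # nS, calibrated for 1-4 mV somatic EPSPs
    ampa_scheme: KineticScheme = field(default_factory=default_ampa_scheme)

    def __post_init__(self) -> None:
        if self.e_fold_voltage <= 0:
            raise ValueError("e_fold_voltage must be positive")
        if self.tau_rise <= 0 or self.tau_fall <= 0:
            raise ValueError("filter time constants must be positive")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")


@dataclass(frozen=True)
class StimulusPulse:
    """A depolarizing step on one synapse's presynaptic clamp."""

    site: SynapseSite
    onset: float  # ms
    duration: float = 3.0  # ms
    contrast: float = 6.0  # mV

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")


def release_rate(v_pre, model: SynapseModel, r0: float = 1.0):
    """Relative transmitter release r = r0 * exp((V_pre - V_base)/e_fold)."""
    v_pre = np.asarray(v_pre, dtype=float)
    return r0 * np.exp((v_pre - model.baseline_presyn_v) / model.e_fold_voltage)


def relative_release_drive(v_pre, model: SynapseModel):
    """Release above baseline, r/r0 - 1; zero at the resting clamp.

    The tonic baseline release is absorbed into the leak/resting state, so
    the filter and receptor see only the stimulus-evoked excess.
    """
    return release_rate(v_pre, model) - 1.0


class AsymmetricFilter:
    """First-order low-pass with distinct rise and fall time constants.

    The instantaneous time constant is tau_rise while the input exceeds
    the current output (rising phase) and tau_fall otherwise.  The
    per-step update is the exact exponential solution for input held
    constant over the step, so unity DC gain is exact.
    """

    def __init__(self, tau_rise: float, tau_fall: float, y0: float = 0.0):
        self.tau_rise = float(tau_rise)
        self.tau_fall = float(tau_fall)
        self.y = float(y0)

    def step(self, u: float, dt: float) -> float:
        tau = self.tau_rise if u > self.y else self.tau_fall
        self.y = u + (self.y - u) * np.exp(-dt / tau)
        return self.y


def filter_release(raw, dt: float, tau_rise: float = 75.0, tau_fall: float = 125.0,
                   y0: float = 0.0) -> np.ndarray:
    """Apply the asymmetric first-order filter to a uniformly sampled input."""
    if dt >= min(tau_rise, tau_fall) / 5.0:
        warnings.warn(
            f"dt={dt} ms is coarse relative to the filter time constants; "
            "accuracy will suffer",
            stacklevel=2,
        )
    filt = AsymmetricFilter(tau_rise, tau_fall, y0)
    return np.array([filt.step(float(u), dt) for u in np.asarray(raw, dtype=float)])


def _occupancy_step(p: np.ndarray, scheme: KineticScheme, glu: float,
                    dt: float) -> np.ndarray:
    """One backward-Euler step of dp/dt = Q(glu) p.

    Backward Euler preserves the occupancy sum exactly (column sums of Q
    are zero) and keeps occupancies in [0, 1] for any dt.
    """
    q = scheme.generator(glu)
    a = np.eye(scheme.n_states) - dt * q
    return np.linalg.solve(a, p)


def ampa_conductance(glu, scheme: KineticScheme, dt: float, g_max: float = 1.0):
    """Drive the receptor scheme with a glutamate waveform.

    Returns (g, occupancies) where g[t] = g_max * open fraction and
    ``occupancies`` has shape (len(glu), n_states).
    """
    glu = np.asarray(glu, dtype=float)
    if np.any(glu < 0):
        raise ValueError("glutamate concentration must be non-negative")
    p = scheme.resting_occupancy()
    occ = np.empty((len(glu), scheme.n_states))
    for i, u in enumerate(glu):
        p = _occupancy_step(p, scheme, float(u), dt)
        if np.any(p < -1e-9):
            raise FloatingPointError(
                "negative occupancy: kinetic scheme unstable at this dt"
            )
        occ[i] = p
    return g_max * occ[:, scheme.open_state], occ
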