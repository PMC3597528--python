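"""Implicit-time-step integration of the compartmental cable equation.

The membrane equation per compartment i,

    C_i dV_i/dt = -I_leak - sum_ch gbar_ch p_ch (V_i - E_ch)
                  - sum_syn g_syn (V_i - E_syn)
                  + sum_j g_ij (V_j - V_i) + I_inj,

is advanced with a backward-Euler voltage step: channel open fractions
and synaptic conductances are frozen over the step (updated first by
exact exponential Rush-Larsen / backward-Euler sub-steps), which leaves a
linear tree-structured system for the voltages.  The system is solved
with a Hines elimination (O(n), exact) -- via a banded solve for
unbranched cables.  Backward Euler is L-stable, so stiff channel
kinetics and coarse equilibration steps cannot blow up.

The full simulation state (voltages, gate values, synapse filter and
receptor occupancies, clock) can be snapshotted and restored bit-exactly,
reproducing the save/restore trick used to decouple successive
directional stimuli.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .channels import ChannelDistribution, ChannelSpec, standard_channels
from .morphology import Morphology, SynapseSite
from .synapse import AsymmetricFilter, StimulusPulse, SynapseModel

__all__ = [
    "CellModel",
    "SimulationState",
    "Trace",
    "Simulation",
    "EquilibrationError",
]


class EquilibrationError(RuntimeError):
    pass


@dataclass
class CellModel:
    """Morphology + regional channel densities + synapses: a runnable cell."""

    morphology: Morphology
    distribution: ChannelDistribution
    channels: dict[str, ChannelSpec] = field(default_factory=standard_channels)
    synapses: list[tuple[SynapseSite, SynapseModel]] = field(default_factory=list)

    def config_hash(self) -> str:
        h = hashlib.sha1()
        for c in self.morphology.compartments:
            h.update(
                f"{c.id},{c.parent_id},{c.path_distance:.9g},{c.length:.9g},"
                f"{c.diameter:.9g},{c.region.value};".encode()
            )
        h.update(self.distribution.to_yaml().encode())
        h.update(repr(sorted(self.channels.items())).encode())
        h.update(repr(self.synapses).encode())
        return h.hexdigest()

    def without(self, channel: str) -> "CellModel":
        """Pharmacological removal: zero one conductance everywhere."""
        return CellModel(
            self.morphology,
            self.distribution.without(channel),
            self.channels,
            list(self.synapses),
        )


@dataclass
class SimulationState:
    """Complete, restorable snapshot of a running simulation."""

    t: float
    v: np.ndarray
    gates: dict[str, dict[str, np.ndarray]]
    syn_filter: np.ndarray
    syn_occ: np.ndarray
    config_hash: str

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.t,
            self.v.copy(),
            {ch: {g: a.copy() for g, a in gs.items()} for ch, gs in self.gates.items()},
            self.syn_filter.copy(),
            self.syn_occ.copy(),
            self.config_hash,
        )

    def to_bytes(self) -> bytes:
        buf = io.BytesIO()
        arrays = {"v": self.v, "syn_filter": self.syn_filter, "syn_occ": self.syn_occ}
        for ch, gs in self.gates.items():
            for g, a in gs.items():
                arrays[f"gate__{ch}__{g}"] = a
        np.savez(
            buf,
            t=np.array([self.t]),
            config_hash=np.frombuffer(self.config_hash.encode(), dtype=np.uint8),
            **arrays,
        )
        return buf.getvalue()

    @classmethod
    def from_bytes(cls, blob: bytes) -> "SimulationState":
        with np.load(io.BytesIO(blob)) as data:
            gates: dict[str, dict[str, np.ndarray]] = {}
            for key in data.files:
                if key.startswith("gate__"):
                    _, ch, g = key.split("__")
                    gates.setdefault(ch, {})[g] = data[key]
            return cls(
                t=float(data["t"][0]),
                v=data["v"],
                gates=gates,
                syn_filter=data["syn_filter"],
                syn_occ=data["syn_occ"],
                config_hash=bytes(data["config_hash"]).decode(),
            )


@dataclass
class Trace:
    """Uniformly sampled time series with stimulus annotations."""

    times: np.ndarray  # ms
    values: np.ndarray  # mV (or pA for clamp-current traces)
    units: str = "mV"
    annotations: dict = field(default_factory=dict)
    vrest: float | None = None

    def __post_init__(self) -> None:
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("trace requires a strictly increasing uniform time grid")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def baseline(self, window_ms: float = 100.0) -> float:
        """Mean value over the window preceding the first stimulus onset.

        Falls back to the stored ``vrest`` (or the first sample) when no
        stimulus annotation is present.
        """
        onsets = self.annotations.get("stimulus_onsets")
        if onsets:
            t0 = min(onsets)
            mask = (self.times >= t0 - window_ms) & (self.times < t0)
            if mask.any():
                return float(self.values[mask].mean())
        if self.vrest is not None:
            return float(self.vrest)
        return float(self.values[0])

    def to_frame(self) -> "pandas.DataFrame":  # noqa: F821
        import pandas as pd

        return pd.DataFrame({"time_ms": self.times, self.units: self.values})


def save_traces(path, traces: dict[str, Trace]) -> None:
    """Write a named set of traces to one .npz container."""
    import json

    arrays = {}
    meta = {}
    for name, tr in traces.items():
        arrays[f"{name}__t"] = tr.times
        arrays[f"{name}__v"] = tr.values
        meta[name] = {
            "units": tr.units,
            "annotations": tr.annotations,
            "vrest": tr.vrest,
        }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_traces(path) -> dict[str, Trace]:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        return {
            name: Trace(
                data[f"{name}__t"],
                data[f"{name}__v"],
                units=m["units"],
                annotations=m["annotations"],
                vrest=m["vrest"],
            )
            for name, m in meta.items()
        }


class Simulation:
    """Time-steps one CellModel; owns the mutable SimulationState."""

    def __init__(self, model: CellModel, dt: float = 0.025):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.model = model
        self.dt = float(dt)
        morph = model.morphology
        dist = model.distribution

        self.n = morph.n
        self.parent = morph.parent_index
        self.is_chain = bool(np.all(self.parent == np.arange(self.n) - 1))
        areas = morph.areas_cm2()
        self.cm_uF = dist.cm * areas
        self.g_leak = areas / dist.rm * 1000.0  # mS
        self.e_leak = dist.v_rev_leak
        self.g_ax = morph.axial_conductances_mS(dist.ri)  # mS, child<->parent

        regions = [r.value for r in morph.regions]
        self.gbar: dict[str, np.ndarray] = {}
        for name in model.channels:
            dens = dist.density_array(name, regions)  # mS/cm^2
            self.gbar[name] = dens * areas  # mS
        self.e_rev = {name: spec.e_rev for name, spec in model.channels.items()}

        self.syn_comp = np.array(
            [site.compartment_id for site, _ in model.synapses], dtype=np.int64
        )
        self.syn_models = [m for _, m in model.synapses]
        n_states = max(
            (m.ampa_scheme.n_states for m in self.syn_models), default=0
        )
        self._hash = model.config_hash()
        self.state = self._initial_state(n_states)

    # -- state management ----------------------------------------------
    def _initial_state(self, n_states: int) -> SimulationState:
        v = np.full(self.n, self.e_leak, dtype=float)
        gates = {
            ch: {g.name: np.asarray(g.rates.steady_state(v)) for g in spec.gates}
            for ch, spec in self.model.channels.items()
        }
        n_syn = len(self.syn_models)
        occ = np.zeros((n_syn, n_states)) if n_syn else np.zeros((0, 0))
        for i, m in enumerate(self.syn_models):
            occ[i, : m.ampa_scheme.n_states] = m.ampa_scheme.resting_occupancy()
        return SimulationState(
            0.0, v, gates, np.zeros(n_syn), occ, self._hash
        )

    def save_state(self) -> SimulationState:
        return self.state.copy()

    def restore_state(self, snapshot: SimulationState) -> None:
        if snapshot.config_hash != self._hash:
            raise ValueError(
                "snapshot belongs to a different model configuration "
                f"({snapshot.config_hash[:8]} != {self._hash[:8]})"
            )
        self.state = snapshot.copy()

    # -- integration ----------------------------------------------------
    def advance(
        self,
        duration: float,
        stimuli: tuple[StimulusPulse, ...] | list[StimulusPulse] = (),
        *,
        record: int | None = 0,
        record_dt: float = 0.1,
        clamp: tuple[int, float] | None = None,
        inject: tuple[int, float] | None = None,
        record_clamp_current: bool = False,
    ):
        """Advance the state by ``duration`` ms.

        Parameters
        ----------
        stimuli : pulses addressed to synapses of the model (matched by
            synapse site); onsets are absolute simulation times.
        record : compartment index to record (None to skip recording).
        clamp : (compartment, command mV) ideal voltage clamp.
        inject : (compartment, current nA) constant current injection.
        record_clamp_current : record clamp current (pA) instead of voltage.

        Returns a Trace (or None when record is None).
        """
        dt = self.dt
        n_steps = max(1, int(round(duration / dt)))
        every = max(1, int(round(record_dt / dt)))

        # pulses per synapse, matched by site value
        pulse_lists: list[list[StimulusPulse]] = [[] for _ in self.syn_models]
        for p in stimuli:
            matched = False
            for i, (site, _) in enumerate(self.model.synapses):
                if site == p.site:
                    pulse_lists[i].append(p)
                    matched = True
            if not matched:
                raise ValueError(f"stimulus site {p.site} not among model synapses")

        st = self.state
        v = st.v
        times: list[float] = []
        values: list[float] = []
        filters = [
            AsymmetricFilter(m.tau_rise, m.tau_fall, st.syn_filter[i])
            for i, m in enumerate(self.syn_models)
        ]

        clamp_idx = clamp[0] if clamp is not None else None
        schemes = [m.ampa_scheme for m in self.syn_models]

        for step in range(n_steps):
            t_new = st.t + dt

            # 1) gate update (Rush-Larsen, exact for frozen V)
            for ch, spec in self.model.channels.items():
                if not np.any(self.gbar[ch] > 0):
                    continue
                for g in spec.gates:
                    a, b = g.rates.rates(v)
                    tot = a + b
                    x_inf = a / tot
                    x = st.gates[ch][g.name]
                    st.gates[ch][g.name] = x_inf + (x - x_inf) * np.exp(-dt * tot)

            # 2) synaptic chain update
            g_syn = np.zeros(self.n)
            b_syn = np.zeros(self.n)
            for i, m in enumerate(self.syn_models):
                v_pre = m.baseline_presyn_v
                for p in pulse_lists[i]:
                    if p.onset <= t_new < p.onset + p.duration:
                        v_pre += p.contrast
                drive = math.exp(
                    (v_pre - m.baseline_presyn_v) / m.e_fold_voltage
                ) - 1.0
                glu = filters[i].step(drive, dt)
                st.syn_filter[i] = filters[i].y
                q = schemes[i].generator(glu)
                ns = schemes[i].n_states
                a_mat = np.eye(ns) - dt * q
                st.syn_occ[i, :ns] = np.linalg.solve(a_mat, st.syn_occ[i, :ns])
                g = m.g_max * st.syn_occ[i, schemes[i].open_state] * 1e-6  # mS
                c = self.syn_comp[i]
                g_syn[c] += g
                b_syn[c] += g * m.e_ampa

            # 3) assemble and solve the implicit voltage system
            diag = self.cm_uF / dt + self.g_leak + g_syn
            rhs = self.cm_uF / dt * v + self.g_leak * self.e_leak + b_syn
            for ch, gb in self.gbar.items():
                if not np.any(gb > 0):
                    continue
                p_open = self.model.channels[ch].open_fraction(st.gates[ch])
                g_ch = gb * p_open
                diag += g_ch
                rhs += g_ch * self.e_rev[ch]
            if inject is not None:
                rhs[inject[0]] += inject[1] * 1e-3  # nA -> uA
            # axial coupling terms
            p_idx = self.parent[1:]
            np.add.at(diag, p_idx, self.g_ax[1:])
            diag[1:] += self.g_ax[1:]

            if clamp_idx is not None:
                v_new = self._solve_tree_clamped(diag, rhs, clamp_idx, clamp[1])
            else:
                v_new = self._solve_tree(diag, rhs)

            if not np.all(np.isfinite(v_new)):
                bad = int(np.argmax(~np.isfinite(v_new)))
                raise FloatingPointError(
                    f"voltage diverged at t={t_new:.3f} ms in compartment {bad}"
                )

            if record_clamp_current and clamp_idx is not None:
                i_clamp = self._clamp_current(v_new, clamp_idx)
            v = v_new
            st.v = v
            st.t = t_new

            if record is not None and (step + 1) % every == 0:
                times.append(st.t)
                if record_clamp_current and clamp_idx is not None:
                    values.append(i_clamp)
                else:
                    values.append(float(v[record]))

        if record is None:
            return None
        units = "pA" if record_clamp_current else "mV"
        onsets = sorted({p.onset for p in stimuli})
        return Trace(
            np.array(times),
            np.array(values),
            units=units,
            annotations={"stimulus_onsets": onsets} if onsets else {},
        )

    # -- linear algebra --------------------------------------------------
    def _solve_tree(self, diag: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        """Solve the symmetric tree system (Hines elimination)."""
        if self.is_chain:
            n = self.n
            ab = np.zeros((3, n))
            ab[0, 1:] = -self.g_ax[1:]
            ab[1] = diag
            ab[2, :-1] = -self.g_ax[1:]
            return solve_banded((1, 1), ab, rhs)
        d = diag.copy()
        b = rhs.copy()
        off = -self.g_ax
        for i in range(self.n - 1, 0, -1):
            p = self.parent[i]
            factor = off[i] / d[i]
            d[p] -= factor * off[i]
            b[p] -= factor * b[i]
        v = np.empty(self.n)
        v[0] = b[0] / d[0]
        for i in range(1, self.n):
            v[i] = (b[i] - off[i] * v[self.parent[i]]) / d[i]
        return v

    def _solve_tree_clamped(
        self, diag: np.ndarray, rhs: np.ndarray, idx: int, v_cmd: float
    ) -> np.ndarray:
        """Solve with one compartment held at a command voltage."""
        d = diag.copy()
        b = rhs.copy()
        # Dirichlet row: V_idx = v_cmd; fold the known value into neighbours
        for i in range(1, self.n):
            p = self.parent[i]
            if i == idx or p == idx:
                other = p if i == idx else i
                b[other] += self.g_ax[i] * v_cmd
        off = -self.g_ax
        order = [i for i in range(self.n - 1, 0, -1) if i != idx and self.parent[i] != idx]
        skip = {idx}
        for i in range(self.n - 1, 0, -1):
            if i == idx:
                continue
            p = self.parent[i]
            if p == idx:
                continue  # decoupled from its clamped parent above
            factor = off[i] / d[i]
            d[p] -= factor * off[i]
            b[p] -= factor * b[i]
        v = np.empty(self.n)
        if idx == 0:
            v[0] = v_cmd
        else:
            v[0] = b[0] / d[0]
        for i in range(1, self.n):
            if i == idx:
                v[i] = v_cmd
            elif self.parent[i] == idx:
                v[i] = b[i] / d[i]
            else:
                v[i] = (b[i] - off[i] * v[self.parent[i]]) / d[i]
        return v

    def _clamp_current(self, v: np.ndarray, idx: int) -> float:
        """Clamp current (pA, positive outward) at the clamped compartment."""
        st = self.state
        i_memb = self.g_leak[idx] * (v[idx] - self.e_leak)
        for ch, gb in self.gbar.items():
            if gb[idx] > 0:
                p_open = self.model.channels[ch].open_fraction(
                    {g: arr[idx] for g, arr in st.gates[ch].items()}
                )
                i_memb += gb[idx] * p_open * (v[idx] - self.e_rev[ch])
        i_axial = 0.0
        for i in range(1, self.n):
            if self.parent[i] == idx:
                i_axial += self.g_ax[i] * (v[idx] - v[i])
            elif i == idx:
                i_axial += self.g_ax[i] * (v[idx] - v[self.parent[i]])
        return (i_memb + i_axial) * 1e6  # uA -> pA

    # -- equilibration ---------------------------------------------------
    def equilibrate(
        self,
        tol: float = 1e-5,
        *,
        dt: float = 0.5,
        max_time: float = 60000.0,
        check_every: float = 50.0,
    ) -> float:
        """Relax to rest: run until max |dV/dt| < tol (mV/ms) everywhere.

        Uses a coarse implicit step (stable for the stiffest gates) and
        returns the somatic resting potential.  Raises EquilibrationError
        if the budget ``max_time`` (ms) is exhausted.
        """
        saved_dt = self.dt
        self.dt = dt
        try:
            elapsed = 0.0
            while elapsed < max_time:
                v_before = self.state.v.copy()
                self.advance(check_every, record=None)
                elapsed += check_every
                dvdt = np.abs(self.state.v - v_before) / check_every
                if dvdt.max() < tol:
                    return float(self.state.v[0])
            raise EquilibrationError(
                f"no equilibrium within {max_time} ms; "
                f"max |dV/dt| = {dvdt.max():.3g} mV/ms"
            )
        finally:
            self.dt = saved_dt
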