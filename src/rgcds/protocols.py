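"""In-silico stimulation experiments on the ganglion-cell model.

Reproduces the simulated "uncaging" experiments: sequential activation of
3-5 dendritic sites in the centrifugal (away from soma) and centripetal
(toward soma) order, same-site summation trains, pharmacology by
conductance removal (ZD7288 as HCN removal), somatic voltage-step
families for tail-current I-V analysis, and parameter-robustness scans.

Between the two directions of a pair the full simulation state is
restored from a snapshot taken after equilibration, so the slow HCN
kinetics of the first sequence cannot contaminate the second -- mirroring
the long inter-trial intervals of the recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import analysis
from .channels import (
    ChannelDistribution,
    calibrate_hcn_offset,
    standard_channels,
    standard_distribution,
)
from .engine import CellModel, Simulation, Trace
from .morphology import Morphology, Region, SynapseSite, build_unbranched_cable, sites_at
from .synapse import StimulusPulse, SynapseModel

__all__ = [
    "DirectionalProtocol",
    "DSResult",
    "build_standard_cell",
    "run_direction_pair",
    "run_same_site_train",
    "apply_pharmacology",
    "run_voltage_step_family",
    "run_parameter_scan",
    "directional_spike_probability",
    "DS_NULL_THRESHOLD",
]

#: |DS| below this (percent) is reported as "no DS" in null-result checks.
DS_NULL_THRESHOLD = 2.0

#: pre-stimulus time simulated before the first pulse (gives the 100 ms
#: baseline window of the Vrest convention plus margin).
PRE_STIMULUS_MS = 100.0

HCN_TARGET_OPEN_FRACTION = 0.25  # at -65 mV, from tail-current I-V data
HCN_TARGET_VOLTAGE = -65.0

#: standard unbranched-cable geometry: a long thin dendrite whose distal
#: half is partially isolated electrotonically from a compact soma, the
#: regime in which the HCN gradient elevates the distal resting potential
#: and subthreshold Na gain can express directional summation.
STANDARD_DENDRITE_LENGTH = 600.0  # um
STANDARD_DENDRITE_DIAMETER = 0.5  # um
STANDARD_SOMA_DIAMETER = 12.0  # um
STANDARD_SITE_DISTANCES = (300.0, 400.0, 500.0)  # um, mid/distal placement
PROXIMAL_SITE_DISTANCES = (30.0, 55.0, 80.0)  # um, all < 100 um


@dataclass(frozen=True)
class DirectionalProtocol:
    """A paired away/toward sequential-activation experiment."""

    sites: tuple[SynapseSite, ...]
    inter_pulse_interval: float = 20.0  # ms (experiment-mode preset: 50 ms)
    pulse_duration: float = 3.0  # ms
    contrast: float = 6.0  # mV presynaptic depolarization per pulse
    use_restore: bool = True
    record_compartment: int = 0  # soma by default; any compartment for local DS
    response_window: float = analysis.DEFAULT_RESPONSE_WINDOW  # ms
    dt: float = 0.025  # ms

    def __post_init__(self) -> None:
        if not (3 <= len(self.sites) <= 5):
            raise ValueError("a directional protocol uses 3 to 5 sites")
        dists = [s.path_distance for s in self.sites]
        if sorted(dists) != dists or len(set(dists)) != len(dists):
            raise ValueError("sites must be strictly ordered by path distance")

    def ordered_sites(self, direction: str) -> tuple[SynapseSite, ...]:
        if direction == "away":
            return self.sites
        if direction == "toward":
            return tuple(reversed(self.sites))
        raise ValueError(f"unknown direction {direction!r}")

    def pulses(self, direction: str, t0: float) -> tuple[StimulusPulse, ...]:
        return tuple(
            StimulusPulse(
                site,
                onset=t0 + k * self.inter_pulse_interval,
                duration=self.pulse_duration,
                contrast=self.contrast,
            )
            for k, site in enumerate(self.ordered_sites(direction))
        )


@dataclass
class DSResult:
    """Paired directional traces plus the derived DS statistics."""

    trace_away: Trace
    trace_toward: Trace
    single_traces: dict[float, Trace]  # keyed by site path distance
    vrest: float
    vpeak_away: float
    vpeak_toward: float
    charge_away: float
    charge_toward: float
    ds_amplitude: float  # percent, positive = centrifugal preference
    ds_charge: float  # percent


def build_standard_cell(
    *,
    channel_set: str = "full",
    length: float = STANDARD_DENDRITE_LENGTH,
    diameter: float = STANDARD_DENDRITE_DIAMETER,
    soma_diameter: float = STANDARD_SOMA_DIAMETER,
    site_distances=STANDARD_SITE_DISTANCES,
    distribution: ChannelDistribution | None = None,
    synapse_model: SynapseModel | None = None,
    na_scale: float = 1.0,
    k_scale: float = 1.0,
    hcn_scale: float = 1.0,
    na_density: float | None = None,
    max_electrotonic_step: float = 0.02,
    calibrate_hcn: bool = True,
) -> CellModel:
    """The unbranched-cable ganglion-cell model with standard parameters.

    ``channel_set`` selects which conductances are present: "full"
    (HCN+Na+Kdr), "passive", "hcn" (HCN only) or "nak" (Na+Kdr only).
    Density scale factors implement the robustness scans (all regions of
    a channel scale together); ``na_density`` sets the dendritic Na
    density (mS/cm^2) directly.  For Na scans with the standard tuning
    rule (K following Na to hold Vrest) see na_robustness_scan.
    """
    dist = distribution if distribution is not None else standard_distribution()
    if na_density is not None:
        na_scale = na_scale * na_density / dist.densities["Na"][Region.DENDRITE]
    if na_scale != 1.0:
        dist = dist.scaled("Na", na_scale)
    if k_scale != 1.0:
        dist = dist.scaled("Kdr", k_scale)
    if hcn_scale != 1.0:
        dist = dist.scaled("HCN", hcn_scale)

    removals = {
        "full": (),
        "passive": ("Na", "Kdr", "HCN"),
        "hcn": ("Na", "Kdr"),
        "nak": ("HCN",),
    }
    try:
        for name in removals[channel_set]:
            dist = dist.without(name)
    except KeyError:
        raise ValueError(f"unknown channel_set {channel_set!r}") from None

    morph = build_unbranched_cable(
        length,
        diameter,
        soma_diameter=soma_diameter,
        max_electrotonic_step=max_electrotonic_step,
        rm=dist.rm,
        ri=dist.ri,
    )
    offset = (
        calibrate_hcn_offset(HCN_TARGET_OPEN_FRACTION, HCN_TARGET_VOLTAGE)
        if calibrate_hcn
        else 0.0
    )
    channels = standard_channels(
        hcn_offset=offset, e_na=dist.e_na, e_k=dist.e_k, e_hcn=dist.e_hcn
    )
    syn_model = synapse_model if synapse_model is not None else SynapseModel()
    sites = sites_at(morph, site_distances)
    synapses = [(s, syn_model) for s in sites]
    return CellModel(morph, dist, channels, synapses)


def _model_sites(model: CellModel) -> tuple[SynapseSite, ...]:
    return tuple(site for site, _ in model.synapses)


def select_sites(sites, preset: str) -> tuple[SynapseSite, ...]:
    """Pick an activation subset from 5 ordered sites.

    Presets follow the four classic configurations: "P" the three most
    proximal, "M" the middle three, "D" the three most distal, "A"
    alternating (first, third, fifth).
    """
    sites = sorted(sites, key=lambda s: s.path_distance)
    if len(sites) != 5:
        raise ValueError("site presets are defined for exactly 5 sites")
    picks = {"P": sites[:3], "M": sites[1:4], "D": sites[2:], "A": sites[0::2]}
    try:
        return tuple(picks[preset])
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; use P, M, D or A") from None


def _protocol_duration(protocol: DirectionalProtocol, n_pulses: int) -> float:
    return (
        PRE_STIMULUS_MS
        + (n_pulses - 1) * protocol.inter_pulse_interval
        + protocol.response_window
        + 10.0
    )


def run_direction_pair(
    model: CellModel,
    protocol: DirectionalProtocol | None = None,
    *,
    include_singles: bool = True,
    equilibrated: Simulation | None = None,
) -> DSResult:
    """Run the away and toward sequences and compute DS statistics.

    The model is equilibrated once; the state is saved and restored
    before each direction (and each single-site run), so run order
    cannot influence the results.  Pass ``use_restore=False`` in the
    protocol to deliberately let the first sequence contaminate the
    second (the directions are then run back-to-back in one simulation).
    """
    if protocol is None:
        protocol = DirectionalProtocol(sites=_model_sites(model))
    model_sites = set(_model_sites(model))
    for s in protocol.sites:
        if s not in model_sites:
            raise ValueError(
                f"protocol site at {s.path_distance:.1f} um is not a synapse "
                "of this model"
            )

    sim = equilibrated if equilibrated is not None else Simulation(model, dt=protocol.dt)
    if equilibrated is None:
        sim.equilibrate()
    vrest = float(sim.state.v[protocol.record_compartment])
    snapshot = sim.save_state()

    duration = _protocol_duration(protocol, len(protocol.sites))
    t0 = snapshot.t + PRE_STIMULUS_MS
    rec = protocol.record_compartment

    if protocol.use_restore:
        traces = {}
        for direction in ("away", "toward"):
            sim.restore_state(snapshot)
            traces[direction] = sim.advance(
                duration, protocol.pulses(direction, t0), record=rec
            )
    else:
        # back-to-back: away first, toward follows in the same simulation
        sim.restore_state(snapshot)
        away = sim.advance(duration, protocol.pulses("away", t0), record=rec)
        t1 = sim.state.t + PRE_STIMULUS_MS
        toward = sim.advance(duration, protocol.pulses("toward", t1), record=rec)
        traces = {"away": away, "toward": toward}

    for tr in traces.values():
        tr.vrest = vrest

    singles: dict[float, Trace] = {}
    if include_singles:
        for site in protocol.sites:
            sim.restore_state(snapshot)
            pulse = StimulusPulse(
                site, onset=t0, duration=protocol.pulse_duration,
                contrast=protocol.contrast,
            )
            tr = sim.advance(
                PRE_STIMULUS_MS + protocol.response_window + 10.0, (pulse,), record=rec
            )
            tr.vrest = vrest
            singles[site.path_distance] = tr
    sim.restore_state(snapshot)

    win = protocol.response_window
    vpeak_away = vrest + analysis.peak_amplitude(traces["away"], baseline=vrest, window=win)
    vpeak_toward = vrest + analysis.peak_amplitude(traces["toward"], baseline=vrest, window=win)
    q_away = analysis.charge(traces["away"], baseline=vrest, window=win)
    q_toward = analysis.charge(traces["toward"], baseline=vrest, window=win)
    return DSResult(
        trace_away=traces["away"],
        trace_toward=traces["toward"],
        single_traces=singles,
        vrest=vrest,
        vpeak_away=vpeak_away,
        vpeak_toward=vpeak_toward,
        charge_away=q_away,
        charge_toward=q_toward,
        ds_amplitude=analysis.directional_selectivity(
            traces["away"], traces["toward"], "amplitude", vrest=vrest, window=win
        ),
        ds_charge=analysis.directional_selectivity(
            traces["away"], traces["toward"], "charge", vrest=vrest, window=win
        ),
    )


def run_same_site_train(
    model: CellModel,
    site: SynapseSite,
    n_pulses: int = 3,
    delay: float = 50.0,
    *,
    contrast: float = 6.0,
    pulse_duration: float = 3.0,
    response_window: float = analysis.DEFAULT_RESPONSE_WINDOW,
    dt: float = 0.025,
    subthreshold: bool = True,
    equilibrated: Simulation | None = None,
) -> tuple[Trace, Trace]:
    """Train of pulses at one site plus the matched single-pulse response.

    Returns (summed, single) traces for summation-ratio analysis.  With
    ``subthreshold`` set, a spiking summed response raises instead of
    being silently accepted.
    """
    sim = equilibrated if equilibrated is not None else Simulation(model, dt=dt)
    if equilibrated is None:
        sim.equilibrate()
    vrest = float(sim.state.v[0])
    snapshot = sim.save_state()
    t0 = snapshot.t + PRE_STIMULUS_MS
    duration = PRE_STIMULUS_MS + (n_pulses - 1) * delay + response_window + 10.0

    train = tuple(
        StimulusPulse(site, onset=t0 + k * delay, duration=pulse_duration,
                      contrast=contrast)
        for k in range(n_pulses)
    )
    summed = sim.advance(duration, train, record=0)
    sim.restore_state(snapshot)
    single = sim.advance(
        PRE_STIMULUS_MS + response_window + 10.0, (train[0],), record=0
    )
    sim.restore_state(snapshot)
    summed.vrest = single.vrest = vrest

    if subthreshold and analysis.spike_probability([summed], dvdt_threshold=None) > 0:
        raise RuntimeError(
            "summed response is suprathreshold under subthreshold scaling"
        )
    return summed, single


def apply_pharmacology(model: CellModel, remove: str) -> CellModel:
    """Model with one named conductance zeroed everywhere (e.g. ZD7288 = HCN)."""
    return model.without(remove)


def run_voltage_step_family(
    model: CellModel,
    steps=tuple(range(-100, -35, 5)),
    *,
    holding: float = -40.0,
    step_duration: float = 3000.0,
    tail_record: float = 25.0,
    settle: float = 2000.0,
    dt_step: float = 1.0,
    dt_tail: float = 0.05,
    blocked_channel: str = "HCN",
) -> dict:
    """Somatic voltage-step family with and without one conductance.

    Protocol per step: clamp at ``holding``, settle, record the holding
    current, step to the test potential for ``step_duration`` ms (long
    enough for the slow HCN gate to equilibrate), then step back and
    record the tail current for ``tail_record`` ms at fine resolution.
    Returns {"steps", "control", "blocked"} with one clamp-current Trace
    per step, annotated for tail_current_iv.
    """
    out: dict = {"steps": list(steps), "control": [], "blocked": []}
    for label, m in (("control", model), ("blocked", model.without(blocked_channel))):
        sim = Simulation(m, dt=dt_step)
        sim.advance(settle, record=None, clamp=(0, holding))
        baseline_state = sim.save_state()
        for step_v in steps:
            sim.restore_state(baseline_state)
            # measure holding current at fine dt just before the step
            sim.dt = dt_tail
            pre = sim.advance(
                5.0, record=0, clamp=(0, holding), record_clamp_current=True
            )
            holding_current = float(pre.values.mean())
            sim.dt = dt_step
            sim.advance(step_duration, record=None, clamp=(0, step_v))
            sim.dt = dt_tail
            t_off = sim.state.t
            tail = sim.advance(
                tail_record, record=0, clamp=(0, holding), record_clamp_current=True
            )
            tail.annotations.update(
                step_mV=float(step_v),
                step_off_ms=float(t_off),
                holding_current=holding_current,
            )
            out[label].append(tail)
    return out


def run_parameter_scan(
    parameter: str,
    values,
    *,
    protocol_kwargs: dict | None = None,
    build_kwargs: dict | None = None,
) -> "pandas.DataFrame":  # noqa: F821
    """DS as a function of one model parameter (density scale, diameter...).

    ``parameter`` is any keyword of build_standard_cell (na_scale,
    k_scale, hcn_scale, na_density, diameter, length...).  Failures in
    individual runs are recorded (column ``error``) and the scan
    continues.
    """
    import pandas as pd

    rows = []
    for value in values:
        kwargs = dict(build_kwargs or {})
        kwargs[parameter] = value
        try:
            model = build_standard_cell(**kwargs)
            proto = DirectionalProtocol(
                sites=_model_sites(model), **(protocol_kwargs or {})
            )
            res = run_direction_pair(model, proto, include_singles=False)
            rows.append(
                {
                    "parameter": parameter,
                    "value": value,
                    "vrest": res.vrest,
                    "vpeak_away": res.vpeak_away,
                    "vpeak_toward": res.vpeak_toward,
                    "ds_amplitude": res.ds_amplitude,
                    "ds_charge": res.ds_charge,
                    "error": "",
                }
            )
        except Exception as exc:  # scan continues, failure recorded
            rows.append(
                {"parameter": parameter, "value": value, "error": str(exc)}
            )
    return pd.DataFrame(rows)


def rebalance_k_for_vrest(
    na_scale: float,
    vrest_target: float,
    *,
    tolerance: float = 0.7,
    max_correction: float = 5.0,
    build_kwargs: dict | None = None,
) -> float:
    """K-density scale accompanying a Na-density scale.

    Mirrors the tuning rule of the standard model: the delayed-rectifier
    density follows the Na density proportionally, with an additional
    correction (found by bisection on the equilibrated somatic Vrest)
    whenever proportional K cannot keep the resting potential from
    drifting above the standard value.  Returns the total K scale.
    """
    kwargs = dict(build_kwargs or {})

    def vrest_at(corr: float) -> float:
        model = build_standard_cell(
            na_scale=na_scale, k_scale=na_scale * corr, **kwargs
        )
        sim = Simulation(model, dt=0.05)
        return sim.equilibrate(dt=1.0)

    lo, hi = 1.0, max_correction
    v_lo = vrest_at(lo)
    if v_lo <= vrest_target + tolerance:
        return na_scale
    v_hi = vrest_at(hi)
    if v_hi > vrest_target + tolerance:
        return na_scale * hi  # best effort at the bracket edge
    for _ in range(6):
        mid = 0.5 * (lo + hi)
        if vrest_at(mid) > vrest_target + tolerance:
            lo = mid
        else:
            hi = mid
    return na_scale * hi


def na_robustness_scan(
    na_scales=(0.75, 1.0, 1.15, 1.375, 1.75),
    *,
    protocol_kwargs: dict | None = None,
    build_kwargs: dict | None = None,
) -> "pandas.DataFrame":  # noqa: F821
    """DS across dendritic Na densities (Table-1 units: scale x 20 mS/cm^2).

    For each Na density the Kdr density is set by rebalance_k_for_vrest,
    reproducing the standard model's tuning rule (K in proportion to Na,
    adjusted to hold the resting potential near the standard value).
    """
    import pandas as pd

    base = build_standard_cell(**(build_kwargs or {}))
    sim = Simulation(base, dt=0.05)
    vrest_std = sim.equilibrate(dt=1.0)

    rows = []
    for na_scale in na_scales:
        k_scale = rebalance_k_for_vrest(
            na_scale, vrest_std, build_kwargs=build_kwargs
        )
        model = build_standard_cell(
            na_scale=na_scale, k_scale=k_scale, **(build_kwargs or {})
        )
        proto = DirectionalProtocol(
            sites=_model_sites(model), **(protocol_kwargs or {})
        )
        res = run_direction_pair(model, proto, include_singles=False)
        rows.append(
            {
                "na_density_mS_cm2": 20.0 * na_scale,
                "k_scale": k_scale,
                "vrest": res.vrest,
                "ds_amplitude": res.ds_amplitude,
                "ds_charge": res.ds_charge,
            }
        )
    return pd.DataFrame(rows)


def directional_spike_probability(
    model: CellModel,
    protocol: DirectionalProtocol | None = None,
    contrasts=tuple(np.linspace(8.0, 14.0, 8)),
    *,
    v_threshold: float = -20.0,
) -> tuple[float, float]:
    """Spike probability for away vs toward over a ladder of near-threshold
    stimulus strengths (each contrast is one "trial" of the deterministic
    model).  Returns (p_away, p_toward)."""
    if protocol is None:
        protocol = DirectionalProtocol(sites=_model_sites(model))
    sim = Simulation(model, dt=protocol.dt)
    sim.equilibrate()
    snapshot = sim.save_state()
    trials: dict[str, list[Trace]] = {"away": [], "toward": []}
    duration = _protocol_duration(protocol, len(protocol.sites))
    t0 = snapshot.t + PRE_STIMULUS_MS
    for c in contrasts:
        proto = replace(protocol, contrast=float(c))
        for direction in trials:
            sim.restore_state(snapshot)
            trials[direction].append(
                sim.advance(duration, proto.pulses(direction, t0), record=0)
            )
    return (
        analysis.spike_probability(trials["away"], v_threshold=v_threshold),
        analysis.spike_probability(trials["toward"], v_threshold=v_threshold),
    )
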