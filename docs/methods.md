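# Methods

`rgcds` is a compartmental model of an On retinal ganglion cell built to
study how the *order* of synaptic activation along a dendrite shapes the
summed somatic EPSP: activation sequences moving away from the soma
(centrifugal) versus toward it (centripetal), quantified as directional
selectivity (DS) percentages for peak amplitude and charge.

## Model

### Cable and compartments

The membrane equation per compartment,

    C dV/dt = -g_L (V - E_L) - Σ_ch ḡ_ch p_ch (V - E_ch)
              - Σ_syn g_syn (V - E_syn) + Σ_axial g_ij (V_j - V_i),

is integrated with a backward-Euler voltage step (L-stable, so coarse
equilibration steps are safe) on a tree solved by Hines elimination —
O(n) and exact; unbranched cables go through a banded solve.  Channel
gates are advanced by exact exponential (Rush–Larsen) updates with the
voltage frozen over the step; receptor occupancies by backward Euler,
which conserves the occupancy sum to machine precision.  The default
step is 25 µs; the protocol suite runs at 50 µs, where halving the step
changes summed peaks by far less than 0.5 % (a tested invariant).

Compartment length is capped at a fraction (default 0.1, standard model
0.02) of the local space constant λ = √(d·Rm/(4·Ri)).  Morphologies come
from builders or standard SWC files; all "distance from soma" logic uses
path distance along the cable.  Dendritic regions — proximal (< 50 µm),
middle, distal (> 100 µm) — can carry different channel densities.

### Passive and channel parameters

The standard regional parameter set (bundled as `data/standard_cell.yaml`):
Rm = 28 000 Ω·cm², Ri = 200 Ω·cm, Cm = 1 µF/cm², leak reversal −68 mV;
densities in mS/cm² for (distal, middle, proximal, soma): Na (20, 20,
20, 5), delayed-rectifier K (5, 5, 5, 2), HCN (0.005, 0.001, 0.0005, 0).
Reversal potentials (free parameters, textbook values): E_Na = +50 mV,
E_K = −77 mV, E_HCN = −30 mV.

Every gate uses a sigmoid opening/closing rate pair
α(V) = a_max·σ(x), β(V) = b_max·σ(−x), x = (V − V½)/k, giving a Boltzmann
steady state and bell-shaped time constant; a voltage offset and
per-direction rate multipliers can be layered on top.  Gate powers are
conventional: Na m³h, K n⁴, HCN a single activation gate.

The HCN gate is slowed asymmetrically — activation ×0.33, deactivation
×2 — and its voltage offset is then calibrated (bisection) so that 25 %
of channels are open at −65 mV, the value obtained from subtraction
tail-current I–V analysis in these cells.  Base parameters V½ = −80 mV,
k = −7 mV, a_max = b_max = 0.012 ms⁻¹ put the calibrated time constant
near 100–200 ms at rest, fast to close on depolarization and slow to
reopen.

The Na and K kinetics are the package's own calibration (the densities
are fixed, the rate functions are free parameters): m (V½ −43, k 7,
rates 2 ms⁻¹), h (V½ −62, k −3, rates 0.1 ms⁻¹), n (V½ −54, k 5, rates
0.3 ms⁻¹).  They were chosen jointly so that, on the standard geometry,
(i) the full model rests near −64/−65 mV at the soma with no spontaneous
activity, (ii) adding Na+K to the passive cable amplifies summed EPSP
peaks by ≈ 5 %, (iii) the dendrite stays subthreshold for ~4 mV summed
EPSPs yet expresses a steep distal gain, and (iv) the model remains
stable across the density perturbations of the robustness scans.  The
steep, fast-recovering h gate acts as the self-limiting cap on the
distal regenerative boost.

### Standard geometry

Soma (12 µm sphere) plus one unbranched dendrite, 600 µm long, 0.5 µm
diameter, compartmentalized at 0.02 λ; stimulation sites at 300/400/500
µm (proximal preset 30/55/80 µm).  The geometry is a deliberate
calibration: the distal half of a long thin dendrite is partially
isolated electrotonically (L ≈ 1.4 λ), so the HCN gradient and
subthreshold Na current can elevate the distal resting potential by
several mV above the soma, while the compact soma lets that dendritic
depolarization pull somatic rest to ≈ −65 mV.  Shorter or thicker
cables, or a large soma, clamp the dendrite to the leak reversal and no
directional behaviour survives — mirroring the finding that proximal
activation and very strong somatic coupling abolish DS.

### Synapse (uncaging surrogate)

Each site is driven by a voltage-clamped presynaptic compartment:
a stimulus "contrast" (default 6 mV, 3 ms) depolarizes the clamp;
release follows exp(ΔV / 2 mV) (2 mV per e-fold); the release excess
over baseline passes through a first-order filter with separate rise
(75 ms) and fall (125 ms) time constants; the filtered transmitter
drives a four-state AMPA scheme (binding 0.3 ms⁻¹ per unit transmitter /
0.2 ms⁻¹, conformational opening 0.03 ms⁻¹, desensitization 0.02 ms⁻¹,
recovery 0.002 ms⁻¹) whose open fraction scales g_max = 0.13 nS with
reversal 0 mV.  g_max and the contrast are calibrated so single somatic
EPSPs are 1–4 mV and three-site summed responses ~4–5 mV.

The chain's somatic kinetics on the standard model are ≈ 29 ms 10–90 %
rise and ≈ 255 ms fitted decay (≈ 46 ms / 154 ms on the passive cable).
The measured photolytic EPSPs (≈ 49 ms rise, ≈ 109 ms decay) cannot be
matched in decay by any passive chain with a 125 ms release-filter fall
time — the somatic voltage can never decay faster than its conductance
drive — and the subthreshold Na window adds a further slow tail.  The
kinetics tests therefore pin the chain's actual calibrated envelope; the
shape (slow rise, ~100 ms-scale decay) is in the physiological regime
even though the decay constant runs long.

## Protocols

* **Directional pairs** — 3–5 sites activated in increasing (away) or
  decreasing (toward) distance order, 3 ms pulses, 20 ms inter-pulse
  interval (50 ms experiment-mode preset).  The full simulation state
  (voltages, gate values, synapse filter and receptor occupancies) is
  snapshotted after equilibration and restored between directions, so
  run order cannot matter (tested sample-for-sample); without the
  restore, slow HCN/receptor state measurably contaminates a second
  sequence within 500 ms.
* **Same-site trains** — three pulses at one site, delays 1–125 ms, with
  a restored single-pulse reference for summation ratios.
* **Pharmacology** — ZD7288 and TTX analogues zero one conductance
  everywhere, leaving everything else untouched.
* **Voltage-step families** — somatic voltage clamp from −100 to −40 mV
  (3 s steps, long enough for the slow HCN gate), with and without HCN;
  subtraction isolates the HCN current and the mean difference current
  over the first 5 ms after step-off is the tail amplitude.  Run on an
  isopotential HCN-expressing compartment, the normalized tail I–V
  reproduces the analytic activation curve to < 2 points.
* **Robustness scans** — any density scale or geometry knob of the
  standard cell.  The Na scan (15–35 mS/cm²) follows the model's tuning
  rule: K scales with Na, with a bisected correction that keeps the
  resting potential near the standard value whenever proportional K is
  not enough.

## Analysis conventions

Vrest is the mean over the 100 ms before the first stimulus.  Charge is
the baseline-subtracted trapezoidal integral from the first onset to
550 ms (≈ five decay constants) after the last onset.  DS(amplitude) =
(Vpeak_away − Vpeak_toward)/(Vpeak_toward − Vrest)·100; DS(charge) =
(Q_away − Q_toward)/Q_toward·100; |DS| < 2 % is reported as "no DS".
Peaks are taken after a 2 ms boxcar so recording noise cannot bias them.
Decay is a log-linear fit between 90 % and 10 % of peak (NaN when there
is no falling phase).  Spike threshold: −20 mV crossing or dV/dt >
20 mV/ms, both configurable.

## What the model does and does not reproduce

With the standard parameter set the model yields: somatic rest −65.0 mV
(full), −68 mV (passive); HCN-only depolarization +0.7 mV (< 5 mV);
HCN added to the passive cable cuts summed peaks by ≈ 6 %; Na+K alone
amplify them by ≈ 5 % with charge DS ≈ 0; the full model is centrifugal
in both amplitude (≈ +2.3 %) and charge (≈ +0.06 %), removal of HCN or
proximal-only activation abolishes DS, and the amplitude DS grows with
Na density (+15 % → ≈ +4.9 %) and shrinks with K density.  The
directional asymmetry comes from the last-activated distal site: in the
away order its EPSP launches from a dendrite already depolarized by the
preceding inputs and fires into the steep distal Na gain, which the HCN
gradient has biased upward; in the toward order the same site fires
first, from rest.

Known limitations, all consequences of the small HCN conductances in
the standard table (≤ 14 % of the leak conductance) on an unbranched
cable:

* charge DS is reliably signed but small (tenths of a percent, versus
  tens of percent in recordings, where HCN blockade changes charge by
  ~30 %);
* same-site trains are sublinear and become more linear as the delay
  grows — local driving-force saturation at the high-impedance distal
  site outweighs the weak HCN-mediated supralinearity, so the measured
  short-delay supralinearity is not reproduced;
* the synthetic-data generator emulates bi-exponential EPSPs with white
  Gaussian noise; real recording noise, NMDA components and inhibition
  are absent, so analysis tests validate the estimators, not biological
  realism.

Test problem sizes (cable of ~70 compartments, 50 µs protocol step,
700 ms sweeps, five-point Na scans) were chosen so each invariant is
exercised well inside its tolerance; all are package defaults or
documented per-test choices.
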