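# Methods

## Model

The package simulates a reduced spiking network of the basal ganglia with
6539 neurons in seven populations: striatal D1- and D2-type spiny
projection neurons (2000 each), striatal fast-spiking interneurons
(FSI, 80), the subthalamic nucleus (STN, 388), the arkypallidal (GPe-TA,
329) and prototypical (GPe-TI, 988) subpopulations of the external globus
pallidus, and the substantia nigra pars reticulata (SNr, 754), the output
nucleus analyzed throughout.

Striatal and STN neurons are leaky integrate-and-fire (LIF) units;
GPe and SNr neurons are adaptive exponential integrate-and-fire (AdEx)
units whose subthreshold adaptation conductance `a`, spike-triggered
increment `b` and slope factor `Delta_T` let them pace-make and fire
rebound bursts on release from hyperpolarization. All synapses are static
conductance-based alpha synapses: a presynaptic spike elicits, after the
projection's conduction delay, a conductance transient
`g(t) = |J| (t/tau) exp(-(t-tau)/tau)` peaking at exactly `|J|` one
synaptic time constant after arrival; negative weights route through the
target's inhibitory channel (reversal `E_in`), positive through the
excitatory channel (`E_ex`). Synaptic current is `g(t) (V - E_rev)`.
Within a channel all inputs share one time constant, so per-neuron
conductances are aggregated into two state variables per channel — an
exact simplification, not an approximation.

Population sizes, in-degrees, weights, delays and all neuron constants
are fixed model tables (see `bgnet.params`); each target neuron draws
exactly K distinct presynaptic partners uniformly at random (no
autapses, no multapses), giving a point-mass in-degree distribution.
One noted oddity of the parameter tables is the STN excitatory reversal
potential of −10 mV (instead of the usual 0 mV); it lies far above the
STN operating range, so excitatory input still depolarizes, and the
printed value is used as-is. Likewise the GPe-TA/GPe-TI synaptic time
constants (1/5.5 ms vs 4.8/1 ms) look transposed between the two tables
but are used exactly as printed, and the AdEx slope factor is printed
with ms units but enters the equations as a voltage (mV).

## Dopamine

A tonic dopamine level `alpha_dop` in [0, 1] modulates the model around
the healthy operating point `alpha_normal = 0.8` through
`phi = alpha_dop - 0.8`. Selected resting potentials (D1-SPN, FSI,
GPe-TA, GPe-TI, SNr), the D1-SPN spike threshold, and a subset of
synaptic weights scale linearly as `(1 + beta * phi)` with per-parameter
sensitivities `beta`. Three presets are shipped:

* **normal** — `alpha_dop = 0.8`, all tables at their printed values;
* **PD-biphasic** — `alpha_dop = 0`, the default dopamine-depleted
  sensitivity set;
* **PD-triphasic** — `alpha_dop = 0` with three sensitivities changed
  (weaker D2-SPN→GPe-TI, stronger D1-SPN→SNr, weaker GPe-TI→STN), the
  minimal modification that restores a four-phase transient response in
  the depleted state.

Dopamine never changes delays or in-degrees. D2-SPN excitability is
unmodulated by default; a toggle (`d2_modulation=True`) enables it for
the control experiment that shows the transient response is insensitive
to it.

## Integration

The network is advanced with a global step of 0.1 ms. The two linear
alpha-synapse state variables per channel use their exact exponential
propagator. LIF membranes use the midpoint (second-order Runge-Kutta)
rule. AdEx membranes use two exponential-Euler substeps per global step:
leak and synaptic conductance terms are advanced with their exact
propagator while the spike-initiation exponential and the adaptation
current are held piecewise constant within a substep. The substeps exist
because SNr neurons can carry several hundred nS of afferent GPe
conductance, giving an effective membrane time constant well below the
global step; a plain RK2 update at 0.1 ms visibly shifts SNr rates when
the step is halved, while the exponential-Euler form is stable and
step-size robust. Delays are realized as a circular buffer of pending
conductance increments (one slot per step); all table delays are integer
multiples of the step, which is asserted.

Halving the step changes the mean rates of the directly integrated
populations by under ~2 %. SNr mean rates can move a few percent more —
not an integration artifact but amplification: SNr is a pure readout
(no feedback), and per-mille changes in GPe-TI firing scale into percent
changes of SNr rate through the ~200 nS inhibitory gain.

External Poisson drive is generated per population group: one Poisson
draw for the group's total event count per step, scattered uniformly
over members — by Poisson thinning exactly equivalent to independent
per-neuron processes, at a fraction of the generator cost. Everything is
deterministic given the seeds: one master seed derives independent
substreams for connectivity (per projection, so lesioning one projection
leaves the others identical), initial conditions, and per-trial noise.

Initial membrane potentials are uniform in `[E_L, V_th]` per neuron with
zero adaptation; stimulation onsets are jittered across [700, 900] ms
precisely so that startup transients never enter the analysis windows.

## External inputs and calibration

Every neuron receives an independent excitatory Poisson background; for
striatum and STN this stands in for cortex/thalamus, for GPe and SNr for
endogenous and extrinsic drive. Background *weights* are fixed design
constants (one value per population — two free knobs per population
would be unidentifiable); only the *rates* are calibrated so that
stimulus-free baseline rates fall inside the published per-population
target bands in each condition. The weights (nS): D1-SPN 2, D2-SPN 2,
FSI 4, STN 4, GPe-TA 8, GPe-TI 4, SNr 4. The relatively large values for
STN/GPe/SNr are deliberate: at a fixed calibrated mean, the variance of
the background conductance grows with the weight, and this per-neuron
noise is what keeps the healthy network asynchronous — with small
weights the homogeneous GPe/SNr pacemakers synchronize spuriously.

Calibration adjusts one population at a time in topological order
(striatum first, SNr — a pure sink — last) by bracketing and log-space
bisection on that population's own drive, repeating the sweep until all
bands are met. A population's rate is monotone in its own excitatory
drive, which makes the inner bisection sound; simultaneous updates of
all populations oscillate because the rate-vs-drive curves are steep and
coupled. Calibrated rates per condition ship as preset files; re-running
the calibration from a shipped preset converges after a single
verification simulation. In the dopamine-depleted presets the GPe-TI
band [17, 20] Hz is unreachable: even with zero background the
(dopamine-strengthened) STN input holds GPe-TI near 24 Hz, a consequence
of the printed 1-ms GPe-TI inhibitory time constant and −65 mV reversal
that make striato-pallidal inhibition weak. The calibrator then reports
best-achieved rates with residuals; every other band is met.

## Transient stimulus

Cortical stimulation is a rate-modulated Poisson injection to a fraction
(default 50 %) of the striatal (D1, D2, FSI) and STN populations:
a rectangular pulse (amplitude in spikes/s, duration in ms, with an
optional linear onset ramp emulating the temporal dispersion of the
cortical volley) followed by a suppression phase in which the stimulated
neurons' background is scaled by `1 - depth`, emulating the brief
cortical excitation followed by recurrent-inhibition silence. The stimulated subsets are drawn once
per network build and fixed across trials; the rate profile is identical
across trials while spike realizations differ. Stimulus synaptic weights
onto D1-SPN, D2-SPN and STN scale with the cortical dopamine
sensitivities, so in the depleted state the hyperdirect (cortex→STN)
branch strengthens (×1.92) while the cortex→D1 branch nearly vanishes
(×0.17) — the mechanism behind the stronger early excitation and lost
early inhibition.

Because the published stimulus waveform is only shown graphically, the
free profile parameters are fitted once, in the healthy condition only,
against three anchors (early-excitation latency 7 ms and duration 4 ms,
early-inhibition latency 11 ms) and then frozen; the fitted profile
ships as a preset and is reused unchanged in every other condition and
experiment. All other transient-response features are therefore
out-of-sample model outputs, not fitted quantities.

## Response analysis

PSTHs use 1-ms bins on a window 100 ms before to 250 ms after onset,
averaged over trials and analyzed neurons; baseline mean and SD come
from the 100 pre-stimulus bins only. A zone opens at the first of at
least two consecutive bins whose one-tailed Z statistic against baseline
exceeds 1.645 (p < 0.05), closes when two consecutive bins fall below
significance, and ends at the last significant bin. Episodes are
labeled by a response grammar: first excitation EE, inhibition followed
by later excitation EI, post-EI excitation LE, trailing inhibition LI.
Consecutive excitatory episodes with no intervening inhibition separated
by less than 15 ms (the scale of the missing EI zone) merge into a
single EE(+LE) zone — the depleted-state biphasic pattern; the gap bound
prevents unrelated late fluctuations from being absorbed. Episodes
beyond the fourth are ignored with a warning. Zone features are latency,
duration, absolute area (summed |deviation| over the zone's bins,
area/duration as average strength), mean and SD of bin heights, and the
peak bin height (reported as deviation from baseline in the feature
tables). The 24-component response signature concatenates the six
features over EE, EI, LE, LI in that fixed order; undetected zones
contribute zeros, and compared signatures must share that policy. The
signature distance is the plain Euclidean norm over the 24 raw
components (no per-component normalization by default, with an optional
flag), mixing ms and spikes/s units as the definition prescribes.
Feature dispersion is estimated by resampling: 100 observations each
drawing 50 % (or 20 %) of the SNr population and recomputing the
features.

## Steady-state metrics

Ongoing activity runs 5 s per trial with no stimulus. Population spike
counts in 3-ms bins (sampling rate 333.3 Hz) yield the population Fano
factor (variance/mean; 1 for an uncorrelated Poisson ensemble) and the
oscillation index: the fraction of spectral power of the mean-subtracted
count series inside 12–30 Hz, estimated with a segment-averaged
periodogram (Welch, 512-bin segments; the DC term is removed by mean
subtraction). Phase relationships use 1-ms binned rates, zero-phase
fourth-order Butterworth bandpass 12–30 Hz, Hilbert instantaneous
phases, and a 100-bin histogram of absolute phase differences folded
into [0, pi]. Phase-conditioned stimulation replays a trial with the
same seed after locating, in a stimulus-free first pass, the time in the
onset window where the band-limited SNr Hilbert phase matches the
requested value; stimulus randomness is only consumed while the
stimulus is active, so the pre-onset trajectory is identical by
construction.

## Experiment protocols and problem sizes

The protocol layer reproduces the study designs: per-condition transient
runs (default 100 trials; analyses in this repository's test suite and
acceptance script use 20 trials for transient features and 5–10 trials
of 5 s for steady-state metrics, the package's scaled-down defaults),
stimulated-fraction sweeps (10–100 %), seven-step weight sweeps of six
key connections from `v/m` to `m v` (`m` the dopamine scaling factor of
each weight; for D1-SPN→SNr the depleted end is the weak end, for the
others the strong end) summarized by the coefficient of variation of
each zone's duration and area/time over the grid, single-projection
restorations of the depleted network (weights and delays back to
healthy values, background recalibrated to the healthy bands, distances
of the 24-D signature to healthy and depleted references), a lesion
battery (projection removal without recalibration, including the
two-way STN↔GPe-TI and GPe-TA↔GPe-TI loops), dopamine-level sweeps
(backgrounds log-interpolated between the calibrated depleted and
healthy presets so the endpoints match them exactly), and
phase-conditioned stimulation at the four preset phases with 48 trials
each.

## What the synthetic inputs do and do not emulate

All inputs are homogeneous or rate-modulated Poisson processes. They
emulate uncorrelated background bombardment and a brief cortical command
volley, but not structured cortical dynamics, correlated input
fluctuations, phasic dopamine transients, short-term synaptic
plasticity, NMDA-type voltage dependence, or spatial connectivity
gradients — all outside the model family. The network is homogeneous,
so all neurons of a population share one response profile; the
population diversity of real recordings is only approximated by the
weight-sweep pooling and by subpopulation resampling. Passing tests
therefore validate the network mechanisms under these idealized inputs,
not quantitative agreement with any in vivo recording.

The frozen profile: rate amplitude 5000 spikes/s, 4-ms pulse with a
3.5-ms ramp, 15 % suppression for 20 ms, stimulus weights 0.65 nS onto
D1-SPN, 2.8 onto D2-SPN, 1.0 onto FSI and 1.5 onto STN.

## Known limitations

* The depleted-state GPe-TI baseline band cannot be reached (see
  calibration above); its rate sits ~20 % high, which plausibly
  sharpens the depleted-state oscillation slightly.
* GPe-TI responds to the stimulus volley in a hair-trigger fashion: it
  is a homogeneous, intrinsically supra-threshold population whose
  calibrated background is near zero, so its stimulus-evoked burst and
  dip are nearly all-or-nothing. Three consequences for the transient
  response: the STN-driven GPe-TI burst silences SNr around 11–17 ms
  even in the dopamine-depleted state, so the depleted "merged"
  excitation is broken by an inhibitory gap rather than continuous; the
  post-response GPe-TI burst/pause ringing truncates the late
  inhibition; and the early-excitation peak is clipped by the same fast
  pallidal echo. The evoked zone *timings* (the delay structure of the
  three pathways) are robust; the zone *amplitudes and widths* that
  depend on graded pallidal responses are not.
* In this realization the beta oscillation requires the STN-GPe-TI
  loop: disconnecting it collapses the oscillation (Fano factor near 1)
  rather than leaving it intact, whereas removing D2-SPN->GPe-TI also
  normalizes it. Which perturbations quench the rhythm is thus partly
  an operating-point property, not a parameter-table property.
* The beta oscillation index is sensitive to how regular the model
  oscillation is; the shipped noise weights were chosen once, at the
  healthy/depleted operating points, and are not per-experiment tuning
  knobs.
* Zone labeling uses a grammar; response patterns outside it (e.g. an
  isolated EE-EI pair with nothing after) are folded onto the nearest
  grammatical reading (EE-LI).
* With 20-trial PSTHs the Z-test has ~5 % per-bin false-positive rate;
  two-bin runs of false positives occasionally create short spurious
  zones in quiet windows. The merge-gap bound and the four-zone cap
  keep them from contaminating the main zones.
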