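# bgnet

A spiking network model of the basal ganglia (BG) for studying how chronic
dopamine depletion — the core physiology of Parkinson's disease — reshapes
both the *transient* response of the BG output nucleus to cortical
stimulation and the *ongoing* beta-band (12–30 Hz) pathology of its
steady-state activity.

The package is aimed at computational neuroscientists who want to
regenerate, perturb and analyze these phenomena: it builds the full
6539-neuron network (striatal D1/D2 spiny projection neurons and
fast-spiking interneurons, subthalamic nucleus, arkypallidal and
prototypical external pallidum, substantia nigra pars reticulata) from
published parameter tables, drives it with calibrated Poisson inputs, and
ships the complete analysis pipeline and experiment protocols.

## Model

* **Neurons** — leaky integrate-and-fire for striatum and STN,
  `C dV/dt = -g_L (V - E_L) + I_syn + I_e`; adaptive exponential
  integrate-and-fire (AdEx) for GPe and SNr,
  `C dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_T)/Δ_T) - w + I_syn + I_e`
  with adaptation `τ_w dw/dt = a (V - E_L) - w`, `w ← w + b` at spikes.
* **Synapses** — static conductance-based alpha synapses
  `g(t) = |J| (t/τ_syn) exp(-(t-τ_syn)/τ_syn)` (peak `|J|` at `t = τ_syn`)
  with fixed conduction delays; 22 projections with exact per-target
  in-degrees.
* **Dopamine** — a tonic level `α_dop ∈ [0, 1]` (healthy point 0.8)
  scales selected resting potentials, the D1-SPN threshold and synaptic
  weights as `(1 + β φ)` with `φ = α_dop − 0.8`; three presets: `normal`,
  `PD-biphasic`, `PD-triphasic`.
* **Analysis** — peristimulus time histograms (1-ms bins) segmented into
  early/late excitation and inhibition zones (EE, EI, LE, LI) by a
  one-tailed Z-test (p < 0.05, ≥ 2 consecutive bins); per-zone features
  {latency, duration, area, mean/SD/peak of bin heights} and the 24-D
  Euclidean response signature; population Fano factor and beta-band
  oscillation index `OI = ∫₁₂³⁰ S(f) df / ∫₀^{Fs/2} S(f) df` of 3-ms-binned
  activity; Hilbert phase-difference histograms.

See `docs/methods.md` for the full account, including the input
calibration and the frozen cortical stimulus.

## Worked example

Evoke the cortical transient in the healthy network and print the SNr
zone structure (20 trials, ~1 min on one core):

```python
from bgnet import protocols

res = protocols.run_transient_experiment("normal", n_trials=20, seed=77)
base = res.baselines["SNr"]
print(f"SNr baseline {base.mean:.1f} Hz")
for z in res.zones:
    print(f"{z.label}: detected={z.detected} latency={z.L:.0f} ms "
          f"duration={z.D:.0f} ms peak_dev={z.peak_deviation(base):+.1f} Hz")
```

Output:

```
SNr baseline 27.9 Hz
EE: detected=True latency=8 ms duration=3 ms peak_dev=+42.0 Hz
EI: detected=True latency=11 ms duration=7 ms peak_dev=-27.9 Hz
LE: detected=True latency=18 ms duration=8 ms peak_dev=+422.2 Hz
LI: detected=True latency=26 ms duration=6 ms peak_dev=-27.0 Hz
```

The healthy output nucleus responds with the classic multiphasic
sequence: a brief early excitation carried by the hyperdirect
(cortex→STN→SNr) pathway, an early inhibition at 11 ms from the direct
(D1-SPN→SNr) and pallidal feed-forward routes, a large late excitation at
17–18 ms when the indirect pathway (D2-SPN→GPe-TI) transiently
disinhibits SNr, and a late inhibition near 26 ms.

Ongoing-activity pathology under dopamine depletion:

```python
res = protocols.run_steady_state("PD-biphasic", n_trials=5, seed=1)
m = res.metrics["GPe-TI"]
print(f"GPe-TI Fano factor {m.fano:.1f}, oscillation index {m.oi:.2f}")
```

```
GPe-TI Fano factor 18.3, oscillation index 0.28
```

against a healthy-state Fano factor of ~2.7 and oscillation index ~0.18 —
the dopamine-depleted network synchronizes and oscillates in the beta
band, and removing the striato-pallidal (D2-SPN→GPe-TI) projection
collapses both measures back toward healthy values
(`protocols.run_lesion_battery`).

A thin CLI mirrors the protocols:

```bash
bgnet transient-response --condition PD-biphasic --trials 20 --outdir results
bgnet steady-state --condition PD-biphasic --trials 5
bgnet lesions --trials 4
```

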