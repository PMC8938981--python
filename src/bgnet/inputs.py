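"""External drives: calibrated Poisson background, the transient cortical
stimulus, trial schedules, and phase-locked stimulus timing.

Every neuron receives its own independent Poisson realization. The
transient stimulus is a rate-modulated Poisson process shared as a *rate
profile* across trials (realizations differ): a rectangular excitatory
pulse followed by a rectangular sub-baseline suppression of the stimulated
neurons' background drive, emulating the brief cortical
excitation-then-suppression evoked by cortical stimulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import simulate
from .network import Network
from .params import CORTEX_BETA, ConfigurationError, DopamineState

logger = logging.getLogger("bgnet")

STIMULATED_POPULATIONS = ("D1-SPN", "D2-SPN", "FSI", "STN")

#: default per-population background synaptic weight (nS); a single nominal
#: EPSP size per population - only the rates are calibrated
DEFAULT_BACKGROUND_WEIGHTS = {
    "D1-SPN": 1.0, "D2-SPN": 1.0, "FSI": 2.0, "STN": 1.0,
    "GPe-TA": 1.0, "GPe-TI": 1.0, "SNr": 1.0,
}


def poisson_trains(rate: float, n_sources: int, duration: float,
                   seed: int) -> list:
    """Independent homogeneous Poisson spike trains (times in ms)."""
    if rate < 0:
        raise ConfigurationError("Poisson rate must be non-negative")
    rng = np.random.default_rng(seed)
    trains = []
    lam = rate * duration / 1000.0
    for _ in range(n_sources):
        n = rng.poisson(lam)
        trains.append(np.sort(rng.random(n) * duration))
    return trains


@dataclass
class BackgroundDrive:
    """Per-population homogeneous Poisson background.

    ``rates`` are per-source rates in spikes/s; each neuron receives
    ``n_sources`` independent sources of the given rate through an
    excitatory synapse of weight ``weights[pop]``.
    """

    rates: dict
    weights: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND_WEIGHTS))
    n_sources: dict = field(default_factory=dict)

    def for_population(self, name: str):
        return (self.rates.get(name, 0.0), self.weights.get(name, 1.0),
                self.n_sources.get(name, 1))

    def scaled(self, name: str, factor: float) -> "BackgroundDrive":
        rates = dict(self.rates)
        rates[name] = rates.get(name, 0.0) * factor
        return replace(self, rates=rates)

    def to_dict(self) -> dict:
        return {"rates": {k: float(v) for k, v in self.rates.items()},
                "weights": {k: float(v) for k, v in self.weights.items()},
                "n_sources": dict(self.n_sources)}

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundDrive":
        return cls(rates=dict(d["rates"]), weights=dict(d["weights"]),
                   n_sources=dict(d.get("n_sources", {})))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "BackgroundDrive":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class CalibrationResult:
    drive: BackgroundDrive
    measured: dict
    converged: bool
    n_iterations: int
    residuals: dict


def measure_baseline_rates(network: Network, drive: BackgroundDrive,
                           seed: int, duration: float = 3000.0,
                           t_discard: float = 500.0) -> dict:
    """Per-population mean rates (Hz) of a stimulus-free run."""
    raster = simulate.run(network, drive, duration, seed=seed)
    return {name: raster.population_rate(name, t_discard)
            for name in network.populations}


def calibrate_background(
    network: Network,
    targets: Optional[dict] = None,
    seed: int = 0,
    initial: Optional[BackgroundDrive] = None,
    tolerance: float = 0.0,
    max_iterations: int = 120,
    duration: float = 2000.0,
    t_discard: float = 500.0,
    inner_steps: int = 6,
    n_passes: int = 4,
) -> CalibrationResult:
    """Tune per-population background rates until baseline firing rates fall
    inside the target bands.

    Populations are adjusted one at a time in topological order (striatum
    first, the output nucleus last) because a population's rate is
    monotone in its *own* excitatory drive but strongly coupled to the
    other drives: per-population bracketing plus log-space bisection with
    everything else frozen is robust where simultaneous updates oscillate.
    The outer loop repeats until joint convergence (all populations in
    band), the per-call simulation budget ``max_iterations`` is spent, or
    ``n_passes`` sweeps complete; on non-convergence the best-achieved
    drive and the residuals are returned. Restarting from a calibrated
    drive converges after a single verification simulation.
    """
    if targets is None:
        targets = network.bundle.background_targets
    drive = initial if initial is not None else _default_initial_drive()
    order = [p for p in ("D2-SPN", "D1-SPN", "FSI", "STN", "GPe-TA",
                         "GPe-TI", "SNr") if p in targets]
    n_sims = 0
    best = None

    def simulate_and_score(d):
        nonlocal n_sims, best
        m = measure_baseline_rates(network, d, seed=seed + n_sims,
                                   duration=duration, t_discard=t_discard)
        n_sims += 1
        resid = _residuals(m, targets, tolerance)
        score = sum(abs(resid[p]) / max(0.5 * sum(targets[p]), 0.1)
                    for p in targets)
        if best is None or score < best[0]:
            best = (score, d, dict(m), dict(resid))
        return m, resid

    measured, resid = simulate_and_score(drive)
    logger.info("calibration start: %s",
                {k: round(v, 2) for k, v in measured.items()})
    for sweep in range(n_passes):
        if all(v == 0.0 for v in resid.values()):
            return CalibrationResult(drive, measured, True, n_sims, resid)
        for pop in order:
            if resid.get(pop, 0.0) == 0.0:
                continue
            lo_t, hi_t = targets[pop]
            lo_d, hi_d = None, None   # bracket on this population's drive
            cur = max(drive.rates.get(pop, 1.0), 1.0)
            for _ in range(inner_steps):
                if n_sims >= max_iterations:
                    break
                r = measured.get(pop, 0.0)
                if lo_t - tolerance <= r <= hi_t + tolerance:
                    break
                if r < lo_t:
                    lo_d = cur
                else:
                    hi_d = cur
                if lo_d is not None and hi_d is not None:
                    cur = float(np.sqrt(lo_d * hi_d))
                else:
                    cur = cur * (1.6 if r < lo_t else 1 / 1.6)
                drive = replace(drive,
                                rates={**drive.rates, pop: max(cur, 1.0)})
                measured, resid = simulate_and_score(drive)
                logger.info("calibration sweep %d %s -> %.1f Hz drive, "
                            "rates %s", sweep, pop, cur,
                            {k: round(v, 2) for k, v in measured.items()})
            if n_sims >= max_iterations:
                break
        if n_sims >= max_iterations:
            break
    if all(v == 0.0 for v in resid.values()):
        return CalibrationResult(drive, measured, True, n_sims, resid)
    score, drive, measured, resid = best
    logger.warning("background calibration did not converge; residuals %s",
                   resid)
    return CalibrationResult(drive, measured, False, n_sims, resid)


def _default_initial_drive() -> BackgroundDrive:
    # Coarse starting point; the calibration loop does the real work.
    return BackgroundDrive(rates={
        "D1-SPN": 6000.0, "D2-SPN": 6000.0, "FSI": 4000.0, "STN": 4000.0,
        "GPe-TA": 300.0, "GPe-TI": 150.0, "SNr": 6000.0,
    })


def _residuals(measured: dict, targets: dict, tol: float) -> dict:
    out = {}
    for pop, (lo, hi) in targets.items():
        r = measured.get(pop, 0.0)
        if r < lo - tol:
            out[pop] = r - lo
        elif r > hi + tol:
            out[pop] = r - hi
        else:
            out[pop] = 0.0
    return out


@dataclass
class StimulusProfile:
    """Onset-relative rate profile of the transient cortical stimulus.

    A rectangular pulse of ``amplitude`` spikes/s for ``pulse_dur`` ms,
    followed by a suppression phase in which the background drive of the
    stimulated neurons is scaled by ``1 - supp_depth`` for ``supp_dur`` ms.
    ``weights`` are the normal-condition synaptic weights (nS) of the
    stimulus pathway onto each target population; in other conditions they
    are scaled by the cortical dopamine sensitivities.
    """

    amplitude: float
    pulse_dur: float
    supp_depth: float
    supp_dur: float
    ramp_ms: float = 0.0
    fraction: float = 0.5
    targets: tuple = ("D1-SPN", "D2-SPN", "FSI", "STN")
    weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ConfigurationError("stimulated fraction must be in (0, 1]")
        if self.amplitude < 0 or self.supp_depth < 0 or self.supp_depth > 1:
            raise ConfigurationError("invalid stimulus profile")
        self.targets = tuple(self.targets)

    def rate(self, t: float) -> float:
        """Stimulus rate (spikes/s) at onset-relative time t; >= 0.

        A linear ramp of ``ramp_ms`` at pulse onset emulates the temporal
        dispersion of the cortical volley.
        """
        if not 0.0 <= t < self.pulse_dur:
            return 0.0
        if self.ramp_ms > 0.0 and t < self.ramp_ms:
            return self.amplitude * t / self.ramp_ms
        return self.amplitude

    def to_dict(self) -> dict:
        return {"amplitude": float(self.amplitude),
                "pulse_dur": float(self.pulse_dur),
                "supp_depth": float(self.supp_depth),
                "supp_dur": float(self.supp_dur),
                "ramp_ms": float(self.ramp_ms),
                "fraction": float(self.fraction),
                "targets": list(self.targets),
                "weights": {k: float(v) for k, v in self.weights.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProfile":
        return cls(amplitude=d["amplitude"], pulse_dur=d["pulse_dur"],
                   supp_depth=d["supp_depth"], supp_dur=d["supp_dur"],
                   ramp_ms=d.get("ramp_ms", 0.0),
                   fraction=d.get("fraction", 0.5),
                   targets=tuple(d.get("targets", STIMULATED_POPULATIONS)),
                   weights=dict(d.get("weights", {})))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "StimulusProfile":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StimulusRealization:
    """A stimulus profile bound to concrete stimulated subsets and
    condition-effective weights."""

    profile: StimulusProfile
    subsets: dict          # population -> global ids (np.ndarray)
    eff_weights: dict      # population -> nS

    def per_step_arrays(self, onset: float, n_steps: int, dt: float):
        t = (np.arange(n_steps) + 1) * dt - onset
        amp = np.full(n_steps, self.profile.amplitude)
        if self.profile.ramp_ms > 0.0:
            amp = amp * np.clip(t / self.profile.ramp_ms, 0.0, 1.0)
        lam = np.where((t >= 0) & (t < self.profile.pulse_dur),
                       amp * dt / 1000.0, 0.0)
        in_supp = ((t >= self.profile.pulse_dur)
                   & (t < self.profile.pulse_dur + self.profile.supp_dur))
        scale = np.where(in_supp, 1.0 - self.profile.supp_depth, 1.0)
        return lam, scale

    def weight_array(self, network: Network) -> np.ndarray:
        w = np.zeros(network.n_neurons)
        for pop, ids in self.subsets.items():
            w[ids] = self.eff_weights[pop]
        return w


def transient_stimulus(profile: StimulusProfile, network: Network,
                       build_seed: int,
                       dopamine: Optional[DopamineState] = None,
                       stn_only: bool = False) -> StimulusRealization:
    """Bind a stimulus profile to a network build.

    The stimulated subset of each target population (``fraction`` of its
    neurons) is drawn once per build seed and reused across trials. The
    stimulus weight onto D1-SPN, D2-SPN and STN is scaled by the
    corresponding cortical dopamine sensitivity.
    """
    from .params import modulate_weight

    if dopamine is None:
        dopamine = network.bundle.dopamine
    targets = ("STN",) if stn_only else profile.targets
    rng = np.random.default_rng(np.uint32(build_seed * 2654435761 % (2**31)))
    subsets, eff = {}, {}
    for pop in targets:
        if pop not in network.populations:
            raise ConfigurationError(f"unknown stimulus target {pop!r}")
        p = network.populations[pop]
        k = int(round(profile.fraction * p.size))
        if k < 1:
            raise ConfigurationError("stimulated fraction selects no neurons")
        subsets[pop] = np.sort(rng.choice(p.size, size=k, replace=False)
                               + p.first_id)
        base_w = profile.weights.get(pop, 1.0)
        beta = CORTEX_BETA.get(pop, 0.0)
        eff[pop] = modulate_weight(base_w, beta, dopamine)
    return StimulusRealization(profile=profile, subsets=subsets,
                               eff_weights=eff)


@dataclass
class TrialSchedule:
    """Per-trial stimulus onsets, uniform in the onset window."""

    n_trials: int = 100
    onset_window: tuple = (700.0, 900.0)
    record_ms: float = 1200.0

    def onsets(self, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        lo, hi = self.onset_window
        return lo + (hi - lo) * rng.random(self.n_trials)


def calibrate_stimulus(
    network: Network,
    drive: BackgroundDrive,
    initial: StimulusProfile,
    seed: int = 0,
    n_trials: int = 20,
    anchors: dict = None,
    max_evals: int = 24,
) -> tuple:
    """Fit the free stimulus parameters against the healthy-condition
    anchors (EE latency 7 ms, EE duration 4 ms, EI latency 11 ms).

    Coordinate search over pulse amplitude, pulse duration and the
    suppression parameters, scoring each candidate by the absolute anchor
    mismatch of a normal-condition transient run. The best profile is
    returned together with its score and per-anchor errors; it is meant to
    be fitted once and then frozen (shipped as a preset) - downstream
    conditions must not re-tune it.
    """
    from . import protocols

    if anchors is None:
        anchors = {("EE", "L"): 7.0, ("EE", "D"): 4.0, ("EI", "L"): 11.0}

    def score(profile: StimulusProfile):
        res = protocols.run_transient_experiment(
            condition="normal", n_trials=n_trials, seed=seed,
            network=network, drive=drive, profile=profile)
        err = 0.0
        per = {}
        for (label, feat), target in anchors.items():
            z = res.zone(label)
            val = getattr(z, feat) if z.detected else -50.0
            per[(label, feat)] = val - target
            err += abs(val - target)
        return err, per

    best = initial
    best_err, best_per = score(initial)
    evals = 1
    steps = {"amplitude": 0.25, "pulse_dur": 0.25,
             "supp_depth": 0.2, "supp_dur": 0.25}
    while evals < max_evals and best_err > 0.0:
        improved = False
        for attr, rel in steps.items():
            for sign in (+1, -1):
                cur = getattr(best, attr)
                new = cur * (1 + sign * rel)
                if attr == "supp_depth":
                    new = float(np.clip(cur + sign * rel, 0.0, 0.95))
                cand = replace(best, **{attr: new})
                err, per = score(cand)
                evals += 1
                if err < best_err:
                    best, best_err, best_per = cand, err, per
                    improved = True
                if evals >= max_evals:
                    break
            if evals >= max_evals:
                break
        if not improved:
            break
    if best_err > 0:
        logger.warning("stimulus calibration residuals: %s", best_per)
    return best, {"error": best_err, "per_anchor": best_per, "evals": evals}


#: stimulation-phase presets (radians / pi) from the phase-conditioned runs
PHASE_PRESETS = {
    "trough": 1.20 * np.pi,
    "rising-early": 1.61 * np.pi,
    "rising-late": 1.81 * np.pi,
    "falling": 0.23 * np.pi,
}


def instantaneous_phase(rate_series: np.ndarray, fs: float,
                        band=(12.0, 30.0)) -> np.ndarray:
    """Hilbert phase of the band-limited (12-30 Hz) rate series."""
    from scipy.signal import butter, filtfilt, hilbert

    b, a = butter(4, [band[0] / (fs / 2), band[1] / (fs / 2)], btype="band")
    filtered = filtfilt(b, a, rate_series - np.mean(rate_series))
    if not np.all(np.isfinite(filtered)):
        raise ConfigurationError("bandpass filter produced non-finite output")
    return np.angle(hilbert(filtered))


def phase_locked_onset(rate_series_1ms: np.ndarray, target_phase: float,
                       window: tuple = (700.0, 900.0),
                       min_power_ratio: float = 0.02) -> float:
    """Pick the onset time (ms) in ``window`` where the 12-30 Hz Hilbert
    phase of the SNr population rate is closest to ``target_phase``.

    Raises when the series carries too little beta power for the phase to
    be meaningful.
    """
    from scipy.signal import butter, filtfilt

    x = rate_series_1ms - np.mean(rate_series_1ms)
    b, a = butter(4, [12.0 / 500.0, 30.0 / 500.0], btype="band")
    filtered = filtfilt(b, a, x)
    total = float(np.var(x))
    if total <= 0 or float(np.var(filtered)) / total < min_power_ratio:
        raise ConfigurationError(
            "insufficient beta-band power for phase-locked stimulation"
        )
    phase = instantaneous_phase(rate_series_1ms, fs=1000.0)
    lo, hi = int(window[0]), int(window[1])
    seg = phase[lo:hi]
    # circular distance to the requested phase
    d = np.angle(np.exp(1j * (seg - target_phase)))
    return float(lo + int(np.argmin(np.abs(d))))
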