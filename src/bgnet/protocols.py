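"""End-to-end experiment protocols: condition presets -> inputs ->
simulation -> analysis, mirroring the study's transient-response,
weight-sweep, restoration, lesion, dopamine-level and phase-conditioned
experiments.

Every protocol is exactly reproducible from its arguments plus a master
seed; results carry provenance (bundle/network hashes and seeds). The
shipped preset files under :mod:`bgnet.presets` hold the calibrated
background rates per condition and the frozen stimulus profile; protocols
use them by default so runs do not re-tune the inputs.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import inputs, simulate, steady, transient
from .inputs import BackgroundDrive, StimulusProfile, TrialSchedule
from .network import (
    Network,
    apply_lesion,
    build_network,
    restore_projection,
)
from .params import ConditionBundle, ConfigurationError, build_condition

logger = logging.getLogger("bgnet")

ANALYZED_POPULATIONS = ("GPe-TA", "GPe-TI", "STN", "SNr")

#: the six connections of the weight-sweep experiment
SWEEP_CONNECTIONS = (
    "D1-SPN->SNr",
    "D2-SPN->GPe-TI",
    "GPe-TA->GPe-TI",
    "GPe-TI->GPe-TA",
    "STN->GPe-TI",
    "GPe-TI->STN",
)

#: the four restorations / lesions of the perturbation experiments
RESTORATIONS = ("D2-SPN->GPe-TI", "STN<->GPe-TI", "GPe-TA<->GPe-TI",
                "D1-SPN->SNr")
LESIONS = ("D2-SPN->GPe-TI", "STN<->GPe-TI", "GPe-TA<->GPe-TI",
           "GPe-TI->FSI")

_PRESET_FILES = {
    "normal": "normal.yaml",
    "PD-biphasic": "pd_biphasic.yaml",
    "PD-triphasic": "pd_triphasic.yaml",
}


def _preset_path(fname: str):
    return importlib.resources.files("bgnet.presets") / fname


def default_background(condition: str) -> BackgroundDrive:
    """Shipped calibrated background drive for a condition preset."""
    if condition not in _PRESET_FILES:
        raise ConfigurationError(f"no background preset for {condition!r}")
    return BackgroundDrive.load(_preset_path(_PRESET_FILES[condition]))


def default_stimulus() -> StimulusProfile:
    """The frozen calibrated cortical stimulus profile."""
    return StimulusProfile.load(_preset_path("stimulus.yaml"))


_BUNDLE_FILES = {
    "normal": "bundle_normal.yaml",
    "PD-biphasic": "bundle_pd_biphasic.yaml",
    "PD-triphasic": "bundle_pd_triphasic.yaml",
}


def default_bundle(condition: str) -> ConditionBundle:
    """Canonical shipped condition bundle (identical to
    :func:`bgnet.params.build_condition` output; shipped for audit and as
    a plain-text configuration interface)."""
    if condition not in _BUNDLE_FILES:
        raise ConfigurationError(f"no bundle preset for {condition!r}")
    return ConditionBundle.load(_preset_path(_BUNDLE_FILES[condition]))


@dataclass
class ExperimentSpec:
    """Declarative description of one protocol run."""

    protocol: str
    condition: str = "normal"
    fraction: float = 0.5
    n_trials: int = 100
    seed: int = 0
    stn_only: bool = False
    extra: dict = field(default_factory=dict)


@dataclass
class TransientResult:
    """PSTHs per analyzed population plus SNr zone features."""

    condition: str
    psths: dict                 # population -> PSTH
    baselines: dict             # population -> BaselineStats
    zones: list                 # SNr ZoneFeatures in EE/EI/LE/LI order
    signature: transient.ResponseSignature
    onsets: np.ndarray
    provenance: dict
    rasters: Optional[list] = None

    def zone(self, label: str) -> transient.ZoneFeatures:
        for z in self.zones:
            if z.label == label:
                return z
        raise KeyError(label)


def _trial_seed(master_seed: int, trial: int) -> int:
    return (master_seed * 100_003 + 7919 * trial + 13) % (2**31 - 1)


def run_trials(network: Network, drive: BackgroundDrive,
               stimulus_realization, schedule: TrialSchedule,
               seed: int) -> tuple:
    """Simulate ``schedule.n_trials`` independent trials; each has its own
    onset and noise realization, the stimulus rate profile is shared."""
    onsets = schedule.onsets(seed + 1_000_001)
    rasters = []
    for trial, onset in enumerate(onsets):
        raster = simulate.run(
            network, drive, schedule.record_ms,
            seed=_trial_seed(seed, trial), stimulus=stimulus_realization,
            onset=float(onset), trial=trial,
        )
        rasters.append(raster)
    return rasters, onsets


def analyze_transient(rasters: Sequence, onsets: Sequence[float],
                      network: Network,
                      populations: Sequence[str] = ANALYZED_POPULATIONS):
    psths, baselines = {}, {}
    for pop in populations:
        ids = network.populations[pop].ids
        psths[pop], baselines[pop] = transient.compute_psth(
            rasters, onsets, ids)
    zones = transient.detect_zones(psths["SNr"], baselines["SNr"])
    signature = transient.extract_signature(zones)
    return psths, baselines, zones, signature


def run_transient_experiment(
    condition: str = "normal",
    fraction: float = 0.5,
    n_trials: int = 100,
    seed: int = 0,
    stn_only: bool = False,
    network: Optional[Network] = None,
    drive: Optional[BackgroundDrive] = None,
    profile: Optional[StimulusProfile] = None,
    schedule: Optional[TrialSchedule] = None,
    keep_rasters: bool = False,
) -> TransientResult:
    """The cortical-stimulation protocol: stimulate a fraction of the
    striatal and STN populations and measure the evoked PSTHs and the SNr
    zone structure."""
    if network is None:
        bundle = build_condition(condition)
        network = build_network(bundle, seed=seed)
    if drive is None:
        drive = default_background(condition)
    if profile is None:
        profile = default_stimulus()
    if fraction != profile.fraction:
        import dataclasses

        profile = dataclasses.replace(profile, fraction=fraction)
    if schedule is None:
        schedule = TrialSchedule(n_trials=n_trials)
    realization = inputs.transient_stimulus(
        profile, network, build_seed=seed, stn_only=stn_only)
    rasters, onsets = run_trials(network, drive, realization, schedule, seed)
    psths, baselines, zones, signature = analyze_transient(
        rasters, onsets, network)
    prov = {
        "condition": condition, "seed": seed, "fraction": fraction,
        "n_trials": schedule.n_trials, "stn_only": stn_only,
        "network_hash": network.provenance_hash(),
        "stimulus": profile.to_dict(),
    }
    return TransientResult(
        condition=condition, psths=psths, baselines=baselines, zones=zones,
        signature=signature, onsets=np.asarray(onsets), provenance=prov,
        rasters=rasters if keep_rasters else None,
    )


@dataclass
class SteadyStateResult:
    condition: str
    metrics: dict                # population -> OscillationMetrics
    rates: dict                  # population -> mean rate (Hz)
    phase_peaks: dict            # (popA, popB) -> peak |phase difference|
    provenance: dict


def run_steady_state(
    condition: str = "PD-biphasic",
    n_trials: int = 10,
    duration: float = 5000.0,
    seed: int = 0,
    t_discard: float = 500.0,
    network: Optional[Network] = None,
    drive: Optional[BackgroundDrive] = None,
    phase_pairs: Sequence = (("GPe-TA", "GPe-TI"), ("GPe-TA", "STN"),
                             ("GPe-TI", "STN")),
) -> SteadyStateResult:
    """Ongoing (stimulus-free) activity: Fano factor, oscillation index,
    spectra, and pairwise beta-phase relationships."""
    if network is None:
        bundle = build_condition(condition)
        network = build_network(bundle, seed=seed)
    if drive is None:
        drive = default_background(condition)
    counts = {pop: [] for pop in ANALYZED_POPULATIONS}
    rates_1ms = {pop: [] for pop in ANALYZED_POPULATIONS}
    mean_rates = {pop: [] for pop in ANALYZED_POPULATIONS}
    for trial in range(n_trials):
        raster = simulate.run(network, drive, duration + t_discard,
                              seed=_trial_seed(seed, trial), trial=trial)
        for pop in ANALYZED_POPULATIONS:
            counts[pop].append(raster.binned_population_counts(
                pop, steady.BIN_FF_MS, t_start=t_discard))
            rates_1ms[pop].append(raster.binned_population_counts(
                pop, 1.0, t_start=t_discard))
            mean_rates[pop].append(raster.population_rate(pop, t_discard))
    metrics = {pop: steady.trial_metrics(counts[pop])
               for pop in ANALYZED_POPULATIONS}
    phase_peaks = {}
    for pa, pb in phase_pairs:
        peaks = []
        for a, b in zip(rates_1ms[pa], rates_1ms[pb]):
            _, _, peak = steady.phase_relation(a, b)
            peaks.append(peak)
        phase_peaks[(pa, pb)] = float(np.median(peaks))
    prov = {"condition": condition, "seed": seed, "n_trials": n_trials,
            "duration": duration, "network_hash": network.provenance_hash()}
    return SteadyStateResult(
        condition=condition, metrics=metrics,
        rates={p: float(np.mean(mean_rates[p])) for p in ANALYZED_POPULATIONS},
        phase_peaks=phase_peaks, provenance=prov,
    )


def run_fraction_sweep(fractions: Sequence[float] = tuple(
        np.round(np.arange(0.1, 1.01, 0.1), 2)),
        condition: str = "normal", n_trials: int = 20,
        seed: int = 0, **kw) -> dict:
    """Transient responses as a function of the stimulated fraction."""
    return {float(f): run_transient_experiment(
        condition=condition, fraction=float(f), n_trials=n_trials,
        seed=seed, **kw) for f in fractions}


@dataclass
class SweepGrid:
    """Seven synaptic-weight values for one connection, spanning the
    high-dopamine to low-dopamine range.

    ``v`` is the normal-condition weight and ``m`` the PD scaling factor
    (from the dopamine sensitivity, m = 1 - 0.8 beta); the grid runs
    linearly from v/m to v in three steps and from v to m*v in three
    steps. For every connection one end is the PD value and the other the
    high-dopamine (dyskinetic) value; for D1-SPN->SNr the PD end is the
    minimum-magnitude end, for the others the maximum.
    """

    projection: str
    v: float
    m: float

    @property
    def values(self) -> np.ndarray:
        lo = np.linspace(self.v / self.m, self.v, 4)
        hi = np.linspace(self.v, self.v * self.m, 4)
        return np.concatenate([lo, hi[1:]])


def sweep_grid(projection: str,
               bundle: Optional[ConditionBundle] = None) -> SweepGrid:
    if bundle is None:
        bundle = build_condition("normal")
    if projection not in bundle.projections_base:
        raise ConfigurationError(f"unknown projection {projection!r}")
    spec = bundle.projections_base[projection]
    m = 1.0 - 0.8 * spec.beta
    return SweepGrid(projection=projection, v=spec.weight, m=m)


def run_weight_sweep(
    connections: Sequence[str] = SWEEP_CONNECTIONS,
    n_trials: int = 20,
    seed: int = 0,
    **kw,
) -> dict:
    """Vary each of the six key connections over its seven-value grid in
    the normal condition and summarize with the CV (SD/mean over grid
    points) of every zone's duration and area/time.

    Returns {connection: {"values": grid, "features": list of per-grid
    zone dicts, "cv_duration": {...}, "cv_area_per_time": {...}}}.
    """
    import dataclasses

    bundle = build_condition("normal")
    results = {}
    for conn in connections:
        grid = sweep_grid(conn, bundle)
        feats = []
        for value in grid.values:
            projections = dict(bundle.projections)
            projections[conn] = dataclasses.replace(
                projections[conn], weight=float(value))
            mod_bundle = dataclasses.replace(bundle, projections=projections)
            network = build_network(mod_bundle, seed=seed)
            res = run_transient_experiment(
                condition="normal", n_trials=n_trials, seed=seed,
                network=network, **kw)
            feats.append({z.label: z for z in res.zones})
        results[conn] = {
            "values": grid.values,
            "features": feats,
            "cv_duration": _grid_cv(feats, "D"),
            "cv_area_per_time": _grid_cv(feats, "area_per_time"),
        }
    return results


def _grid_cv(feats: list, attr: str) -> dict:
    out = {}
    for label in transient.ZONE_ORDER:
        vals = []
        for f in feats:
            z = f[label]
            if z.detected:
                vals.append(getattr(z, attr) if attr != "area_per_time"
                            else z.area_per_time)
            else:
                vals.append(0.0)
        v = np.asarray(vals, float)
        out[label] = float(v.std() / v.mean()) if v.mean() != 0 else 0.0
    return out


@dataclass
class RestorationResult:
    projection: str
    distance_to_normal: float
    distance_to_pd: float
    result: TransientResult


def run_restoration(
    projections: Sequence[str] = RESTORATIONS,
    n_trials: int = 20,
    seed: int = 0,
    calibrate: bool = True,
    calibration_kw: Optional[dict] = None,
    reference_normal: Optional[TransientResult] = None,
    reference_pd: Optional[TransientResult] = None,
) -> dict:
    """Restore selected connections of the PD(triphasic) network to their
    healthy weights/delays one at a time and measure the 24-D signature
    distances to the healthy and PD references.

    Restoration recalibrates the background so baseline rates return to
    the normal bands (the unrestored PD reference does not).
    """
    normal_bundle = build_condition("normal")
    if reference_normal is None:
        reference_normal = run_transient_experiment(
            "normal", n_trials=n_trials, seed=seed)
    if reference_pd is None:
        reference_pd = run_transient_experiment(
            "PD-triphasic", n_trials=n_trials, seed=seed)
    out = {}
    for proj in projections:
        bundle = build_condition("PD-triphasic")
        network = build_network(bundle, seed=seed)
        network = restore_projection(network, proj, normal_bundle)
        drive = default_background("PD-triphasic")
        if calibrate:
            kwargs = dict(duration=2000.0, max_iterations=6)
            kwargs.update(calibration_kw or {})
            cal = inputs.calibrate_background(
                network, targets=normal_bundle.background_targets,
                seed=seed + 17, initial=drive, **kwargs)
            drive = cal.drive
        res = run_transient_experiment(
            condition="PD-triphasic", n_trials=n_trials, seed=seed,
            network=network, drive=drive)
        out[proj] = RestorationResult(
            projection=proj,
            distance_to_normal=transient.signature_distance(
                res.signature, reference_normal.signature),
            distance_to_pd=transient.signature_distance(
                res.signature, reference_pd.signature),
            result=res,
        )
    return out


def run_lesion_battery(
    conditions: Sequence[str] = ("PD-biphasic", "PD-triphasic"),
    lesions: Sequence[str] = LESIONS,
    n_trials: int = 10,
    duration: float = 5000.0,
    seed: int = 0,
    include_normal: bool = True,
) -> dict:
    """OI and Fano factor per population for each PD preset, each lesion,
    and the normal reference. Lesions do not recalibrate the background."""
    out = {}
    if include_normal:
        out[("normal", None)] = run_steady_state(
            "normal", n_trials=n_trials, duration=duration, seed=seed)
    for cond in conditions:
        bundle = build_condition(cond)
        base_net = build_network(bundle, seed=seed)
        drive = default_background(cond)
        out[(cond, None)] = run_steady_state(
            cond, n_trials=n_trials, duration=duration, seed=seed,
            network=base_net, drive=drive)
        for lesion in lesions:
            net = apply_lesion(base_net, lesion)
            out[(cond, lesion)] = run_steady_state(
                cond, n_trials=n_trials, duration=duration, seed=seed,
                network=net, drive=drive)
    return out


def interpolated_background(condition: str, alpha_dop: float) -> BackgroundDrive:
    """Background drive for an intermediate dopamine level.

    Rates are interpolated log-linearly between the calibrated PD drive
    (level 0) and the calibrated normal drive (level 0.8); above 0.8 the
    normal drive is used unchanged. This keeps the endpoints exactly equal
    to the calibrated presets.
    """
    pd_drive = default_background(condition)
    normal_drive = default_background("normal")
    if alpha_dop >= 0.8:
        return normal_drive
    frac = alpha_dop / 0.8
    rates = {}
    for pop, r_pd in pd_drive.rates.items():
        r_n = normal_drive.rates.get(pop, r_pd)
        rates[pop] = float(np.exp((1 - frac) * np.log(max(r_pd, 1e-9))
                                  + frac * np.log(max(r_n, 1e-9))))
    import dataclasses

    return dataclasses.replace(pd_drive, rates=rates)


def run_dopamine_sweep(
    levels: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    preset: str = "PD-biphasic",
    n_trials: int = 20,
    seed: int = 0,
    **kw,
) -> dict:
    """Transient responses of a PD preset across dopamine levels."""
    out = {}
    for level in levels:
        bundle = build_condition(preset, alpha_dop=float(level))
        network = build_network(bundle, seed=seed)
        drive = interpolated_background(preset, float(level))
        out[float(level)] = run_transient_experiment(
            condition=preset, n_trials=n_trials, seed=seed,
            network=network, drive=drive, **kw)
    return out


@dataclass
class PhaseConditionedResult:
    phase: float
    result: TransientResult
    realized_phases: np.ndarray


def run_phase_conditioned(
    phases: Optional[dict] = None,
    n_trials: int = 48,
    seed: int = 0,
    condition: str = "PD-biphasic",
    record_ms: float = 1200.0,
) -> dict:
    """Deliver the stimulus at chosen phases of the ongoing SNr beta
    oscillation (PD-biphasic network).

    Each trial is first simulated without a stimulus; the beta-band
    Hilbert phase of the SNr rate picks the onset inside the onset window
    at the requested phase, and the trial is replayed with the same seed
    with the stimulus at that onset (the pre-onset trajectory is
    identical by construction). Also returns the grand average over all
    phases under key ``"grand"``.
    """
    if phases is None:
        phases = dict(inputs.PHASE_PRESETS)
    bundle = build_condition(condition)
    network = build_network(bundle, seed=seed)
    drive = default_background(condition)
    profile = default_stimulus()
    realization = inputs.transient_stimulus(profile, network, build_seed=seed)

    out = {}
    all_rasters, all_onsets = [], []
    for name, phi in phases.items():
        rasters, onsets, realized = [], [], []
        for trial in range(n_trials):
            t_seed = _trial_seed(seed + 31 * (1 + hash(name) % 997), trial)
            free = simulate.run(network, drive, record_ms, seed=t_seed,
                                trial=trial)
            rate = free.binned_population_counts("SNr", 1.0)
            onset = inputs.phase_locked_onset(rate, phi)
            phase_series = inputs.instantaneous_phase(rate, fs=1000.0)
            realized.append(phase_series[int(onset)])
            raster = simulate.run(network, drive, record_ms, seed=t_seed,
                                  stimulus=realization, onset=onset,
                                  trial=trial)
            rasters.append(raster)
            onsets.append(onset)
        psths, baselines, zones, signature = analyze_transient(
            rasters, onsets, network)
        prov = {"condition": condition, "phase": phi, "seed": seed,
                "n_trials": n_trials,
                "network_hash": network.provenance_hash()}
        out[name] = PhaseConditionedResult(
            phase=phi,
            result=TransientResult(
                condition=condition, psths=psths, baselines=baselines,
                zones=zones, signature=signature,
                onsets=np.asarray(onsets), provenance=prov),
            realized_phases=np.asarray(realized),
        )
        all_rasters.extend(rasters)
        all_onsets.extend(onsets)
    psths, baselines, zones, signature = analyze_transient(
        all_rasters, all_onsets, network)
    out["grand"] = TransientResult(
        condition=condition, psths=psths, baselines=baselines, zones=zones,
        signature=signature, onsets=np.asarray(all_onsets),
        provenance={"condition": condition, "phase": "grand", "seed": seed})
    return out
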