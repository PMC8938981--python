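"""Transient-response analysis: peristimulus time histograms, statistical
segmentation of the response into excitatory/inhibitory zones, per-zone
features, the 24-dimensional response signature and its Euclidean distance,
and subpopulation resampling statistics.

The PSTH uses 1-ms rectangular bins on a window from 100 ms before to
250 ms after stimulus onset (350 bins, onset at t = 0). Baseline statistics
come exclusively from the 100 pre-stimulus bins. A zone is a run of bins
whose rate is significantly above (excitation) or below (inhibition) the
baseline on a one-tailed Z-test at p < 0.05 (|Z| > 1.645) for at least two
consecutive bins; a zone ends when two consecutive bins drop below
significance, its end being the last significant bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .params import ConfigurationError

WINDOW_PRE = 100   # ms before onset
WINDOW_POST = 250  # ms after onset
BIN_MS = 1.0
N_BINS = WINDOW_PRE + WINDOW_POST

#: one-tailed z critical value for p < 0.05
Z_CRIT = 1.645

ZONE_ORDER = ("EE", "EI", "LE", "LI")
FEATURE_ORDER = ("L", "D", "A", "H_mu", "H_sigma", "H_p")


@dataclass
class PSTH:
    """Trial- and neuron-averaged rate (spikes/s) per 1-ms bin."""

    rates: np.ndarray        # (350,) spikes/s
    n_trials: int
    n_neurons: int

    @property
    def times(self) -> np.ndarray:
        """Left edge of each bin relative to onset (ms)."""
        return np.arange(-WINDOW_PRE, WINDOW_POST, dtype=float)

    @property
    def post(self) -> np.ndarray:
        return self.rates[WINDOW_PRE:]


@dataclass
class BaselineStats:
    mean: float   # H_bas
    sd: float

    @classmethod
    def from_psth(cls, psth: PSTH) -> "BaselineStats":
        pre = psth.rates[:WINDOW_PRE]
        return cls(mean=float(np.mean(pre)), sd=float(np.std(pre, ddof=1)))


@dataclass
class ZoneFeatures:
    """Features of one response zone.

    L: latency (ms, time of the first significant bin); D: duration (ms);
    A: absolute area (summed |deviation from baseline| over the zone's
    bins); H_mu/H_sigma: mean/SD of raw bin heights; H_p: peak bin height
    (max for excitatory, min for inhibitory zones). ``merged`` marks an
    excitatory zone that spans a merged EE+LE response.
    """

    label: str
    detected: bool = False
    L: float = 0.0
    D: float = 0.0
    A: float = 0.0
    H_mu: float = 0.0
    H_sigma: float = 0.0
    H_p: float = 0.0
    merged: bool = False

    def peak_deviation(self, baseline: BaselineStats) -> float:
        return self.H_p - baseline.mean if self.detected else 0.0

    @property
    def area_per_time(self) -> float:
        return self.A / self.D if self.detected and self.D > 0 else 0.0

    def vector(self) -> np.ndarray:
        if not self.detected:
            return np.zeros(6)
        return np.array([self.L, self.D, self.A,
                         self.H_mu, self.H_sigma, self.H_p])


@dataclass
class ResponseSignature:
    """24-component feature vector: {L, D, A, H_mu, H_sigma, H_p} for each
    of EE, EI, LE, LI in that fixed order."""

    F: np.ndarray
    missing: tuple = ()   # labels of not-detected zones (zero-filled)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (24,):
            raise ConfigurationError("signature must have 24 components")


def compute_psth(rasters: Sequence, onsets: Sequence[float],
                 neuron_ids: np.ndarray) -> tuple:
    """PSTH and baseline statistics for a set of trials.

    ``rasters`` are :class:`bgnet.simulate.SpikeRaster` objects (one per
    trial), each aligned to its own onset; ``neuron_ids`` selects the
    analyzed neuron set (global ids). Rate per bin is
    count / (n_trials * n_neurons * 1 ms).
    """
    neuron_ids = np.asarray(neuron_ids)
    if len(rasters) < 1 or len(rasters) != len(onsets):
        raise ConfigurationError("need >= 1 trial with one onset per trial")
    if neuron_ids.size == 0:
        raise ConfigurationError("empty neuron subset")
    id_mask_set = np.zeros(0, dtype=bool)
    counts = np.zeros(N_BINS)
    edges = np.arange(-WINDOW_PRE, WINDOW_POST + 1, dtype=float)
    for raster, onset in zip(rasters, onsets):
        if id_mask_set.size < raster.ids.max(initial=0) + 1:
            id_mask_set = np.zeros(int(raster.ids.max(initial=0)) + 1,
                                   dtype=bool)
            sel = neuron_ids[neuron_ids < id_mask_set.size]
            id_mask_set[sel] = True
        m = id_mask_set[raster.ids]
        rel = raster.times[m] - onset
        c, _ = np.histogram(rel, bins=edges)
        counts += c
    rates = counts / (len(rasters) * neuron_ids.size * (BIN_MS / 1000.0))
    psth = PSTH(rates=rates, n_trials=len(rasters), n_neurons=neuron_ids.size)
    return psth, BaselineStats.from_psth(psth)


def _significant_episodes(sig: np.ndarray) -> list:
    """Episodes (start, end inclusive) of a boolean significance series.

    Opens at the first bin of >= 2 consecutive significant bins; terminates
    when two consecutive bins are non-significant; the end is the last
    significant bin.
    """
    episodes = []
    n = sig.size
    i = 0
    while i < n - 1:
        if sig[i] and sig[i + 1]:
            start = i
            last_sig = i + 1
            j = i + 2
            gap = 0
            while j < n:
                if sig[j]:
                    last_sig = j
                    gap = 0
                else:
                    gap += 1
                    if gap >= 2:
                        break
                j += 1
            episodes.append((start, last_sig))
            i = last_sig + 2
        else:
            i += 1
    return episodes


def detect_zones(psth: PSTH, baseline: BaselineStats,
                 max_zones: int = 4, merge_gap_ms: float = 15.0) -> list:
    """Segment the post-onset PSTH into EE/EI/LE/LI zones.

    Excitation and inhibition episodes are found by separate one-tailed
    scans and interleaved in temporal order. Labels follow the response
    grammar: the first excitatory episode is EE; an inhibitory episode
    followed by a later excitatory episode is EI; an excitatory episode
    after EI is LE; a trailing inhibitory episode is LI. Consecutive
    excitatory episodes with no intervening inhibition and separated by
    less than ``merge_gap_ms`` (the scale of the missing early-inhibition
    zone) are merged into a single (EE+LE) zone spanning both, mirroring
    the merged excitatory response of the dopamine-depleted biphasic
    condition; the gap bound keeps unrelated late fluctuations from being
    absorbed. Absent zones are returned with ``detected=False``.
    """
    if baseline.sd <= 0:
        raise ConfigurationError("baseline SD must be positive")
    post = psth.post
    z = (post - baseline.mean) / baseline.sd
    exc = _significant_episodes(z > Z_CRIT)
    inh = _significant_episodes(z < -Z_CRIT)

    episodes = sorted([(s, e, +1) for s, e in exc]
                      + [(s, e, -1) for s, e in inh])
    # merge consecutive excitatory episodes with no inhibition between
    merged_eps = []
    for ep in episodes:
        if (merged_eps and ep[2] == 1 and merged_eps[-1][2] == 1
                and ep[0] - merged_eps[-1][1] - 1 < merge_gap_ms):
            s0, _, _, _ = merged_eps[-1]
            merged_eps[-1] = (s0, ep[1], 1, True)
        else:
            merged_eps.append((ep[0], ep[1], ep[2], False))
    if len(merged_eps) > max_zones:
        import warnings

        warnings.warn(f"{len(merged_eps)} episodes detected; zones beyond "
                      f"the fourth are ignored", RuntimeWarning)
        merged_eps = merged_eps[:max_zones]

    zones = {label: ZoneFeatures(label=label) for label in ZONE_ORDER}
    n_exc_seen = 0
    for idx, (s, e, pol, was_merged) in enumerate(merged_eps):
        later_exc = any(p == 1 for _, _, p, _ in merged_eps[idx + 1:])
        if pol == 1:
            label = "EE" if n_exc_seen == 0 else "LE"
            n_exc_seen += 1
        else:
            label = "EI" if later_exc else "LI"
        if zones[label].detected:
            continue
        zones[label] = _zone_features(label, s, e, post, baseline,
                                      merged=was_merged)
    return [zones[label] for label in ZONE_ORDER]


def _zone_features(label: str, start: int, end: int, post: np.ndarray,
                   baseline: BaselineStats, merged: bool) -> ZoneFeatures:
    seg = post[start:end + 1]
    dev = seg - baseline.mean
    peak = float(seg.max()) if label in ("EE", "LE") else float(seg.min())
    return ZoneFeatures(
        label=label, detected=True, L=float(start),
        D=float(end - start + 1), A=float(np.abs(dev).sum()),
        H_mu=float(seg.mean()), H_sigma=float(seg.std()),
        H_p=peak, merged=merged,
    )


def extract_signature(zones: Sequence[ZoneFeatures],
                      baseline: Optional[BaselineStats] = None,
                      peak_as_deviation: bool = False) -> ResponseSignature:
    """Pack zone features into the fixed-order 24-vector.

    With ``peak_as_deviation`` the H_p component is reported relative to
    the baseline mean (the convention of the feature tables); undetected
    zones contribute zeros and are listed in ``missing``.
    """
    by_label = {z.label: z for z in zones}
    parts, missing = [], []
    for label in ZONE_ORDER:
        z = by_label.get(label, ZoneFeatures(label=label))
        v = z.vector()
        if z.detected and peak_as_deviation:
            if baseline is None:
                raise ConfigurationError(
                    "peak_as_deviation requires baseline stats")
            v = v.copy()
            v[5] = z.H_p - baseline.mean
        if not z.detected:
            missing.append(label)
        parts.append(v)
    return ResponseSignature(F=np.concatenate(parts), missing=tuple(missing))


def signature_distance(f_test: ResponseSignature,
                       f_ref: ResponseSignature,
                       normalize: bool = False) -> float:
    """Euclidean distance between two 24-D response signatures.

    Signatures must share the missing-zone policy (the same set of
    zero-filled zones is allowed to differ in which zones are missing, but
    both must have been packed with zeros for missing zones - enforced by
    construction). With ``normalize`` each component is scaled by the
    reference magnitude before the sum (off by default: the printed
    formula sums raw components).
    """
    a, b = f_test.F, f_ref.F
    if normalize:
        scale = np.where(np.abs(b) > 1e-12, np.abs(b), 1.0)
        a, b = a / scale, b / scale
    return float(np.sqrt(np.sum((a - b) ** 2)))


@dataclass
class FeatureStats:
    """Mean and SD per (zone, feature) over resampled observations."""

    mean: dict
    sd: dict
    n_observations: int
    subset_fraction: float


def subsample_features(rasters: Sequence, onsets: Sequence[float],
                       neuron_ids: np.ndarray, n_s: float = 0.5,
                       o_s: int = 100, seed: int = 0,
                       peak_as_deviation: bool = True) -> FeatureStats:
    """Resampling statistics of the zone features.

    Each of ``o_s`` observations draws ``n_s`` (fraction) of the analyzed
    neurons, recomputes the PSTH and zone features, and the per-feature
    mean and SD over observations are returned. Keys are
    ``(zone, feature)`` with features in {L, D, A, H_mu, H_sigma, H_p};
    H_p is reported as deviation from baseline by default.
    """
    neuron_ids = np.asarray(neuron_ids)
    k = int(round(n_s * neuron_ids.size))
    if k < 1:
        raise ConfigurationError("subset fraction selects no neurons")
    rng = np.random.default_rng(seed)
    samples: dict = {}
    for _ in range(o_s):
        subset = rng.choice(neuron_ids, size=k, replace=False)
        psth, base = compute_psth(rasters, onsets, subset)
        zones = detect_zones(psth, base)
        for z in zones:
            for feat in FEATURE_ORDER:
                val = getattr(z, feat if feat != "H_p" else "H_p")
                if feat == "H_p":
                    val = z.peak_deviation(base) if peak_as_deviation else val
                samples.setdefault((z.label, feat), []).append(
                    val if z.detected else np.nan)
    mean, sd = {}, {}
    for key, vals in samples.items():
        v = np.asarray(vals, dtype=float)
        good = v[~np.isnan(v)]
        mean[key] = float(np.mean(good)) if good.size else float("nan")
        sd[key] = float(np.std(good, ddof=0)) if good.size else float("nan")
    return FeatureStats(mean=mean, sd=sd, n_observations=o_s,
                        subset_fraction=n_s)
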