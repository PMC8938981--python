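"""PSTH construction, zone segmentation, signatures, and resampling.

The zone oracle used here is a direct hand count on noise-free synthetic
PSTHs: bins are set an exact number of baseline SDs above/below a flat
baseline, so zone boundaries are known by construction.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgnet import transient
from bgnet.simulate import SpikeRaster
from bgnet.transient import (
    N_BINS,
    WINDOW_PRE,
    BaselineStats,
    PSTH,
    ResponseSignature,
    compute_psth,
    detect_zones,
    extract_signature,
    signature_distance,
    subsample_features,
)


def synthetic_psth(baseline=30.0, sd=1.0, segments=(), seed=None):
    """Flat PSTH with noise-free baseline and rectangular deviations.

    ``segments``: (t_start, t_end_inclusive, amplitude_in_sd) post-onset.
    A deterministic +/-1 SD alternation in the pre-window fixes the
    baseline SD without adding randomness.
    """
    rates = np.full(N_BINS, baseline)
    pre = np.arange(WINDOW_PRE)
    rates[:WINDOW_PRE] += sd * np.where(pre % 2 == 0, 1.0, -1.0)
    for t0, t1, amp in segments:
        rates[WINDOW_PRE + t0:WINDOW_PRE + t1 + 1] = baseline + amp * sd
    return PSTH(rates=rates, n_trials=1, n_neurons=1)


FOUR_ZONE_SEGMENTS = [(7, 10, 5), (11, 16, -5), (17, 26, 5), (27, 36, -5)]


class TestComputePsth:
    def _raster(self, times, ids, duration=1200.0):
        return SpikeRaster(times=np.asarray(times, float),
                           ids=np.asarray(ids, np.int32),
                           duration=duration,
                           populations={"SNr": (0, 10)})

    def test_single_spike_at_onset_counting_oracle(self):
        n_trials = 4
        rasters = [self._raster([800.0001], [0]) for _ in range(n_trials)]
        onsets = [800.0] * n_trials
        psth, base = compute_psth(rasters, onsets, np.arange(10))
        # one spike per trial in bin t=0: rate = 1 / (n_neurons * 1 ms)
        assert psth.rates[WINDOW_PRE] == pytest.approx(1000.0 / 10)
        assert psth.rates.sum() == pytest.approx(1000.0 / 10)

    def test_homogeneous_poisson_flat(self):
        rng = np.random.default_rng(5)
        rate, n_neurons, n_trials = 30.0, 40, 30
        rasters, onsets = [], []
        for _ in range(n_trials):
            events = []
            for i in range(n_neurons):
                n = rng.poisson(rate * 1.2)
                events.append((np.sort(rng.random(n) * 1200.0), i))
            times = np.concatenate([t for t, _ in events])
            ids = np.concatenate([np.full(len(t), i)
                                  for t, i in events])
            rasters.append(self._raster(times, ids))
            onsets.append(800.0)
        psth, base = compute_psth(rasters, onsets, np.arange(n_neurons))
        assert base.mean == pytest.approx(30.0, rel=0.1)
        assert abs(psth.post.mean() - 30.0) < 3.0

    def test_empty_subset_raises(self):
        r = self._raster([1.0], [0])
        with pytest.raises(Exception):
            compute_psth([r], [800.0], np.array([]))


class TestDetectZones:
    def test_flat_psth_no_zones(self):
        psth = synthetic_psth()
        zones = detect_zones(psth, BaselineStats.from_psth(psth))
        assert all(not z.detected for z in zones)

    def test_four_zone_hand_oracle(self):
        psth = synthetic_psth(segments=FOUR_ZONE_SEGMENTS)
        base = BaselineStats.from_psth(psth)
        zones = {z.label: z for z in detect_zones(psth, base)}
        assert zones["EE"].detected and zones["EE"].L == 7 \
            and zones["EE"].D == 4
        assert zones["EI"].detected and zones["EI"].L == 11 \
            and zones["EI"].D == 6
        assert zones["LE"].detected and zones["LE"].L == 17 \
            and zones["LE"].D == 10
        assert zones["LI"].detected and zones["LI"].L == 27 \
            and zones["LI"].D == 10

    def test_merged_excitation_when_no_early_inhibition(self):
        # excitation split by a 4-bin sub-significance gap, then inhibition:
        # the two excitatory episodes merge and the inhibition is late (LI)
        psth = synthetic_psth(segments=[(7, 10, 5), (15, 26, 5),
                                        (29, 38, -5)])
        base = BaselineStats.from_psth(psth)
        zones = {z.label: z for z in detect_zones(psth, base)}
        assert zones["EE"].detected and zones["EE"].merged
        assert zones["EE"].L == 7 and zones["EE"].D == 20
        assert not zones["EI"].detected
        assert not zones["LE"].detected
        assert zones["LI"].detected and zones["LI"].L == 29

    def test_single_long_excitation_then_inhibition_is_ee_li(self):
        # the dopamine-depleted biphasic pattern: one long excitatory zone
        # whose trailing inhibition is labeled LI, not EI
        psth = synthetic_psth(segments=[(7, 28, 5), (31, 60, -5)])
        base = BaselineStats.from_psth(psth)
        zones = {z.label: z for z in detect_zones(psth, base)}
        assert zones["EE"].detected and zones["EE"].D == 22
        assert not zones["EI"].detected
        assert zones["LI"].detected and zones["LI"].D == 30

    def test_single_nonsignificant_bin_does_not_terminate(self):
        psth = synthetic_psth(segments=[(7, 11, 5), (13, 17, 5)])
        base = BaselineStats.from_psth(psth)
        zones = {z.label: z for z in detect_zones(psth, base)}
        # one sub-threshold bin inside: still one zone ending at t=17
        assert zones["EE"].detected
        assert zones["EE"].L == 7 and zones["EE"].D == 11

    def test_shift_invariance(self):
        psth = synthetic_psth(segments=FOUR_ZONE_SEGMENTS)
        shifted = PSTH(rates=psth.rates + 17.3, n_trials=1, n_neurons=1)
        za = detect_zones(psth, BaselineStats.from_psth(psth))
        zb = detect_zones(shifted, BaselineStats.from_psth(shifted))
        for a, b in zip(za, zb):
            assert (a.L, a.D, a.detected) == (b.L, b.D, b.detected)

    def test_zones_ordered_and_non_overlapping(self):
        psth = synthetic_psth(segments=FOUR_ZONE_SEGMENTS)
        zones = [z for z in detect_zones(psth,
                                         BaselineStats.from_psth(psth))
                 if z.detected]
        spans = [(z.L, z.L + z.D - 1) for z in zones]
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert e0 < s1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(3, 40), st.integers(2, 12)),
                    min_size=0, max_size=4),
           st.booleans())
    def test_brute_force_scan_agreement(self, gaps_durs, start_excited):
        """On noise-free PSTHs with alternating polarity (the domain of the
        four-zone grammar), episode boundaries equal a brute-force scan."""
        segments = []
        t = 5
        pol = 6 if start_excited else -6
        if not start_excited:
            # a leading inhibition supports at most the EI-LE(-LI) pattern
            gaps_durs = gaps_durs[:3]
        for gap, dur in gaps_durs:
            s = t + gap
            e = s + dur - 1
            if e > 249:
                break
            segments.append((s, e, pol))
            pol = -pol
            t = e + 1
        psth = synthetic_psth(segments=segments)
        base = BaselineStats.from_psth(psth)
        detected = sorted((z for z in detect_zones(psth, base)
                           if z.detected), key=lambda z: z.L)
        # brute force: contiguous runs of bins beyond +/-1.645 SD
        z = (psth.post - base.mean) / base.sd
        runs = []
        i = 0
        while i < 250:
            if abs(z[i]) > 1.645:
                j = i
                while j + 1 < 250 and abs(z[j + 1]) > 1.645 \
                        and np.sign(z[j + 1]) == np.sign(z[i]):
                    j += 1
                if j > i:
                    runs.append((i, j, np.sign(z[i])))
                i = j + 1
            else:
                i += 1
        # merge adjacent same-polarity runs (the detector's merge rule)
        merged = []
        for run in runs:
            if merged and run[2] == merged[-1][2] == 1:
                merged[-1] = (merged[-1][0], run[1], 1)
            else:
                merged.append(list(run) if isinstance(run, tuple) else run)
        merged = merged[:4]
        assert len(detected) == len(merged)
        for zone, (s, e, _pol) in zip(detected, merged):
            assert zone.L == s
            assert zone.D == e - s + 1


class TestSignature:
    def test_area_is_sum_of_absolute_deviations(self):
        psth = synthetic_psth(segments=FOUR_ZONE_SEGMENTS)
        base = BaselineStats.from_psth(psth)
        zones = {z.label: z for z in detect_zones(psth, base)}
        # segment amplitudes are 5.0 above/below the 30.0 baseline exactly
        assert zones["EE"].A == pytest.approx(4 * 5.0)
        assert zones["EI"].A == pytest.approx(6 * 5.0)

    def test_constant_zone_has_zero_height_sd(self):
        psth = synthetic_psth(segments=[(7, 12, 5)])
        base = BaselineStats.from_psth(psth)
        zones = {z.label: z for z in detect_zones(psth, base)}
        assert zones["EE"].H_sigma == pytest.approx(0.0)

    def test_packing_order_and_missing_zones(self):
        psth = synthetic_psth(segments=[(7, 10, 5)])
        base = BaselineStats.from_psth(psth)
        zones = detect_zones(psth, base)
        sig = extract_signature(zones)
        assert sig.F.shape == (24,)
        assert sig.missing == ("EI", "LE", "LI")
        assert np.all(sig.F[6:] == 0.0)
        assert sig.F[0] == 7.0 and sig.F[1] == 4.0

    def test_peak_deviation_convention(self):
        psth = synthetic_psth(segments=FOUR_ZONE_SEGMENTS)
        base = BaselineStats.from_psth(psth)
        zones = detect_zones(psth, base)
        sig = extract_signature(zones, baseline=base,
                                peak_as_deviation=True)
        assert sig.F[5] == pytest.approx(5.0)

    def test_distance_identity_and_single_component(self):
        f = ResponseSignature(F=np.arange(24, dtype=float))
        assert signature_distance(f, f) == 0.0
        g = ResponseSignature(F=f.F.copy())
        g.F[3] += 2.5
        assert signature_distance(f, g) == pytest.approx(2.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_distance_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = ResponseSignature(F=rng.normal(size=24))
        b = ResponseSignature(F=rng.normal(size=24))
        brute = np.sqrt(sum((x - y) ** 2 for x, y in zip(a.F, b.F)))
        assert signature_distance(a, b) == pytest.approx(brute)


class TestSubsampling:
    def _poisson_rasters(self, n_neurons=60, n_trials=10, seed=2,
                         burst_rate=400.0):
        rng = np.random.default_rng(seed)
        rasters, onsets = [], []
        for _ in range(n_trials):
            times, ids = [], []
            for i in range(n_neurons):
                n = rng.poisson(30 * 1.2)
                t = np.sort(rng.random(n) * 1200.0)
                # add an evoked burst 5-15 ms after onset
                nb = rng.poisson(burst_rate * 0.010)
                tb = 805.0 + 10.0 * rng.random(nb)
                t = np.concatenate([t, tb])
                times.append(t)
                ids.append(np.full(len(t), i))
            rasters.append(SpikeRaster(
                times=np.concatenate(times),
                ids=np.concatenate(ids).astype(np.int32),
                duration=1200.0, populations={"SNr": (0, n_neurons)}))
            onsets.append(800.0)
        return rasters, onsets

    def test_full_subset_has_zero_variance(self):
        rasters, onsets = self._poisson_rasters()
        stats = subsample_features(rasters, onsets, np.arange(60),
                                   n_s=1.0, o_s=5, seed=3)
        for key, sd in stats.sd.items():
            if not np.isnan(sd):
                assert sd == pytest.approx(0.0, abs=1e-9)

    def test_smaller_subsets_have_larger_spread(self):
        rasters, onsets = self._poisson_rasters()
        s50 = subsample_features(rasters, onsets, np.arange(60),
                                 n_s=0.5, o_s=30, seed=3)
        s20 = subsample_features(rasters, onsets, np.arange(60),
                                 n_s=0.2, o_s=30, seed=3)
        key = ("EE", "H_p")
        assert not np.isnan(s50.sd.get(key, np.nan))
        assert s20.sd[key] >= s50.sd[key]

    def test_observation_mean_tracks_full_population(self):
        rasters, onsets = self._poisson_rasters()
        psth, base = compute_psth(rasters, onsets, np.arange(60))
        zones = {z.label: z for z in detect_zones(psth, base)}
        stats = subsample_features(rasters, onsets, np.arange(60),
                                   n_s=0.5, o_s=40, seed=4)
        assert stats.mean[("EE", "D")] == pytest.approx(
            zones["EE"].D, abs=2.5)
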