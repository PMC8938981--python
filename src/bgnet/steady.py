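"""Steady-state (ongoing-activity) pathology metrics: population Fano
factor, beta-band oscillation index, spectra, and pairwise Hilbert
phase-difference histograms.

Population activity is binned with 3-ms rectangular bins (sampling
frequency 333.3 Hz) for the Fano factor and the oscillation index, and
with 1-ms bins for the phase analysis. The oscillation index is the
fraction of spectral power of the mean-subtracted binned population rate
that falls in the 12-30 Hz beta band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

BIN_FF_MS = 3.0
FS_FF = 1000.0 / BIN_FF_MS      # 333.3 Hz
BETA_BAND = (12.0, 30.0)


@dataclass
class OscillationMetrics:
    """Per-population steady-state metrics for one condition."""

    fano: float
    oi: float
    freqs: Optional[np.ndarray] = None
    spectrum: Optional[np.ndarray] = None


def fano_factor(counts: np.ndarray) -> float:
    """Variance/mean of a binned population spike-count series.

    1 for pooled independent Poisson trains; grows with synchrony. A
    zero-mean series has an undefined Fano factor (returned as NaN).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two bins")
    m = counts.mean()
    if m == 0:
        return float("nan")
    return float(counts.var() / m)


def spectrum(series: np.ndarray, fs: float = FS_FF,
             nperseg: Optional[int] = None):
    """Segment-averaged periodogram of the mean-subtracted series."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    if nperseg is None:
        nperseg = min(x.size, 512)
    freqs, pxx = signal.welch(x, fs=fs, nperseg=nperseg, detrend="constant")
    return freqs, pxx


def oscillation_index(series: np.ndarray, fs: float = FS_FF,
                      band: tuple = BETA_BAND,
                      nperseg: Optional[int] = None) -> float:
    """Relative beta-band power of the binned population rate.

    Ratio of integrated power in ``band`` to the total power in
    (0, fs/2]; the DC component is excluded via mean subtraction.
    Invariant to uniform amplitude scaling.
    """
    x = np.asarray(series, dtype=float)
    if x.size * (1000.0 / fs) < 1000.0:
        raise ValueError("series must cover at least 1 s")
    if not np.any(x != x[0]):
        raise ValueError("oscillation index undefined for a constant series")
    freqs, pxx = spectrum(x, fs=fs, nperseg=nperseg)
    total = np.trapezoid(pxx[1:], freqs[1:])
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    beta = np.trapezoid(pxx[in_band], freqs[in_band])
    return float(beta / total) if total > 0 else float("nan")


def trial_metrics(count_series: Sequence[np.ndarray],
                  fs: float = FS_FF) -> OscillationMetrics:
    """Fano factor and oscillation index averaged over trials, with the
    trial-averaged spectrum."""
    ffs = [fano_factor(c) for c in count_series]
    ois = [oscillation_index(c, fs=fs) for c in count_series]
    spectra = [spectrum(c, fs=fs) for c in count_series]
    freqs = spectra[0][0]
    pxx = np.mean([p for _, p in spectra], axis=0)
    return OscillationMetrics(fano=float(np.nanmean(ffs)),
                              oi=float(np.nanmean(ois)),
                              freqs=freqs, spectrum=pxx)


def bandpass_beta(series: np.ndarray, fs: float,
                  band: tuple = BETA_BAND) -> np.ndarray:
    """Zero-phase fourth-order Butterworth bandpass of the rate series."""
    b, a = signal.butter(4, [band[0] / (fs / 2), band[1] / (fs / 2)],
                         btype="band")
    out = signal.filtfilt(b, a, np.asarray(series, float)
                          - np.mean(series))
    if not np.all(np.isfinite(out)):
        raise RuntimeError("bandpass filter unstable (non-finite output)")
    return out


def phase_relation(rate_a: np.ndarray, rate_b: np.ndarray,
                   fs: float = 1000.0, n_bins: int = 100):
    """Histogram of absolute instantaneous phase differences.

    Both series (1-ms binned population rates) are beta-bandpassed, their
    Hilbert phases differenced per sample, folded by absolute value into
    [0, pi], and binned into ``n_bins``. Returns (bin_centers, normalized
    histogram, peak_phase).
    """
    a = np.asarray(rate_a, float)
    b = np.asarray(rate_b, float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    pa = np.angle(signal.hilbert(bandpass_beta(a, fs)))
    pb = np.angle(signal.hilbert(bandpass_beta(b, fs)))
    d = np.abs(np.angle(np.exp(1j * (pa - pb))))
    hist, edges = np.histogram(d, bins=n_bins, range=(0.0, np.pi))
    hist = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = float(centers[int(np.argmax(hist))])
    return centers, hist, peak
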