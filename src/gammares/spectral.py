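"""Multitaper window power and baseline normalization.

The downstream gamma-response statistics only ever consume power averaged over
a fixed analysis window (baseline -0.9..0 s, stimulation 0.3..1.2 s), so this
module computes one DPSS multitaper power spectrum per window per trial and
vertex rather than a sliding spectrogram.  With a 0.9 s window and a 10 Hz
(full) spectral bandwidth the time-half-bandwidth product is 4.5 and 8 Slepian
tapers are used (2*NW - 1, the standard multitaper rule); the rfft grid gives
the ~1.11 Hz bin spacing.

Power is one-sided PSD (units^2/Hz): tapers are unit-energy, so integrating
the taper-averaged PSD over frequency recovers the windowed signal variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import windows

from .errors import DegenerateDataError
from .synth import EpochSet

__all__ = ["WindowPower", "VertexNormalizedSpectra", "multitaper_window_power", "normalize_response"]


@dataclass
class WindowPower:
    """Per-trial, per-vertex one-sided power spectra of one analysis window."""

    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # (trials, vertices, bins), >= 0
    window: str  # 'baseline' | 'stimulation' | custom label
    window_bounds: tuple[float, float]  # seconds relative to stimulus onset


@dataclass
class VertexNormalizedSpectra:
    """Baseline-normalized response per vertex: (stim - base)/base on
    trial-averaged power.  Values are >= -1 wherever baseline power > 0."""

    freqs: np.ndarray
    norm_power: np.ndarray  # (vertices, bins)


def n_tapers(n_samples: int, sfreq: float, bandwidth: float) -> tuple[float, int]:
    """(time-half-bandwidth NW, taper count K) for a window of ``n_samples``."""
    nw = bandwidth * n_samples / (2.0 * sfreq)
    k = max(1, int(round(2 * nw)) - 1)
    return nw, k


@lru_cache(maxsize=8)
def _dpss_cached(n: int, nw: float, k: int) -> np.ndarray:
    return windows.dpss(n, nw, Kmax=k)


def multitaper_window_power(
    epochs: EpochSet,
    window_bounds: tuple[float, float],
    bandwidth: float = 10.0,
    window: str | None = None,
) -> WindowPower:
    """DPSS multitaper power of one time window, per trial and vertex.

    Parameters
    ----------
    window_bounds
        (start, end) in seconds relative to stimulus onset; the half-open
        interval [start, end) is extracted with sample index round(t*sfreq).
    bandwidth
        Full spectral bandwidth in Hz (half-bandwidth = bandwidth/2).
    """
    t0, t1 = window_bounds
    if t1 <= t0:
        raise ValueError("window_bounds must be increasing")
    if t0 < epochs.t0 - 1e-9 or t1 > epochs.t_end + 1e-9:
        raise ValueError(f"window {window_bounds} lies outside the epoch ({epochs.t0}, {epochs.t_end})")
    if (t1 - t0) < 2.0 / bandwidth:
        raise ValueError("window too short for the requested bandwidth (need length >= 2/bandwidth)")

    sf = epochs.sfreq
    i0 = int(round((t0 - epochs.t0) * sf))
    i1 = int(round((t1 - epochs.t0) * sf))
    seg = epochs.data[:, :, i0:i1]
    n = seg.shape[-1]

    nw, k = n_tapers(n, sf, bandwidth)
    tapers = _dpss_cached(n, nw, k)  # (K, n), unit energy

    # (trials, vertices, K, n) -> one-sided PSD averaged over tapers
    x = np.fft.rfft(seg[:, :, None, :] * tapers[None, None, :, :], axis=-1)
    psd = (2.0 / sf) * (x.real**2 + x.imag**2).mean(axis=2)
    psd[..., 0] /= 2.0
    if n % 2 == 0:
        psd[..., -1] /= 2.0

    freqs = np.fft.rfftfreq(n, 1.0 / sf)
    if window is None:
        window = "baseline" if t1 <= 0 else "stimulation"
    return WindowPower(freqs=freqs, power=psd, window=window, window_bounds=(t0, t1))


def normalize_response(base: WindowPower, stim: WindowPower) -> VertexNormalizedSpectra:
    """Baseline-normalized response spectrum per vertex and frequency bin:
    (mean-over-trials stimulation - mean-over-trials baseline) / baseline.

    Raw-amplitude gain cancels exactly; swapping the two windows maps a
    normalized value x to 1/(1+x) - 1.
    """
    if base.power.shape != stim.power.shape:
        raise ValueError("baseline and stimulation power shapes differ")
    if base.freqs.shape != stim.freqs.shape or not np.allclose(base.freqs, stim.freqs):
        raise ValueError("frequency grids differ between windows")
    mb = base.power.mean(axis=0)
    ms = stim.power.mean(axis=0)
    if np.any(mb <= 0):
        raise DegenerateDataError("non-positive trial-averaged baseline power")
    return VertexNormalizedSpectra(freqs=base.freqs.copy(), norm_power=(ms - mb) / mb)
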