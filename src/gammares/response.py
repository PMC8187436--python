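"""Per-condition gamma-response extraction.

Reduces vertex-wise normalized spectra to one GammaResponse per condition:

1. select the k = 26 vertices with maximal band-mean (40-80 Hz) normalized
   power;
2. average the selected vertices' normalized spectra over the gamma range
   (30-115 Hz) and smooth with a centered 3-bin moving average (edges use the
   shrinking window);
3. locate the peak in 35-90 Hz and compute weighted GR power (mean of bins
   strictly above 2/3 of the peak) and weighted GR frequency (power-weighted
   center of gravity of those bins);
4. gate reliability with a paired Wilcoxon signed-rank test on single-trial
   baseline vs stimulation power at the peak bin (p < 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, NoResponseError
from .spectral import VertexNormalizedSpectra, WindowPower

__all__ = [
    "NormalizedSpectrum",
    "GammaResponse",
    "select_max_vertices",
    "average_and_smooth",
    "weighted_gr",
    "reliability_test",
    "analyze_condition",
    "subject_gate",
]

VERTEX_BAND = (40.0, 80.0)
PEAK_BAND = (35.0, 90.0)
GAMMA_RANGE = (30.0, 115.0)
N_SELECT = 26
SMOOTH_WINDOW = 3
RELIABILITY_ALPHA = 1e-4
PEAK_FRACTION = 2.0 / 3.0


@dataclass
class NormalizedSpectrum:
    """Vertex-averaged, smoothed normalized response spectrum."""

    freqs: np.ndarray
    norm_power: np.ndarray  # (bins,)
    selected_vertices: np.ndarray


@dataclass
class GammaResponse:
    """Weighted gamma-response summary for one condition/visit.

    A condition with no positive spectral peak (no detectable response) is
    represented with NaN metrics and ``reliable = False``.
    """

    condition: str
    velocity: float
    weighted_power: float
    weighted_freq: float
    peak_freq: float
    peak_power: float
    reliability_p: float
    reliable: bool
    visit: int = 0

    @property
    def usable(self) -> bool:
        return np.isfinite(self.weighted_power)

    @classmethod
    def no_response(cls, condition: str, velocity: float, visit: int = 0) -> "GammaResponse":
        nan = float("nan")
        return cls(condition, velocity, nan, nan, nan, nan, nan, False, visit)


def select_max_vertices(
    spectra: VertexNormalizedSpectra,
    band: tuple[float, float] = VERTEX_BAND,
    k: int = N_SELECT,
) -> np.ndarray:
    """Indices of the k vertices with largest mean normalized power over bins
    whose center frequency lies in ``band`` (inclusive).  If fewer than k
    vertices exist, all are returned.  Ties break by ascending vertex index;
    the result is sorted ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    lo, hi = band
    mask = (spectra.freqs >= lo) & (spectra.freqs <= hi)
    if not mask.any():
        raise ValueError(f"no frequency bins in band {band}")
    scores = spectra.norm_power[:, mask].mean(axis=1)
    order = np.argsort(-scores, kind="stable")  # stable: ties by ascending index
    return np.sort(order[: min(k, scores.size)])


def moving_average(x: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average; edge bins average over the available
    (shrinking) window, so constants are preserved everywhere."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def average_and_smooth(
    spectra: VertexNormalizedSpectra,
    selected: Sequence[int],
    window: int = SMOOTH_WINDOW,
    gamma_range: tuple[float, float] = GAMMA_RANGE,
) -> NormalizedSpectrum:
    """Unweighted mean over the selected vertices within ``gamma_range``,
    then a centered moving average of width ``window``."""
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("selected vertex list is empty")
    lo, hi = gamma_range
    mask = (spectra.freqs >= lo) & (spectra.freqs <= hi)
    mean = spectra.norm_power[selected][:, mask].mean(axis=0)
    return NormalizedSpectrum(
        freqs=spectra.freqs[mask].copy(),
        norm_power=moving_average(mean, window),
        selected_vertices=selected,
    )


def weighted_gr(
    spectrum: NormalizedSpectrum,
    band: tuple[float, float] = PEAK_BAND,
    fraction: float = PEAK_FRACTION,
) -> tuple[float, float, float, float]:
    """Weighted GR metrics in ``band``.

    Returns (weighted_power, weighted_freq, peak_freq, peak_power) where the
    weighted power is the mean of bins strictly exceeding ``fraction`` of the
    in-band peak and the weighted frequency is the power-weighted center of
    gravity over those bins.
    """
    lo, hi = band
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if not mask.any():
        raise ValueError(f"no frequency bins in band {band}")
    f = spectrum.freqs[mask]
    p = spectrum.norm_power[mask]
    ipk = int(np.argmax(p))
    peak_power = float(p[ipk])
    if peak_power <= 0:
        raise NoResponseError("no positive peak in the analysis band")
    sel = p > fraction * peak_power
    ps, fs = p[sel], f[sel]
    weighted_power = float(ps.mean())
    weighted_freq = float((fs * ps).sum() / ps.sum())
    return weighted_power, weighted_freq, float(f[ipk]), peak_power


def reliability_test(
    trial_base_power: np.ndarray,
    trial_stim_power: np.ndarray,
    alpha: float = RELIABILITY_ALPHA,
) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired single-trial power
    differences (stimulation - baseline) at the peak frequency bin.

    Exact null distribution up to n = 50 (no zeros/ties), normal approximation
    with continuity correction above; zero differences are dropped.
    """
    b = np.asarray(trial_base_power, dtype=float)
    s = np.asarray(trial_stim_power, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError("paired per-trial vectors of equal length required")
    if b.size < 6:
        raise ValueError("need at least 6 paired trials")
    d = s - b
    if np.all(d == 0):
        raise DegenerateDataError("all paired differences are zero")
    res = stats.wilcoxon(s, b, zero_method="wilcox", correction=True, method="auto")
    p = float(res.pvalue)
    return p, bool(p < alpha)


def trial_power_at(freqs: np.ndarray, power: np.ndarray, selected: np.ndarray, freq: float) -> np.ndarray:
    """Per-trial power at the bin nearest ``freq``, averaged over the selected
    vertices (the single-trial series fed to the reliability test)."""
    ibin = int(np.argmin(np.abs(freqs - freq)))
    return power[:, selected, ibin].mean(axis=1)


def analyze_condition(
    base: WindowPower,
    stim: WindowPower,
    condition: str = "",
    velocity: float = 0.0,
    visit: int = 0,
    vertex_band: tuple[float, float] = VERTEX_BAND,
    n_select: int = N_SELECT,
    gamma_range: tuple[float, float] = GAMMA_RANGE,
    peak_band: tuple[float, float] = PEAK_BAND,
    smooth_window: int = SMOOTH_WINDOW,
    alpha: float = RELIABILITY_ALPHA,
) -> GammaResponse:
    """Full per-condition reduction from window power to a GammaResponse."""
    from .spectral import normalize_response

    vns = normalize_response(base, stim)
    selected = select_max_vertices(vns, band=vertex_band, k=n_select)
    spectrum = average_and_smooth(vns, selected, window=smooth_window, gamma_range=gamma_range)
    wp, wf, pf, pp = weighted_gr(spectrum, band=peak_band)
    p, reliable = reliability_test(
        trial_power_at(base.freqs, base.power, selected, pf),
        trial_power_at(stim.freqs, stim.power, selected, pf),
        alpha=alpha,
    )
    return GammaResponse(
        condition=condition,
        velocity=velocity,
        weighted_power=wp,
        weighted_freq=wf,
        peak_freq=pf,
        peak_power=pp,
        reliability_p=p,
        reliable=reliable,
        visit=visit,
    )


def subject_gate(responses_by_visit: Mapping[int, Mapping[str, GammaResponse]]) -> bool:
    """Inclusion rule: in every visit, the condition with maximal weighted GR
    power must have a reliable response.  The maximal condition is determined
    per visit and may differ between visits."""
    if not responses_by_visit:
        raise ValueError("no visits provided")
    visits = list(responses_by_visit.values())
    conditions = set(visits[0])
    for v in visits[1:]:
        if set(v) != conditions:
            raise ValueError("visits cover different condition sets")
    for v in visits:
        usable = [r for r in v.values() if r.usable]
        if not usable:
            return False
        best = max(usable, key=lambda r: r.weighted_power)
        if not best.reliable:
            return False
    return True
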