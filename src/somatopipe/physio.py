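"""Physiological nuisance regressors from cardiac and respiratory traces.

Cardiac phase is linear between successive pulse peaks; respiratory phase
uses the amplitude-histogram-equalised transfer of the bellows waveform
with the sign of its derivative (the RETROICOR conventions). Harmonic
regressors are Fourier series of these phases, with multiplicative
cardiac-respiratory interaction terms and optional slow regressors (heart
rate, respiration volume per time, heart-rate variability).

Two named configurations reproduce common tool defaults:

* ``PNM_CONFIG`` — 4th-order cardiac and respiratory harmonics, 2nd-order
  interactions, heart rate and RVT: 34 columns.
* ``PHYSIO_CONFIG`` — 3rd-order cardiac, 4th-order respiratory, 1st-order
  interactions, RVT and HRV: 20 columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RetroicorConfig:
    cardiac_order: int = 4
    resp_order: int = 4
    interaction_order: int = 2
    extras: tuple[str, ...] = ("heart_rate", "rvt")

    VALID_EXTRAS = ("heart_rate", "rvt", "hrv")

    def __post_init__(self):
        for name, v in (("cardiac_order", self.cardiac_order),
                        ("resp_order", self.resp_order),
                        ("interaction_order", self.interaction_order)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        for e in self.extras:
            if e not in self.VALID_EXTRAS:
                raise ValueError(f"unknown extra regressor {e!r}")

    @property
    def n_columns(self) -> int:
        """2c + 2r + 4i^2 + |extras| (all interaction pairs m,n <= i)."""
        return (2 * self.cardiac_order + 2 * self.resp_order
                + 4 * self.interaction_order ** 2 + len(self.extras))


PNM_CONFIG = RetroicorConfig(4, 4, 2, ("heart_rate", "rvt"))
PHYSIO_CONFIG = RetroicorConfig(3, 4, 1, ("rvt", "hrv"))


@dataclass
class PhaseSeries:
    """Per-volume cardiac and respiratory phases, each in [0, 2*pi)."""

    volume_times_s: np.ndarray
    cardiac: np.ndarray
    respiratory: np.ndarray

    def __post_init__(self):
        n = len(self.volume_times_s)
        if len(self.cardiac) != n or len(self.respiratory) != n:
            raise ValueError("phase series lengths must match volume times")


@dataclass
class NuisanceMatrix:
    """Time x regressor matrix of physiological confounds."""

    matrix: np.ndarray
    labels: list[str]
    config: RetroicorConfig

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("label list must match column count")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("nuisance matrix contains non-finite values")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.labels)


def cardiac_phase(peaks, t_query) -> np.ndarray:
    """Cardiac phase at query times: 2*pi*(t - t_k)/(t_{k+1} - t_k) for the
    bracketing peaks. Times outside the peak span are extrapolated with the
    nearest inter-peak interval and flagged with a warning."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.ndim != 1 or len(peaks) < 2:
        raise ValueError("need at least two cardiac peaks")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("cardiac peak times must be strictly increasing")
    t = np.atleast_1d(np.asarray(t_query, dtype=float))
    k = np.searchsorted(peaks, t, side="right") - 1
    outside = (t < peaks[0]) | (t >= peaks[-1])
    if np.any(outside):
        warnings.warn("query times outside cardiac peak span; extrapolating",
                      stacklevel=2)
    k = np.clip(k, 0, len(peaks) - 2)
    phase = 2 * np.pi * (t - peaks[k]) / (peaks[k + 1] - peaks[k])
    phase = np.mod(phase, 2 * np.pi)
    if np.isscalar(t_query) or np.ndim(t_query) == 0:
        return float(phase[0])
    return phase


def respiratory_phase(waveform, sampling_rate_hz: float, t_query) -> np.ndarray:
    """Respiratory phase via histogram equalisation of the waveform amplitude.

    phi = pi * H(b(t)) / H_max on the inspiration (rising) side and
    2*pi - pi * H(b(t)) / H_max on expiration, where H is the cumulative
    amplitude histogram of the whole waveform.
    """
    b = np.asarray(waveform, dtype=float)
    if sampling_rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    if b.ndim != 1 or len(b) < 2:
        raise ValueError("waveform must be a 1-D series")
    if np.ptp(b) == 0:
        raise ValueError("constant respiratory waveform: phase undefined")
    t = np.atleast_1d(np.asarray(t_query, dtype=float))
    times = np.arange(len(b)) / sampling_rate_hz
    bt = np.interp(t, times, b)
    slope = np.interp(t, times, np.gradient(b, 1.0 / sampling_rate_hz))
    # empirical CDF of the amplitude distribution (exact cumulative histogram)
    order = np.sort(b)
    cdf = np.searchsorted(order, bt, side="right") / len(order)
    phase = np.where(slope >= 0, np.pi * cdf, 2 * np.pi - np.pi * cdf)
    phase = np.mod(phase, 2 * np.pi)
    if np.isscalar(t_query) or np.ndim(t_query) == 0:
        return float(phase[0])
    return phase


def phase_series(trace, volume_times_s) -> PhaseSeries:
    """Evaluate cardiac and respiratory phases at volume mid-acquisition times.

    ``trace`` is any object with ``cardiac_peak_times_s``,
    ``respiratory_waveform`` and ``sampling_rate_hz`` attributes
    (:class:`somatopipe.synthetic_data.PhysioTrace`).
    """
    t = np.asarray(volume_times_s, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        card = cardiac_phase(trace.cardiac_peak_times_s, t)
    resp = respiratory_phase(trace.respiratory_waveform,
                             trace.sampling_rate_hz, t)
    return PhaseSeries(volume_times_s=t, cardiac=np.asarray(card),
                       respiratory=np.asarray(resp))


def _heart_rate_series(peaks: np.ndarray, t: np.ndarray,
                       smooth_beats: int = 6) -> np.ndarray:
    ibi = np.diff(peaks)
    mid = (peaks[:-1] + peaks[1:]) / 2.0
    hr = 1.0 / ibi
    if len(hr) >= smooth_beats:
        kernel = np.ones(smooth_beats) / smooth_beats
        hr = np.convolve(hr, kernel, mode="same")
    return np.interp(t, mid, hr)


def _hrv_series(peaks: np.ndarray, t: np.ndarray, window: int = 6) -> np.ndarray:
    """Centred moving standard deviation of inter-beat intervals."""
    ibi = np.diff(peaks)
    mid = (peaks[:-1] + peaks[1:]) / 2.0
    half = window // 2
    sd = np.empty_like(ibi)
    for i in range(len(ibi)):
        lo, hi = max(0, i - half), min(len(ibi), i + half + 1)
        sd[i] = np.std(ibi[lo:hi])
    return np.interp(t, mid, sd)


def _rvt_series(waveform: np.ndarray, sampling_rate_hz: float,
                t: np.ndarray) -> np.ndarray:
    """Respiration volume per time: breath peak-to-trough amplitude over
    breath period, interpolated to volume times."""
    from scipy.signal import find_peaks

    b = np.asarray(waveform, dtype=float)
    times = np.arange(len(b)) / sampling_rate_hz
    # breaths are at most ~1.2 Hz; enforce a minimal peak distance
    min_dist = max(1, int(0.5 * sampling_rate_hz))
    peaks, _ = find_peaks(b, distance=min_dist)
    troughs, _ = find_peaks(-b, distance=min_dist)
    if len(peaks) < 2 or len(troughs) < 1:
        return np.zeros_like(t)
    rvt_t, rvt_v = [], []
    for i in range(len(peaks) - 1):
        p0, p1 = peaks[i], peaks[i + 1]
        between = troughs[(troughs > p0) & (troughs < p1)]
        if len(between) == 0:
            continue
        trough = between[0]
        period = times[p1] - times[p0]
        amp = b[p0] - b[trough]
        rvt_t.append((times[p0] + times[p1]) / 2.0)
        rvt_v.append(amp / period)
    if not rvt_v:
        return np.zeros_like(t)
    return np.interp(t, np.asarray(rvt_t), np.asarray(rvt_v))


def retroicor_regressors(
    phases: PhaseSeries,
    config: RetroicorConfig = PNM_CONFIG,
    trace=None,
) -> NuisanceMatrix:
    """Fourier-series nuisance matrix from physiological phases.

    Columns: sin/cos(k * cardiac phase) for k = 1..c; sin/cos(k * resp
    phase) for k = 1..r; for every interaction pair (m, n) with m, n <= i,
    sin/cos of (m*cardiac + n*resp) and (m*cardiac - n*resp); one column
    per requested extra. Total 2c + 2r + 4i^2 + |extras|.

    ``trace`` (a PhysioTrace) is required when extras are requested.
    """
    pc, pr = phases.cardiac, phases.respiratory
    t = phases.volume_times_s
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for k in range(1, config.cardiac_order + 1):
        cols += [np.sin(k * pc), np.cos(k * pc)]
        labels += [f"cardiac_sin{k}", f"cardiac_cos{k}"]
    for k in range(1, config.resp_order + 1):
        cols += [np.sin(k * pr), np.cos(k * pr)]
        labels += [f"resp_sin{k}", f"resp_cos{k}"]
    for m in range(1, config.interaction_order + 1):
        for n in range(1, config.interaction_order + 1):
            plus, minus = m * pc + n * pr, m * pc - n * pr
            cols += [np.sin(plus), np.cos(plus), np.sin(minus), np.cos(minus)]
            labels += [f"interact_sin_c{m}+r{n}", f"interact_cos_c{m}+r{n}",
                       f"interact_sin_c{m}-r{n}", f"interact_cos_c{m}-r{n}"]
    if config.extras:
        if trace is None:
            raise ValueError("extras requested but no physio trace given")
        peaks = np.asarray(trace.cardiac_peak_times_s, dtype=float)
        for extra in config.extras:
            if extra == "heart_rate":
                cols.append(_heart_rate_series(peaks, t))
            elif extra == "rvt":
                cols.append(_rvt_series(trace.respiratory_waveform,
                                        trace.sampling_rate_hz, t))
            elif extra == "hrv":
                cols.append(_hrv_series(peaks, t))
            labels.append(extra)
    matrix = (np.column_stack(cols) if cols
              else np.empty((len(t), 0)))
    return NuisanceMatrix(matrix=matrix, labels=labels, config=config)


def read_physio_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column time/value TSV; returns (times, values)."""
    df = pd.read_csv(path, sep="\t")
    cols = df.columns
    return df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float)
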