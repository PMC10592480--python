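"""Moving-window correlation maps, windowed SD, spectra and map distances.

The central object is the time-indexed stack of ROI×ROI Pearson correlation
matrices computed over 10-s moving windows (200 samples at 20 Hz). Hemodynamic
windows are linearly detrended per ROI before correlation; window centers index
each map in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from scipy import signal

from corticostate.preprocess import RoiMatrix


@dataclass
class CorrelationMapSeries:
    """Time-indexed stack of windowed Pearson matrices.

    ``maps[i]`` is the correlation matrix of the window starting at frame
    ``starts[i]``; ``centers[i] = starts[i] + window_frames // 2``.
    """

    maps: np.ndarray  # (n_windows, n_rois, n_rois)
    starts: np.ndarray
    window_s: float
    frame_rate: float
    signal_kind: str = "neural_dff"

    @property
    def window_frames(self) -> int:
        return int(round(self.window_s * self.frame_rate))

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.window_frames // 2

    def map_at_start(self, start: int) -> np.ndarray:
        idx = np.flatnonzero(self.starts == start)
        if len(idx) == 0:
            raise KeyError(f"no window starting at frame {start}")
        return self.maps[idx[0]]

    def save_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("maps", data=self.maps)
            f.create_dataset("starts", data=self.starts)
            f.attrs["window_s"] = self.window_s
            f.attrs["frame_rate"] = self.frame_rate
            f.attrs["signal_kind"] = self.signal_kind


def _window_correlation(seg: np.ndarray, detrend: bool) -> np.ndarray:
    if detrend:
        seg = signal.detrend(seg, axis=1, type="linear")
    else:
        seg = seg - seg.mean(axis=1, keepdims=True)
    sd = seg.std(axis=1)
    dead = sd < 1e-14
    sd = np.where(dead, 1.0, sd)
    z = seg / sd[:, None]
    c = z @ z.T / seg.shape[1]
    if dead.any():
        c[dead, :] = 0.0
        c[:, dead] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def windowed_correlation(
    roi: RoiMatrix,
    window_s: float = 10.0,
    step_frames: int = 1,
    detrend: bool = False,
    starts: np.ndarray | None = None,
) -> CorrelationMapSeries:
    """Pearson correlation matrix per moving window.

    ``detrend=True`` removes a first-degree polynomial per ROI per window
    (used for hemodynamic signals). ``starts`` overrides the regular grid with
    explicit window start frames. Zero-variance ROIs within a window get zeroed
    rows/columns (diagonal kept at 1) with a warning.
    """
    w = int(round(window_s * roi.frame_rate))
    if w > roi.n_frames:
        raise ValueError("window longer than recording")
    if w < 3:
        raise ValueError("window must contain >= 3 samples")
    if starts is None:
        starts = np.arange(0, roi.n_frames - w + 1, step_frames)
    else:
        starts = np.asarray(starts, dtype=int)
        if np.any(starts < 0) or np.any(starts + w > roi.n_frames):
            raise ValueError("explicit window start out of range")
    x = roi.values
    n_dead = 0
    maps = np.empty((len(starts), roi.n_rois, roi.n_rois))
    for i, s in enumerate(starts):
        seg = x[:, s : s + w]
        if np.any(seg.std(axis=1) < 1e-14):
            n_dead += 1
        maps[i] = _window_correlation(seg, detrend)
    if n_dead:
        warnings.warn(f"{n_dead} window(s) contained zero-variance ROIs", stacklevel=2)
    return CorrelationMapSeries(maps=maps, starts=starts, window_s=window_s,
                                frame_rate=roi.frame_rate, signal_kind=roi.signal_kind)


def long_epoch_correlation(roi: RoiMatrix, detrend: bool = False) -> np.ndarray:
    """Single Pearson map over the whole epoch."""
    if roi.n_frames < 3:
        raise ValueError("epoch too short")
    return _window_correlation(roi.values, detrend)


def windowed_sd(roi: RoiMatrix, window_s: float = 2.0, causal: bool = True) -> np.ndarray:
    """Temporal SD of each ROI over a trailing (causal) moving window.

    Output is ROI × time; frames with an incomplete window are NaN. With
    ``causal=False`` the window is centered instead.
    """
    w = int(round(window_s * roi.frame_rate))
    if w < 2:
        raise ValueError("window must contain >= 2 samples")
    x = roi.values
    out = np.full_like(x, np.nan, dtype=float)
    sw = np.lib.stride_tricks.sliding_window_view(x, w, axis=1)
    sds = sw.std(axis=2)
    if causal:
        out[:, w - 1 :] = sds
    else:
        out[:, w // 2 : w // 2 + sds.shape[1]] = sds
    return out


def band_power(
    roi: RoiMatrix,
    method: str = "welch_psd",
    nperseg_s: float = 4.0,
    overlap: float = 0.5,
    bands: list[tuple[float, float]] | None = None,
) -> dict:
    """One-sided PSD (Welch) or spectrogram of ROI traces, plus band averages.

    Welch defaults: 4-s Hann segments, 50% overlap. Returns frequencies,
    power (ROI × freq, or ROI × freq × time for the spectrogram), and mean
    power within each requested band.
    """
    fs = roi.frame_rate
    nperseg = int(round(nperseg_s * fs))
    if roi.n_frames < nperseg:
        raise ValueError("segment too short for the requested spectral resolution")
    noverlap = int(nperseg * overlap)
    if method == "welch_psd":
        freqs, psd = signal.welch(roi.values, fs=fs, nperseg=nperseg,
                                  noverlap=noverlap, axis=1)
        power = psd
    elif method == "spectrogram":
        freqs, times, power = signal.spectrogram(roi.values, fs=fs, nperseg=nperseg,
                                                 noverlap=noverlap, axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    out = {"freqs": freqs, "power": power}
    if method == "spectrogram":
        out["times"] = times
    if bands:
        band_means = {}
        for lo, hi in bands:
            sel = (freqs >= lo) & (freqs <= hi)
            if not sel.any():
                raise ValueError(f"band ({lo}, {hi}) Hz contains no frequency bins")
            band_means[(lo, hi)] = power[:, sel].mean(axis=1)
        out["band_means"] = band_means
    return out


def fft_bandpass(x: np.ndarray, band: tuple[float, float], frame_rate: float) -> np.ndarray:
    """Ideal FFT-domain band-pass along the last axis (input made zero-mean)."""
    lo, hi = band
    nyq = frame_rate / 2.0
    if not (0 <= lo < hi <= nyq):
        raise ValueError(f"band {band} must satisfy 0 <= lo < hi <= Nyquist ({nyq} Hz)")
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=-1, keepdims=True)
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    spec = np.fft.rfft(x, axis=-1)
    keep = (freqs >= lo) & (freqs <= hi)
    if not keep.any():
        raise ValueError(f"band {band} contains no FFT bins at n={n}")
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def band_filtered_maps(
    roi: RoiMatrix, bands: list[tuple[float, float]], window_starts: np.ndarray | None = None,
    window_s: float = 10.0,
) -> dict[tuple[float, float], np.ndarray]:
    """Mean correlation map per frequency band.

    Each ROI trace is zero-meaned, ideally band-passed in the FFT domain, and
    correlated over the stated window set (default: the full epoch as one
    window). Returns band -> mean map.
    """
    out = {}
    for band in bands:
        filt = fft_bandpass(roi.values, band, roi.frame_rate)
        rb = RoiMatrix(values=filt, roi_ids=roi.roi_ids, frame_rate=roi.frame_rate,
                       signal_kind=roi.signal_kind)
        if window_starts is None:
            out[band] = long_epoch_correlation(rb)
        else:
            series = windowed_correlation(rb, window_s=window_s, starts=window_starts)
            out[band] = series.maps.mean(axis=0)
    return out


def merge_series(a: CorrelationMapSeries, b: CorrelationMapSeries) -> CorrelationMapSeries:
    """Union of two map series on the same signal; duplicate starts keep a's map."""
    if a.window_s != b.window_s or a.frame_rate != b.frame_rate:
        raise ValueError("series must share window length and frame rate")
    starts = np.concatenate([a.starts, b.starts])
    maps = np.concatenate([a.maps, b.maps])
    order = np.argsort(starts, kind="stable")
    starts, maps = starts[order], maps[order]
    keep = np.concatenate([[True], np.diff(starts) > 0])
    return CorrelationMapSeries(maps=maps[keep], starts=starts[keep], window_s=a.window_s,
                                frame_rate=a.frame_rate, signal_kind=a.signal_kind)


def upper_triangle(map_: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle (diagonal excluded)."""
    iu = np.triu_indices(map_.shape[-1], k=1)
    return np.asarray(map_)[..., iu[0], iu[1]]


def map_distance(map_a: np.ndarray, map_b: np.ndarray, metric: str = "euclidean") -> float:
    """Distance between two correlation maps over the strict upper triangle.

    ``euclidean``: Frobenius norm of the difference restricted to the upper
    triangle; ``correlation``: Pearson r between the vectorized triangles.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share shape")
    a, b = upper_triangle(map_a), upper_triangle(map_b)
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    if metric == "correlation":
        return float(np.corrcoef(a, b)[0, 1])
    raise ValueError(f"unknown metric {metric!r}")
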