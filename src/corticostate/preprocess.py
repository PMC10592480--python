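"""Temporal filtering, PCA denoising, global-pulsation removal, ROI extraction.

Filtering convention throughout the pipeline: zero-phase (forward-backward)
Chebyshev type-I filters, order 20, 0.2 dB passband ripple, applied as
second-order sections for numerical stability. Neural traces are low-passed at
6.5 Hz (heart-rate suppression); hemodynamic traces at 0.25 Hz (breathing
vascular artifacts live around 1-4 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from corticostate.parcellation import ParcellationMap


@dataclass
class FilterSpec:
    """Chebyshev-I zero-phase filter description.

    ``edges`` are cutoff frequencies in Hz: one for low/highpass, two for
    bandpass. Edges must lie strictly inside (0, frame_rate/2).
    """

    kind: str  # lowpass | highpass | bandpass
    edges: tuple[float, ...]
    order: int = 20
    passband_ripple: float = 0.2  # dB
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        n_edges = 2 if self.kind == "bandpass" else 1
        if len(self.edges) != n_edges:
            raise ValueError(f"{self.kind} needs {n_edges} edge(s)")

    def design(self, frame_rate: float) -> np.ndarray:
        nyq = frame_rate / 2.0
        if any(e <= 0 or e >= nyq for e in self.edges):
            raise ValueError(f"filter edges {self.edges} must lie strictly inside (0, {nyq}) Hz")
        wn = self.edges if self.kind == "bandpass" else self.edges[0]
        return signal.cheby1(
            self.order, self.passband_ripple, wn, btype=self.kind,
            output="sos", fs=frame_rate,
        )


@dataclass
class RoiMatrix:
    """ROI × time signal matrix in the parcellation's paired row order."""

    values: np.ndarray
    roi_ids: np.ndarray
    frame_rate: float
    signal_kind: str = "neural_dff"  # neural_dff | hbt | hbo | hbr

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.roi_ids):
            raise ValueError("row count must match roi_ids")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=pd.Index(self.roi_ids, name="roi_id"))
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, frame_rate: float, signal_kind: str = "neural_dff") -> "RoiMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            roi_ids=df.index.to_numpy(dtype=int),
            frame_rate=frame_rate,
            signal_kind=signal_kind,
        )


def zero_phase_filter(series: np.ndarray, spec: FilterSpec, frame_rate: float) -> np.ndarray:
    """Forward-backward application of the designed filter along the last axis.

    Zero net phase shift; the effective magnitude response is the squared
    single-pass response. Low-pass filtering operates on mean-removed data with
    the mean restored, so constants pass through exactly (an even-order
    Chebyshev-I otherwise sits ``ripple`` dB below unity at DC).
    """
    x = np.asarray(series, dtype=float)
    sos = spec.design(frame_rate)
    padlen = 3 * (2 * sos.shape[0])
    if x.shape[-1] <= max(3 * spec.order, padlen):
        raise ValueError(
            f"series length {x.shape[-1]} too short for order-{spec.order} zero-phase filter"
        )
    mean = x.mean(axis=-1, keepdims=True)
    out = signal.sosfiltfilt(sos, x - mean, axis=-1)
    if spec.kind == "lowpass":
        out = out + mean
    return out


def remove_global_pulsation(
    stack: np.ndarray, cutoff_hz: float, frame_rate: float, order: int = 4
) -> np.ndarray:
    """Divide out the high-frequency global (spatially uniform) component.

    Heart-rate pulsation is near-uniform across the field of view and
    multiplicative in raw intensities. Each frame is divided by
    ``1 + highpass(global_mean)/mean(global_mean)``; spatially structured
    low-frequency signal is untouched.
    """
    x = np.asarray(stack, dtype=float)
    if not np.all(x > 0):
        raise ValueError("stack must be strictly positive")
    g = x.mean(axis=0)
    g_mean = g.mean()
    if g_mean <= 0:
        raise ValueError("nonpositive global mean")
    # modest-order Butterworth here: the target is broadband pulsation removal,
    # not a sharp analysis band
    sos = signal.butter(order, cutoff_hz, btype="highpass", output="sos", fs=frame_rate)
    g_hp = signal.sosfiltfilt(sos, g / g_mean - 1.0)
    return x / (1.0 + g_hp)[None, :]


def pca_denoise(stack: np.ndarray, n_components: int) -> np.ndarray:
    """Rank-``n_components`` reconstruction of the mean-centered pixel×time
    matrix by truncated SVD, temporal mean restored.

    Idempotent at fixed ``n_components``; with ``n_components`` >= rank this is
    the identity.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x = np.asarray(stack, dtype=float)
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    mean = x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x - mean, full_matrices=False)
    k = n_components
    return (u[:, :k] * s[:k]) @ vt[:k] + mean


def extract_roi_timecourses(
    stack: np.ndarray,
    parcellation: ParcellationMap,
    frame_rate: float,
    signal_kind: str = "neural_dff",
) -> RoiMatrix:
    """Unweighted per-ROI pixel means per frame, rows in paired ROI order."""
    x = np.asarray(stack, dtype=float)
    labels = parcellation.labels.ravel()
    if labels.shape[0] != x.shape[0]:
        raise ValueError("label image does not match stack pixel count")
    roi_ids = parcellation.roi_order()
    rows = np.empty((len(roi_ids), x.shape[1]))
    for i, roi in enumerate(roi_ids):
        members = labels == roi
        if not members.any():
            raise ValueError(f"ROI {roi} has no member pixels")
        rows[i] = x[members].mean(axis=0)
    return RoiMatrix(values=rows, roi_ids=np.asarray(roi_ids), frame_rate=frame_rate,
                     signal_kind=signal_kind)


def apply_lag(
    series: np.ndarray, lag_s: float, frame_rate: float
) -> tuple[np.ndarray, tuple[int, int]]:
    """Shift a series by ``lag_s`` (integer frames, shift-and-trim).

    Positive lag delays the series: output frame t holds input frame
    ``t - round(lag_s * frame_rate)``. Returns the trimmed overlap and the
    half-open frame range of the *original* timebase it corresponds to, so
    callers can trim companion series identically.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    exact = lag_s * frame_rate
    k = int(round(exact))
    if abs(exact - k) > 0.5:  # unreachable by construction; guards float oddities
        raise ValueError("lag rounding exceeded half a frame")
    if abs(exact - k) > 1e-9:
        warnings.warn(
            f"lag {lag_s}s is {exact:.3f} frames at {frame_rate} Hz; rounding to {k}",
            stacklevel=2,
        )
    if abs(k) >= n:
        raise ValueError("lag magnitude exceeds series duration")
    if k >= 0:
        return x[..., : n - k], (k, n)
    return x[..., -k:], (0, n + k)
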