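"""Behavioral scalar traces from keypoints and wheel-encoder counts.

The analyses index mouse behavior by three per-frame scalars: pupil diameter
(circle fit to eight circumferential keypoints), whisking speed (mean
frame-to-frame keypoint displacement over nine whisker points), and wheel
velocity (differentiated rotary-encoder counts). Keypoint tracking itself is
upstream; this module consumes keypoint tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BehaviorTrace:
    """Per-frame behavioral scalars aligned to the imaging clock.

    wheel_velocity : arbitrary distance units / s
    pupil_diameter : pixels (NaN where the circle fit failed)
    whisk_speed    : pixels / frame (NaN at the first frame), always >= 0
    """

    wheel_velocity: np.ndarray
    pupil_diameter: np.ndarray
    whisk_speed: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        n = len(self.wheel_velocity)
        if len(self.pupil_diameter) != n or len(self.whisk_speed) != n:
            raise ValueError("behavior traces must share length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.wheel_velocity)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "wheel_velocity": self.wheel_velocity,
                "pupil_diameter": self.pupil_diameter,
                "whisk_speed": self.whisk_speed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kåsa) least-squares circle fit.

    Solves the normal equations of ``x^2 + y^2 + D x + E y + F = 0`` — exact
    for points on a circle, closed-form otherwise. Returns (cx, cy, radius).
    Raises ``ValueError`` for < 3 points or (near-)collinear configurations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    # collinearity check via the rank of the design matrix
    if np.linalg.matrix_rank(A - A.mean(axis=0), tol=1e-9 * max(1.0, np.abs(A).max())) < 2:
        raise ValueError("points are collinear; circle fit is degenerate")
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = coef[0] / 2.0, coef[1] / 2.0
    r2 = coef[2] + cx**2 + cy**2
    if r2 <= 0:
        raise ValueError("degenerate circle fit (nonpositive radius)")
    return float(cx), float(cy), float(np.sqrt(r2))


def pupil_diameter(points8: np.ndarray) -> np.ndarray:
    """Pupil diameter per frame from circumferential keypoints.

    Parameters
    ----------
    points8 : (n_frames, n_points, 2) array
        Keypoint coordinates per frame; NaN entries mark missing/sub-confidence
        points. Frames with < 3 valid points, or collinear points, are masked.

    Returns
    -------
    (n_frames,) array of diameters (2 * fitted radius); NaN where masked.
    """
    pts = np.asarray(points8, dtype=float)
    if pts.ndim != 3 or pts.shape[2] != 2:
        raise ValueError("points8 must have shape (frames, points, 2)")
    out = np.full(pts.shape[0], np.nan)
    n_masked = 0
    for t in range(pts.shape[0]):
        frame = pts[t]
        valid = frame[~np.isnan(frame).any(axis=1)]
        try:
            _, _, r = fit_circle(valid)
        except ValueError:
            n_masked += 1
            continue
        out[t] = 2.0 * r
    if n_masked:
        warnings.warn(f"pupil circle fit masked {n_masked} frame(s)", stacklevel=2)
    return out


def whisk_speed(points9: np.ndarray) -> np.ndarray:
    """Whisking speed: mean per-point Euclidean displacement between frames.

    The first frame has no predecessor and is NaN. Output is >= 0 wherever
    defined.
    """
    pts = np.asarray(points9, dtype=float)
    if pts.ndim != 3 or pts.shape[2] != 2:
        raise ValueError("points9 must have shape (frames, points, 2)")
    if pts.shape[0] < 2:
        raise ValueError("need >= 2 frames")
    disp = np.linalg.norm(np.diff(pts, axis=0), axis=2)  # (frames-1, points)
    out = np.full(pts.shape[0], np.nan)
    out[1:] = np.nanmean(disp, axis=1)
    return out


def wheel_velocity(
    encoder_counts: np.ndarray,
    counts_per_unit: float,
    frame_rate: float,
    modulus: int | None = None,
) -> np.ndarray:
    """Wheel velocity from rotary-encoder counts.

    First difference of (optionally unwrapped) counts, scaled by the encoder
    calibration and frame rate. ``modulus`` is the counter rollover period; when
    given, jumps larger than half the modulus are treated as wraparound so
    velocity is continuous across the wrap. First frame repeats the second
    difference so the trace length matches the imaging frame count.
    """
    counts = np.asarray(encoder_counts, dtype=float)
    if counts_per_unit <= 0 or frame_rate <= 0:
        raise ValueError("counts_per_unit and frame_rate must be positive")
    d = np.diff(counts)
    if modulus is not None:
        d = np.mod(d + modulus / 2.0, modulus) - modulus / 2.0
    vel = d / counts_per_unit * frame_rate
    if len(vel) == 0:
        return np.zeros_like(counts)
    return np.concatenate([[vel[0]], vel])


def read_keypoints_csv(path, n_points: int, likelihood_threshold: float = 0.9) -> np.ndarray:
    """Read a keypoint table (frame, point_id, x, y[, likelihood]) to an array.

    Returns (n_frames, n_points, 2); sub-threshold-likelihood points are NaN.
    """
    df = pd.read_csv(path)
    required = {"frame", "point_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"keypoint table must have columns {sorted(required)}")
    n_frames = int(df["frame"].max()) + 1
    out = np.full((n_frames, n_points, 2), np.nan)
    xy = df[["x", "y"]].to_numpy(dtype=float)
    if "likelihood" in df.columns:
        xy[df["likelihood"].to_numpy(dtype=float) < likelihood_threshold] = np.nan
    out[df["frame"].to_numpy(int), df["point_id"].to_numpy(int)] = xy
    return out
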