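"""Raw session container: triple-channel image stacks + synchronized behavior.

A WFOM acquisition interleaves three LEDs at 60 Hz, giving 20 frames/s per
channel: lime-excited red fluorescence (neural), and green / red reflectance
(hemodynamic). Stacks are stored pixel-major as ``(n_pixels, n_frames)`` with a
``(rows, cols)`` image shape for reshaping back to maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from corticostate.behavior import BehaviorTrace


@dataclass
class RawSession:
    """Raw optical intensities with behavior, the unit of pipeline input.

    ``baseline_window`` is a ``(start, stop)`` frame range (half-open) marking a
    resting segment suitable for baseline normalization.
    """

    fluor_raw: np.ndarray  # (pixels, frames) I_em
    green_raw: np.ndarray  # (pixels, frames) I_R at the green wavelength
    red_raw: np.ndarray  # (pixels, frames) I_R at the red wavelength
    frame_rate: float
    behavior: BehaviorTrace
    image_shape: tuple[int, int]
    baseline_window: tuple[int, int] = field(default=(0, 100))

    def __post_init__(self) -> None:
        shapes = {self.fluor_raw.shape, self.green_raw.shape, self.red_raw.shape}
        if len(shapes) != 1:
            raise ValueError("channel stacks must share shape")
        if self.fluor_raw.shape[0] != self.image_shape[0] * self.image_shape[1]:
            raise ValueError("pixel count inconsistent with image_shape")
        if self.behavior.n_frames != self.fluor_raw.shape[1]:
            raise ValueError("behavior length must match frame count")
        for name in ("fluor_raw", "green_raw", "red_raw"):
            arr = getattr(self, name)
            if not np.all(arr > 0):
                raise ValueError(f"{name} must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.fluor_raw.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.fluor_raw.shape[0]

    def save_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("fluor_raw", data=self.fluor_raw)
            f.create_dataset("green_raw", data=self.green_raw)
            f.create_dataset("red_raw", data=self.red_raw)
            beh = f.create_group("behavior")
            beh.create_dataset("wheel_velocity", data=self.behavior.wheel_velocity)
            beh.create_dataset("pupil_diameter", data=self.behavior.pupil_diameter)
            beh.create_dataset("whisk_speed", data=self.behavior.whisk_speed)
            f.attrs["frame_rate"] = self.frame_rate
            f.attrs["image_shape"] = self.image_shape
            f.attrs["baseline_window"] = self.baseline_window

    @classmethod
    def load_hdf5(cls, path) -> "RawSession":
        with h5py.File(path, "r") as f:
            frame_rate = float(f.attrs["frame_rate"])
            behavior = BehaviorTrace(
                wheel_velocity=f["behavior/wheel_velocity"][:],
                pupil_diameter=f["behavior/pupil_diameter"][:],
                whisk_speed=f["behavior/whisk_speed"][:],
                frame_rate=frame_rate,
            )
            return cls(
                fluor_raw=f["fluor_raw"][:],
                green_raw=f["green_raw"][:],
                red_raw=f["red_raw"][:],
                frame_rate=frame_rate,
                behavior=behavior,
                image_shape=tuple(int(v) for v in f.attrs["image_shape"]),
                baseline_window=tuple(int(v) for v in f.attrs["baseline_window"]),
            )
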