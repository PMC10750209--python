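"""Thermal-camera emulator.

Projects a simulated temperature volume along the camera's line of sight
(maximum-intensity, since the camera sees the hottest surface it faces),
resamples to the camera pixel pitch and quantizes to the sensor's
temperature resolution.  Optics and emissivity are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .thermal import TemperatureField

__all__ = ["CameraFrame", "camera_view"]

DEFAULT_PITCH_MM = 0.308
QUANTIZATION_K = 0.02


@dataclass
class CameraFrame:
    values: np.ndarray  # degC, quantized
    pixel_pitch: float  # mm
    timestamp: float  # s

    @property
    def max_temperature(self) -> float:
        return float(self.values.max())

    def hotspot_mm(self, fov: tuple) -> np.ndarray:
        """Position (mm) of the hottest pixel in the frame plane, FOV-centered."""
        iy, iz = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return np.array([(iy + 0.5) * self.pixel_pitch - fov[0] / 2.0,
                         (iz + 0.5) * self.pixel_pitch - fov[1] / 2.0])


def camera_view(tfield: TemperatureField, axis: int = 0,
                pixel_pitch: float = DEFAULT_PITCH_MM,
                quantization: float = QUANTIZATION_K,
                timestamp: float | None = None) -> CameraFrame:
    """Project a temperature volume into a quantized 2D camera frame.

    ``axis`` is the line of sight (default X, the bore axis).  Nearest
    resampling preserves the frame maximum to within one quantization step.
    """
    proj = np.max(tfield.values, axis=axis)
    axes = [i for i in range(3) if i != axis]
    vs = tfield.grid.voxel_size
    zoom = (vs[axes[0]] / pixel_pitch, vs[axes[1]] / pixel_pitch)
    frame = ndimage.zoom(proj, zoom, order=0, mode="nearest")
    frame = np.round(frame / quantization) * quantization
    return CameraFrame(values=frame, pixel_pitch=pixel_pitch,
                       timestamp=tfield.time if timestamp is None else timestamp)
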