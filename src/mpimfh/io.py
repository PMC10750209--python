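"""Volume and table output helpers (NIfTI volumes, CSV spectra/traces)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .imaging import ImagingGrid, Spectrum

__all__ = ["write_volume", "read_volume", "write_spectrum_csv", "write_trace_csv"]


def write_volume(path, values: np.ndarray, grid: ImagingGrid) -> None:
    """Write a volume as NIfTI with mm voxel spacing from the grid."""
    affine = np.diag([*grid.voxel_size, 1.0])
    affine[:3, 3] = np.asarray(grid.origin) - np.asarray(grid.fov) / 2.0 + grid.voxel_size / 2.0
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_spectrum_csv(path, spectrum: Spectrum) -> None:
    pd.DataFrame({
        "frequency_Hz": spectrum.frequency_axis,
        "real": spectrum.values.real,
        "imag": spectrum.values.imag,
        "magnitude": np.abs(spectrum.values),
    }).to_csv(Path(path), index=False)


def write_trace_csv(path, times_s, temperatures_c, label: str = "temperature_C") -> None:
    pd.DataFrame({"time_s": times_s, label: temperatures_c}).to_csv(Path(path), index=False)
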