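"""Synthetic phantoms and their file I/O.

Three families mirror the platform's bench experiments: a 3x3 grid of glass
sample vials in the Y-Z plane, a thin agarose dish facing the camera, and a
circulation tubing loop crossing the bore.  Phantoms carry per-voxel tracer
concentration and a medium label map from which thermal property volumes are
derived.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .catalog import get_particle
from .imaging import ImagingGrid
from .particles import ParticleSpec
from .thermal import FlowSpec, VolumetricProps

__all__ = [
    "MEDIA",
    "Phantom",
    "make_grid_phantom",
    "make_agarose_dish",
    "make_flow_loop",
    "resample_to_grid",
]

#: media properties: (density g/mL, heat capacity J/gK, conductivity W/mK);
#: air is handled as convection-dominated ambient, not a conducting medium
MEDIA = {
    "air": None,
    "water": (1.0, 4.168, 0.6),
    "glass": (2.23, 0.84, 1.0),
    "agarose": (1.0, 4.168, 0.55),
    "silicone": (1.1, 1.2, 0.2),
}
LABELS = list(MEDIA)


@dataclass
class Phantom:
    """Voxelized object: tracer concentration (mg(Fe)/mL) + medium labels."""

    concentration: np.ndarray
    labels: np.ndarray  # uint8 index into LABELS
    grid: ImagingGrid
    particle: str
    metadata: dict = field(default_factory=dict)
    boundary_coefficient: float = 10.0  # W/(m^2 K)
    ambient: float = 23.0  # degC

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.concentration.shape != tuple(self.grid.shape):
            raise ValueError("concentration array does not match the grid")
        if self.labels.shape != self.concentration.shape:
            raise ValueError("label array does not match the grid")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any(self.labels >= len(LABELS)):
            raise ValueError("unknown medium label")
        # normalize to JSON-native types so file round-trips are identity
        self.metadata = json.loads(json.dumps(self.metadata))

    def particle_spec(self) -> ParticleSpec:
        return get_particle(self.particle)

    def thermal_volumes(self) -> VolumetricProps:
        shape = self.concentration.shape
        rho_c = np.zeros(shape)
        k = np.zeros(shape)
        medium = np.zeros(shape, dtype=bool)
        for idx, name in enumerate(LABELS):
            sel = self.labels == idx
            props = MEDIA[name]
            if props is None:
                continue
            rho, c, cond = props
            rho_c[sel] = rho * 1e3 * c * 1e3
            k[sel] = cond
            medium[sel] = True
        return VolumetricProps(rho_c=rho_c, conductivity=k, medium=medium,
                               boundary_coefficient=self.boundary_coefficient,
                               ambient=self.ambient)

    def total_iron_mass_mg(self) -> float:
        """Total tracer iron in mg: sum of c * voxel volume."""
        return float(self.concentration.sum() * np.prod(self.grid.voxel_size) * 1e-3)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("concentration", data=self.concentration)
            f.create_dataset("labels", data=self.labels)
            f.attrs["fov"] = self.grid.fov
            f.attrs["matrix"] = self.grid.matrix
            f.attrs["origin"] = self.grid.origin
            f.attrs["particle"] = self.particle
            f.attrs["boundary_coefficient"] = self.boundary_coefficient
            f.attrs["ambient"] = self.ambient
            f.attrs["metadata"] = json.dumps(self.metadata)

    @classmethod
    def load(cls, path) -> "Phantom":
        with h5py.File(path, "r") as f:
            grid = ImagingGrid(tuple(f.attrs["fov"]), tuple(int(m) for m in f.attrs["matrix"]),
                               tuple(f.attrs["origin"]))
            return cls(concentration=f["concentration"][()], labels=f["labels"][()],
                       grid=grid, particle=str(f.attrs["particle"]),
                       metadata=json.loads(f.attrs["metadata"]),
                       boundary_coefficient=float(f.attrs["boundary_coefficient"]),
                       ambient=float(f.attrs["ambient"]))


# ---------------------------------------------------------------------------
# generators

#: vial-grid fill order: central row first (the interleaved-session layout),
#: then the upper and lower rows
_VIAL_ORDER = [(-8, 0), (0, 0), (8, 0),
               (-8, 8), (0, 8), (8, 8),
               (-8, -8), (0, -8), (8, -8)]  # (y, z) mm


def make_grid_phantom(n_filled: int = 9, particle: str = "synomag-S-90",
                      concentration: float = 10.0, volume_ul: float = 140.0,
                      grid: ImagingGrid | None = None,
                      boundary_coefficient: float = 200.0,
                      ambient: float = 23.0) -> Phantom:
    """3x3 vial grid in the Y-Z plane (spacing 8 mm center to center).

    Vials are thin-walled glass tubes lying along X, filled with
    ``volume_ul`` of suspension; unfilled voxels inside the holder are air.
    The default boundary coefficient is an effective surface-loss value that
    lumps the forced bore airflow and holder conduction.
    """
    if not 0 <= n_filled <= 9:
        raise ValueError("n_filled must be between 0 and 9")
    if grid is None:
        grid = ImagingGrid((32.0, 32.0, 20.0), (32, 32, 20))
    conc = np.zeros(grid.shape)
    labels = np.zeros(grid.shape, dtype=np.uint8)  # air
    centers = grid.centers().reshape(grid.shape + (3,))
    radius = 2.6  # mm, inner bore of the 6 mm glass tube
    length = volume_ul / (np.pi * radius**2)  # mm of fill along X
    vial_centers = []
    for (y0, z0) in _VIAL_ORDER[:n_filled]:
        inside = (((centers[..., 1] - y0) ** 2 + (centers[..., 2] - z0) ** 2 <= radius**2)
                  & (np.abs(centers[..., 0]) <= length / 2.0))
        conc[inside] = concentration
        labels[inside] = LABELS.index("water")
        vial_centers.append((0.0, float(y0), float(z0)))
    return Phantom(concentration=conc, labels=labels, grid=grid, particle=particle,
                   metadata={"kind": "vial_grid", "vial_centers": vial_centers,
                             "fill_volume_ul": volume_ul},
                   boundary_coefficient=boundary_coefficient, ambient=ambient)


def make_agarose_dish(particle: str = "synomag-D-70", concentration: float = 1.0,
                      grid: ImagingGrid | None = None,
                      boundary_coefficient: float = 10.0,
                      ambient: float = 23.0) -> Phantom:
    """50 mm culture dish with a ~5 mm agarose-SPION layer facing the camera
    (the disc spans the Y-Z plane, its axis along X)."""
    if grid is None:
        grid = ImagingGrid((8.0, 56.0, 56.0), (8, 56, 56))
    centers = grid.centers().reshape(grid.shape + (3,))
    disc = ((centers[..., 1] ** 2 + centers[..., 2] ** 2 <= 25.0**2)
            & (centers[..., 0] >= -2.5) & (centers[..., 0] < 2.5))
    conc = np.where(disc, float(concentration), 0.0)
    labels = np.where(disc, LABELS.index("agarose"), 0).astype(np.uint8)
    return Phantom(concentration=conc, labels=labels, grid=grid, particle=particle,
                   metadata={"kind": "agarose_dish", "diameter_mm": 50.0,
                             "thickness_mm": 5.0},
                   boundary_coefficient=boundary_coefficient, ambient=ambient)


def make_flow_loop(flow: FlowSpec, particle: str = "synomag-D-70",
                   concentration: float = 1.0,
                   grid: ImagingGrid | None = None,
                   envelope_support_mm: float = 32.0,
                   boundary_coefficient: float = 30.0,
                   ambient: float = 23.0) -> Phantom:
    """In-bore tubing segment of the circulation loop, running along Y.

    Only the straight in-bore segment is voxelized (the return path lies
    outside the field of view); the full loop is handled by the 1D solver.
    """
    if grid is None:
        grid = ImagingGrid((8.0, 40.0, 8.0), (8, 40, 8))
    centers = grid.centers().reshape(grid.shape + (3,))
    vs = grid.voxel_size
    tube = (np.abs(centers[..., 0]) <= vs[0] / 2.0) & (np.abs(centers[..., 2]) <= vs[2] / 2.0)
    conc = np.where(tube, float(concentration), 0.0)
    labels = np.where(tube, LABELS.index("water"), 0).astype(np.uint8)
    heated = min(float(grid.fov[1]), envelope_support_mm)
    return Phantom(concentration=conc, labels=labels, grid=grid, particle=particle,
                   metadata={"kind": "flow_loop", "flow": {
                       "tube_inner_diameter": flow.tube_inner_diameter,
                       "loop_length": flow.loop_length,
                       "velocity": flow.velocity,
                       "volumetric_rate": flow.volumetric_rate},
                       "heated_segment_mm": heated,
                       "consistency_note": flow.consistency_note},
                   boundary_coefficient=boundary_coefficient, ambient=ambient)


# ---------------------------------------------------------------------------
# resampling


def resample_to_grid(values: np.ndarray, src_grid: ImagingGrid, dst_grid: ImagingGrid,
                     weights: np.ndarray | None = None) -> np.ndarray:
    """Mean-pool a field from a fine source grid onto a coarser target grid.

    Each destination voxel averages the source voxels whose centers fall
    inside it (``weights`` makes it a weighted average, e.g. temperature
    weighted by concentration).  Source voxels outside the target FOV are
    ignored.
    """
    src_centers = src_grid.centers()
    rel = (src_centers - np.asarray(dst_grid.origin)
           + np.asarray(dst_grid.fov) / 2.0) / dst_grid.voxel_size
    idx = np.floor(rel).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(dst_grid.matrix)), axis=1)
    flat = np.ravel_multi_index(tuple(idx[ok].T), dst_grid.shape)
    v = np.asarray(values, dtype=float).ravel()[ok]
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float).ravel()[ok]
    acc = np.zeros(dst_grid.n_voxels)
    norm = np.zeros(dst_grid.n_voxels)
    np.add.at(acc, flat, v * w)
    np.add.at(norm, flat, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, acc / norm, 0.0)
    return out.reshape(dst_grid.shape)
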