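"""Heat deposition, diffusion and flow.

Deposition is confined by the selection field: outside the FFR the particles
sit on the saturated part of their magnetization curve and barely respond to
the AMF, which is modelled by the normalized differential susceptibility of
the tracer at the local static offset field.  The temperature field evolves
by explicit conservative finite differences (forward-time, central-space)
with Robin surface losses; "air" voxels are convection-dominated and held at
ambient.  A dedicated 1D solver handles the circulation-loop phantom, where
plug-flow advection competes with deposition inside the AMF envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB
from .fields import (AMFSpec, FocusSpec, ScannerSpec, amf_envelope,
                     selection_field)
from .particles import ParticleSpec, _moment_weights, heating_power, langevin_deriv

__all__ = [
    "ThermalProps",
    "VolumetricProps",
    "TemperatureField",
    "FlowSpec",
    "suppression_factor",
    "heat_deposition_field",
    "step_heat",
    "run_heating",
    "max_stable_dt",
    "heating_psf",
    "calibrate_psf_threshold",
    "simulate_flow_heating",
]


@dataclass(frozen=True)
class ThermalProps:
    """Homogeneous medium properties (water-like defaults)."""

    density: float = 1.0  # g/mL
    heat_capacity: float = 4.168  # J/(g K)
    conductivity: float = 0.6  # W/(m K)
    boundary_coefficient: float = 10.0  # W/(m^2 K)
    ambient: float = 23.0  # degC

    def __post_init__(self):
        if min(self.density, self.heat_capacity, self.conductivity) <= 0:
            raise ValueError("thermal properties must be positive")
        if self.boundary_coefficient < 0:
            raise ValueError("boundary coefficient must be nonnegative")

    @property
    def rho_c(self) -> float:
        """Volumetric heat capacity, J/(m^3 K)."""
        return self.density * 1e3 * self.heat_capacity * 1e3


@dataclass
class VolumetricProps:
    """Per-voxel thermal properties on a grid.

    ``medium`` is False on air voxels, which are pinned at ambient and couple
    to their neighbours through the boundary coefficient only.
    """

    rho_c: np.ndarray  # J/(m^3 K)
    conductivity: np.ndarray  # W/(m K)
    medium: np.ndarray  # bool
    boundary_coefficient: float = 10.0
    ambient: float = 23.0

    @classmethod
    def uniform(cls, shape, props: ThermalProps) -> "VolumetricProps":
        return cls(rho_c=np.full(shape, props.rho_c),
                   conductivity=np.full(shape, props.conductivity),
                   medium=np.ones(shape, dtype=bool),
                   boundary_coefficient=props.boundary_coefficient,
                   ambient=props.ambient)


@dataclass
class TemperatureField:
    values: np.ndarray  # degC
    grid: object  # ImagingGrid
    time: float = 0.0

    @classmethod
    def uniform(cls, grid, temperature: float) -> "TemperatureField":
        return cls(values=np.full(grid.shape, float(temperature)), grid=grid, time=0.0)


@dataclass(frozen=True)
class FlowSpec:
    """Circulation loop: geometry and plug-flow velocity.

    When both a velocity and a volumetric rate are given they are checked
    against the stated inner diameter; the velocity is authoritative and any
    mismatch is surfaced in ``consistency_note`` (the characterised loop's
    rate<->velocity pairs imply a larger effective bore than the nominal
    inner diameter).
    """

    tube_inner_diameter: float = 0.2  # mm
    loop_length: float = 375.0  # cm
    velocity: float = 0.0  # cm/s
    volumetric_rate: float | None = None  # mL/min

    def __post_init__(self):
        if self.velocity < 0:
            raise ValueError("flow velocity must be nonnegative")

    @property
    def consistency_note(self) -> str | None:
        if self.volumetric_rate is None:
            return None
        area_mm2 = np.pi * (self.tube_inner_diameter / 2.0) ** 2
        v_implied = self.volumetric_rate * 1000.0 / 60.0 / area_mm2 / 10.0  # cm/s
        if self.velocity == 0 and self.volumetric_rate == 0:
            return None
        if self.velocity == 0 or abs(v_implied - self.velocity) > 0.1 * max(self.velocity, 1e-9):
            return (f"rate {self.volumetric_rate} mL/min implies {v_implied:.3g} cm/s "
                    f"for an inner diameter of {self.tube_inner_diameter} mm, but the "
                    f"stated velocity is {self.velocity} cm/s; using the velocity")
        return None


# ---------------------------------------------------------------------------
# deposition


def suppression_factor(offset_field_mT, p: ParticleSpec, temperature: float = 296.15):
    """Normalized differential susceptibility at a static bias field.

    1 at zero offset, strictly decreasing in |offset|; this is the fraction
    of the AMF heating that survives at a given selection-field offset.
    """
    b = np.abs(np.asarray(offset_field_mT, dtype=float)) * 1e-3  # T
    _, moments, n = _moment_weights(p, temperature)
    xi = np.multiply.outer(b, moments) / (KB * temperature)
    w = n * moments**2  # initial-susceptibility weights per node
    s = np.sum(3.0 * langevin_deriv(xi) * w, axis=-1) / np.sum(w)
    return s if np.ndim(offset_field_mT) else float(s)


def heat_deposition_field(phantom, scanner: ScannerSpec, ffr_target,
                          particle: ParticleSpec | None = None,
                          amf: AMFSpec | None = None) -> np.ndarray:
    """Volumetric AMF power map q(r) (W/m^3) on the phantom grid.

    q = P_vol(concentration) * S(|selection+focus field|) * envelope(r)^2.
    With the selection field disabled (global mode) the suppression factor is
    1 everywhere and q follows the envelope alone.  ``ffr_target`` (mm) is
    realized by the focus fields; limits are enforced.
    """
    amf = scanner.amf if amf is None else amf
    if amf.amplitude <= 0:
        raise ValueError("AMF amplitude must be positive for heat deposition")
    particle = phantom.particle_spec() if particle is None else particle
    centers = phantom.grid.centers()
    conc = np.asarray(phantom.concentration, dtype=float).ravel()
    env = amf_envelope(centers, amf)
    p_unit = heating_power(particle, amf.amplitude, amf.frequency, 1.0)
    if scanner.gradient.enabled:
        target = np.asarray(ffr_target, dtype=float)
        focus = FocusSpec(*(-target * scanner.gradient.diagonal))
        offset = selection_field(centers, scanner.gradient) + focus.vector
        s = suppression_factor(np.sqrt(np.sum(offset**2, axis=1)), particle)
    else:
        s = np.ones(centers.shape[0])
    q = p_unit * conc * s * env**2
    return q.reshape(phantom.grid.shape)


# ---------------------------------------------------------------------------
# explicit diffusion solver


def _face_conductance(props: VolumetricProps, voxel_mm: np.ndarray):
    """Per-axis arrays of (lower-face) conductance G = k_face/dx^2, W/(m^3 K),
    plus per-voxel Robin coupling for medium-air and domain-edge faces."""
    k = np.where(props.medium, props.conductivity, 0.0)
    dx_m = voxel_mm * 1e-3
    face = []
    robin = np.zeros_like(k)
    h = props.boundary_coefficient
    for ax in range(3):
        k_lo = np.concatenate([np.zeros_like(np.take(k, [0], axis=ax)),
                               np.take(k, range(k.shape[ax] - 1), axis=ax)], axis=ax)
        with np.errstate(divide="ignore", invalid="ignore"):
            hm = np.where((k > 0) & (k_lo > 0), 2.0 * k * k_lo / (k + k_lo), 0.0)
        face.append(hm / dx_m[ax] ** 2)
        # Robin faces: medium voxel with non-medium (or out-of-domain) neighbour
        med = props.medium
        lo_nb = np.concatenate([np.zeros_like(np.take(med, [0], axis=ax)),
                                np.take(med, range(med.shape[ax] - 1), axis=ax)], axis=ax)
        hi_nb = np.concatenate([np.take(med, range(1, med.shape[ax]), axis=ax),
                                np.zeros_like(np.take(med, [0], axis=ax))], axis=ax)
        robin += np.where(med & ~lo_nb.astype(bool), h / dx_m[ax], 0.0)
        robin += np.where(med & ~hi_nb.astype(bool), h / dx_m[ax], 0.0)
    return face, robin


def max_stable_dt(props: VolumetricProps, grid, flow: FlowSpec | None = None) -> float:
    """Largest admissible explicit time step for the given medium and grid."""
    face, robin = _face_conductance(props, grid.voxel_size)
    coeff = robin.copy()
    for ax, g in enumerate(face):
        coeff += g  # lower face
        g_hi = np.concatenate([np.take(g, range(1, g.shape[ax]), axis=ax),
                               np.zeros_like(np.take(g, [0], axis=ax))], axis=ax)
        coeff += g_hi
    rate = np.divide(coeff, props.rho_c, out=np.zeros_like(coeff), where=props.medium)
    if flow is not None and flow.velocity > 0:
        rate += np.where(props.medium, flow.velocity * 1e-2 / (grid.voxel_size[1] * 1e-3), 0.0)
    peak = float(rate.max())
    return np.inf if peak == 0 else 1.0 / peak


def step_heat(tfield: TemperatureField, q: np.ndarray, dt: float,
              props: VolumetricProps | ThermalProps,
              flow: FlowSpec | None = None) -> TemperatureField:
    """One forward-Euler step of rho c dT/dt = div(k grad T) + q - advection.

    Conservative in the insulated, unheated limit; raises when ``dt``
    violates the explicit stability bound (the message names the bound).
    Advection (when a flow is given) is upwind plug flow along the Y axis of
    the grid, with ambient-temperature fluid entering at the upstream face.
    """
    grid = tfield.grid
    if isinstance(props, ThermalProps):
        props = VolumetricProps.uniform(tfield.values.shape, props)
    dt_max = max_stable_dt(props, grid, flow)
    if dt > dt_max * (1 + 1e-9):
        raise ValueError(f"time step {dt:g} s violates the stability bound; "
                         f"maximal admissible dt = {dt_max:g} s")
    t = tfield.values
    med = props.medium
    face, robin = _face_conductance(props, grid.voxel_size)
    flux = np.zeros_like(t)
    for ax, g in enumerate(face):
        t_lo = np.concatenate([np.take(t, [0], axis=ax),
                               np.take(t, range(t.shape[ax] - 1), axis=ax)], axis=ax)
        contrib = g * (t_lo - t)
        flux += contrib
        # equal and opposite on the lower neighbour
        back = np.concatenate([np.take(contrib, range(1, t.shape[ax]), axis=ax),
                               np.zeros_like(np.take(t, [0], axis=ax))], axis=ax)
        flux -= back
    flux += robin * (props.ambient - t)
    dtdt = np.divide(flux + np.asarray(q), props.rho_c,
                     out=np.zeros_like(flux), where=med)
    if flow is not None and flow.velocity > 0:
        v = flow.velocity * 1e-2  # m/s, along +Y
        dy = grid.voxel_size[1] * 1e-3
        t_up = np.concatenate([np.full_like(t[:, :1, :], props.ambient), t[:, :-1, :]], axis=1)
        t_up = np.where(np.concatenate([np.zeros_like(med[:, :1, :], dtype=bool),
                                        med[:, :-1, :]], axis=1), t_up, props.ambient)
        dtdt -= np.where(med, v * (t - t_up) / dy, 0.0)
    new = np.where(med, t + dt * dtdt, props.ambient)
    return TemperatureField(values=new, grid=grid, time=tfield.time + dt)


def run_heating(tfield: TemperatureField, q: np.ndarray, duration: float,
                props: VolumetricProps | ThermalProps,
                flow: FlowSpec | None = None, safety: float = 0.4) -> TemperatureField:
    """Advance the field by ``duration`` using the auto-chosen stable step."""
    if isinstance(props, ThermalProps):
        props = VolumetricProps.uniform(tfield.values.shape, props)
    dt = safety * max_stable_dt(props, tfield.grid, flow)
    if not np.isfinite(dt):
        dt = duration
    n = max(1, int(np.ceil(duration / dt)))
    dt = duration / n
    for _ in range(n):
        tfield = step_heat(tfield, q, dt, props, flow)
    return tfield


# ---------------------------------------------------------------------------
# heating point-spread function


#: calibration vial used for point-spread scans: 27 uL suspension in a thin tube
PSF_SAMPLE_VOLUME_M3 = 27e-9
PSF_SAMPLE_AREA_M2 = 6.0e-5
PSF_SAMPLE_RHO_C = 4.168e6
PSF_BOUNDARY_H = 50.0
PSF_DWELL_S = 30.0


def _psf_delta_t(offset_mm: np.ndarray, axis: int, scanner: ScannerSpec,
                 particle: ParticleSpec, concentration: float,
                 include_envelope: bool) -> np.ndarray:
    """Temperature rise of a lumped point vial at offsets along one axis."""
    pos = np.zeros((offset_mm.size, 3))
    pos[:, axis] = offset_mm
    p_unit = heating_power(particle, scanner.amf.amplitude, scanner.amf.frequency, 1.0)
    if scanner.gradient.enabled:
        offset_field = np.abs(offset_mm * scanner.gradient.diagonal[axis])
        s = suppression_factor(offset_field, particle)
    else:
        s = np.ones_like(offset_mm)
    env = amf_envelope(pos, scanner.amf) if include_envelope else np.ones(pos.shape[0])
    q = p_unit * concentration * s * env**2
    tau = PSF_SAMPLE_RHO_C * PSF_SAMPLE_VOLUME_M3 / (PSF_BOUNDARY_H * PSF_SAMPLE_AREA_M2)
    return q / PSF_SAMPLE_RHO_C * tau * (1.0 - np.exp(-PSF_DWELL_S / tau))


def _psf_offsets(axis: int, max_mm: float = 12.0) -> np.ndarray:
    step = 0.5 if axis == 2 else 1.0
    return np.arange(0.0, max_mm + 1e-9, step)


def calibrate_psf_threshold(scanner: ScannerSpec, particle: ParticleSpec,
                            axis: int = 0, half_extent: float = 5.0,
                            concentration: float = 10.0,
                            include_envelope: bool = True) -> float:
    """Temperature-rise threshold that puts the half-extent along ``axis`` at
    ``half_extent`` mm (the rise measured exactly at that offset)."""
    dt = _psf_delta_t(np.array([half_extent]), axis, scanner, particle,
                      concentration, include_envelope)
    return float(dt[0])


def heating_psf(scanner: ScannerSpec, particle: ParticleSpec, threshold: float,
                concentration: float = 10.0, include_envelope: bool = True) -> np.ndarray:
    """Per-axis half-extent (mm) of the localized-heating point-spread function.

    A point calibration vial is stepped outward from the FFR along each axis
    (1 mm steps in X/Y, 0.5 mm in Z) and heated for a fixed dwell; the
    half-extent is the largest offset whose steady temperature rise still
    reaches ``threshold`` K.
    """
    if not scanner.gradient.enabled:
        raise ValueError("heating PSF requires the selection field to be enabled")
    extents = []
    for axis in range(3):
        offs = _psf_offsets(axis)
        dts = _psf_delta_t(offs, axis, scanner, particle, concentration, include_envelope)
        above = offs[dts >= threshold * (1 - 1e-12)]
        extents.append(float(above.max()) if above.size else 0.0)
    return np.array(extents)


# ---------------------------------------------------------------------------
# circulation loop


def simulate_flow_heating(flow: FlowSpec, particle: ParticleSpec,
                          concentration: float, scanner: ScannerSpec,
                          timing=((21.0, 1.0),) * 4, dx_mm: float = 2.0,
                          base_temperature: float = 23.0,
                          wall_coefficient: float = 30.0):
    """Interleaved MFH/MPI heating of the circulation loop.

    1D advection-diffusion around the closed loop (periodic), with AMF
    deposition only on the in-bore segment weighted by the envelope along the
    tube (Y) axis.  ``timing`` lists (mfh_duration, mpi_duration) per cycle;
    deposition acts during the MFH windows only.  Returns (max temperature
    rise K, final temperature profile degC, loop coordinate mm).
    """
    length_mm = flow.loop_length * 10.0
    n = int(round(length_mm / dx_mm))
    s = (np.arange(n) + 0.5) * dx_mm - length_mm / 2.0  # tube coordinate, mm
    pos = np.zeros((n, 3))
    pos[:, 1] = s  # in-bore segment along Y through the isocenter
    env = amf_envelope(pos, scanner.amf)
    p_unit = heating_power(particle, scanner.amf.amplitude, scanner.amf.frequency, 1.0)
    if scanner.gradient.enabled:
        offset = np.sqrt(np.sum(selection_field(pos, scanner.gradient) ** 2, axis=1))
        supp = suppression_factor(offset, particle)
    else:
        supp = np.ones(n)
    q = p_unit * concentration * supp * env**2  # W/m^3

    rho_c = 4.168e6
    alpha = 0.6 / rho_c
    d_m = flow.tube_inner_diameter * 1e-3
    loss = wall_coefficient * 4.0 / d_m / rho_c  # 1/s
    v = flow.velocity * 1e-2  # m/s
    dx = dx_mm * 1e-3
    dt_bound = 1.0 / (2.0 * alpha / dx**2 + (v / dx if v > 0 else 0.0) + loss)
    dt = 0.4 * dt_bound

    t = np.full(n, float(base_temperature))
    tmax = 0.0
    for mfh_s, mpi_s in timing:
        for seg_duration, heating in ((mfh_s, True), (mpi_s, False)):
            steps = max(1, int(np.ceil(seg_duration / dt)))
            h = seg_duration / steps
            for _ in range(steps):
                lap = (np.roll(t, 1) - 2 * t + np.roll(t, -1)) / dx**2
                adv = v * (t - np.roll(t, 1)) / dx if v > 0 else 0.0
                src = q / rho_c if heating else 0.0
                t = t + h * (alpha * lap - adv - loss * (t - base_temperature) + src)
            tmax = max(tmax, float(t.max()))
    return tmax - base_temperature, t, s
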