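"""Analytic models of the scanner's magnetic fields.

The virtual instrument is a preclinical MPI scanner with a concentric
hyperthermia insert.  Four field subsystems are modelled:

* a static selection gradient whose zero defines the field-free region (FFR),
* quasi-static homogeneous focus fields that translate the FFR,
* three orthogonal ~25 kHz drive fields sweeping the FFR over a closed 3D
  Lissajous trajectory,
* the 715 kHz hyperthermia AMF along the bore (X) axis with a separable
  flat-top envelope describing its useful field of therapy.

Coordinates are right-handed with X the bore/AMF axis and Z the high-gradient
axis, origin at the isocenter; positions in mm, fields in mT, gradients in
T/m (= mT/mm).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GradientSpec",
    "FocusSpec",
    "DriveSpec",
    "AMFSpec",
    "ScannerSpec",
    "selection_field",
    "ffr_position",
    "drive_trajectory",
    "drive_fov_extent",
    "amf_envelope",
    "amf_field",
]

# instrument limits (hardware of the virtual scanner)
GRADIENT_LIMIT_XY = 1.25  # T/m
GRADIENT_LIMIT_Z = 2.5  # T/m
FOCUS_LIMITS = (17.0, 17.0, 42.0)  # mT
DRIVE_LIMIT = 14.0  # mT
AMF_AMPLITUDE_LIMIT = 11.2  # mT
AMF_POWER_LIMIT = 600.0  # W


@dataclass(frozen=True)
class GradientSpec:
    """Diagonal of the (divergence-free) selection-field gradient tensor, T/m."""

    g_x: float
    g_y: float
    g_z: float
    enabled: bool = True

    def __post_init__(self):
        if abs(self.g_x) > GRADIENT_LIMIT_XY + 1e-12 or abs(self.g_y) > GRADIENT_LIMIT_XY + 1e-12:
            raise ValueError(f"transverse gradient exceeds {GRADIENT_LIMIT_XY} T/m limit")
        if abs(self.g_z) > GRADIENT_LIMIT_Z + 1e-12:
            raise ValueError(f"axial gradient exceeds {GRADIENT_LIMIT_Z} T/m limit")

    @classmethod
    def axial(cls, g_z: float, enabled: bool = True) -> "GradientSpec":
        """Divergence-free axisymmetric gradient from the axial strength alone.

        Maxwell's equations force the transverse components to -g_z/2 each.
        """
        return cls(-g_z / 2.0, -g_z / 2.0, g_z, enabled=enabled)

    @property
    def diagonal(self) -> np.ndarray:
        return np.array([self.g_x, self.g_y, self.g_z])

    @property
    def trace(self) -> float:
        return self.g_x + self.g_y + self.g_z

    def disabled(self) -> "GradientSpec":
        return replace(self, enabled=False)


@dataclass(frozen=True)
class FocusSpec:
    """Homogeneous offset field amplitudes, mT."""

    b_x: float = 0.0
    b_y: float = 0.0
    b_z: float = 0.0

    def __post_init__(self):
        for b, lim, ax in zip((self.b_x, self.b_y, self.b_z), FOCUS_LIMITS, "xyz"):
            if abs(b) > lim + 1e-9:
                raise ValueError(f"focus field |b_{ax}| = {abs(b):g} mT exceeds {lim} mT limit")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.b_x, self.b_y, self.b_z])


def _divider_period(base: float, dividers: tuple[int, int, int]) -> float:
    return math.lcm(*dividers) / base


@dataclass(frozen=True)
class DriveSpec:
    """Sinusoidal drive fields: amplitudes (mT), frequencies (Hz), period (s).

    Default frequencies follow the divider family f_i = 2.5 MHz / n_i with
    n = (96, 99, 102), giving three pairwise distinct tones near 25 kHz and a
    closed 21.54 ms 3D Lissajous.  ``desk()`` provides a coarser divider set
    (90, 96, 100) with a 2.88 ms repetition period for fast simulations.
    """

    a_x: float = 14.0
    a_y: float = 14.0
    a_z: float = 14.0
    f_x: float = 2.5e6 / 96
    f_y: float = 2.5e6 / 99
    f_z: float = 2.5e6 / 102
    repetition_period: float = _divider_period(2.5e6, (96, 99, 102))

    def __post_init__(self):
        for a in (self.a_x, self.a_y, self.a_z):
            if abs(a) > DRIVE_LIMIT + 1e-9:
                raise ValueError(f"drive amplitude exceeds {DRIVE_LIMIT} mT limit")
        freqs = (self.f_x, self.f_y, self.f_z)
        if len({round(f, 6) for f in freqs}) != 3:
            raise ValueError("drive frequencies must be pairwise distinct (closed Lissajous)")

    @classmethod
    def from_dividers(cls, dividers=(96, 99, 102), base=2.5e6, amplitude=14.0) -> "DriveSpec":
        return cls(
            a_x=amplitude, a_y=amplitude, a_z=amplitude,
            f_x=base / dividers[0], f_y=base / dividers[1], f_z=base / dividers[2],
            repetition_period=_divider_period(base, tuple(dividers)),
        )

    @classmethod
    def desk(cls, amplitude: float = 14.0) -> "DriveSpec":
        return cls.from_dividers((90, 96, 100), amplitude=amplitude)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([self.a_x, self.a_y, self.a_z])

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([self.f_x, self.f_y, self.f_z])


@dataclass(frozen=True)
class AMFSpec:
    """Hyperthermia field: peak amplitude (mT) along X at a single frequency.

    ``homogeneity_extent``/``homogeneity_deviation`` record the vendor-style
    homogeneity characterisation of the insert; the simulated envelope is the
    separable flat-top roll-off parameterised by ``envelope_flat``/
    ``envelope_zero`` (mm per axis).  Along the bore (X) heating is
    effectively suppressed beyond ±8 mm and vanishes at ±12 mm; transversally
    the insert stays effective across the ±8 mm sample grid, rolling off to
    zero at ±16 mm.
    """

    amplitude: float = 10.0
    frequency: float = 715e3
    power: float = 600.0
    homogeneity_extent: tuple = (22.5, 18.0, 12.0)
    homogeneity_deviation: tuple = (-0.085, 0.0325, 0.015)
    envelope_flat: tuple = (4.0, 9.0, 9.0)
    envelope_zero: tuple = (12.0, 16.0, 16.0)

    def __post_init__(self):
        if not 0.0 <= self.amplitude <= AMF_AMPLITUDE_LIMIT + 1e-9:
            raise ValueError(f"AMF amplitude exceeds {AMF_AMPLITUDE_LIMIT} mT limit")
        if not 0.0 <= self.power <= AMF_POWER_LIMIT + 1e-9:
            raise ValueError(f"AMF power exceeds {AMF_POWER_LIMIT} W limit")


@dataclass
class ScannerSpec:
    """The virtual instrument: one spec per field subsystem."""

    gradient: GradientSpec = field(default_factory=lambda: GradientSpec(-1.25, -1.25, 2.5))
    focus: FocusSpec = field(default_factory=FocusSpec)
    drive: DriveSpec = field(default_factory=DriveSpec)
    amf: AMFSpec = field(default_factory=AMFSpec)

    def to_dict(self) -> dict:
        return {
            "gradient": asdict(self.gradient),
            "focus": asdict(self.focus),
            "drive": asdict(self.drive),
            "amf": asdict(self.amf),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScannerSpec":
        kw = {}
        if "gradient" in d:
            kw["gradient"] = GradientSpec(**d["gradient"])
        if "focus" in d:
            kw["focus"] = FocusSpec(**d["focus"])
        if "drive" in d:
            kw["drive"] = DriveSpec(**d["drive"])
        if "amf" in d:
            amf = dict(d["amf"])
            for key in ("homogeneity_extent", "homogeneity_deviation", "envelope_flat", "envelope_zero"):
                if key in amf:
                    amf[key] = tuple(amf[key])
            kw["amf"] = AMFSpec(**amf)
        return cls(**kw)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "ScannerSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# field evaluation


def selection_field(r, g: GradientSpec) -> np.ndarray:
    """Static selection field (mT) at position(s) ``r`` (mm).

    With the gradient disabled the scanner is in "global mode" and the
    selection field is identically zero everywhere.
    """
    r = np.asarray(r, dtype=float)
    if not g.enabled:
        return np.zeros_like(r)
    return r * g.diagonal


def ffr_position(focus: FocusSpec, g: GradientSpec) -> np.ndarray:
    """Position (mm) where selection + focus field vanishes: r*_i = -b_i/g_i."""
    if not g.enabled:
        raise ValueError("FFR position undefined: selection field disabled (global mode)")
    diag = g.diagonal
    if np.any(diag == 0.0):
        axis = "xyz"[int(np.argmin(np.abs(diag)))]
        raise ValueError(f"FFR shift undefined along axis {axis}: zero gradient component")
    return -focus.vector / diag


def drive_fov_extent(d: DriveSpec, g: GradientSpec) -> np.ndarray:
    """Edge lengths (mm) of the drive-field FOV box, 2*a_i/|g_i| per axis."""
    return 2.0 * d.amplitudes / np.abs(g.diagonal)


def drive_trajectory(t, d: DriveSpec, g: GradientSpec, focus: FocusSpec | None = None) -> np.ndarray:
    """FFR path (mm) at time(s) ``t`` under drive + focus fields.

    Returns shape (3,) for scalar ``t`` and (n, 3) for a vector of times.
    """
    if focus is None:
        focus = FocusSpec()
    t = np.asarray(t, dtype=float)
    center = ffr_position(focus, g)
    amp = d.amplitudes / g.diagonal
    phase = 2.0 * np.pi * np.outer(t, d.frequencies)
    path = center + amp * np.sin(phase)
    return path[0] if t.ndim == 0 else path


def _axis_envelope(u: np.ndarray, flat: float, zero: float) -> np.ndarray:
    """Flat-top raised-cosine window: 1 for |u|<=flat, 0 for |u|>=zero."""
    a = np.abs(u)
    out = np.ones_like(a)
    taper = (a > flat) & (a < zero)
    out[taper] = np.cos(0.5 * np.pi * (a[taper] - flat) / (zero - flat)) ** 2
    out[a >= zero] = 0.0
    return out


def amf_envelope(r, spec: AMFSpec) -> np.ndarray:
    """Normalized AMF amplitude envelope at position(s) ``r`` (mm).

    Separable, even in each coordinate, 1 at the isocenter.
    """
    r = np.atleast_2d(np.asarray(r, dtype=float))
    env = np.ones(r.shape[0])
    for i in range(3):
        env = env * _axis_envelope(r[:, i], spec.envelope_flat[i], spec.envelope_zero[i])
    return env[0] if np.asarray(r).ndim == 1 else env


def amf_field(t, r, spec: AMFSpec) -> np.ndarray:
    """Instantaneous AMF X-component (mT) at time ``t`` and position ``r``."""
    env = amf_envelope(r, spec)
    return spec.amplitude * env * np.sin(2.0 * np.pi * spec.frequency * np.asarray(t, dtype=float))
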