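"""Theranostic session scheduling.

Interleaves MFH (AMF on, imaging off) and MPI (AMF off, acquisition +
multi-contrast reconstruction) windows with strict mutual exclusion, plans
focus-field settings for arbitrary FFR targets, runs MFH-walk sequences over
several targets, and records everything — applied fields, reconstructed
temperatures, ground truth, camera frames — in a session log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import camera_view
from .catalog import get_particle
from .fields import AMFSpec, FocusSpec, GradientSpec, ScannerSpec, ffr_position
from .imaging import (ImagingGrid, ReconParams, ThermometryCalib,
                      build_system_matrix, kaczmarz_reconstruct,
                      multicontrast_temperature, simulate_signal)
from .phantoms import Phantom, resample_to_grid
from .thermal import TemperatureField, heat_deposition_field, run_heating

__all__ = ["SessionPlan", "SessionLog", "plan_targets", "run_session", "mfh_walk"]


@dataclass
class SessionPlan:
    """Interleaved MPI-MFH protocol: per-cycle MFH at one target, then MPI.

    ``targets`` lists FFR positions (mm); cycle ``i`` heats
    ``targets[i % len(targets)]``.  Default cadence follows the platform's
    fixed-target session: 5 s of MFH + 1.1 s of MPI per cycle.
    """

    cycles: int = 40
    mfh_duration: float = 5.0
    mpi_duration: float = 1.1
    targets: list = dc_field(default_factory=lambda: [(0.0, -8.0, 0.0)])
    amf: AMFSpec = dc_field(default_factory=AMFSpec)
    recon: ReconParams = dc_field(default_factory=ReconParams)
    calib: ThermometryCalib = dc_field(default_factory=ThermometryCalib)
    imaging_grid: ImagingGrid = dc_field(
        default_factory=lambda: ImagingGrid((28.0, 28.0, 14.0), (14, 14, 14)))
    noise_std: float = 0.0
    sm_averages: int = 1
    roi_radius: float = 3.0  # mm

    def __post_init__(self):
        if self.mfh_duration <= 0 or self.mpi_duration <= 0:
            raise ValueError("window durations must be positive")
        if self.cycles < 1:
            raise ValueError("at least one cycle required")
        if not self.targets:
            raise ValueError("at least one MFH target required")

    @property
    def cycle_duration(self) -> float:
        return self.mfh_duration + self.mpi_duration

    def timeline(self) -> list[dict]:
        """Compiled event list; AMF and acquisition windows never overlap."""
        events = []
        t = 0.0
        for i in range(self.cycles):
            target = tuple(self.targets[i % len(self.targets)])
            events.append({"cycle": i, "kind": "mfh", "start": t,
                           "end": t + self.mfh_duration, "target": target})
            t += self.mfh_duration
            events.append({"cycle": i, "kind": "mpi", "start": t,
                           "end": t + self.mpi_duration, "target": None})
            t += self.mpi_duration
        return events


@dataclass
class SessionLog:
    events: list
    temperatures: pd.DataFrame  # per cycle x ROI: reconstructed and ground truth
    ground_truth_traces: pd.DataFrame  # fine-grained ROI mean temperature
    frames: list  # CameraFrame per cycle
    final_temperature: TemperatureField
    final_temperature_map: np.ndarray | None
    seed: int | None

    def export(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.events).to_csv(outdir / "events.csv", index=False)
        self.temperatures.to_csv(outdir / "temperatures.csv", index=False)
        self.ground_truth_traces.to_csv(outdir / "ground_truth.csv", index=False)
        from .io import write_volume
        write_volume(outdir / "final_temperature.nii.gz",
                     self.final_temperature.values, self.final_temperature.grid)
        if self.final_temperature_map is not None:
            np.savetxt(outdir / "final_temperature_map.csv",
                       self.final_temperature_map.reshape(self.final_temperature_map.shape[0], -1),
                       delimiter=",")
        frames_dir = outdir / "frames"
        frames_dir.mkdir(exist_ok=True)
        from PIL import Image
        for i, fr in enumerate(self.frames):
            mk = np.clip(fr.values * 1000.0 / 20.0, 0, 65535).astype(np.uint16)
            Image.fromarray(mk).save(frames_dir / f"frame_{i:04d}.png")
        (outdir / "session.json").write_text(json.dumps(
            {"seed": self.seed, "n_frames": len(self.frames)}, indent=2))


def plan_targets(positions, g: GradientSpec) -> list[FocusSpec]:
    """Focus-field settings that place the FFR at each requested position.

    Solves G r* + B_focus = 0 per target; a position needing more focus field
    than the hardware provides raises an error naming the violated axis.
    """
    out = []
    for pos in positions:
        pos = np.asarray(pos, dtype=float)
        b = -pos * g.diagonal
        try:
            focus = FocusSpec(*b)
        except ValueError as err:
            raise ValueError(f"target {tuple(pos)} mm unreachable: {err}") from None
        assert np.max(np.abs(ffr_position(focus, g) - pos)) < 1e-9
        out.append(focus)
    return out


def _roi_masks(grid: ImagingGrid, centers, radius: float):
    pts = grid.centers()
    return [np.sum((pts - np.asarray(c)) ** 2, axis=1) <= radius**2 for c in centers]


def _roi_mean(values, weights, mask):
    w = weights[mask]
    if w.sum() <= 0:
        return np.nan
    return float(np.sum(values[mask] * w) / w.sum())


def run_session(plan: SessionPlan, phantom: Phantom, scanner: ScannerSpec,
                base_temperature: float | None = None,
                seed: int | None = None) -> SessionLog:
    """Execute an interleaved MPI-MFH session on a phantom.

    Each cycle heats the cycle's target (focus-field shifted FFR) for the MFH
    window while the thermal solver advances the ground-truth temperature
    field, then switches the AMF off, acquires MPI data of the full FOV,
    reconstructs hot and cold channels, and logs per-ROI reconstructed and
    ground-truth temperatures.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    particle = phantom.particle_spec()
    calib = plan.calib
    base = calib.t_cold if base_temperature is None else base_temperature
    grid = plan.imaging_grid

    sm_noise = plan.noise_std
    sm_hot = build_system_matrix(scanner, grid, particle, calib.t_hot,
                                 averages=plan.sm_averages, noise_std=sm_noise, rng=rng)
    sm_cold = build_system_matrix(scanner, grid, particle, calib.t_cold,
                                  averages=plan.sm_averages, noise_std=sm_noise, rng=rng)

    props = phantom.thermal_volumes()
    tfield = TemperatureField.uniform(phantom.grid, base)
    plan_events = plan.timeline()
    roi_centers = phantom.metadata.get("vial_centers") or [(0.0, 0.0, 0.0)]
    rois_ph = _roi_masks(phantom.grid, roi_centers, plan.roi_radius)
    rois_im = _roi_masks(grid, roi_centers, plan.roi_radius)
    conc_ph = phantom.concentration.ravel()

    rows = []
    truth_rows = []
    frames = []
    temp_map = None
    for i in range(plan.cycles):
        ev_mfh, ev_mpi = plan_events[2 * i], plan_events[2 * i + 1]
        try:
            target = ev_mfh["target"]
            if plan.amf.amplitude > 0:
                q = heat_deposition_field(phantom, scanner, target, particle, amf=plan.amf)
            else:
                q = np.zeros(phantom.grid.shape)
            tfield = run_heating(tfield, q, plan.mfh_duration, props)
            tfield = run_heating(tfield, np.zeros_like(q), plan.mpi_duration, props)

            conc_im = resample_to_grid(phantom.concentration, phantom.grid, grid)
            temp_im = resample_to_grid(tfield.values, phantom.grid, grid,
                                       weights=np.maximum(phantom.concentration, 1e-12))
            spec = simulate_signal(_GridView(conc_im, phantom.particle), _TView(temp_im),
                                   scanner, grid, noise_std=plan.noise_std, rng=rng)
            c_hot, c_cold = kaczmarz_reconstruct(spec, [sm_hot, sm_cold], plan.recon,
                                                 scanner=scanner)
            temp_map, mask = multicontrast_temperature(c_hot, c_cold, calib)
            total = (c_hot + c_cold).ravel()
        except Exception as err:
            raise RuntimeError(f"cycle {i} failed: {err}") from err

        t_stamp = ev_mpi["end"]
        tmap_flat = np.where(np.isnan(temp_map.ravel()), 0.0, temp_map.ravel())
        w_rec = np.where(mask.ravel(), total, 0.0)
        for j, (roi_p, roi_i) in enumerate(zip(rois_ph, rois_im)):
            rec = _roi_mean(tmap_flat, w_rec, roi_i)
            truth = _roi_mean(tfield.values.ravel(), conc_ph, roi_p)
            rows.append({"cycle": i, "time_s": t_stamp, "roi": j,
                         "reconstructed_C": rec, "ground_truth_C": truth})
        truth_rows.append({"time_s": t_stamp, **{
            f"roi{j}_C": _roi_mean(tfield.values.ravel(), conc_ph, roi_p)
            for j, roi_p in enumerate(rois_ph)}})
        frames.append(camera_view(tfield))

    return SessionLog(events=plan_events, temperatures=pd.DataFrame(rows),
                      ground_truth_traces=pd.DataFrame(truth_rows), frames=frames,
                      final_temperature=tfield, final_temperature_map=temp_map,
                      seed=seed)


class _GridView:
    """Concentration resampled onto the imaging grid, phantom-like."""

    def __init__(self, concentration, particle):
        self.concentration = concentration
        self.particle = particle

    def particle_spec(self):
        return get_particle(self.particle)


class _TView:
    def __init__(self, values):
        self.values = values


def mfh_walk(trajectory, dwell: float, phantom: Phantom, scanner: ScannerSpec,
             amf: AMFSpec | None = None, frame_interval: float = 3.3,
             base_temperature: float = 23.0):
    """MFH-only walk: dwell at each target in sequence, logging camera frames.

    ``trajectory`` entries are FFR positions (mm) or the string ``"global"``
    for a gradient-OFF step that heats everything inside the envelope.
    Returns (list of CameraFrame, DataFrame of per-frame hot-spot positions,
    final TemperatureField).
    """
    amf = scanner.amf if amf is None else amf
    particle = phantom.particle_spec()
    # validate reachability up front
    plan_targets([t for t in trajectory if not isinstance(t, str)], scanner.gradient)
    props = phantom.thermal_volumes()
    tfield = TemperatureField.uniform(phantom.grid, base_temperature)
    frames = []
    spots = []
    plane_fov = (phantom.grid.fov[1], phantom.grid.fov[2])
    for k, target in enumerate(trajectory):
        if isinstance(target, str) and target == "global":
            glob = ScannerSpec(gradient=scanner.gradient.disabled(), focus=scanner.focus,
                               drive=scanner.drive, amf=amf)
            q = heat_deposition_field(phantom, glob, (0.0, 0.0, 0.0), particle, amf=amf)
        else:
            q = heat_deposition_field(phantom, scanner, target, particle, amf=amf)
        remaining = dwell
        while remaining > 1e-9:
            chunk = min(frame_interval, remaining)
            tfield = run_heating(tfield, q, chunk, props)
            remaining -= chunk
            frame = camera_view(tfield)
            frames.append(frame)
            y, z = frame.hotspot_mm(plane_fov)
            spots.append({"time_s": tfield.time, "target_index": k,
                          "hotspot_y_mm": y, "hotspot_z_mm": z,
                          "max_C": frame.max_temperature})
    return frames, pd.DataFrame(spots), tfield
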