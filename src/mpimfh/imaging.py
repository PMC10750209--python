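"""MPI image formation and inversion.

Signal model: the FFR sweeps a Lissajous trajectory; each voxel carrying
tracer experiences the local offset field G*(r - r_ffr(t)) and responds with
its equilibrium Langevin magnetization at the voxel's temperature.  Three
ideal orthogonal receive channels pick up dM/dt; spectra are analysed on the
frequency comb k / T_repetition.

Calibration simulates the classical delta-sample scan: one system-matrix
column per voxel, acquired at a stated particle temperature.  Reconstruction
is row-regularized Kaczmarz over SNR-thresholded, band-limited rows; the
multi-contrast ("hot"/"cold" channel) variant stacks two system matrices and
unmixes per-voxel temperature from the channel weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .constants import KB
from .fields import ScannerSpec, drive_fov_extent, drive_trajectory, ffr_position
from .particles import ParticleSpec, _moment_weights

__all__ = [
    "ImagingGrid",
    "Spectrum",
    "SystemMatrix",
    "ReconParams",
    "ThermometryCalib",
    "simulate_signal",
    "build_system_matrix",
    "kaczmarz_reconstruct",
    "multicontrast_temperature",
]

#: receive-chain sample rate, Hz (sets the spectral bandwidth at Nyquist)
SAMPLE_RATE = 2.5e6


@dataclass(frozen=True)
class ImagingGrid:
    """Voxel lattice: FOV and matrix size per axis, origin at FOV center (mm)."""

    fov: tuple
    matrix: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(f <= 0 for f in self.fov) or any(m <= 0 for m in self.matrix):
            raise ValueError("FOV and matrix entries must be positive")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.asarray(self.fov, dtype=float) / np.asarray(self.matrix)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.matrix))

    @property
    def shape(self) -> tuple:
        return tuple(int(m) for m in self.matrix)

    def centers(self) -> np.ndarray:
        """Voxel center positions, shape (n_voxels, 3), C-order over (x,y,z)."""
        vs = self.voxel_size
        axes = [
            np.asarray(self.origin)[i] + (np.arange(self.matrix[i]) + 0.5) * vs[i]
            - self.fov[i] / 2.0
            for i in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def voxel_volume_m3(self) -> float:
        return float(np.prod(self.voxel_size)) * 1e-9


@dataclass
class Spectrum:
    """Stacked receive spectra: one complex value per (channel, frequency bin)."""

    values: np.ndarray
    frequency_axis: np.ndarray

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if not np.allclose(self.frequency_axis, other.frequency_axis):
            raise ValueError("spectra have different frequency axes")
        return Spectrum(self.values + other.values, self.frequency_axis)


@dataclass
class SystemMatrix:
    """Frequency-component x voxel calibration array at one particle temperature."""

    entries: np.ndarray  # complex, (n_rows, n_voxels)
    frequency_axis: np.ndarray  # Hz per row
    calibration_temperature: float  # degC
    grid: ImagingGrid
    particle: str
    snr_per_row: np.ndarray
    unreachable_voxels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    calibration_concentration: float = 5.0

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("entries", data=self.entries)
            f.create_dataset("frequency_axis", data=self.frequency_axis)
            f.create_dataset("snr_per_row", data=self.snr_per_row)
            f.create_dataset("unreachable_voxels", data=self.unreachable_voxels)
            f.attrs["calibration_temperature"] = self.calibration_temperature
            f.attrs["calibration_concentration"] = self.calibration_concentration
            f.attrs["particle"] = self.particle
            f.attrs["fov"] = self.grid.fov
            f.attrs["matrix"] = self.grid.matrix
            f.attrs["origin"] = self.grid.origin

    @classmethod
    def load(cls, path) -> "SystemMatrix":
        with h5py.File(path, "r") as f:
            grid = ImagingGrid(tuple(f.attrs["fov"]), tuple(int(m) for m in f.attrs["matrix"]),
                               tuple(f.attrs["origin"]))
            return cls(entries=f["entries"][()], frequency_axis=f["frequency_axis"][()],
                       calibration_temperature=float(f.attrs["calibration_temperature"]),
                       grid=grid, particle=str(f.attrs["particle"]),
                       snr_per_row=f["snr_per_row"][()],
                       unreachable_voxels=f["unreachable_voxels"][()],
                       calibration_concentration=float(f.attrs["calibration_concentration"]))


@dataclass(frozen=True)
class ReconParams:
    """Kaczmarz reconstruction parameters (scanner-software style defaults)."""

    relative_regularization: float = 0.01
    iterations: int = 15
    snr_threshold: float = 10.0
    border_frequency: float = 0.625e6
    nonnegativity: bool = True

    def __post_init__(self):
        if self.relative_regularization < 0:
            raise ValueError("regularization must be nonnegative")
        if self.iterations < 1:
            raise ValueError("at least one iteration required")


@dataclass(frozen=True)
class ThermometryCalib:
    t_hot: float = 45.0  # degC
    t_cold: float = 23.0  # degC
    mask_threshold: float = 0.1  # fraction of the maximum total concentration

    def __post_init__(self):
        if self.t_hot <= self.t_cold:
            raise ValueError("hot calibration temperature must exceed the cold one")


# ---------------------------------------------------------------------------
# signal generation


def _langevin_over_xi(xi: np.ndarray) -> np.ndarray:
    """L(xi)/xi, stable at 0 (-> 1/3)."""
    out = np.empty_like(xi)
    small = np.abs(xi) < 1e-4
    xs = xi[small]
    out[small] = 1.0 / 3.0 - xs**2 / 45.0
    xl = xi[~small]
    out[~small] = (1.0 / np.tanh(xl) - 1.0 / xl) / xl
    return out


def _n_samples(scanner: ScannerSpec) -> int:
    n = scanner.drive.repetition_period * SAMPLE_RATE
    n_int = int(round(n))
    if abs(n - n_int) > 1e-6:
        raise ValueError("drive repetition period must be an integer number of samples")
    return n_int


def _voxel_spectra(positions: np.ndarray, temperatures_c: np.ndarray,
                   concentrations: np.ndarray, scanner: ScannerSpec,
                   particle: ParticleSpec, chunk: int = 64) -> np.ndarray:
    """Receive spectra of independent point samples, shape (n_rows, n_pos).

    Rows are channel-major: all bins of channel X, then Y, then Z, DC bin
    excluded.  Amplitudes are in model units (consistent across the package).

    The equilibrium Langevin waveform is evaluated at the reference
    temperature; temperature enters through the two-state activation
    response f(T) + (1 - f(T)) exp(-i omega t_rev): the mobile fraction
    follows the drive quasi-instantaneously while hindered cores lag by the
    thermally blocked reversal delay.  The spectrum is thus affine in T over
    the activation window.
    """
    from .particles import MS_REFERENCE_K

    nt = _n_samples(scanner)
    times = np.arange(nt) / SAMPLE_RATE
    traj = drive_trajectory(times, scanner.drive, scanner.gradient, scanner.focus)
    diag = scanner.gradient.diagonal
    nbins = nt // 2
    freqs = np.fft.rfftfreq(nt, d=1.0 / SAMPLE_RATE)[1:nbins + 1]
    omega = 2j * np.pi * freqs
    delayed = np.exp(-1j * 2.0 * np.pi * freqs * particle.reversal_delay)

    n_pos = positions.shape[0]
    out = np.zeros((3 * nbins, n_pos), dtype=np.complex128)
    t_ref = MS_REFERENCE_K
    _, moments, ndens = _moment_weights(particle, t_ref)
    frac = np.atleast_1d(particle.active_fraction(np.asarray(temperatures_c, dtype=float)))

    for start in range(0, n_pos, chunk):
        sl = slice(start, min(start + chunk, n_pos))
        pos = positions[sl]
        conc = concentrations[sl]
        b = (pos[:, None, :] - traj[None, :, :]) * diag  # mT, (nv, nt, 3)
        babs_t = np.sqrt(np.sum(b * b, axis=-1)) * 1e-3  # T
        m = np.zeros_like(b)
        for mom, nd in zip(moments, ndens):
            s = mom / (KB * t_ref)
            pref = nd * mom * s * 1e-3  # A/m per mT per (mg Fe/mL)
            m += (pref * _langevin_over_xi(babs_t * s))[:, :, None] * b
        m *= conc[:, None, None]
        spec = np.fft.rfft(m, axis=1)[:, 1:nbins + 1, :] / nt
        spec = spec * omega[None, :, None]
        f = frac[sl]
        response = f[:, None] + (1.0 - f[:, None]) * delayed[None, :]
        spec = spec * response[:, :, None]
        # channel-major stacking
        out[:, sl] = np.transpose(spec, (2, 1, 0)).reshape(3 * nbins, -1)
    return out


def _frequency_rows(scanner: ScannerSpec) -> np.ndarray:
    nt = _n_samples(scanner)
    nbins = nt // 2
    freqs = np.fft.rfftfreq(nt, d=1.0 / SAMPLE_RATE)[1:nbins + 1]
    return np.tile(freqs, 3)


def simulate_signal(phantom, temperature_field, scanner: ScannerSpec,
                    grid: ImagingGrid, noise_std: float = 0.0,
                    rng: np.random.Generator | None = None) -> Spectrum:
    """Induced-voltage spectrum of a phantom under the moving FFR.

    ``phantom`` provides per-voxel concentration on ``grid`` (resample first
    if needed); ``temperature_field`` the per-voxel temperature in degC.
    Additive white Gaussian noise of standard deviation ``noise_std`` (in
    signal units, per spectral bin and channel) is applied when requested.
    """
    conc = np.asarray(phantom.concentration, dtype=float)
    if tuple(conc.shape) != grid.shape:
        raise ValueError("phantom grid does not match the imaging grid")
    temps = np.asarray(temperature_field.values, dtype=float)
    if temps.shape != conc.shape:
        raise ValueError("temperature field grid does not match the phantom grid")

    freq = _frequency_rows(scanner)
    mask = conc.ravel() > 0
    if not np.any(mask):
        values = np.zeros(freq.size, dtype=np.complex128)
    else:
        centers = grid.centers()[mask]
        spectra = _voxel_spectra(centers, temps.ravel()[mask], conc.ravel()[mask],
                                 scanner, particle=phantom.particle_spec(), chunk=64)
        values = spectra.sum(axis=1)
    if noise_std > 0:
        rng = np.random.default_rng() if rng is None else rng
        values = values + noise_std * (rng.standard_normal(values.shape)
                                       + 1j * rng.standard_normal(values.shape)) / np.sqrt(2)
    return Spectrum(values=values, frequency_axis=freq)


def build_system_matrix(scanner: ScannerSpec, grid: ImagingGrid,
                        particle: ParticleSpec, temperature: float,
                        averages: int = 1, noise_std: float = 0.0,
                        rng: np.random.Generator | None = None,
                        calibration_concentration: float = 5.0) -> SystemMatrix:
    """Simulated delta-sample calibration scan at ``temperature`` (degC).

    One column per voxel; voxels outside the drive-field FOV (around the
    current focus shift) produce zero columns and are flagged.  Per-row SNR
    is estimated from the noise level reduced by ``averages``.
    """
    centers = grid.centers()
    reach_center = ffr_position(scanner.focus, scanner.gradient)
    half_extent = drive_fov_extent(scanner.drive, scanner.gradient) / 2.0
    reachable = np.all(np.abs(centers - reach_center) <= half_extent + 1e-9, axis=1)

    entries = np.zeros((_frequency_rows(scanner).size, centers.shape[0]),
                       dtype=np.complex128)
    if np.any(reachable):
        temps = np.full(reachable.sum(), float(temperature))
        conc = np.full(reachable.sum(), float(calibration_concentration))
        entries[:, reachable] = _voxel_spectra(centers[reachable], temps, conc,
                                               scanner, particle)
    sigma_eff = noise_std / np.sqrt(max(averages, 1))
    if sigma_eff > 0:
        rng = np.random.default_rng() if rng is None else rng
        noise = sigma_eff * (rng.standard_normal(entries.shape)
                             + 1j * rng.standard_normal(entries.shape)) / np.sqrt(2)
        snr = np.max(np.abs(entries), axis=1) / sigma_eff
        entries = entries + noise
    else:
        snr = np.full(entries.shape[0], np.inf)
        snr[np.max(np.abs(entries), axis=1) == 0.0] = 0.0
    return SystemMatrix(entries=entries, frequency_axis=_frequency_rows(scanner),
                        calibration_temperature=float(temperature), grid=grid,
                        particle=particle.name, snr_per_row=snr,
                        unreachable_voxels=np.flatnonzero(~reachable),
                        calibration_concentration=float(calibration_concentration))


# ---------------------------------------------------------------------------
# reconstruction


def _row_selection(matrices: list[SystemMatrix], params: ReconParams,
                   scanner: ScannerSpec | None) -> np.ndarray:
    freq = matrices[0].frequency_axis
    snr = np.max(np.stack([m.snr_per_row for m in matrices]), axis=0)
    keep = (freq > 0) & (freq <= params.border_frequency) & (snr >= params.snr_threshold)
    if scanner is not None:
        df = freq[1] - freq[0] if freq.size > 1 else 1.0
        for f0 in scanner.drive.frequencies:
            keep &= np.abs(freq - f0) > 0.5 * df
    return keep


def kaczmarz_reconstruct(spectrum: Spectrum, matrices, params: ReconParams,
                         scanner: ScannerSpec | None = None) -> list[np.ndarray]:
    """Row-action Tikhonov-regularized solve of the stacked system.

    Rows are filtered to SNR >= threshold and f <= border frequency (drive
    fundamentals excluded when the scanner is given) and processed in fixed
    descending-SNR order; the regularized update uses the augmented-variable
    Kaczmarz scheme, with an optional nonnegativity projection of the voxel
    values after each sweep.  Returns one concentration map per system matrix.
    """
    if isinstance(matrices, SystemMatrix):
        matrices = [matrices]
    matrices = list(matrices)
    for m in matrices[1:]:
        if not np.allclose(m.frequency_axis, matrices[0].frequency_axis):
            raise ValueError("system matrices have different frequency axes")
    if not np.allclose(spectrum.frequency_axis, matrices[0].frequency_axis):
        raise ValueError("spectrum and system matrices have different frequency axes")

    keep = _row_selection(matrices, params, scanner)
    if not np.any(keep):
        raise ValueError("no usable frequency components after SNR/border filtering")

    a = np.hstack([m.entries for m in matrices])[keep]
    b = spectrum.values[keep]
    snr = np.max(np.stack([m.snr_per_row for m in matrices]), axis=0)[keep]
    order = np.argsort(-snr, kind="stable")

    # whiten: unit-energy rows (the standard SNR-type row weighting); the
    # Tikhonov weight is the relative regularization times the mean row
    # energy of the whitened system
    norms = np.linalg.norm(a, axis=1)
    nonzero = norms > 0
    a = a[nonzero] / norms[nonzero, None]
    b = b[nonzero] / norms[nonzero]
    order = np.argsort(-snr[nonzero], kind="stable")

    row_energy = np.sum(np.abs(a) ** 2, axis=1)
    lam = params.relative_regularization * float(np.mean(row_energy))
    sqrt_lam = np.sqrt(lam)

    n_unknowns = a.shape[1]
    x = np.zeros(n_unknowns, dtype=np.complex128)
    v = np.zeros(a.shape[0], dtype=np.complex128)
    denom = row_energy + lam
    for _ in range(params.iterations):
        for i in order:
            ai = a[i]
            tau = (b[i] - ai @ x - sqrt_lam * v[i]) / denom[i]
            x += tau * ai.conj()
            v[i] += tau * sqrt_lam
        if params.nonnegativity:
            x = np.maximum(x.real, 0.0).astype(np.complex128)
    x = x.real
    if params.nonnegativity:
        x = np.maximum(x, 0.0)
    nv = matrices[0].grid.n_voxels
    return [m.calibration_concentration * x[i * nv:(i + 1) * nv].reshape(m.grid.shape)
            for i, m in enumerate(matrices)]


def multicontrast_temperature(c_hot: np.ndarray, c_cold: np.ndarray,
                              calib: ThermometryCalib):
    """Per-voxel temperature from hot/cold channel weights.

    T = (c_hot t_hot + c_cold t_cold) / (c_hot + c_cold) on voxels whose
    total concentration reaches ``mask_threshold`` of the map maximum;
    clipped to [t_cold, t_hot].  Returns (temperature map degC, valid mask).
    """
    c_hot = np.asarray(c_hot, dtype=float)
    c_cold = np.asarray(c_cold, dtype=float)
    if c_hot.shape != c_cold.shape:
        raise ValueError("channel maps have different shapes")
    if np.any(c_hot < 0) or np.any(c_cold < 0):
        raise ValueError("channel maps must be nonnegative")
    total = c_hot + c_cold
    peak = total.max()
    mask = total >= calib.mask_threshold * peak if peak > 0 else np.zeros_like(total, bool)
    temp = np.full(c_hot.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (c_hot * calib.t_hot + c_cold * calib.t_cold) / total
    temp[mask] = np.clip(t[mask], calib.t_cold, calib.t_hot)
    return temp, mask
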