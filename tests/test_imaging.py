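import numpy as np
import pytest

from mpimfh.catalog import get_particle
from mpimfh.imaging import (ImagingGrid, ReconParams, Spectrum, SystemMatrix,
                            ThermometryCalib, build_system_matrix,
                            kaczmarz_reconstruct, multicontrast_temperature,
                            simulate_signal)
from mpimfh.phantoms import Phantom
from mpimfh.thermal import TemperatureField


class TestImagingGrid:
    def test_protocol_voxel_size(self):
        grid = ImagingGrid((40.0, 40.0, 20.0), (20, 20, 20))
        assert np.allclose(grid.voxel_size, [2.0, 2.0, 1.0])

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            ImagingGrid((0.0, 10.0, 10.0), (5, 5, 5))

    def test_centers_symmetric_about_origin(self):
        grid = ImagingGrid((10.0, 10.0, 10.0), (5, 5, 5))
        assert np.allclose(grid.centers().mean(axis=0), 0.0)


class TestSimulateSignal:
    def test_empty_phantom_silent(self, desk_scanner, small_grid):
        ph = Phantom(concentration=np.zeros(small_grid.shape),
                     labels=np.zeros(small_grid.shape, np.uint8),
                     grid=small_grid, particle="synomag-S-90")
        spec = simulate_signal(ph, TemperatureField.uniform(small_grid, 23.0),
                               desk_scanner, small_grid)
        assert np.all(spec.values == 0)

    def test_linear_in_concentration(self, desk_scanner, small_grid,
                                     single_vial_phantom):
        tf = TemperatureField.uniform(small_grid, 23.0)
        s1 = simulate_signal(single_vial_phantom, tf, desk_scanner, small_grid)
        doubled = Phantom(concentration=2 * single_vial_phantom.concentration,
                          labels=single_vial_phantom.labels, grid=small_grid,
                          particle="synomag-S-90")
        s2 = simulate_signal(doubled, tf, desk_scanner, small_grid)
        assert (np.linalg.norm(s2.values - 2 * s1.values)
                <= 1e-9 * np.linalg.norm(s2.values))

    def test_point_sample_matches_system_matrix_column(
            self, desk_scanner, small_grid, thermo_matrices, single_vial_phantom):
        sm_hot, _ = thermo_matrices
        spec = simulate_signal(single_vial_phantom,
                               TemperatureField.uniform(small_grid, 45.0),
                               desk_scanner, small_grid)
        column = sm_hot.entries[:, np.ravel_multi_index((4, 4, 1), small_grid.shape)]
        assert np.allclose(spec.values, column, rtol=1e-10)

    def test_mismatched_grids_rejected(self, desk_scanner, small_grid,
                                       single_vial_phantom):
        other = ImagingGrid((20.0, 20.0, 8.0), (10, 10, 4))
        with pytest.raises(ValueError):
            simulate_signal(single_vial_phantom,
                            TemperatureField.uniform(small_grid, 23.0),
                            desk_scanner, other)

    def test_noise_is_seeded(self, desk_scanner, small_grid, single_vial_phantom):
        tf = TemperatureField.uniform(small_grid, 23.0)
        a = simulate_signal(single_vial_phantom, tf, desk_scanner, small_grid,
                            noise_std=1.0, rng=np.random.default_rng(5))
        b = simulate_signal(single_vial_phantom, tf, desk_scanner, small_grid,
                            noise_std=1.0, rng=np.random.default_rng(5))
        assert np.array_equal(a.values, b.values)


class TestSystemMatrix:
    def test_hot_and_cold_matrices_differ(self, thermo_matrices):
        sm_hot, sm_cold = thermo_matrices
        rel = (np.linalg.norm(sm_hot.entries - sm_cold.entries)
               / np.linalg.norm(sm_cold.entries))
        assert rel > 0.05

    def test_unreachable_voxels_flagged_and_zero(self, desk_scanner):
        wide = ImagingGrid((60.0, 60.0, 20.0), (6, 6, 2))  # beyond drive FOV
        sm = build_system_matrix(desk_scanner, wide, get_particle("synomag-S-90"), 23.0)
        assert sm.unreachable_voxels.size > 0
        assert np.all(sm.entries[:, sm.unreachable_voxels] == 0)

    def test_zero_concentration_gives_zero_matrix(self, desk_scanner, small_grid):
        sm = build_system_matrix(desk_scanner, small_grid,
                                 get_particle("synomag-S-90"), 23.0,
                                 calibration_concentration=0.0)
        assert np.all(sm.entries == 0)

    def test_round_trip(self, thermo_matrices, tmp_path):
        sm_hot, _ = thermo_matrices
        sm_hot.save(tmp_path / "sm.h5")
        back = SystemMatrix.load(tmp_path / "sm.h5")
        assert np.array_equal(back.entries, sm_hot.entries)
        assert back.calibration_temperature == sm_hot.calibration_temperature
        assert back.grid == sm_hot.grid


class TestKaczmarz:
    def test_zero_spectrum_zero_map(self, desk_scanner, thermo_matrices):
        sm_hot, sm_cold = thermo_matrices
        spec = Spectrum(values=np.zeros_like(sm_hot.entries[:, 0]),
                        frequency_axis=sm_hot.frequency_axis)
        maps = kaczmarz_reconstruct(spec, [sm_hot, sm_cold], ReconParams(),
                                    scanner=desk_scanner)
        assert all(np.all(m == 0) for m in maps)

    def test_no_rows_error(self, desk_scanner, thermo_matrices):
        sm_hot, _ = thermo_matrices
        spec = Spectrum(values=sm_hot.entries[:, 0].copy(),
                        frequency_axis=sm_hot.frequency_axis)
        with pytest.raises(ValueError, match="no usable frequency components"):
            kaczmarz_reconstruct(spec, sm_hot,
                                 ReconParams(border_frequency=1.0),
                                 scanner=desk_scanner)

    def test_matches_dense_tikhonov_oracle(self):
        # small noiseless complex system: many sweeps must agree with the
        # closed-form regularized least squares solution
        rng = np.random.default_rng(11)
        n_rows, n_cols = 60, 12
        a = rng.standard_normal((n_rows, n_cols)) + 1j * rng.standard_normal((n_rows, n_cols))
        x_true = rng.random(n_cols)
        b = a @ x_true
        grid = ImagingGrid((12.0, 1.0, 1.0), (n_cols, 1, 1))
        freq = np.linspace(1e3, 1e4, n_rows)
        sm = SystemMatrix(entries=a, frequency_axis=freq, calibration_temperature=23.0,
                          grid=grid, particle="synomag-S-90",
                          snr_per_row=np.full(n_rows, np.inf),
                          calibration_concentration=1.0)
        params = ReconParams(relative_regularization=0.01, iterations=4000,
                             snr_threshold=0.0, border_frequency=1e6,
                             nonnegativity=False)
        (xk,) = kaczmarz_reconstruct(Spectrum(values=b, frequency_axis=freq), sm, params)
        norms = np.linalg.norm(a, axis=1)
        aw = a / norms[:, None]
        bw = b / norms
        lam = 0.01 * np.mean(np.sum(np.abs(aw) ** 2, axis=1))
        oracle = np.linalg.solve(aw.conj().T @ aw + lam * np.eye(n_cols),
                                 aw.conj().T @ bw).real
        assert np.linalg.norm(xk.ravel() - oracle) / np.linalg.norm(oracle) < 1e-6

    def test_single_voxel_phantom_recovers_argmax(
            self, desk_scanner, small_grid, thermo_matrices, single_vial_phantom):
        sm_hot, _ = thermo_matrices
        spec = simulate_signal(single_vial_phantom,
                               TemperatureField.uniform(small_grid, 45.0),
                               desk_scanner, small_grid)
        (cmap,) = kaczmarz_reconstruct(spec, sm_hot, ReconParams(), scanner=desk_scanner)
        assert np.unravel_index(np.argmax(cmap), cmap.shape) == (4, 4, 1)

    def test_linearity_of_reconstruction(self, desk_scanner, small_grid,
                                         thermo_matrices):
        sm_hot, _ = thermo_matrices
        params = ReconParams(nonnegativity=False)
        col = lambda i, j, k: sm_hot.entries[:, np.ravel_multi_index((i, j, k), small_grid.shape)]
        s1 = Spectrum(values=col(2, 4, 1), frequency_axis=sm_hot.frequency_axis)
        s2 = Spectrum(values=col(6, 4, 1), frequency_axis=sm_hot.frequency_axis)
        (m1,) = kaczmarz_reconstruct(s1, sm_hot, params, scanner=desk_scanner)
        (m2,) = kaczmarz_reconstruct(s2, sm_hot, params, scanner=desk_scanner)
        (m12,) = kaczmarz_reconstruct(s1 + s2, sm_hot, params, scanner=desk_scanner)
        assert np.linalg.norm(m12 - (m1 + m2)) / np.linalg.norm(m1 + m2) < 1e-6


class TestMulticontrastTemperature:
    def test_cold_fixed_point(self):
        c_cold = np.ones((3, 3, 1))
        tmap, mask = multicontrast_temperature(np.zeros_like(c_cold), c_cold,
                                               ThermometryCalib())
        assert np.all(mask)
        assert np.allclose(tmap, 23.0)

    def test_equal_channels_midpoint(self):
        c = np.ones((2, 2, 2))
        tmap, mask = multicontrast_temperature(c, c, ThermometryCalib())
        assert np.allclose(tmap[mask], 34.0)

    def test_all_zero_fully_masked(self):
        z = np.zeros((2, 2, 2))
        tmap, mask = multicontrast_temperature(z, z, ThermometryCalib())
        assert not mask.any()
        assert np.all(np.isnan(tmap))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            multicontrast_temperature(-np.ones((2, 2)), np.ones((2, 2)),
                                      ThermometryCalib())

    def test_calibration_order_enforced(self):
        with pytest.raises(ValueError):
            ThermometryCalib(t_hot=20.0, t_cold=23.0)


def _reconstruct_roi_temperature(scanner, grid, matrices, phantom, temperature):
    spec = simulate_signal(phantom, TemperatureField.uniform(grid, temperature),
                           scanner, grid)
    c_hot, c_cold = kaczmarz_reconstruct(spec, list(matrices), ReconParams(),
                                         scanner=scanner)
    tmap, mask = multicontrast_temperature(c_hot, c_cold, ThermometryCalib())
    weights = np.where(mask, c_hot + c_cold, 0.0)
    return float(np.nansum(np.nan_to_num(tmap) * weights) / weights.sum())


class TestThermometryEndToEnd:
    def test_fixed_points_recovered(self, desk_scanner, small_grid,
                                    thermo_matrices, single_vial_phantom):
        hot = _reconstruct_roi_temperature(desk_scanner, small_grid,
                                           thermo_matrices, single_vial_phantom, 45.0)
        cold = _reconstruct_roi_temperature(desk_scanner, small_grid,
                                            thermo_matrices, single_vial_phantom, 23.0)
        assert hot == pytest.approx(45.0, abs=0.5)
        assert cold == pytest.approx(23.0, abs=0.5)

    def test_monotone_recovery_of_intermediate_temperatures(
            self, desk_scanner, small_grid, thermo_matrices, single_vial_phantom):
        truths = np.arange(25.0, 43.1, 2.0)
        recons = [_reconstruct_roi_temperature(desk_scanner, small_grid,
                                               thermo_matrices, single_vial_phantom, t)
                  for t in truths]
        assert all(b > a for a, b in zip(recons, recons[1:]))
        assert np.max(np.abs(np.array(recons) - truths)) <= 1.0
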