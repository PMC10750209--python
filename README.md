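# mpimfh

A desk-scale digital twin of an integrated **magnetic particle imaging /
magnetic fluid hyperthermia (MPI–MFH) theranostic platform**: a preclinical
MPI scanner with a concentric 715 kHz hyperthermia insert that images,
heats, and thermometers the *same* superparamagnetic iron-oxide
nanoparticles (SPION), using the *same* field-free region (FFR) to localize
both the imaging sensitivity and the therapy.

The package is written for imaging physicists and nanoparticle researchers
who want to prototype interleaved imaging/therapy protocols, reconstruction
settings, or tracer choices in software before touching a scanner. It
simulates:

- **Fields** — selection gradient (up to 1.25/1.25/2.5 T/m) with its FFR,
  focus-field FFR shifting (≤ 17/17/42 mT), ~25 kHz Lissajous drive fields
  (≤ 14 mT), and the hyperthermia AMF (10 mT at 715 kHz) with its
  field-of-therapy envelope.
- **SPION physics** — size-distributed Langevin magnetization, Néel–Brown
  relaxation, MPS harmonic spectra with the A5/A3 quality metric,
  linear-response heating power, and calorimetric SAR
  (SAR = c_w·(m_w/m_Fe)·dT/dt), with a ten-product commercial particle
  catalog.
- **Imaging** — voxelized signal generation over the Lissajous cycle,
  simulated system-matrix calibration at a stated tracer temperature, and
  row-regularized Kaczmarz reconstruction (SNR-thresholded, band-limited,
  15 sweeps, relative regularization 0.01).
- **Thermometry** — multi-contrast ("hot"/"cold" channel) reconstruction:
  T = (c_hot·T_hot + c_cold·T_cold)/(c_hot + c_cold) per voxel, against
  system matrices calibrated at 45 °C and 23 °C.
- **Heat transport** — FFR-localized power deposition, explicit
  finite-difference diffusion in labelled phantoms, plug-flow advection in
  a circulation loop, heating point-spread-function characterisation.
- **Session control** — interleaved MFH/MPI cycles with strict mutual
  exclusion, focus-field target planning, multi-target MFH walks, a thermal
  camera emulator, and full session logging (CSV, NIfTI, 16-bit PNG).

## Worked example: hot/cold thermometry of a single vial

```python
import numpy as np
from mpimfh.catalog import get_particle
from mpimfh.fields import DriveSpec, GradientSpec, ScannerSpec
from mpimfh.imaging import (ImagingGrid, ReconParams, ThermometryCalib,
                            build_system_matrix, kaczmarz_reconstruct,
                            multicontrast_temperature, simulate_signal)
from mpimfh.phantoms import Phantom
from mpimfh.thermal import TemperatureField

scanner = ScannerSpec(gradient=GradientSpec(1.0, 1.0, 2.0), drive=DriveSpec.desk())
grid = ImagingGrid((18.0, 18.0, 6.0), (9, 9, 3))
particle = get_particle("synomag-S-90")

sm_hot = build_system_matrix(scanner, grid, particle, temperature=45.0)
sm_cold = build_system_matrix(scanner, grid, particle, temperature=23.0)

conc = np.zeros(grid.shape); conc[4, 4, 1] = 5.0          # one vial, 5 mg(Fe)/mL
phantom = Phantom(conc, np.where(conc > 0, 1, 0).astype("uint8"), grid, "synomag-S-90")

spectrum = simulate_signal(phantom, TemperatureField.uniform(grid, 45.0), scanner, grid)
c_hot, c_cold = kaczmarz_reconstruct(spectrum, [sm_hot, sm_cold], ReconParams(),
                                     scanner=scanner)
tmap, mask = multicontrast_temperature(c_hot, c_cold, ThermometryCalib())
w = np.where(mask, c_hot + c_cold, 0.0)
print(f"masked mean temperature: {np.nansum(np.nan_to_num(tmap) * w) / w.sum():.2f} C")
```

Output:

```
masked mean temperature: 44.92 C
```

The vial was simulated at the hot calibration temperature, so nearly all
reconstructed concentration lands in the hot channel and the channel-weighted
temperature reads back 44.92 °C (the calibration is 45 °C; the residual is
regularization leakage into the cold channel). A vial simulated at 23 °C
reads 23.07 °C, and intermediate temperatures interpolate linearly — the
same command is exposed as `mpimfh thermometry <outdir>`.

Other entry points: `mpimfh psf` (localized-heating point spread function:
prints half-extents `(5.0, 5.0, 2.5) mm` at gradients (1.25, 1.25, 2.5) T/m),
`mpimfh simulate-session` (interleaved MPI–MFH cycles on the 3-vial
phantom), `mpimfh flow-study`, `mpimfh sar`, `mpimfh mps`, `mpimfh build-sm`,
`mpimfh reconstruct`.

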