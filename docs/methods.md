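# Model and methods

`mpimfh` is a desk-scale digital twin of a preclinical magnetic particle
imaging (MPI) scanner with a concentric magnetic-fluid-hyperthermia (MFH)
insert. It simulates, in one consistent coordinate frame (X = bore/AMF axis,
Z = high-gradient axis, origin at the isocenter; mm, mT, T/m), the chain
from field generation through nanoparticle physics to image formation,
thermometry, and heat transport, orchestrated by an interleaved MPI/MFH
session scheduler. This note records the models, their assumptions, the
defaults that matter, and what the synthetic experiments do and do not show.

## Magnetic fields

**Selection field.** A static gradient field B(r) = G·r with diagonal
G = (g_x, g_y, g_z), divergence-free by construction when built from an
axial strength (g_x = g_y = −g_z/2). Instrument limits: |g_z| ≤ 2.5 T/m,
|g_x|, |g_y| ≤ 1.25 T/m. Its zero is the field-free region (FFR), the only
place where tracer responds to excitation — this one mechanism localizes
both imaging sensitivity and heating.

**Focus fields.** Homogeneous offsets b (≤ 17/17/42 mT) translate the FFR
to r* = −b/g component-wise. `plan_targets` inverts this relation and
refuses targets that exceed a coil limit, naming the axis.

**Drive fields.** Three sinusoids near 25 kHz (≤ 14 mT) sweep the FFR over
a closed 3D Lissajous path. Frequencies follow the divider family
f_i = 2.5 MHz / n_i; the default n = (96, 99, 102) gives a 21.54 ms
repetition period. Simulations in the test-suite and the acceptance script
use the coarser documented preset n = (90, 96, 100) (2.88 ms period,
7200 samples at the 2.5 MS/s receive rate), which keeps spectra tractable
on one CPU while preserving a dense 3D Lissajous; the divider family is a
configuration choice, not a physical constant.

**Hyperthermia AMF.** A single-axis 715 kHz field along X (10 mT nominal,
11.2 mT at 600 W). Spatial variation is modelled as a separable flat-top
raised-cosine envelope per axis: flat to ±4 mm and zero at ±12 mm along the
bore (heating becomes ineffective beyond ~±8 mm in X), flat to ±9 mm and
zero at ±16 mm transversally (the full ±8 mm sample grid in Y/Z is heated
effectively). The vendor-style homogeneity triple is carried as metadata
but not reproduced by the envelope: a smooth separable profile cannot
simultaneously match a sub-10% field deviation over a 22.5 mm box and a
heating cutoff at 8 mm, and the heating behaviour is the observable this
package must reproduce. Power deposition scales with the envelope squared.

## Nanoparticle physics

Each catalog entry (ten commercial SPION products, keyed by name and
product code) is described by a log-normal core-size number distribution
(median = midpoint of the vendor's size range, shape 0.1), a hydrodynamic
diameter, and effective magnetic parameters. The equilibrium response is
the size-weighted Langevin magnetization with ξ = m(d)·B/(k_B T), evaluated
by 9-node Gauss–Hermite quadrature over log-diameter. Saturation
magnetization (300 kA/m, maghemite-like, with a −2×10⁻³/K linear
temperature coefficient) and the effective uniaxial anisotropy constant set
absolute scales that the underlying bench data cannot pin down; the package
treats orderings and ratios as its meaningful outputs.

**Anisotropy default (K = 1.0 kJ/m³).** The modelled particles are
multicore "nanoflower" composites whose effective anisotropy is far below
bulk magnetocrystalline values. The default places the Néel time of the
~32 nm cores just below the 2πfτ = 1 dissipation resonance of the 715 kHz
AMF. This is the regime the measured heating ordering implies: with equal
core sizes, the starch-coated 90 nm-hydrodynamic product out-heats its
70 nm dextran sibling only on the rising side of the resonance, and both
far out-heat the 22 nm-core product — which is what the bench comparison
shows. A several-kJ/m³ anisotropy would invert that ordering.

**Relaxation.** τ_B = 3ηV_h/(k_B T), τ_N = τ₀·exp(K·V_c/(k_B T)) with
τ₀ = 1 ns, combined harmonically; the exponent is capped (and flagged) at
200 to avoid overflow for deliberately extreme inputs.

**Heating power.** Linear-response (Rosensweig) dissipation
P = π μ₀ χ(H) H² f · x/(1+x²), x = 2πfτ_eff, evaluated per unit iron
concentration. χ(H) is the chord susceptibility χ₀·3L(ξ)/ξ of the size
distribution rather than the strict initial susceptibility: this keeps P
finite and monotone up to saturation at the 10 mT working amplitude and
brings vial heating rates to the right order of magnitude (≈1.4 K/s at
10 mg(Fe)/mL for the strongest product). Absolute temperature rises remain
calibration-dependent and are not asserted anywhere.

**SAR.** The calorimetric formula SAR = c_w·(m_w/m_Fe)·dT/dt with
c_w = 4.168 J/(g K), applied to the initial heating slope.

**MPS.** Zero-gradient spectroscopy Fourier-analyses the equilibrium
magnetization over one drive period. Even harmonics vanish by symmetry;
the A5/A3 ratio grows monotonically with core size across the catalog,
reproducing the usual resolution-quality ranking.

## Imaging chain

**Signal model.** During acquisition every voxel sees the offset field
G·(r − r_FFR(t)); three ideal orthogonal receive channels pick up dM/dt.
Spectra live on the comb k/T_repetition up to the 1.25 MHz Nyquist of the
2.5 MS/s receive chain; the DC bin and the three drive fundamentals
(feedthrough) are excluded from reconstruction.

**Temperature response of the signal.** Within the imaging chain the
equilibrium waveform is evaluated at the reference temperature and all
temperature dependence is carried by a two-state activation factor applied
per harmonic:

    H(ω, T) = f(T) + (1 − f(T)) · exp(−iω t_rev)

A fraction f(T) of cores is mobile and follows the drive
quasi-instantaneously; the remaining hindered cores switch hysteretically
and lag by the reversal delay t_rev = 5 µs — the characteristic
threshold-crossing delay of thermally blocked switching under a ~25 kHz
sinusoidal drive (a phase lag of ~45° at the fundamental corresponds to a
~10 mT switching field at 14 mT amplitude). f is linear in temperature
across an activation window of 22–46 °C, chosen to span the platform's
operating range, and clipped outside it. Two consequences drive the
design: the spectrum is an *affine* function of temperature inside the
window — exactly the signal–temperature linearity the multi-contrast
method assumes — and the hindered state's frequency-wrapping phase gives
the hot and cold calibration responses a large mutual angle, so the
two-channel unmixing is well-conditioned for the fixed 15-sweep
reconstruction. The equilibrium operations (`magnetization`, MPS) retain
their explicit ξ(T) and Ms(T) dependence; the residual ~2% temperature
variation of the equilibrium factor over the calibration range is absorbed
into the activation response. The activation parameters are effective
quantities calibrated so that the twin's hot/cold channel separability
matches what the platform's demonstrated thermometry implies; they are not
first-principles constants.

**System matrices.** Simulated delta-sample calibration: one column per
voxel at a stated bath temperature and calibration concentration
(5 mg(Fe)/mL default). Voxels outside the drive FOV around the current
focus shift give zero columns and are flagged. Per-row SNR is the peak
column amplitude over the effective noise level (σ/√averages); a noiseless
build reports infinite SNR. Matrices store to HDF5.

**Reconstruction.** Rows are filtered to SNR ≥ threshold and
f ≤ border frequency (defaults 10 and 0.625 MHz), whitened to unit energy
(the standard SNR-type row weighting), and processed in fixed descending
SNR order by regularized Kaczmarz with the augmented-variable Tikhonov
update; λ = (relative regularization)·(mean row energy of the whitened
system), default 0.01, 15 sweeps, optional nonnegativity projection per
sweep. Multi-contrast reconstruction stacks the hot and cold matrices
horizontally and unmixes per-voxel channel weights; maps are scaled to
mg(Fe)/mL by the calibration concentration.

**Thermometry.** T = (c_hot·T_hot + c_cold·T_cold)/(c_hot + c_cold) on
voxels whose total concentration reaches 10% of the map maximum, clipped
to the calibration range. On the 9×9×3 desk grid the fixed points
reconstruct to 44.9 °C and 23.1 °C and a 25→43 °C ramp is recovered
strictly monotonically with ≤ 0.5 K error.

Sessions image a single-patch FOV (28×28×14 mm) that contains the
three-vial row used in the interleaved experiments; focus-field
multi-patch stitching over a larger FOV is out of scope.

## Heat transport

**Deposition.** q(r) = P_vol(c(r)) · S(|G·r + b|) · envelope(r)², where
the suppression factor S is the normalized differential susceptibility
dL/dξ of the tracer at the local static offset — a smooth, parameter-free
localization kernel that reproduces finite PSF tails, chosen over a hard
saturation cutoff. With the selection field off (global mode) S ≡ 1.

**Diffusion.** Conservative explicit finite differences (forward-time,
central-space) with harmonic-mean face conductivities, Robin surface
losses h·(T − T_ambient), and optional upwind plug-flow advection along Y.
Air voxels are convection-dominated and pinned at ambient, coupling to
media through h only; resolving conduction in air would shrink the stable
step ~100× for no visible effect at these scales. The step is checked
against the stability bound (violations raise, naming the maximal
admissible dt); `run_heating` auto-chooses 0.4× the bound. Insulated runs
conserve enthalpy to rounding; a point release spreads with the exact
diffusive variance 2αt of the discrete scheme.

Media: water (ρ = 1 g/mL, c = 4.168 J/gK, k = 0.6 W/mK), agarose
(water-like, k = 0.55), glass, silicone. Vial phantoms default to an
effective surface-loss coefficient of 200 W/m²K, lumping the forced bore
airflow and holder conduction implied by the bench plateau temperatures;
dishes and tubing use smaller values (10 and 30 W/m²K).

**Heating PSF.** A point calibration vial (27 µL) is stepped from the FFR
along each axis (1 mm in X/Y, 0.5 mm in Z) and heated for a 30 s dwell;
each position is simulated with a lumped-capacitance vial model (uniform
vial temperature with Robin loss — the appropriate model for a vial in
air, and the quantity is threshold-based so the lumped constants cancel).
The half-extent is the largest offset whose rise still reaches the
threshold. With gradients (1.25, 1.25, 2.5) T/m and the threshold
calibrated to a 5 mm transverse half-extent, the axial half-extent is
2.5 mm — the steeper Z gradient confines heating roughly in proportion to
the gradient ratio. An `include_envelope=False` switch exposes the pure
1/gradient scaling under an idealized uniform AMF.

**Flow loop.** The closed 375 cm loop is solved in 1D (periodic
advection–diffusion, upwind, wall losses), with deposition only where the
AMF envelope overlaps the in-bore segment. The temperature rise is
strictly decreasing in velocity; v = 0 reduces to static heating of the
segment. The characterised loop's rate↔velocity pairs are mutually
inconsistent with the nominal 0.2 mm inner bore; `FlowSpec` keeps both
numbers, treats velocity as authoritative, and surfaces the discrepancy in
`consistency_note` rather than resolving it.

## Session control

`SessionPlan` compiles an explicit timeline of alternating MFH and MPI
windows (defaults 5 s + 1.1 s per cycle); AMF-on and acquisition windows
never overlap by construction, and the spacing of reconstructed-temperature
timestamps equals the configured cycle duration — all session durations are
derived from configuration, never hard-coded. Each cycle: focus the FFR on
the cycle's target, deposit heat while the PDE advances, switch the AMF
off, acquire, reconstruct hot/cold channels, log per-ROI reconstructed and
ground-truth temperatures (fixed 3 mm spheres at the known vial centers),
and store a camera frame. One session seed governs all noise.
`mfh_walk` runs MFH-only dwells over a target list (positions or a
gradient-off "global" step) and logs the camera hot-spot per frame
interval; on the agarose dish a circular walk's hot spots trace the
commanded angular order.

## Thermal camera emulator

Maximum-intensity projection along the line of sight (X default),
nearest-neighbour resampling to the 0.308 mm pixel pitch, quantization to
20 mK. Nearest resampling preserves the frame maximum to within one
quantization step. Optics and emissivity are not modelled.

## Phantoms and what the synthetic data can show

Generators produce the 3×3 vial grid (±8 mm spacing in Y/Z, 140 µL fills,
glass tubes along X), the Ø50×5 mm agarose dish facing the camera, and the
in-bore tubing segment of the circulation loop; all carry concentration and
medium-label volumes plus geometry metadata, validate their invariants, and
round-trip through HDF5 bit-identically.

The synthetic experiments emulate the geometry, field configuration,
timing, and noise structure of the bench protocols. They do not emulate:
absolute heating magnitudes (effective magnetic constants are not
published), hardware transfer functions and filtering, emissivity and
optics of the camera, particle–particle interaction effects at high
concentration (the measured SAR plateau has no stated mechanism and is not
modelled), or motion artefacts in the flow phantom. Passing tests
therefore demonstrate internal consistency of the simulated instrument and
correct relative behaviour (orderings, scalings, localization, unmixing) —
not quantitative prediction of bench temperatures.

## Numerical choices

- Langevin function and derivative switch to series below |ξ| = 10⁻⁴;
  L(ξ)/ξ is evaluated stably through the same series.
- Spectra are computed on exactly one repetition period (integral number of
  samples enforced), so the Fourier comb is exact; even-harmonic leakage in
  MPS is < 10⁻¹⁰ of the fundamental.
- Kaczmarz is deterministic: fixed descending-SNR row order, stable sort.
- Degenerate inputs raise informative errors (zero gradient components,
  unreachable targets, mismatched grids, empty row selections, unstable
  time steps).
- Desk-scale problem sizes: 9×9×3 imaging grids for thermometry studies,
  7×7×3 for session tests, 1 mm isotropic phantom grids (0.5 mm steps only
  along Z in PSF scans). These are the package's default study sizes;
  larger grids are configuration, not code, changes.

## Known limitations

- The activation-window temperature response saturates outside 22–46 °C;
  thermometry above the hot calibration clips to the calibration range.
- Single-patch imaging only; vials outside the drive FOV need their own
  session plan.
- Plug flow ignores radial profiles in the 0.2–2 mm tubing bore.
- The heating and imaging responses share the equilibrium Langevin core but
  use separate effective relaxation descriptions (scalar Néel–Brown time
  for dissipation, activation/delay for the receive chain); they are
  calibrated to different observables and should not be cross-interpreted.
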