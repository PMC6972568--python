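# Methods

## Scope

`swigpc` implements a fully synthetic pipeline for sector-wise golden-angle
(SWIG) radial phase-contrast imaging of cardiac velocities: trajectory
generation, acquisition simulation, retrospective sliding-window
reconstruction with shared velocity encoding, sampling-quality metrics, and
velocimetry. Everything runs on a single CPU at matrix 64; no scanner data,
pulse-sequence hardware modeling, or clinical statistics are involved.

## Trajectory model

Spokes are full diameters, angles on [0, π). The SWIG recurrence applies a
golden-section division (fraction (√5−1)/2 in double precision) inside the
current heartbeat's sector of width π/N, with the within-sector offset
carried continuously across beats; heartbeat s occupies sector
[s·π/N, (s+1)·π/N) exactly. Design choices:

- φ0 = 0 by default, configurable within the first sector.
- Sectors are indexed s = 0..N−1 (N sectors for N planned beats). With the
  first beat later discarded for steady state, sector 0 remains empty in
  every reconstruction window; see "Known limitations".
- Spokes per beat = floor(RR/TR); the trailing partial TR acquires nothing.
- Velocity-encoding signs alternate +1, −1 over the *global* spoke index,
  uninterrupted at beat boundaries.
- Within one sector the angle gaps obey the three-gap theorem for golden
  rotations: at most three distinct gaps, max/min ≤ φ² ≈ 2.618 (not 2; the
  tighter bound holds only at Fibonacci spoke counts).

The conventional golden-angle comparator uses the same beat structure and
sign alternation but increments the angle by π·(√5−1)/2 mod π continuously.

## k-space conventions

Normalized coordinates, cycles/pixel, |k| ≤ 0.5. Even readout lengths use
the half-sample convention k_j = (j − readout/2 + 0.5)/readout (no exact DC
sample); odd lengths include DC. Readout samples default to the matrix size
(no zero-filling). Consequence: the radial replica ring of the discrete
readout sits at exactly one FOV from the PSF center; numerical-oracle tests
that need a cleaner gridding inverse oversample the readout 2× via the
protocol's `readout_samples` override.

## Synthetic acquisition

**Phantom.** Ordered regions (disk / annulus / ellipse) with painter's-
algorithm occlusion, rasterized with 8× anti-aliasing into per-region
weight maps. Each region carries a constant magnitude and one periodic
velocity waveform (sum of Gaussian peaks in cardiac phase), so the k-space
of any frame factorizes into static per-region transforms times a scalar
encoding phase per spoke — the sampler evaluates every spoke at its exact
acquisition time, and temporal-footprint blurring emerges naturally in the
reconstruction rather than being imposed.

Default phantom (all values configurable): static chest-wall ellipse
(130×100 mm, magnitude 1.0); myocardial annulus (outer 35 mm, inner 25 mm,
magnitude 0.8) with s′ = +8 cm/s at phase 0.15, e′ = −9 cm/s at 0.55,
a′ = −10 cm/s at 0.85, Gaussian width 0.04 of the cycle; transmitral
inflow disk (radius 12 mm, magnitude 1.5) with E = 60 cm/s at 0.55 and
A = 51 cm/s at 0.85. Peak amplitudes sit at the in-vivo MR group means for
these quantities; the tissue VENC is 30 cm/s and the inflow protocol
variant uses VENC 150 cm/s, TR 6.6 ms.

**Velocity-to-phase convention.** Each encoding contributes
±(π/2)·v/VENC of image phase, so the subtracted phase spans π at v = VENC.

**RR intervals** are i.i.d. Gaussian (mean 60000/HR ms, configurable SD,
truncated at ±3 SD); defaults 67 bpm and SD 17 ms (20 ms in the uniformity
analyses), matching the reported in-vivo medians.

**Coils.** Gaussian-profile magnitudes centered on a ring around the FOV,
gentle linear phases; noise covariance Ψ with unit diagonal and constant
off-diagonal ρ (default 8 coils, ρ = 0.3). k-space noise is complex
circular Gaussian with covariance noise_sd²·Ψ.

**Backends.** `raster-nufft` (any phantom) and `analytic` (closed-form
jinc/ellipse transforms; requires non-overlapping regions and spatially
constant coil maps). The two agree to <1% relative L2 on a static disk at
matrix 64 — the rasterization error budget.

## Reconstruction

- **Pre-whitening**: inverse lower Cholesky factor of Ψ across coils.
- **Coil maps**: Walsh-style adaptive estimation — per-pixel dominant
  eigenvector of the 5×5-box-smoothed coil covariance of the all-spokes
  time-averaged gridding image, unit-norm per pixel, phase referenced to
  coil 0.
- **NUFFT**: Kaiser-Bessel gridding, oversampling 2, kernel width 4,
  Beatty β; implemented as (apodization correction) ∘ (zero-padded FFT) ∘
  (sparse interpolation matrix). Forward accuracy ~6·10⁻⁴ relative against
  the direct Fourier sum; the adjoint is the exact conjugate transpose
  (dot-product test at machine precision), which CG-SENSE requires.
- **Density compensation**: ramp |k| scaled to annular cell areas
  (π|k|Δk/n_spokes; the central disk area for an exact-DC sample), so the
  compensated adjoint approximates the inverse Fourier integral on the
  image's own scale.
- **CG-SENSE**: conjugate gradients on the density-weighted normal
  equations, zero initial image, defaults 15 iterations / tol 10⁻⁶.
  Residual 2-norms oscillate transiently on these operators (condition
  numbers 10³–10⁴ from the weakly sampled corner frequencies), so
  divergence is judged on the final residual level only; the error
  decreases monotonically in the operator energy norm, and the solution
  matches a dense weighted-least-squares oracle to <10⁻³ on small problems.
- **Phase subtraction**: always through the complex product
  atan2(Im Z₁Z₂*, Re Z₁Z₂*) — never by differencing separate phases — so
  the ±π boundary cannot cancel; v = VENC·Δφ/π.
- Per-frame undersampling is reported as R = (π/2·matrix)/spokes per
  encoding (R ≈ 2.8 for 36 spokes at matrix 64).

### Gridding vs CG-SENSE in the footprint sweep

The peak-velocity-versus-footprint analysis uses the gridding
reconstruction. CG-SENSE at a fixed iteration count has a convergence state
that depends on the undersampling factor, which varies with the footprint;
at footprint 4 (R ≈ 4.2) the partially converged CG estimate under- or
over-shoots the peak depending on iterations and coil count, confounding
the temporal attenuation under study. Gridding has no such knob: its
temporal response is set purely by the window, and the measured e′ declines
monotonically from footprint 4 to 16 while footprint 6 recovers the
configured amplitude within a few percent. The CG-SENSE path is validated
separately (fp 6, 10 iterations: e′ within ~3% of truth).

## Sampling metrics

PSF = density-compensated adjoint gridding of unitary k-space on a 2×
oversampled image grid, normalized to unit central peak; aliasing energy
(sum of squares) and peak |PSF| are read on 128 concentric circles (720
bilinear samples each) out to one full FOV. Uniformity = population SD of
adjacent sorted-angle gaps (wrap gap included) over the spokes of one
frame window, both encodings pooled (the physical aliasing is set by all
acquired angles; a per-encoding mode exists). The radial replica ring at
exactly 1.0 FOV (readout = matrix) is common to both orderings and is
excluded from sidelobe-level assertions but retained in profiles.

## Velocimetry

Quadratic eddy-current-style background phase is removed by least-squares
fitting a + bx + cy + dx² + exy + fy² to the time-averaged velocity on a
static-tissue mask and subtracting the surface globally (an exact
projection for any quadratic field; ≥6 mask pixels required). Temporal
unwrapping corrects frame-to-frame jumps >VENC in steps of 2·VENC with the
first frame as reference, returning a wrap-count audit map. The
Doppler-mimicking voxel is the mask voxel with the highest |v| over the
cycle (row-major tie-break). Peaks are raw-curve extrema inside fixed
cardiac-phase windows — systole [0, 0.4), early diastole [0.4, 0.75), late
diastole [0.75, 1.0), configurable; diastolic tissue peaks are reported
sign-switched. E/e′ uses the mean of septal and lateral e′ (single-wall
use is flagged); Bland-Altman agreement uses bias ± 1.96·SD.

## What the generator does and does not emulate

It emulates: sector-confined golden-angle ordering with on-the-fly beat
switching, beat-to-beat RR variability, per-spoke cardiac dynamics,
multi-coil sensitivity and correlated noise, velocity aliasing beyond
VENC, and (by injection) quadratic background phase. It does **not**
emulate: in-plane motion or myocardial deformation, spatially varying
velocity profiles within a region, off-resonance, relaxation during the
readout, gradient imperfections or real eddy-current physics, or
respiratory drift. A green end-to-end test therefore establishes the
correctness of the sampling/binning/reconstruction chain for rigid
through-plane motion — not robustness to the omitted effects.

## Known limitations

- With sectors s = 0..N−1 and the steady-state beat discarded, sector 0 is
  empty in every window; the adjacent-gap SD of a 72-spoke frame is then
  bounded below by ≈0.023 rad regardless of how uniform the filled sectors
  are. An acquisition scheme in which an (N+1)-th beat refills the first
  sector (mod π) would remove this floor; it is not part of the present
  trajectory definition.
- The conventional golden-angle comparator, binned with the same
  per-beat nearest-neighbor windows, is only mildly less uniform than SWIG
  in gap-SD terms (though consistently worse in PSF aliasing energy and
  peak). Comparators whose angle counter resets at each R-wave cluster far
  more severely; such a variant is not implemented.
- Gridding accuracy at readout = matrix is limited by the replica ring at
  one FOV and by ramp-DCF quadrature near DC (few-percent shading on
  extended objects); CG-SENSE, which inverts the true operator, is the
  quantitative reference.
- Spatial phase unwrapping, arrhythmia rejection, nonlinear heartbeat
  scaling and GPU execution are out of scope.
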