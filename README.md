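# swigpc — sector-wise golden-angle radial phase-contrast MRI

`swigpc` is a desk-scale toolkit for **sector-wise golden-angle (SWIG)
radial phase-contrast CMR**: it generates SWIG and conventional
golden-angle spoke orderings, simulates multi-coil radial acquisitions of a
digital cardiac phantom with through-plane velocity encoding, performs
retrospective sliding-window reconstruction with shared velocity encoding
(gridding or CG-SENSE), quantifies sampling quality (PSF aliasing profiles,
angular-gap uniformity), and extracts diastolic-function parameters
(s′, e′, a′, E, A, E/A, E/e′) from the reconstructed velocity series.

It is aimed at MRI methods researchers who want a reproducible, fully
synthetic testbed for golden-angle phase-contrast sampling strategies —
no scanner data required.

## The method in brief

**Trajectory.** k-space is divided into one angular sector per heartbeat
(*N* sectors of width π/*N*), and spoke angles follow a golden-section
division of the current sector:

    φ_{n+1} = mod(φ_n + (π/N)·(√5−1)/2, π/N) + s·π/N

where *s* is the current heartbeat. Each sector is filled by exactly one
beat, so retrospective cardiac binning never mixes beats within a sector
and the resorted spokes stay near-uniform for any window length. The
conventional comparator applies the increment π·(√5−1)/2 mod π
continuously.

**Velocity encoding.** Encodings with ±M1 alternate every TR
(phase contribution ±(π/2)·v/VENC per encoding). Sliding windows centered
on each cardiac phase pair the two encodings ("shared velocity encoding"),
so a phase-subtracted frame exists every TR:

    Δφ = atan2(Im(Z₁·Z₂*), Re(Z₁·Z₂*)),     v = VENC · Δφ / π

**Temporal resolution** is reported as *temporal footprint* (spokes per
beat entering one frame) and *temporal increment* (1 TR). With the default
protocol (TR 6.8 ms, 13 heartbeats, matrix 64, FOV 320 mm, VENC 30 cm/s)
a footprint of 6 TRs is a 40.8 ms window and, after discarding the
steady-state beat, 36 spokes per encoding per frame — an undersampling
factor R ≈ 2.8 versus the radial Nyquist limit (π/2·64 spokes).

## Worked example

```python
import numpy as np
from swigpc import (ProtocolParams, default_phantom, simulate_rr,
                    make_coil_model, swig_angles, sample_spokes,
                    discard_steady_state, assign_frames, reconstruct_series,
                    auto_select_voxel, detect_peaks, extract_curve)

proto = ProtocolParams()                      # TR 6.8 ms, VENC 30 cm/s, 13 beats
phantom = default_phantom()                   # chest wall + myocardium + inflow
rr = simulate_rr(13, median_hr=67, sd_rr=17, seed=5)
coil = make_coil_model(n_coils=4, matrix=64, seed=6)
sched = swig_angles(13, rr, proto.tr)
raw = sample_spokes(phantom, sched, rr, proto, coil)

ret = discard_steady_state(raw)
frames = assign_frames(ret, footprint_tr=6, increment_tr=1)
series = reconstruct_series(ret, frames, method="cgsense", n_iter=10)

mask = phantom.rasterize(64, 320.0)[1] > 0.99          # myocardial annulus
voxel, _ = auto_select_voxel(series, mask)
print(frames.n_frames, frames.spokes_per_encoding)
print(detect_peaks(extract_curve(series, voxel), "tissue"))
```

Output:

```
128 36
{'flags': [], 's_prime': 7.850245816265058,
 'e_prime': 9.228087138268254, 'a_prime': 10.075901799502976}
```

128 frames were reconstructed (shortest retained beat / TR), each from 36
spokes per encoding. The phantom's configured tissue peaks are s′ = 8,
e′ = 9, a′ = 10 cm/s; at the 40.8 ms footprint the single-voxel readout
recovers them within a few percent, with the residual deviation set by
temporal smoothing, partial-volume effects at the 5 mm pixel size and
undersampling artifacts.

A command-line pipeline covers the same chain
(`swigpc simulate | bin | reconstruct | psf | analyze | run`); see
`swigpc --help`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
simulates 20 seeded 13-beat acquisitions (67 bpm, RR SD 20 ms), discards
the steady-state beat, bins with footprint 6 / increment 1, and recomputes
the mean per-frame standard deviation of adjacent spoke-angle gaps for the
SWIG ordering and for the conventional golden-angle ordering under the
identical resorting, writing both values (radians) as JSON.

## Documentation

`docs/methods.md` describes the simulation model, the reconstruction and
its numerical choices, what the synthetic phantom does and does not
emulate, and known limitations.
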