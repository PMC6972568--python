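"""Sampling-quality metrics: point-spread function of a spoke set and the
adjacent-angle-gap uniformity statistic.

The PSF is obtained by gridding a unitary k-space (all samples = 1) on the
acquired spoke angles with the same ramp density compensation used for
reconstruction, on a 2x oversampled image grid so sidelobes out to the full
FOV are resolved. Aliasing is summarized on concentric circles: the sum of
squared PSF values (aliasing energy) and the maximum (peak PSF) per radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage

from .nufft import NufftOperator2D, radial_dcf
from .trajectory import spoke_coordinates


@dataclass
class PsfProfile:
    """radius (fractions of the FOV) -> (aliasing energy, peak |PSF|),
    normalized so the central peak is 1."""

    radii: np.ndarray
    energy: np.ndarray
    peak: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"radius_fov": self.radii, "energy": self.energy, "peak": self.peak}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def mean_energy(self, lo: float = 0.1, hi: float = 1.0) -> float:
        sel = (self.radii >= lo) & (self.radii <= hi)
        return float(self.energy[sel].mean())

    def mean_peak(self, lo: float = 0.1, hi: float = 1.0) -> float:
        sel = (self.radii >= lo) & (self.radii <= hi)
        return float(self.peak[sel].mean())


def psf(angles: np.ndarray, matrix: int, oversample: int = 2,
        readout: int | None = None) -> np.ndarray:
    """PSF of a spoke set: density-compensated adjoint gridding of all-ones
    samples, on an (oversample*matrix)^2 grid, normalized to unit central
    peak. Pixel size equals the acquisition pixel, so the image spans
    ``oversample`` FOVs."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if readout is None:
        readout = matrix
    coords = spoke_coordinates(angles, readout, matrix).reshape(-1, 2)
    side = oversample * matrix
    op = NufftOperator2D(coords, side)
    dcf = radial_dcf(coords, angles.size, readout)
    img = op.adjoint(np.ones(coords.shape[0], dtype=complex) * dcf)
    center = img[side // 2, side // 2]
    return img / center


def psf_radial_profile(psf_img: np.ndarray, n_radii: int = 128,
                       samples_per_circle: int = 720,
                       matrix: int | None = None) -> PsfProfile:
    """Resample |PSF| on concentric circles (bilinear) out to one full FOV.

    ``matrix`` is the acquisition matrix (defaults to side/2, i.e. PSF grid
    oversampled by 2); radius 1.0 then corresponds to the full FOV.
    """
    side = psf_img.shape[0]
    if matrix is None:
        matrix = side // 2
    c = side // 2
    radii = np.linspace(0.0, 1.0, n_radii)
    th = np.linspace(0.0, 2.0 * np.pi, samples_per_circle, endpoint=False)
    mag = np.abs(psf_img)
    energy = np.empty(n_radii)
    peak = np.empty(n_radii)
    for i, r in enumerate(radii):
        rx = c + r * matrix * np.cos(th)
        ry = c + r * matrix * np.sin(th)
        vals = scipy.ndimage.map_coordinates(mag, [rx, ry], order=1, mode="grid-wrap")
        energy[i] = float(np.sum(vals**2))
        peak[i] = float(vals.max())
    return PsfProfile(radii=radii, energy=energy, peak=peak)


def angular_gap_sd(angles: np.ndarray) -> float:
    """Population SD of the gaps between adjacent spoke angles on [0, pi),
    including the wrap-around gap. Zero iff the spokes are equiangular.
    Duplicate angles contribute zero gaps."""
    a = np.sort(np.mod(np.asarray(angles, dtype=float), np.pi))
    if a.size < 2:
        raise ValueError("need at least two spokes")
    gaps = np.diff(a)
    wrap = np.pi - a[-1] + a[0]
    gaps = np.append(gaps, wrap)
    return float(np.std(gaps))


def frame_gap_sd(raw, frames, pooled: bool = True) -> np.ndarray:
    """Adjacent-angle-gap SD for every frame window of an assignment.

    By default the +/- encodings of a window are pooled (the physical
    aliasing pattern is set by all acquired angles in the window); with
    ``pooled=False`` the SD is averaged over the two encodings separately.
    """
    ang = raw.schedule.angle
    out = np.empty(frames.n_frames)
    for f in range(frames.n_frames):
        if pooled:
            out[f] = angular_gap_sd(ang[frames.indices[f].ravel()])
        else:
            out[f] = np.mean(
                [angular_gap_sd(ang[frames.indices[f, si]]) for si in (0, 1)]
            )
    return out
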