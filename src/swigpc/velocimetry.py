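"""Velocity post-processing: quadratic eddy-current phase correction,
temporal unwrapping, Doppler-mimicking single-voxel selection, time-velocity
curves, peak detection (s', e', a', E, A) and derived diastolic indices.

Residual eddy-current phase after subtraction varies slowly in space and is
modeled as a full 2-D quadratic polynomial fitted on static tissue and
subtracted globally. Peak detection mimics pulsed-wave Doppler reading:
the extremum of the raw curve inside fixed cardiac-phase windows, with
diastolic tissue peaks reported sign-switched (e', a' positive numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import InvalidProtocolError
from .recon import VelocitySeries

#: Cardiac-phase windows (fractions of the cycle) for peak search.
DEFAULT_WINDOWS = {
    "systole": (0.0, 0.4),
    "early_diastole": (0.4, 0.75),
    "late_diastole": (0.75, 1.0),
}


@dataclass
class VelocityCurve:
    """Single-voxel time-velocity curve on the common cardiac-phase axis."""

    phases: np.ndarray  # cardiac-phase fractions, one per frame
    velocity: np.ndarray  # cm/s
    voxel: tuple | None = None
    roi_label: str | None = None  # septal | lateral | mitral | ...

    def __post_init__(self):
        if len(self.phases) != len(self.velocity):
            raise InvalidProtocolError("curve axes must have equal length")

    def to_dataframe(self, rr_ms: float | None = None) -> pd.DataFrame:
        d = {"phase": self.phases, "velocity_cm_s": self.velocity}
        if rr_ms is not None:
            d["time_ms"] = self.phases * rr_ms
        return pd.DataFrame(d)


@dataclass
class DiastolicReport:
    """Diastolic-function summary. Tissue peaks are per wall; e' used for
    E/e' is the mean of septal and lateral when both exist."""

    s_prime: dict = field(default_factory=dict)  # wall -> cm/s
    e_prime: dict = field(default_factory=dict)
    a_prime: dict = field(default_factory=dict)
    E: float | None = None
    A: float | None = None
    E_over_A: float | None = None
    E_over_e_prime: float | None = None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "s_prime": self.s_prime,
            "e_prime": self.e_prime,
            "a_prime": self.a_prime,
            "E": self.E,
            "A": self.A,
            "E_over_A": self.E_over_A,
            "E_over_e_prime": self.E_over_e_prime,
            "flags": self.flags,
        }


# ----------------------------------------------------------- phase correction
def _quad_design(shape: tuple) -> np.ndarray:
    m, n = shape
    x = np.arange(m) - m // 2
    y = np.arange(n) - n // 2
    X, Y = np.meshgrid(x, y, indexing="ij")
    return np.stack(
        [np.ones_like(X), X, Y, X**2, X * Y, Y**2], axis=-1
    ).astype(float)


def quadratic_phase_correction(series: VelocitySeries, static_mask: np.ndarray):
    """Fit a + bx + cy + dx^2 + exy + fy^2 to the time-averaged velocity on
    the static-tissue mask and subtract the fitted surface from every frame.

    Exact for any quadratic background, so applying it twice equals applying
    it once (projection). Returns (corrected_series, coefficients).
    """
    mask = np.asarray(static_mask, dtype=bool)
    if mask.sum() < 6:
        raise InvalidProtocolError(
            f"static mask has {int(mask.sum())} pixels; the quadratic fit needs >= 6"
        )
    if mask.shape != series.velocity.shape[1:]:
        raise InvalidProtocolError("mask shape must match the velocity maps")
    vbar = series.velocity.mean(axis=0)
    A = _quad_design(mask.shape)
    coef, *_ = np.linalg.lstsq(A[mask], vbar[mask], rcond=None)
    surface = A @ coef
    return (
        VelocitySeries(
            velocity=series.velocity - surface[None],
            phases=series.phases,
            venc=series.venc,
            magnitude=series.magnitude,
            undersampling=series.undersampling,
        ),
        coef,
    )


# ---------------------------------------------------------------- unwrapping
def unwrap_temporal(series: VelocitySeries, venc: float | None = None):
    """Per-voxel temporal phase unwrapping with the first frame as
    reference: frame-to-frame velocity jumps larger than VENC (phase jumps
    larger than pi) are removed in steps of 2*VENC.

    Returns (unwrapped_series, wrap_count_map) where the map counts net
    wraps per voxel for audit.
    """
    if venc is None:
        venc = series.venc
    v = series.velocity
    d = np.diff(v, axis=0)
    steps = np.round(d / (2.0 * venc))
    corr = np.zeros_like(v)
    corr[1:] = -2.0 * venc * np.cumsum(steps, axis=0)
    wraps = np.sum(np.abs(steps), axis=0).astype(int)
    return (
        VelocitySeries(
            velocity=v + corr,
            phases=series.phases,
            venc=series.venc,
            magnitude=series.magnitude,
            undersampling=series.undersampling,
        ),
        wraps,
    )


# ------------------------------------------------------------- voxel / peaks
def auto_select_voxel(series: VelocitySeries, roi_mask: np.ndarray):
    """Doppler-mimicking single-voxel ROI: the voxel inside the mask with
    the highest absolute velocity over the cycle. Ties break row-major.

    Returns ((i, j), flags) — flags contains 'all-zero-roi' when the ROI
    carries no velocity at all (first masked voxel returned).
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise InvalidProtocolError("ROI mask is empty")
    vmax = np.max(np.abs(series.velocity), axis=0)
    flags = []
    if np.all(vmax[mask] == 0):
        flags.append("all-zero-roi")
        ij = tuple(np.argwhere(mask)[0])
        return ij, flags
    score = np.where(mask, vmax, -np.inf)
    flat = int(np.argmax(score))  # first max in row-major order
    return np.unravel_index(flat, score.shape), flags


def extract_curve(series: VelocitySeries, voxel: tuple,
                  roi_label: str | None = None) -> VelocityCurve:
    return VelocityCurve(
        phases=series.phases.copy(),
        velocity=series.velocity[:, voxel[0], voxel[1]].copy(),
        voxel=tuple(int(c) for c in voxel),
        roi_label=roi_label,
    )


def _window_extremum(phases, velocity, lo, hi, which):
    sel = (phases >= lo) & (phases < hi)
    if not sel.any():
        return None
    v = velocity[sel]
    return float(v.max() if which == "max" else v.min())


def detect_peaks(curve: VelocityCurve, mode: str,
                 windows: dict | None = None) -> dict:
    """Named peaks from a single-voxel curve.

    tissue mode: s' = max v in the systolic window; e', a' = |min v| in the
    early/late diastolic windows (sign switched, as Doppler reports them).
    inflow mode: E, A = max v in the early/late windows. Peaks are raw-curve
    extrema (no fitting). Windows without samples yield a missing-peak flag.
    """
    if mode not in ("tissue", "inflow"):
        raise InvalidProtocolError(f"unknown mode {mode!r}")
    w = DEFAULT_WINDOWS if windows is None else windows
    p, v = np.asarray(curve.phases), np.asarray(curve.velocity)
    flags = []
    if np.all(v == 0):
        flags.append("low-confidence: all-zero curve")
    out = {"flags": flags}
    if mode == "tissue":
        s = _window_extremum(p, v, *w["systole"], "max")
        e = _window_extremum(p, v, *w["early_diastole"], "min")
        a = _window_extremum(p, v, *w["late_diastole"], "min")
        for name, val, sign in (("s_prime", s, 1), ("e_prime", e, -1),
                                ("a_prime", a, -1)):
            if val is None:
                flags.append(f"missing-peak: {name}")
            else:
                out[name] = sign * val
    else:
        E = _window_extremum(p, v, *w["early_diastole"], "max")
        A = _window_extremum(p, v, *w["late_diastole"], "max")
        for name, val in (("E", E), ("A", A)):
            if val is None:
                flags.append(f"missing-peak: {name}")
            else:
                out[name] = val
    return out


def diastolic_report(tissue_peaks: dict | None = None,
                     inflow_peaks: dict | None = None) -> DiastolicReport:
    """Combine per-ROI peaks into the diastolic indices.

    ``tissue_peaks`` maps wall label ('septal'/'lateral') to a detect_peaks
    result; ``inflow_peaks`` is a single inflow result. E/e' divides E by
    the mean of septal and lateral e' (single-wall fallback is flagged);
    E/A = E / A. Missing inputs leave fields absent — never silently
    substituted. Zero denominators yield an 'undefined' flag.
    """
    rep = DiastolicReport()
    tissue_peaks = tissue_peaks or {}
    for wall, peaks in tissue_peaks.items():
        for name, store in (("s_prime", rep.s_prime), ("e_prime", rep.e_prime),
                            ("a_prime", rep.a_prime)):
            if name in peaks:
                store[wall] = peaks[name]
    if inflow_peaks:
        rep.E = inflow_peaks.get("E")
        rep.A = inflow_peaks.get("A")
    if rep.E is not None and rep.A is not None:
        if rep.A == 0:
            rep.flags.append("undefined: E/A (A = 0)")
        else:
            rep.E_over_A = rep.E / rep.A
    if rep.E is not None and rep.e_prime:
        walls = sorted(rep.e_prime)
        e_mean = float(np.mean([rep.e_prime[wl] for wl in walls]))
        if len(walls) == 1:
            rep.flags.append(f"single-wall e_prime ({walls[0]})")
        if e_mean == 0:
            rep.flags.append("undefined: E/e_prime (e_prime = 0)")
        else:
            rep.E_over_e_prime = rep.E / e_mean
    return rep


def bland_altman(x: np.ndarray, y: np.ndarray) -> dict:
    """Bias and 95% limits of agreement of paired measurements:
    bias = mean(y - x), limits = bias +- 1.96 * SD(y - x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise InvalidProtocolError("bland_altman needs paired arrays of length >= 2")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd": sd,
        "n": int(x.size),
    }
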