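"""Acquisition protocol parameters and RR-interval series."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


class InvalidProtocolError(ValueError):
    """Raised when acquisition parameters violate their physical constraints."""


@dataclass(frozen=True)
class ProtocolParams:
    """Scan-protocol parameters for a single-slice radial phase-contrast
    acquisition.

    Parameters
    ----------
    tr, te : float
        Repetition and echo time in ms; ``tr > te > 0``.
    flip_angle : float
        Excitation flip angle in degrees.
    venc : float
        Velocity (cm/s) that maps to a subtracted phase of pi.
    n_heartbeats : int
        Number of acquired heartbeats (the first is discarded downstream
        to reach magnetization steady state), so at least 2.
    matrix : int
        Image matrix side in pixels.
    fov : float
        Field of view in mm.
    slice_thickness : float
        Slice thickness in mm.
    readout_samples : int or None
        Samples per spoke; defaults to ``matrix`` (no zero-filling).
    """

    tr: float = 6.8
    te: float = 4.4
    flip_angle: float = 8.0
    venc: float = 30.0
    n_heartbeats: int = 13
    matrix: int = 64
    fov: float = 320.0
    slice_thickness: float = 5.0
    readout_samples: int | None = None

    def __post_init__(self):
        if not (self.tr > self.te > 0):
            raise InvalidProtocolError(
                f"require TR > TE > 0, got TR={self.tr}, TE={self.te}"
            )
        if self.venc <= 0:
            raise InvalidProtocolError(f"VENC must be positive, got {self.venc}")
        if self.n_heartbeats < 2:
            raise InvalidProtocolError(
                f"need >= 2 heartbeats (first is discarded), got {self.n_heartbeats}"
            )
        if self.matrix < 8:
            raise InvalidProtocolError(f"matrix must be >= 8, got {self.matrix}")
        if self.readout_samples is None:
            object.__setattr__(self, "readout_samples", self.matrix)
        if self.readout_samples < 2:
            raise InvalidProtocolError("readout_samples must be >= 2")

    @property
    def pixel_mm(self) -> float:
        return self.fov / self.matrix

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolParams":
        return cls(**d)


# Transmitral-flow protocol variant: shorter TE/TR, larger flip and VENC.
TISSUE_PROTOCOL = ProtocolParams(tr=6.8, te=4.4, flip_angle=8.0, venc=30.0)
INFLOW_PROTOCOL = ProtocolParams(tr=6.6, te=4.0, flip_angle=20.0, venc=150.0)


@dataclass(frozen=True)
class RRSeries:
    """A sequence of RR intervals (ms), one per acquired heartbeat."""

    rr_ms: np.ndarray

    def __post_init__(self):
        rr = np.asarray(self.rr_ms, dtype=float)
        if rr.ndim != 1 or rr.size == 0:
            raise InvalidProtocolError("RR series must be a non-empty 1-D array")
        if np.any(rr <= 0) or not np.all(np.isfinite(rr)):
            raise InvalidProtocolError("all RR intervals must be positive and finite")
        object.__setattr__(self, "rr_ms", rr)

    def __len__(self) -> int:
        return self.rr_ms.size

    @property
    def n_beats(self) -> int:
        return self.rr_ms.size

    @property
    def median_hr_bpm(self) -> float:
        """Median heart rate over the series, beats per minute."""
        return float(np.median(60000.0 / self.rr_ms))

    @property
    def sd_ms(self) -> float:
        """Heart-rate variability as the SD of the RR intervals (ms)."""
        return float(np.std(self.rr_ms))

    def spokes_per_beat(self, tr: float) -> np.ndarray:
        """Spokes acquired in each beat: floor(RR/TR); the trailing partial
        TR acquires nothing."""
        if tr <= 0:
            raise InvalidProtocolError(f"TR must be positive, got {tr}")
        return np.floor(self.rr_ms / tr).astype(int)
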