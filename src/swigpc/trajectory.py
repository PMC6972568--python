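"""Radial spoke orderings: sector-wise golden angle (SWIG) and the
conventional golden-angle comparator.

A spoke is a full diameter through the k-space origin, so azimuthal angles
live on [0, pi). SWIG splits that range into one angular sector per
heartbeat and applies the golden-section division inside the current
beat's sector:

    phi_{n+1} = mod(phi_n + (pi/N) * (sqrt(5)-1)/2, pi/N) + s * pi/N

with s the current heartbeat and N the planned number of beats. Because a
sector is filled by exactly one beat, retrospective cardiac binning never
mixes beats inside a sector and the resorted spokes stay near-uniform.
The conventional ordering applies the increment pi*(sqrt(5)-1)/2 mod pi
continuously, ignoring the heartbeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import InvalidProtocolError, RRSeries

#: Golden fraction (sqrt(5)-1)/2 in double precision.
GOLDEN_FRACTION = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class SpokeSchedule:
    """Ordered acquisition plan for one scan.

    Arrays are indexed by the global spoke index ``n`` in acquisition order.

    Attributes
    ----------
    angle : (n_spokes,) float array, radians in [0, pi)
    beat : (n_spokes,) int array, heartbeat index s >= 0
    t_since_R : (n_spokes,) float array, ms from the beat's R-wave
    enc_sign : (n_spokes,) int array, velocity-encoding sign in {+1, -1}
    n_sectors : int, planned beat/sector count N (1 for conventional ordering)
    tr : float, ms
    ordering : str, 'swig' or 'ga'
    """

    angle: np.ndarray
    beat: np.ndarray
    t_since_R: np.ndarray
    enc_sign: np.ndarray
    n_sectors: int
    tr: float
    ordering: str = "swig"

    def __post_init__(self):
        self.angle = np.asarray(self.angle, dtype=float)
        self.beat = np.asarray(self.beat, dtype=int)
        self.t_since_R = np.asarray(self.t_since_R, dtype=float)
        self.enc_sign = np.asarray(self.enc_sign, dtype=int)
        n = self.angle.size
        if not (self.beat.size == self.t_since_R.size == self.enc_sign.size == n):
            raise ValueError("schedule arrays must have equal length")

    @property
    def n_spokes(self) -> int:
        return self.angle.size

    def __len__(self) -> int:
        return self.angle.size

    def subset(self, mask_or_idx) -> "SpokeSchedule":
        return SpokeSchedule(
            angle=self.angle[mask_or_idx],
            beat=self.beat[mask_or_idx],
            t_since_R=self.t_since_R[mask_or_idx],
            enc_sign=self.enc_sign[mask_or_idx],
            n_sectors=self.n_sectors,
            tr=self.tr,
            ordering=self.ordering,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": np.arange(self.n_spokes),
                "s": self.beat,
                "phi": self.angle,
                "t_since_R_ms": self.t_since_R,
                "enc_sign": self.enc_sign,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, n_sectors: int, tr: float, ordering: str = "swig"
    ) -> "SpokeSchedule":
        return cls(
            angle=df["phi"].to_numpy(),
            beat=df["s"].to_numpy(),
            t_since_R=df["t_since_R_ms"].to_numpy(),
            enc_sign=df["enc_sign"].to_numpy(),
            n_sectors=n_sectors,
            tr=tr,
            ordering=ordering,
        )


def _beat_structure(rr: RRSeries, tr: float):
    """Per-beat spoke counts and the flat (beat, t_since_R) arrays."""
    if tr <= 0:
        raise InvalidProtocolError(f"TR must be positive, got {tr}")
    counts = rr.spokes_per_beat(tr)
    if np.any(counts < 1):
        raise InvalidProtocolError("every RR interval must fit at least one TR")
    beat = np.repeat(np.arange(counts.size), counts)
    t = np.concatenate([np.arange(c) * tr for c in counts])
    return counts, beat, t


def swig_angles(
    n_beats: int, rr: RRSeries, tr: float, phi0: float = 0.0
) -> SpokeSchedule:
    """Generate the SWIG spoke schedule for ``n_beats`` heartbeats.

    Heartbeat ``s`` (0-based, s = 0..N-1) contributes ``floor(rr[s]/TR)``
    spokes confined to the angular sector ``[s*pi/N, (s+1)*pi/N)``. The
    within-sector offset follows the golden-section recurrence continuously
    across beats; encoding signs alternate +1, -1, ... over the global index.

    Parameters
    ----------
    n_beats : planned number of heartbeats N (>= 1).
    rr : RR intervals, one per beat (length must equal ``n_beats``).
    tr : repetition time, ms.
    phi0 : first spoke angle, must lie in the first sector [0, pi/N).
    """
    if n_beats < 1:
        raise InvalidProtocolError(f"n_beats must be >= 1, got {n_beats}")
    if len(rr) != n_beats:
        raise InvalidProtocolError(
            f"RR series has {len(rr)} entries, expected {n_beats}"
        )
    sector = np.pi / n_beats
    if not (0.0 <= phi0 < sector):
        raise InvalidProtocolError(
            f"phi0 must lie in the first sector [0, {sector:.6f}), got {phi0}"
        )
    counts, beat, t = _beat_structure(rr, tr)
    n_total = int(counts.sum())
    # Within-sector offsets: f_{n+1} = mod(f_n + sector*g, sector), f_0 = phi0.
    incr = sector * GOLDEN_FRACTION
    offsets = np.mod(phi0 + incr * np.arange(n_total), sector)
    angles = offsets + beat * sector
    sched = SpokeSchedule(
        angle=angles,
        beat=beat,
        t_since_R=t,
        enc_sign=np.ones(n_total, dtype=int),
        n_sectors=n_beats,
        tr=tr,
        ordering="swig",
    )
    return assign_venc_signs(sched, first_sign=+1)


def conventional_golden_angles(
    n_spokes: int | None = None,
    rr: RRSeries | None = None,
    tr: float | None = None,
    phi0: float = 0.0,
) -> SpokeSchedule:
    """Conventional golden-angle ordering: phi_{n+1} = mod(phi_n + pi*g, pi).

    Either pass ``n_spokes`` directly (beats then labelled 0, timestamps in
    multiples of TR if given, else spaced 1 ms), or pass an RR series and TR
    so heartbeat labels and timestamps match a SWIG acquisition spoke for
    spoke (no sector structure in the angles).
    """
    if rr is not None:
        if tr is None:
            raise InvalidProtocolError("tr is required when rr is given")
        counts, beat, t = _beat_structure(rr, tr)
        n_total = int(counts.sum())
        if n_spokes is not None and n_spokes != n_total:
            raise InvalidProtocolError(
                f"n_spokes={n_spokes} inconsistent with RR series ({n_total})"
            )
    else:
        if n_spokes is None or n_spokes < 1:
            raise InvalidProtocolError("n_spokes must be >= 1")
        n_total = n_spokes
        beat = np.zeros(n_total, dtype=int)
        step = tr if tr is not None else 1.0
        t = np.arange(n_total) * step
    angles = np.mod(phi0 + np.pi * GOLDEN_FRACTION * np.arange(n_total), np.pi)
    sched = SpokeSchedule(
        angle=angles,
        beat=beat,
        t_since_R=t,
        enc_sign=np.ones(n_total, dtype=int),
        n_sectors=1,
        tr=tr if tr is not None else 1.0,
        ordering="ga",
    )
    return assign_venc_signs(sched, first_sign=+1)


def assign_venc_signs(schedule: SpokeSchedule, first_sign: int = +1) -> SpokeSchedule:
    """Set strictly alternating velocity-encoding signs over the global
    spoke index: sign(n) = first_sign * (-1)^n. Heartbeat boundaries do not
    reset the alternation."""
    if schedule.n_spokes < 1:
        raise InvalidProtocolError("schedule must contain at least one spoke")
    if first_sign not in (+1, -1):
        raise InvalidProtocolError(f"first_sign must be +1 or -1, got {first_sign}")
    signs = first_sign * (-1) ** np.arange(schedule.n_spokes)
    out = schedule.subset(slice(None))
    out.enc_sign = signs.astype(int)
    return out


def spoke_coordinates(
    angle: float | np.ndarray, readout_samples: int, matrix: int | None = None
) -> np.ndarray:
    """k-space sample coordinates of one or more spokes.

    Samples lie on the diameter at azimuth ``angle``, in normalized units
    of cycles/pixel with |k| <= 0.5. Even readout lengths use the
    half-sample convention k_j = (j - readout/2 + 0.5)/readout, so no
    sample sits exactly at DC; odd lengths include the exact DC sample.

    Returns
    -------
    (..., readout_samples, 2) array of (kx, ky).
    """
    if readout_samples < 2:
        raise InvalidProtocolError("readout_samples must be >= 2")
    j = np.arange(readout_samples)
    if readout_samples % 2 == 0:
        k = (j - readout_samples / 2 + 0.5) / readout_samples
    else:
        k = (j - (readout_samples - 1) / 2) / readout_samples
    ang = np.atleast_1d(np.asarray(angle, dtype=float))
    kx = np.outer(np.cos(ang), k)
    ky = np.outer(np.sin(ang), k)
    coords = np.stack([kx, ky], axis=-1)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return coords[0]
    return coords
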