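"""Retrospective cardiac binning with a sliding window.

The steady-state (first) heartbeat is discarded, the remaining beats are
linearly stretched onto a common cardiac-phase axis p = t/RR, and frames
are placed equidistantly on that axis with a temporal increment of 1 TR.
For every frame and velocity-encoding sign, the nearest footprint/2 spokes
of that sign are taken from *each* retained beat (nearest-neighbor in
cyclic cardiac phase — no temporal interpolation of k-space lines), so a
window pools the same angular sector coverage from every beat and the
+/- windows stay sign-balanced as shared velocity encoding requires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import InvalidProtocolError, RRSeries


class ScheduleInconsistencyError(ValueError):
    """Raised when spoke timestamps and RR intervals disagree."""


@dataclass
class FrameAssignment:
    """The realized sliding window: for each reconstructed frame and
    encoding sign, the indices of the contributing spokes (rows of the
    RawKSpace the assignment was built from).

    ``indices`` has shape (n_frames, 2, k) with axis 1 ordered (+1, -1)
    and k = footprint/2 * n_retained_beats.
    """

    n_frames: int
    centers: np.ndarray  # cardiac-phase fractions, equidistant on [0,1)
    indices: np.ndarray
    footprint_tr: int
    increment_tr: int

    @property
    def spokes_per_encoding(self) -> int:
        return self.indices.shape[2]

    @property
    def spokes_per_frame(self) -> int:
        """Spokes entering one phase-subtracted frame (both signs)."""
        return 2 * self.indices.shape[2]

    def frame_indices(self, frame: int, enc_sign: int) -> np.ndarray:
        return self.indices[frame, 0 if enc_sign > 0 else 1]

    def to_json(self, path) -> None:
        payload = {
            "n_frames": self.n_frames,
            "footprint_tr": self.footprint_tr,
            "increment_tr": self.increment_tr,
            "centers": self.centers.tolist(),
            "indices": self.indices.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FrameAssignment":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_frames=d["n_frames"],
            centers=np.asarray(d["centers"]),
            indices=np.asarray(d["indices"], dtype=int),
            footprint_tr=d["footprint_tr"],
            increment_tr=d["increment_tr"],
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f in range(self.n_frames):
            for si, sign in enumerate((+1, -1)):
                rows.append(
                    {
                        "frame": f,
                        "enc_sign": sign,
                        "spokes": " ".join(map(str, self.indices[f, si])),
                    }
                )
        return pd.DataFrame(rows)


def discard_steady_state(raw) -> "RawKSpace":
    """Drop all spokes of heartbeat s = 0 (magnetization steady state).

    Beat labels are preserved, so a second call is a no-op. Raises on a
    single-beat acquisition.
    """
    from .simulator import RawKSpace

    beats = np.unique(raw.schedule.beat)
    if beats.size < 2 and 0 in beats:
        raise InvalidProtocolError("cannot discard the only heartbeat")
    keep = raw.schedule.beat != 0
    return RawKSpace(
        data=raw.data[keep],
        schedule=raw.schedule.subset(keep),
        rr=raw.rr,
        protocol=raw.protocol,
        psi=raw.psi,
        maps=raw.maps,
        phantom=raw.phantom,
        seed=raw.seed,
    )


def cardiac_phase(raw) -> np.ndarray:
    """Per-spoke cardiac phase p = t_since_R / RR(beat), in [0, 1)."""
    rr_of_beat = raw.rr.rr_ms[raw.schedule.beat]
    t = raw.schedule.t_since_R
    if np.any(t >= rr_of_beat):
        raise ScheduleInconsistencyError(
            "spoke timestamp t_since_R >= its beat's RR interval"
        )
    return t / rr_of_beat


def retained_rr(raw) -> RRSeries:
    """RR intervals of the beats actually present in the schedule."""
    beats = np.unique(raw.schedule.beat)
    return RRSeries(raw.rr.rr_ms[beats])


def n_frames(rr_retained: RRSeries, tr: float, increment_tr: int = 1) -> int:
    """Frame count: shortest retained heartbeat divided by the temporal
    increment, floor."""
    if increment_tr < 1:
        raise InvalidProtocolError("increment_tr must be >= 1")
    return int(np.floor(rr_retained.rr_ms.min() / (increment_tr * tr)))


def footprint_duration(footprint_tr: int, tr: float) -> float:
    """Temporal footprint in ms: footprint_tr * TR."""
    if footprint_tr < 1:
        raise InvalidProtocolError("footprint_tr must be >= 1")
    return footprint_tr * tr


def assign_frames(raw, footprint_tr: int, increment_tr: int = 1) -> FrameAssignment:
    """Build the sliding-window frame assignment.

    For each frame center (equidistant on [0,1)) and each encoding sign,
    the footprint_tr/2 spokes of that sign nearest in cyclic cardiac phase
    are selected from every retained beat. Ties break toward the lower
    spoke index. The footprint must be even — shared velocity encoding
    needs sign-balanced windows.
    """
    if footprint_tr < 2 or footprint_tr % 2:
        raise InvalidProtocolError(
            f"footprint_tr must be even and >= 2, got {footprint_tr}"
        )
    half = footprint_tr // 2
    p = cardiac_phase(raw)
    sched = raw.schedule
    beats = np.unique(sched.beat)
    rr_ret = retained_rr(raw)
    nf = n_frames(rr_ret, sched.tr, increment_tr)
    centers = np.arange(nf) / nf

    indices = np.empty((nf, 2, half * beats.size), dtype=int)
    for bi, b in enumerate(beats):
        for si, sign in enumerate((+1, -1)):
            sel = np.flatnonzero((sched.beat == b) & (sched.enc_sign == sign))
            if sel.size < half:
                raise InvalidProtocolError(
                    f"beat {b} has only {sel.size} spokes of sign {sign}; "
                    f"footprint {footprint_tr} needs {half}"
                )
            d = np.abs(p[sel][None, :] - centers[:, None])
            d = np.minimum(d, 1.0 - d)  # cyclic distance on [0,1)
            # stable partial sort: ties resolved toward lower global index
            order = np.argsort(d, axis=1, kind="stable")[:, :half]
            chosen = np.sort(sel[order], axis=1)
            indices[:, si, bi * half : (bi + 1) * half] = chosen
    return FrameAssignment(
        n_frames=nf,
        centers=centers,
        indices=indices,
        footprint_tr=footprint_tr,
        increment_tr=increment_tr,
    )
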