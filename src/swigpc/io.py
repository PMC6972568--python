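"""Persistence: HDF5 raw-data container (ISMRMRD-inspired layout), NIfTI
image export, and schedule/profile tables.

Container layout (one acquisition per file):

    /data        complex spoke samples [spoke, readout, coil]
    /schedule    angle, beat, t_since_R, enc_sign  (+ attrs n_sectors, tr,
                 ordering)
    /rr          RR intervals, ms
    /protocol    scalar attrs (tr, te, venc, matrix, fov, ...)
    /noise_psi   coil noise covariance
    /maps        (optional) ground-truth coil sensitivities
    /provenance  seed, phantom hash, phantom JSON, package version

Round trips are bit-exact for data and metadata.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .protocol import ProtocolParams, RRSeries
from .simulator import PhantomSpec, RawKSpace
from .trajectory import SpokeSchedule


class SchemaError(IOError):
    """Raw container is missing a required group or is inconsistent."""


REQUIRED_GROUPS = ("data", "schedule", "rr", "protocol", "noise_psi")


def save_raw(raw: RawKSpace, path) -> None:
    from . import __version__

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=raw.data)
        g = f.create_group("schedule")
        g.create_dataset("angle", data=raw.schedule.angle)
        g.create_dataset("beat", data=raw.schedule.beat)
        g.create_dataset("t_since_R", data=raw.schedule.t_since_R)
        g.create_dataset("enc_sign", data=raw.schedule.enc_sign)
        g.attrs["n_sectors"] = raw.schedule.n_sectors
        g.attrs["tr"] = raw.schedule.tr
        g.attrs["ordering"] = raw.schedule.ordering
        f.create_dataset("rr", data=raw.rr.rr_ms)
        p = f.create_group("protocol")
        for k, v in raw.protocol.to_dict().items():
            p.attrs[k] = v
        f.create_dataset("noise_psi", data=raw.psi)
        if raw.maps is not None:
            f.create_dataset("maps", data=raw.maps)
        prov = f.create_group("provenance")
        prov.attrs["version"] = __version__
        if raw.seed is not None:
            prov.attrs["seed"] = raw.seed
        if raw.phantom is not None:
            prov.attrs["phantom_hash"] = raw.phantom.hash()
            prov.attrs["phantom_json"] = json.dumps(raw.phantom.to_dict())


def load_raw(path) -> RawKSpace:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SchemaError(f"not a readable HDF5 raw container: {path}") from exc
    with f:
        for grp in REQUIRED_GROUPS:
            if grp not in f:
                raise SchemaError(f"raw container missing group '/{grp}'")
        g = f["schedule"]
        for ds in ("angle", "beat", "t_since_R", "enc_sign"):
            if ds not in g:
                raise SchemaError(f"raw container missing dataset '/schedule/{ds}'")
        sched = SpokeSchedule(
            angle=g["angle"][:],
            beat=g["beat"][:],
            t_since_R=g["t_since_R"][:],
            enc_sign=g["enc_sign"][:],
            n_sectors=int(g.attrs["n_sectors"]),
            tr=float(g.attrs["tr"]),
            ordering=str(g.attrs["ordering"]),
        )
        proto = ProtocolParams.from_dict(
            {k: (v.item() if hasattr(v, "item") else v)
             for k, v in f["protocol"].attrs.items()}
        )
        prov = f["provenance"].attrs if "provenance" in f else {}
        phantom = None
        if "phantom_json" in prov:
            phantom = PhantomSpec.from_dict(json.loads(prov["phantom_json"]))
        return RawKSpace(
            data=f["data"][:],
            schedule=sched,
            rr=RRSeries(f["rr"][:]),
            protocol=proto,
            psi=f["noise_psi"][:],
            maps=f["maps"][:] if "maps" in f else None,
            phantom=phantom,
            seed=int(prov["seed"]) if "seed" in prov else None,
        )


def check_consistency(raw: RawKSpace, frames) -> None:
    """Fail loudly when a frame assignment refers to spokes outside the
    container or has a footprint the protocol cannot support."""
    if frames.indices.max() >= raw.schedule.n_spokes:
        raise SchemaError(
            "frame assignment references spoke indices beyond the raw container "
            "(was it built from a different acquisition?)"
        )


def save_velocity_nifti(series, path, protocol: ProtocolParams,
                        rr_ms: float | None = None) -> None:
    """4-D NIfTI export of the velocity series (cm/s); voxel size from the
    protocol, frame duration (ms) in the time pixdim when known."""
    import nibabel as nib

    vol = np.moveaxis(series.velocity, 0, -1)[:, :, None, :]  # x, y, z, t
    dt = (rr_ms / series.n_frames) if rr_ms else 1.0
    aff = np.diag([protocol.pixel_mm, protocol.pixel_mm,
                   protocol.slice_thickness, 1.0])
    img = nib.Nifti1Image(vol.astype(np.float32), aff)
    img.header["pixdim"][4] = dt
    img.header.set_xyzt_units(xyz="mm", t="msec")
    nib.save(img, str(path))


def load_mask_nifti(path, label: int | None = None) -> np.ndarray:
    """Load a (label) mask image; returns a 2-D boolean array."""
    import nibabel as nib

    arr = np.asanyarray(nib.load(str(path)).dataobj)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise SchemaError(f"mask must be 2-D after squeezing, got shape {arr.shape}")
    return (arr == label) if label is not None else (arr > 0)
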