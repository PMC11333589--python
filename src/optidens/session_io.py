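"""On-disk session schema: HDF5 container with a JSON+CSV text fallback.

One *session file* holds a subject's full measurement session: a manifest
(subject id, schema version, noise configuration), the shared TCSPC time
axis, the measured/simulated IRF, and 18 acquisition blocks each carrying
protocol metadata (breast L/R, posture sitting/supine, position O/L/I/C/CC,
mode, rho or slab thickness), the 51-wavelength list (600:10:1100 nm,
identified by value, never by index) and the counts matrix
(51 x n_channels, non-negative integers).

HDF5 (`.h5`) is the primary container; passing a directory path instead
writes a human-inspectable bundle (``manifest.json``, ``irf.csv``, one
``acqNN_counts.csv`` per acquisition).  Round trips are lossless with
bit-exact counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from optidens.chromophores import PROTOCOL_WAVELENGTHS_NM
from optidens.forward_model import DTOF, Geometry, SpectralAcquisition, TimeAxis
from optidens.synthetic_cohort import SessionRecord

SCHEMA_VERSION = "optidens-session-1"

_META_KEYS = ("subject_id", "breast", "posture", "position", "mode")


class SchemaError(ValueError):
    """Raised when a session file violates the on-disk schema."""


def _validate_session(session: SessionRecord) -> None:
    n = session.time_axis.n_channels
    if session.irf.shape != (n,):
        raise SchemaError("IRF length must equal n_channels")
    for acq in session.acquisitions:
        wl = acq.wavelengths
        if not np.array_equal(wl, PROTOCOL_WAVELENGTHS_NM):
            raise SchemaError("wavelength list must be 600:10:1100 nm (51 points)")
        if acq.counts_matrix.shape != (wl.size, n):
            raise SchemaError("counts matrix must be (51, n_channels)")


def _geometry_attrs(geometry: Geometry) -> dict:
    if geometry.mode == "reflectance":
        return {"mode": "reflectance", "rho_cm": float(geometry.rho)}
    return {
        "mode": "transmittance",
        "thickness_cm": float(geometry.thickness),
        "lateral_offset_cm": float(geometry.lateral_offset),
    }


def _geometry_from_attrs(attrs: dict) -> Geometry:
    if attrs["mode"] == "reflectance":
        return Geometry(mode="reflectance", rho=float(attrs["rho_cm"]))
    return Geometry(
        mode="transmittance",
        thickness=float(attrs["thickness_cm"]),
        lateral_offset=float(attrs.get("lateral_offset_cm", 0.0)),
    )


def _acq_meta(acq: SpectralAcquisition) -> dict:
    md = acq.metadata
    out = {k: md.get(k, "") for k in _META_KEYS}
    out["distance_cm"] = md.get("distance_cm")
    out.update(_geometry_attrs(acq.geometry))
    return out


def write_session(session: SessionRecord, path: str | Path) -> Path:
    """Write a session to ``path`` (``.h5``/``.hdf5`` -> HDF5; otherwise a
    JSON+CSV directory bundle).  Returns the written path."""
    _validate_session(session)
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_hdf5(session, path)
    else:
        _write_bundle(session, path)
    return path


def read_session(path: str | Path) -> SessionRecord:
    """Read a session file, validating the schema (version, shapes, IRF)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        session = _read_hdf5(path)
    elif path.is_dir():
        session = _read_bundle(path)
    else:
        raise SchemaError(f"{path}: not an HDF5 file or bundle directory")
    _validate_session(session)
    return session


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def _write_hdf5(session: SessionRecord, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["subject_id"] = session.subject_id
        f.attrs["noise_config"] = json.dumps(session.noise_config)
        ta = f.create_group("time_axis")
        ta.attrs["t0_s"] = session.time_axis.t0
        ta.attrs["dt_s"] = session.time_axis.dt
        ta.attrs["n_channels"] = session.time_axis.n_channels
        f.create_dataset("irf", data=session.irf)
        grp = f.create_group("acquisitions")
        for i, acq in enumerate(session.acquisitions):
            g = grp.create_group(f"acq{i:02d}")
            for key, val in _acq_meta(acq).items():
                g.attrs[key] = "" if val is None else val
            g.create_dataset("wavelengths_nm", data=acq.wavelengths)
            g.create_dataset("counts", data=acq.counts_matrix.astype(np.int64))


def _read_hdf5(path: Path) -> SessionRecord:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(f"schema version mismatch: {version!r} != {SCHEMA_VERSION!r}")
        if "irf" not in f:
            raise SchemaError("session file has no IRF block")
        ta = f["time_axis"].attrs
        axis = TimeAxis(t0=float(ta["t0_s"]), dt=float(ta["dt_s"]), n_channels=int(ta["n_channels"]))
        irf = np.asarray(f["irf"])
        acquisitions = []
        for name in sorted(f["acquisitions"]):
            g = f["acquisitions"][name]
            attrs = dict(g.attrs)
            wl = np.asarray(g["wavelengths_nm"])
            counts = np.asarray(g["counts"])
            if counts.shape[0] != wl.size:
                raise SchemaError(
                    f"{name}: counts matrix has {counts.shape[0]} rows for {wl.size} wavelengths"
                )
            acquisitions.append(_build_acquisition(attrs, wl, counts, irf, axis))
        return SessionRecord(
            subject_id=str(f.attrs["subject_id"]),
            acquisitions=acquisitions,
            irf=irf,
            time_axis=axis,
            noise_config=json.loads(f.attrs.get("noise_config", "{}")),
        )


def _build_acquisition(
    attrs: dict, wl: np.ndarray, counts: np.ndarray, irf: np.ndarray, axis: TimeAxis
) -> SpectralAcquisition:
    geometry = _geometry_from_attrs(attrs)
    distance = attrs.get("distance_cm")
    metadata = {k: attrs.get(k, "") for k in _META_KEYS}
    metadata["distance_cm"] = None if distance in ("", None) else float(distance)
    if geometry.mode == "transmittance":
        metadata["thickness_cm"] = geometry.thickness
    dtofs = [
        DTOF(wavelength=float(w), counts=counts[i], time_axis=axis)
        for i, w in enumerate(wl)
    ]
    return SpectralAcquisition(
        dtofs=dtofs, irf=irf, geometry=geometry, time_axis=axis, metadata=metadata
    )


# ---------------------------------------------------------------------------
# JSON + CSV text bundle
# ---------------------------------------------------------------------------


def _write_bundle(session: SessionRecord, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": session.subject_id,
        "noise_config": session.noise_config,
        "time_axis": {
            "t0_s": session.time_axis.t0,
            "dt_s": session.time_axis.dt,
            "n_channels": session.time_axis.n_channels,
        },
        "irf_file": "irf.csv",
        "acquisitions": [],
    }
    np.savetxt(directory / "irf.csv", session.irf, delimiter=",", header="irf", comments="# ")
    for i, acq in enumerate(session.acquisitions):
        fname = f"acq{i:02d}_counts.csv"
        meta = _acq_meta(acq)
        meta["counts_file"] = fname
        manifest["acquisitions"].append(meta)
        matrix = np.column_stack([acq.wavelengths, acq.counts_matrix])
        np.savetxt(
            directory / fname,
            matrix,
            delimiter=",",
            fmt=["%.1f"] + ["%d"] * acq.time_axis.n_channels,
            header="wavelength_nm,counts...",
            comments="# ",
        )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _read_bundle(directory: Path) -> SessionRecord:
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"{directory}: no manifest.json")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"schema version mismatch: {manifest.get('schema_version')!r} != {SCHEMA_VERSION!r}"
        )
    if "irf_file" not in manifest or not (directory / manifest["irf_file"]).exists():
        raise SchemaError("bundle has no IRF file")
    ta = manifest["time_axis"]
    axis = TimeAxis(t0=float(ta["t0_s"]), dt=float(ta["dt_s"]), n_channels=int(ta["n_channels"]))
    irf = np.loadtxt(directory / manifest["irf_file"], delimiter=",")
    acquisitions = []
    for meta in manifest["acquisitions"]:
        matrix = np.loadtxt(directory / meta["counts_file"], delimiter=",", ndmin=2)
        wl = matrix[:, 0]
        counts = matrix[:, 1:].astype(np.int64)
        if counts.shape[0] != wl.size:  # pragma: no cover - np guarantees
            raise SchemaError("counts matrix rows do not match wavelength list")
        acquisitions.append(_build_acquisition(meta, wl, counts, irf, axis))
    return SessionRecord(
        subject_id=str(manifest["subject_id"]),
        acquisitions=acquisitions,
        irf=irf,
        time_axis=axis,
        noise_config=manifest.get("noise_config", {}),
    )
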