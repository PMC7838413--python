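"""File I/O: 32-bit-float TIFF images with JSON sidecars, and CSV tables.

Every image (scan, attenuation map, reconstruction) is stored as a single
32-bit-float TIFF page with depth as rows and lateral position as columns.
A JSON sidecar next to it (same stem, ``.json``) carries the acquisition
geometry and any provenance (seed, truncation fraction, prior parameters,
software version).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .dr_recovery import DRMap
from .speckle_forward import AcquisitionGeometry, AttenuationProfile, ScanField

__all__ = [
    "write_image",
    "read_image",
    "write_scan",
    "read_scan",
    "write_profile",
    "read_profile",
    "write_dr_map",
    "read_dr_map",
    "write_csv_matrix",
    "read_csv_matrix",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image(path, array: np.ndarray, geometry: AcquisitionGeometry, **metadata) -> Path:
    """Write a float32 TIFF plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        path = path.with_suffix(".tif")
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    sidecar = {"geometry": geometry.to_dict(), "software_version": __version__}
    sidecar.update(metadata)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_image(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    array = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar_path(path).read_text())
    return array, meta


def write_scan(path, scan: ScanField) -> Path:
    return write_image(
        path,
        scan.intensities,
        scan.geometry,
        kind="scan",
        is_realization=scan.is_realization,
        seed=scan.seed,
    )


def read_scan(path) -> ScanField:
    array, meta = read_image(path)
    return ScanField(
        intensities=array,
        geometry=AcquisitionGeometry.from_dict(meta["geometry"]),
        is_realization=bool(meta.get("is_realization", False)),
        seed=meta.get("seed"),
    )


def write_profile(path, profile: AttenuationProfile, **metadata) -> Path:
    return write_image(path, profile.values, profile.geometry, kind="profile", **metadata)


def read_profile(path) -> AttenuationProfile:
    array, meta = read_image(path)
    return AttenuationProfile(
        values=array, geometry=AcquisitionGeometry.from_dict(meta["geometry"])
    )


def write_dr_map(path, dr_map: DRMap) -> Path:
    # the mask is recoverable from truncation_fraction plus the zero-denominator
    # sentinel; store it explicitly anyway for fidelity
    return write_image(
        path,
        dr_map.estimates,
        dr_map.geometry,
        kind="dr_map",
        truncation_fraction=dr_map.truncation_fraction,
        admissible_mask=dr_map.admissible_mask.astype(int),
    )


def read_dr_map(path) -> DRMap:
    array, meta = read_image(path)
    return DRMap(
        estimates=array,
        admissible_mask=np.asarray(meta["admissible_mask"], dtype=bool),
        truncation_fraction=meta["truncation_fraction"],
        geometry=AcquisitionGeometry.from_dict(meta["geometry"]),
    )


def write_csv_matrix(path, array: np.ndarray) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(array, dtype=float), delimiter=",")
    return path


def read_csv_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
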