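"""File formats: NIfTI volumes with JSON acquisition sidecars, label maps,
parameter maps, ROI spectra as CSV, and run manifests.

A 4-D image series is stored as ``<stem>.nii.gz`` plus ``<stem>.json``
listing (b, TE, n_avg) per volume, mirroring common multi-b conventions.
All round-trips preserve values to float64 precision and grid metadata.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import GridMismatchError, RenalDwiError
from .fitting import ParameterMap
from .phantom import PhantomLabelMap
from .protocol import AcquisitionProtocol
from .signal import ImageSeries
from .spectrum import DT2Mesh, DT2Spectrum

__all__ = [
    "save_image_series", "load_image_series",
    "save_label_map", "load_label_map",
    "save_parameter_map", "load_parameter_map",
    "save_roi_spectrum_csv", "load_roi_spectrum_csv",
    "write_manifest", "file_sha256",
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def _voxel_size(img: nib.Nifti1Image) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def save_image_series(stem: str | Path, series: ImageSeries) -> tuple[Path, Path]:
    """Write ``<stem>.nii.gz`` and the ``<stem>.json`` acquisition sidecar."""
    stem = Path(stem)
    nii_path = stem.with_suffix(".nii.gz")
    json_path = stem.with_suffix(".json")
    img = nib.Nifti1Image(series.data.astype(np.float64), _affine(series.voxel_size_mm))
    nib.save(img, nii_path)
    sidecar = {
        "protocol_name": series.protocol.name,
        "acquisition_table": series.protocol.to_table(),
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return nii_path, json_path


def load_image_series(stem: str | Path) -> ImageSeries:
    stem = Path(stem)
    nii_path = stem.with_suffix(".nii.gz")
    json_path = stem.with_suffix(".json")
    if not json_path.exists():
        raise RenalDwiError(f"missing acquisition sidecar {json_path}")
    try:
        sidecar = json.loads(json_path.read_text())
        protocol = AcquisitionProtocol.from_table(
            sidecar["protocol_name"], sidecar["acquisition_table"]
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise RenalDwiError(f"malformed sidecar {json_path}: {exc}") from exc
    img = nib.load(nii_path)
    return ImageSeries(
        data=np.asarray(img.dataobj, float), protocol=protocol,
        voxel_size_mm=_voxel_size(img),
    )


def save_label_map(path: str | Path, labels: PhantomLabelMap) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(labels.labels.astype(np.int16), _affine(labels.voxel_size_mm))
    nib.save(img, path)
    return path


def load_label_map(path: str | Path) -> PhantomLabelMap:
    img = nib.load(path)
    return PhantomLabelMap(
        labels=np.asarray(img.dataobj).astype(int), voxel_size_mm=_voxel_size(img)
    )


def check_same_grid(shape_a: tuple, shape_b: tuple, what: str = "image/mask") -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise GridMismatchError(f"{what} grids differ: {tuple(shape_a)} vs {tuple(shape_b)}")


def save_parameter_map(stem: str | Path, pmap: ParameterMap,
                       voxel_size_mm=(2.0, 2.0, 3.0)) -> tuple[Path, Path]:
    stem = Path(stem)
    nii_path = stem.with_suffix(".nii.gz")
    json_path = stem.with_suffix(".json")
    img = nib.Nifti1Image(pmap.data.astype(np.float64), _affine(voxel_size_mm))
    nib.save(img, nii_path)
    json_path.write_text(json.dumps(
        {"name": pmap.name, "units": pmap.units, "provenance": pmap.provenance}, indent=1
    ))
    return nii_path, json_path


def load_parameter_map(stem: str | Path) -> ParameterMap:
    stem = Path(stem)
    img = nib.load(stem.with_suffix(".nii.gz"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return ParameterMap(
        name=meta["name"], data=np.asarray(img.dataobj, float),
        units=meta["units"], provenance=meta.get("provenance", {}),
    )


def save_roi_spectrum_csv(path: str | Path, spectrum: DT2Spectrum) -> Path:
    """Per-ROI spectrum CSV with columns d_um2_ms, t2_ms, intensity."""
    path = Path(path)
    mesh = spectrum.mesh
    dd, tt = np.meshgrid(mesh.d, mesh.t2, indexing="ij")
    pd.DataFrame({
        "d_um2_ms": dd.ravel(), "t2_ms": tt.ravel(),
        "intensity": spectrum.intensity.ravel(),
    }).to_csv(path, index=False, float_format="%.12g")
    return path


def load_roi_spectrum_csv(path: str | Path, source: str = "roi") -> DT2Spectrum:
    frame = pd.read_csv(path)
    mesh = DT2Mesh()
    if len(frame) != mesh.size:
        raise RenalDwiError(f"spectrum CSV has {len(frame)} rows, expected {mesh.size}")
    return DT2Spectrum(
        intensity=frame["intensity"].to_numpy().reshape(mesh.shape),
        mesh=mesh, source=source,
    )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, *, seed: int, options: dict,
                   outputs: list[str | Path]) -> Path:
    """JSON run manifest: seed, options, package version, output hashes."""
    from . import __version__

    path = Path(path)
    manifest = {
        "package": "renaldwi",
        "version": __version__,
        "seed": seed,
        "options": options,
        "outputs": {
            str(p): file_sha256(p) for p in outputs if Path(p).exists()
        },
    }
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise RenalDwiError(f"config {path} must be a YAML mapping")
    return data
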