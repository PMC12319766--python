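"""File I/O: NIfTI volumes, HDF5 k-space containers, streamline JSON.

NIfTI is used for all image-like maps (data array preserved bit-exactly,
voxel size in the affine); k-space data travel in an HDF5 container with
datasets ``samples``, ``coords``, ``tr_index``, ``time_ms`` and optional
``coils``; streamline bundles are stored as JSON (mm coordinates).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .encoding import KSpaceData
from .sampling import SamplingScheme
from .tracts import StreamlineBundle

__all__ = [
    "save_nifti",
    "load_nifti",
    "io_roundtrip",
    "save_kspace",
    "load_kspace",
    "save_bundle",
    "load_bundle",
]


def save_nifti(
    volume: np.ndarray,
    path: str | Path,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume), affine)
    img.header.set_data_dtype(volume.dtype)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI volume; malformed/truncated files raise ``ValueError``."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as e:  # noqa: BLE001 - normalise parser failures
        raise ValueError(f"failed to parse NIfTI file {path}: {e}") from e
    return data, vox


def io_roundtrip(
    volume: np.ndarray,
    path: str | Path,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Write then re-read a volume; returns the re-read data array."""
    save_nifti(volume, path, voxel_size_mm)
    data, _ = load_nifti(path)
    return data


def save_kspace(data: KSpaceData, path: str | Path, coils: np.ndarray | None = None) -> None:
    s = data.scheme
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=data.samples)
        f.create_dataset("coords", data=s.coords)
        f.create_dataset("tr_index", data=s.tr_index)
        f.create_dataset("time_ms", data=s.time_ms)
        f.create_dataset("readout_times_ms", data=s.readout_times_ms)
        f.attrs["shape"] = s.shape
        f.attrs["trs_per_group"] = s.trs_per_group
        f.attrs["complementary"] = s.complementary
        f.attrs["noise_sd"] = data.noise_sd
        if coils is not None:
            f.create_dataset("coils", data=coils)


def load_kspace(path: str | Path) -> tuple[KSpaceData, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        scheme = SamplingScheme(
            shape=tuple(int(v) for v in f.attrs["shape"]),
            coords=f["coords"][()],
            tr_index=f["tr_index"][()],
            time_ms=f["time_ms"][()],
            trs_per_group=int(f.attrs["trs_per_group"]),
            readout_times_ms=f["readout_times_ms"][()],
            complementary=bool(f.attrs["complementary"]),
        )
        data = KSpaceData(
            samples=f["samples"][()], scheme=scheme, noise_sd=float(f.attrs["noise_sd"])
        )
        coils = f["coils"][()] if "coils" in f else None
    return data, coils


def save_bundle(bundle: StreamlineBundle, path: str | Path) -> None:
    payload = {
        "name": bundle.name,
        "orientation": bundle.orientation,
        "units": "mm",
        "streamlines": [s.tolist() for s in bundle.streamlines],
    }
    Path(path).write_text(json.dumps(payload))


def load_bundle(path: str | Path) -> StreamlineBundle:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        streamlines = [np.asarray(s, dtype=float) for s in payload["streamlines"]]
        return StreamlineBundle(
            streamlines=streamlines,
            name=payload.get("name", "tract"),
            orientation=payload.get("orientation", "anterior-posterior"),
        )
    except (json.JSONDecodeError, KeyError) as e:
        raise ValueError(f"failed to parse streamline file {path}: {e}") from e
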