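"""HDF5 dataset and NIfTI time-series I/O.

HDF5 layout (complex arrays stored as paired ``*_real`` / ``*_imag``
datasets):

    /kspace_real, /kspace_imag   (volume, group, coil, ky, kz)
    /masks                       (group, ky, kz) uint8
    /maps_real, /maps_imag       (coil, y, z)
    /ground_truth_real, _imag    (y, z)            [optional]
    /phase_truth                 (volume, y, z)    [optional]
"""

from __future__ import annotations

from typing import Sequence

import h5py
import numpy as np

from .encoding import AcquiredData

__all__ = ["save_dataset", "load_dataset", "save_nifti", "load_nifti"]


def _write_complex(f: h5py.File, name: str, arr: np.ndarray) -> None:
    f.create_dataset(f"{name}_real", data=np.ascontiguousarray(arr.real))
    f.create_dataset(f"{name}_imag", data=np.ascontiguousarray(arr.imag))


def _read_complex(f: h5py.File, name: str) -> np.ndarray:
    return np.asarray(f[f"{name}_real"]) + 1j * np.asarray(f[f"{name}_imag"])


def save_dataset(
    path: str,
    volumes: Sequence[AcquiredData],
    maps: np.ndarray,
    ground_truth: np.ndarray | None = None,
    phase_truth: np.ndarray | None = None,
    attrs: dict | None = None,
) -> None:
    """Write a multi-volume acquisition to ``path``."""
    if not volumes:
        raise ValueError("no volumes to save")
    y = np.stack([v.y for v in volumes])
    masks = volumes[0].masks
    with h5py.File(path, "w") as f:
        _write_complex(f, "kspace", y)
        f.create_dataset("masks", data=masks.astype(np.uint8))
        _write_complex(f, "maps", np.asarray(maps))
        if ground_truth is not None:
            _write_complex(f, "ground_truth", np.asarray(ground_truth, dtype=complex))
        if phase_truth is not None:
            f.create_dataset("phase_truth", data=np.asarray(phase_truth, dtype=float))
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_dataset(path: str) -> tuple[list[AcquiredData], np.ndarray, dict]:
    """Read a dataset written by :func:`save_dataset`.

    Returns (volumes, maps, attrs); ground truth arrays, when present,
    appear in ``attrs`` under ``"ground_truth"`` / ``"phase_truth"``.
    """
    with h5py.File(path, "r") as f:
        y = _read_complex(f, "kspace")
        masks = np.asarray(f["masks"]).astype(bool)
        maps = _read_complex(f, "maps")
        attrs = dict(f.attrs)
        if "ground_truth_real" in f:
            attrs["ground_truth"] = _read_complex(f, "ground_truth")
        if "phase_truth" in f:
            attrs["phase_truth"] = np.asarray(f["phase_truth"])
    volumes = [AcquiredData(y=y[t], masks=masks.copy()) for t in range(y.shape[0])]
    return volumes, maps, attrs


def save_nifti(path: str, series: np.ndarray, volume_tr: float = 1.0) -> None:
    """Write a (frames, ny, nz) magnitude series as a 4D NIfTI volume
    with spatial shape (ny, nz, 1)."""
    import nibabel as nib

    series = np.asarray(series, dtype=np.float32)
    if series.ndim != 3:
        raise ValueError("series must be (frames, ny, nz)")
    data = series.transpose(1, 2, 0)[:, :, None, :]  # (ny, nz, 1, frames)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(volume_tr)))
    nib.save(img, path)


def load_nifti(path: str) -> tuple[np.ndarray, float]:
    """Read a series written by :func:`save_nifti`; returns (frames, ny, nz)."""
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim == 4:
        series = data[:, :, 0, :].transpose(2, 0, 1)
    elif data.ndim == 3:
        series = data.transpose(2, 0, 1)
    else:
        raise ValueError(f"unsupported NIfTI dimensionality {data.ndim}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 1.0
    return series, tr
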