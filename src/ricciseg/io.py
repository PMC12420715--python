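"""NIfTI readers/writers and the volume header abstraction.

Volumes are canonicalized to channel-first ``(C, nx, ny, nz)`` float arrays
in memory; all voxel coordinates in files, seeds and logs are 0-based
``(i, j, k)`` indices matching the array layout.  World (affine)
coordinates exist only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["VolumeHeader", "read_volume", "write_volume", "write_mask"]

#: axes with at most this many entries are treated as a channel axis in 4D data
_MAX_CHANNELS = 8


@dataclass
class VolumeHeader:
    dims: tuple
    spacing: tuple          # voxel size (mm) per spatial axis
    affine: np.ndarray
    channels: int = 1
    dtype: object = np.float64

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @classmethod
    def for_array(cls, shape, spacing=(1.0, 1.0, 1.0)) -> "VolumeHeader":
        affine = np.diag(list(spacing) + [1.0])
        return cls(dims=tuple(shape), spacing=tuple(spacing), affine=affine)


def read_volume(path):
    """Read a NIfTI volume as ``(data, header)``, channel-first if 4D.

    A 4D axis of length <= 8 at either end is interpreted as channels and
    moved to the front.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - report path and reason
        raise IOError(f"cannot read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 3:
        channels = 1
        canonical = data[None]
    elif data.ndim == 4:
        if data.shape[-1] <= _MAX_CHANNELS:
            canonical = np.moveaxis(data, -1, 0)
        elif data.shape[0] <= _MAX_CHANNELS:
            canonical = data
        else:
            raise ValueError(
                f"{path}: cannot locate a channel axis (<= {_MAX_CHANNELS}) in shape {data.shape}"
            )
        channels = canonical.shape[0]
    else:
        raise ValueError(f"{path}: expected 3D or 4D data, got shape {data.shape}")
    if not np.isfinite(canonical).all():
        raise ValueError(f"{path}: volume contains NaN/Inf voxels")
    zooms = img.header.get_zooms()[:3]
    header = VolumeHeader(
        dims=canonical.shape[1:],
        spacing=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine, dtype=float),
        channels=channels,
        dtype=data.dtype,
    )
    return canonical, header


def _to_disk_layout(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim == 4:
        if data.shape[0] == 1:
            return data[0]
        return np.moveaxis(data, 0, -1)  # store channels last, the NIfTI norm
    if data.ndim != 3:
        raise ValueError(f"expected 3D or channel-first 4D data, got shape {data.shape}")
    return data


def write_volume(path, data: np.ndarray, header: VolumeHeader) -> None:
    img = nib.Nifti1Image(_to_disk_layout(data).astype(np.float64), header.affine)
    img.header.set_zooms(tuple(header.spacing) + ((1.0,) if data.ndim == 4 and data.shape[0] > 1 else ()))
    nib.save(img, str(path))


def write_mask(path, mask: np.ndarray, header: VolumeHeader) -> None:
    """Masks are written as uint8 {0, 1}."""
    arr = np.asarray(mask).astype(np.uint8)
    if arr.ndim != 3:
        raise ValueError(f"mask must be 3D, got shape {arr.shape}")
    img = nib.Nifti1Image(arr, header.affine)
    img.header.set_zooms(tuple(header.spacing))
    nib.save(img, str(path))
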