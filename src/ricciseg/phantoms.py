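"""Synthetic 3D phantoms with ground truth, auto-placed seed curves, and
segmentation metrics.

The generator emulates the interactive protocol of seed-based selective
segmentation: a closed foreground seed curve drawn on a slice inside the
object and a closed background curve outside it.  Volumes are two-intensity
shapes (sphere, ellipsoid, two blobs, torus) with optional i.i.d. Gaussian
noise and multiple channels, so every solver path can be exercised without
any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .prior import SeedSet

__all__ = ["PhantomSpec", "make_phantom", "dsc", "iou", "hausdorff"]

_OBJECTS = ("sphere", "ellipsoid", "two_blobs", "torus")


@dataclass
class PhantomSpec:
    """Recipe for one synthetic volume.

    ``fg`` / ``bg`` are per-channel intensities (scalar broadcasts over
    channels).  ``radius`` defaults to ``min(shape) // 6`` (10 voxels on the
    standard 64^3 grid).  Generation is fully determined by ``rng_seed``.
    """

    shape: tuple = (64, 64, 64)
    object: str = "sphere"
    fg: float | tuple = 1.0
    bg: float | tuple = 0.0
    noise_sigma: float = 0.1
    channels: int = 1
    rng_seed: int = 0
    radius: float | None = None

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or min(self.shape) < 16:
            raise ValueError(f"shape must be 3 dims of >= 16 voxels, got {self.shape}")
        if self.object not in _OBJECTS:
            raise ValueError(f"object must be one of {_OBJECTS}, got {self.object!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.radius is None:
            self.radius = min(self.shape) // 6
        fg = np.broadcast_to(np.asarray(self.fg, dtype=float).ravel(), (self.channels,))
        bg = np.broadcast_to(np.asarray(self.bg, dtype=float).ravel(), (self.channels,))
        if np.allclose(fg, bg):
            raise ValueError("fg and bg intensities must differ in at least one channel")
        self._fg, self._bg = np.array(fg), np.array(bg)


def _truth_mask(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    x, y, z = np.indices(spec.shape, dtype=float)
    r = spec.radius
    if r * 2 + 4 > min(spec.shape):
        raise ValueError(f"object radius {r} does not fit in grid {spec.shape}")
    if spec.object == "sphere":
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
    if spec.object == "ellipsoid":
        a, b, c = r, 0.75 * r, 0.6 * r
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
    if spec.object == "two_blobs":
        r2 = 0.7 * r
        off = r + r2 / 2 + 1
        m1 = (x - (cx - off / 2)) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
        m2 = (x - (cx + off)) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r2**2
        return m1 | m2
    # torus around the z mid-slice: tube radius r/2.5, ring radius r
    rho = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    return (rho - r) ** 2 + (z - cz) ** 2 <= (r / 2.5) ** 2


def _circle_seeds(center, radius: float, z: int, shape, n: int = 64) -> list:
    """Rasterize a closed circle of voxels on slice ``z``."""
    ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = {
        (
            int(round(center[0] + radius * np.cos(a))),
            int(round(center[1] + radius * np.sin(a))),
            int(z),
        )
        for a in ang
    }
    return sorted(
        p for p in pts if all(0 <= c < s for c, s in zip(p, shape))
    )


def _auto_seeds(spec: PhantomSpec, truth: np.ndarray) -> SeedSet:
    """One closed curve inside the object, one outside, never touching the
    truth boundary."""
    nx, ny, nz = spec.shape
    center = ((nx - 1) / 2, (ny - 1) / 2)
    zmid = nz // 2
    r = float(spec.radius)
    if spec.object == "torus":
        fg = _circle_seeds(center, r, zmid, spec.shape)  # tube centre line
    elif spec.object == "two_blobs":
        c1 = ((nx - 1) / 2 - (r + 0.7 * r / 2 + 1) / 2, (ny - 1) / 2)
        fg = _circle_seeds(c1, max(2.0, 0.45 * r), zmid, spec.shape)
    else:
        fg = _circle_seeds(center, max(2.0, 0.45 * r), zmid, spec.shape)
    if spec.object == "two_blobs":
        # the outer curve must clear both blobs
        outer = (r + 0.7 * r / 2 + 1) + 0.7 * r
        bg_r = min(outer + max(3.0, 0.3 * r), min(nx, ny) / 2 - 2)
    else:
        bg_r = min(r + max(4.0, 0.6 * r), min(nx, ny) / 2 - 2)
    bg = _circle_seeds(center, bg_r, zmid, spec.shape)
    seeds = SeedSet(foreground=fg, background=bg)
    for p in seeds.foreground:
        if not truth[p]:
            raise RuntimeError(f"auto foreground seed {p} fell outside the object")
    for p in seeds.background:
        if truth[p]:
            raise RuntimeError(f"auto background seed {p} fell inside the object")
    return seeds


def make_phantom(spec: PhantomSpec):
    """Build ``(f, truth, seeds)``: the volume (channel-first, shape
    ``(C, nx, ny, nz)``), the analytic ground-truth mask, and the auto seed
    curves.  Bit-reproducible for a given ``rng_seed``."""
    truth = _truth_mask(spec)
    rng = np.random.default_rng(spec.rng_seed)
    f = np.empty((spec.channels,) + spec.shape, dtype=float)
    for c in range(spec.channels):
        base = np.where(truth, spec._fg[c], spec._bg[c])
        f[c] = base + spec.noise_sigma * rng.standard_normal(spec.shape)
    seeds = _auto_seeds(spec, truth)
    return f, truth, seeds


# ---------------------------------------------------------------------------
# Metrics


def _as_bool(A: np.ndarray, B: np.ndarray):
    A, B = np.asarray(A, dtype=bool), np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError(f"mask shapes differ: {A.shape} vs {B.shape}")
    return A, B


def dsc(A: np.ndarray, B: np.ndarray) -> float:
    """Dice coefficient ``2|A & B| / (|A| + |B|)`` (1.0 for two empty masks)."""
    A, B = _as_bool(A, B)
    denom = int(A.sum()) + int(B.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((A & B).sum()) / denom


def iou(A: np.ndarray, B: np.ndarray) -> float:
    """Jaccard index ``|A & B| / |A | B|`` (1.0 for two empty masks)."""
    A, B = _as_bool(A, B)
    union = int((A | B).sum())
    if union == 0:
        return 1.0
    return int((A & B).sum()) / union


def _boundary(mask: np.ndarray) -> np.ndarray:
    inner = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1)
    )
    return mask & ~inner


def hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric Hausdorff distance between 6-connected boundary voxel sets,
    in voxel units (Euclidean point distances via distance transforms)."""
    A, B = _as_bool(A, B)
    if not A.any() or not B.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    bA, bB = _boundary(A), _boundary(B)
    dt_to_B = ndimage.distance_transform_edt(~bB)
    dt_to_A = ndimage.distance_transform_edt(~bA)
    return float(max(dt_to_B[bA].max(), dt_to_A[bB].max()))
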