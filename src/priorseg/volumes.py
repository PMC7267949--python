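"""Volume containers, NIfTI I/O, patch extraction and appearance normalization.

Everything downstream operates in the common voxel grid: 0-based indices,
array axes (0, 1, 2) = (x, y, z).  World (affine) transforms read from NIfTI
headers are carried through untouched and never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CommonSpaceVolume",
    "LabelMap",
    "Patch",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "extract_patch",
    "normalize_appearance",
]


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class CommonSpaceVolume:
    """A 3D scalar image assumed pre-aligned to the cohort's common space.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z)
        Scalar intensities; must be finite.
    voxel_size : tuple of float
        Voxel edge lengths in mm, all positive.  Anisotropic sizes are
        accepted and preserved.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-world transform, carried through I/O but never used by the
        segmentation method itself.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        n_bad = int(np.size(self.data) - np.count_nonzero(np.isfinite(self.data)))
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive floats, got {self.voxel_size}")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMap:
    """A 3D integer volume of mutually exclusive structure labels.

    Label 0 is background; values form the range ``0..n_classes-1``.
    """

    data: np.ndarray
    n_classes: int
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D label map, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise ValueError("label map has non-integer values")
            self.data = self.data.astype(np.int32)
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        lo, hi = int(self.data.min()), int(self.data.max())
        if lo < 0 or hi >= self.n_classes:
            raise ValueError(
                f"labels out of range: found [{lo}, {hi}] for n_classes={self.n_classes}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def class_mask(self, c: int) -> np.ndarray:
        return self.data == c

    def one_hot(self, dtype=np.float32) -> np.ndarray:
        """Return a (C, X, Y, Z) one-hot encoding."""
        out = np.zeros((self.n_classes, *self.data.shape), dtype=dtype)
        for c in range(self.n_classes):
            out[c] = self.data == c
        return out


@dataclass
class Patch:
    """A multichannel cubic sub-grid around a voxel of a parent volume.

    ``channels`` has shape (N, side, side, side) with odd spatial side so the
    center voxel is well defined; ``center`` is the 0-based voxel coordinate
    of that center in the parent volume.
    """

    channels: np.ndarray
    center: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 4:
            raise ValueError("patch channels must be (N, side, side, side)")
        s = self.channels.shape[1]
        if self.channels.shape[1:] != (s, s, s):
            raise ValueError("patch must be cubic")
        if s % 2 == 0:
            raise ValueError("patch side must be odd")
        self.center = tuple(int(c) for c in self.center)

    @property
    def side(self) -> int:
        return self.channels.shape[1]


def read_volume(path: str | Path) -> CommonSpaceVolume:
    """Read a 3D NIfTI scalar image.

    Raises ``ValueError`` for non-3D input or non-finite voxels.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {data.ndim}D")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CommonSpaceVolume(data=data, voxel_size=voxel_size, affine=img.affine)


def write_volume(vol: CommonSpaceVolume, path: str | Path) -> None:
    """Write a volume as NIfTI; round-trips data bit-exactly."""
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def read_labels(path: str | Path, n_classes: int | None = None) -> LabelMap:
    """Read an integer label NIfTI; infers ``n_classes`` as max label + 1."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D label map in {path}, got {data.ndim}D")
    data = np.rint(data).astype(np.int32)
    if n_classes is None:
        n_classes = int(data.max()) + 1
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(data=data, n_classes=n_classes, voxel_size=voxel_size, affine=img.affine)


def write_labels(labels: LabelMap, path: str | Path) -> None:
    img = nib.Nifti1Image(labels.data.astype(np.uint16), labels.affine)
    img.header.set_zooms(labels.voxel_size)
    nib.save(img, str(path))


def extract_patch(
    vol_or_stack: np.ndarray | CommonSpaceVolume,
    center: tuple[int, int, int],
    side: int,
) -> Patch:
    """Extract a cubic patch of odd ``side`` centered on ``center``.

    Accepts a 3D array / :class:`CommonSpaceVolume` (one channel) or a
    (N, X, Y, Z) channel stack.  Regions falling outside the volume are
    zero-filled; the center itself must lie inside the volume.
    """
    if isinstance(vol_or_stack, CommonSpaceVolume):
        arr = vol_or_stack.data[None]
    else:
        arr = np.asarray(vol_or_stack)
        if arr.ndim == 3:
            arr = arr[None]
        elif arr.ndim != 4:
            raise ValueError("expected a 3D volume or a (N, X, Y, Z) stack")
    if side % 2 == 0 or side < 1:
        raise ValueError(f"patch side must be odd and positive, got {side}")
    shape = arr.shape[1:]
    center = tuple(int(c) for c in center)
    if any(c < 0 or c >= s for c, s in zip(center, shape)):
        raise ValueError(f"patch center {center} outside volume bounds {shape}")

    half = side // 2
    out = np.zeros((arr.shape[0], side, side, side), dtype=arr.dtype)
    src = []
    dst = []
    for c, s in zip(center, shape):
        lo, hi = c - half, c + half + 1
        src.append(slice(max(lo, 0), min(hi, s)))
        dst.append(slice(max(lo, 0) - lo, side - (hi - min(hi, s))))
    out[(slice(None), *dst)] = arr[(slice(None), *src)]
    return Patch(channels=out, center=center)


def normalize_appearance(patch_channel: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Normalize one scalar channel to zero mean and unit SD.

    Constant channels map to all zeros (SD is floored at ``eps``), so a
    zero-filled out-of-volume region sits at the patch mean.
    """
    x = np.asarray(patch_channel, dtype=np.float32)
    sd = float(x.std(dtype=np.float64))  # float64: exactly 0 for constant input
    if sd <= eps:  # constant (or numerically constant) patch
        return np.zeros_like(x)
    return (x - x.mean()) / sd
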