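"""Random 3D elastic deformation of multichannel training samples.

A deformation field is built by drawing an i.i.d. U(-1, 1) value per voxel
and direction, smoothing each direction with a Gaussian kernel of standard
deviation ``sigma_e`` (the elasticity), rescaling the field globally so the
mean Euclidean displacement per voxel is exactly one, and multiplying by the
magnitude ``alpha_i``.  One field is drawn per training sample and warps the
appearance channel, the three coordinate channels and the one-hot label
target alike, so all channels of a sample stay spatially consistent.

``sigma_e`` and ``alpha_i`` are in mm; at the 1 mm isotropic voxels assumed
throughout, mm and voxels coincide.  Defaults are sigma_e = 4 mm and
alpha_i = 2 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DeformationConfig",
    "DeformationField",
    "sample_field",
    "warp_scalar",
    "warp_labels",
    "augment_sample",
]


@dataclass
class DeformationConfig:
    """Elastic deformation parameters.

    sigma_e : Gaussian smoothing SD in mm (> 0); larger = smoother fields.
    alpha_i : mean per-voxel displacement magnitude in mm (>= 0); 0 disables
        the deformation entirely.
    voxel_size : mm per voxel, used to convert mm to voxel units.
    """

    sigma_e: float = 4.0
    alpha_i: float = 2.0
    voxel_size: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be > 0")
        if self.alpha_i < 0:
            raise ValueError("alpha_i must be >= 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")


@dataclass
class DeformationField:
    """Per-voxel displacement vectors, shape (3, X, Y, Z), voxel units."""

    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=np.float32)
        if self.displacements.ndim != 4 or self.displacements.shape[0] != 3:
            raise ValueError("displacements must have shape (3, X, Y, Z)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[1:]

    def mean_magnitude(self) -> float:
        return float(np.sqrt((self.displacements.astype(np.float64) ** 2).sum(axis=0)).mean())


def sample_field(
    shape: tuple[int, int, int],
    config: DeformationConfig,
    rng: np.random.Generator,
) -> DeformationField:
    """Draw one random elastic deformation field for a grid of ``shape``.

    U(-1,1) noise per component -> per-axis Gaussian smoothing (SD sigma_e,
    truncated at 4 SD) -> global rescale to unit mean displacement magnitude
    -> multiply by alpha_i.  The mean Euclidean norm of the returned vectors
    is ``alpha_i / voxel_size`` voxels by construction.
    """
    if len(shape) != 3:
        raise ValueError("shape must be 3D")
    sigma_vox = config.sigma_e / config.voxel_size
    alpha_vox = config.alpha_i / config.voxel_size
    if alpha_vox == 0.0:
        return DeformationField(np.zeros((3, *shape), dtype=np.float32))
    while True:
        raw = rng.uniform(-1.0, 1.0, size=(3, *shape))
        for ax in range(3):
            raw[ax] = ndimage.gaussian_filter(raw[ax], sigma=sigma_vox, truncate=4.0)
        mean_mag = np.sqrt((raw**2).sum(axis=0)).mean()
        if mean_mag > 0:  # zero field has probability ~0; resample if it occurs
            break
    field = (raw * (alpha_vox / mean_mag)).astype(np.float32)
    return DeformationField(field)


def _sample_positions(field: DeformationField) -> np.ndarray:
    """Sampling positions = identity grid + displacement, clamped to edges."""
    shape = field.shape
    pos = np.indices(shape, dtype=np.float32) + field.displacements
    for ax, s in enumerate(shape):
        np.clip(pos[ax], 0.0, s - 1.0, out=pos[ax])
    return pos


def warp_scalar(channel: np.ndarray, field: DeformationField) -> np.ndarray:
    """Trilinearly interpolate one scalar channel at position + displacement.

    Out-of-grid sample positions clamp to the nearest edge voxel.
    """
    channel = np.asarray(channel)
    if channel.shape != field.shape:
        raise ValueError(f"channel shape {channel.shape} != field shape {field.shape}")
    pos = _sample_positions(field)
    out = ndimage.map_coordinates(
        channel.astype(np.float32), pos, order=1, mode="nearest"
    )
    return out.astype(np.float32)


def warp_labels(labels: np.ndarray, field: DeformationField, n_classes: int | None = None) -> np.ndarray:
    """Warp labels as a soft one-hot stack.

    Accepts an integer label volume (one-hot encoded internally) or a
    (C, X, Y, Z) one-hot/soft stack with C >= 2.  Each channel is trilinearly
    interpolated, then channels are renormalized to sum to one per voxel
    (interpolation of a one-hot stack already sums to one except where edge
    clamping intervenes).  The slight blurring this introduces at structure
    boundaries acts as label smoothing.
    """
    labels = np.asarray(labels)
    if labels.ndim == 3:
        if n_classes is None:
            n_classes = int(labels.max()) + 1
        stack = np.zeros((n_classes, *labels.shape), dtype=np.float32)
        for c in range(n_classes):
            stack[c] = labels == c
    elif labels.ndim == 4:
        stack = labels.astype(np.float32)
    else:
        raise ValueError("labels must be a 3D label volume or a (C, X, Y, Z) stack")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 classes")
    if stack.shape[1:] != field.shape:
        raise ValueError(f"label shape {stack.shape[1:]} != field shape {field.shape}")

    pos = _sample_positions(field)
    out = np.empty_like(stack)
    for c in range(stack.shape[0]):
        out[c] = ndimage.map_coordinates(stack[c], pos, order=1, mode="nearest")
    np.clip(out, 0.0, 1.0, out=out)
    total = out.sum(axis=0)
    total[total == 0] = 1.0
    out /= total
    return out


def augment_sample(
    channels: np.ndarray,
    label_stack: np.ndarray,
    config: DeformationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp one training sample (all channels + soft label target) by one
    freshly sampled field.

    ``channels`` is (N, s, s, s) (appearance + coordinate channels);
    ``label_stack`` is (C, s, s, s) one-hot or soft.  Both are warped by the
    same field so appearance, location and target stay consistent.  With
    ``alpha_i == 0`` (or ``enabled=False``) the sample is returned unchanged.
    """
    channels = np.asarray(channels, dtype=np.float32)
    label_stack = np.asarray(label_stack, dtype=np.float32)
    if channels.ndim != 4 or label_stack.ndim != 4:
        raise ValueError("channels and label_stack must be 4D (C, X, Y, Z)")
    if channels.shape[1:] != label_stack.shape[1:]:
        raise ValueError("channels and labels must share spatial dims")
    if not config.enabled or config.alpha_i == 0.0:
        return channels, label_stack
    field = sample_field(channels.shape[1:], config, rng)
    warped = np.stack([warp_scalar(ch, field) for ch in channels])
    warped_labels = warp_labels(label_stack, field)
    return warped, warped_labels
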