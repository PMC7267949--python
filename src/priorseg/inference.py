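"""Sliding-window inference restricted to the working volume.

The trained network is applied on a regular grid of output tiles (stride 4
by default) covering the global working volume B; per-voxel class
probabilities are arithmetic means over all overlapping tiles.  The hard
label map assigns, inside B, the argmax class (ties to the lowest class
index); every voxel of a positive volume P^c is assigned c without network
evaluation; all other voxels are background.  Optional postprocessing keeps
only the largest connected component per class, removing isolated clusters
of false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .model import Network
from .priors import PriorSet, coordinate_images
from .volumes import CommonSpaceVolume, LabelMap, extract_patch, normalize_appearance

__all__ = [
    "InferenceConfig",
    "SegmentationResult",
    "plan_tiles",
    "predict_volume",
    "merge_with_priors",
    "keep_largest_component",
    "segment_subject",
]


@dataclass
class InferenceConfig:
    """stride: tile spacing in voxels (1..output side); connectivity: 6 or 26
    for the largest-component postprocessing."""

    stride: int = 4
    batch_size: int = 32
    connectivity: int = 26
    apply_postprocessing: bool = True

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


def plan_tiles(mask: np.ndarray, output_side: int, stride: int) -> np.ndarray:
    """Centers of a minimal regular stride-spaced grid of output tiles such
    that every voxel of ``mask`` is covered by at least one tile.

    Per axis, tile starts run from the mask's bounding box minimum in steps
    of ``stride``; a final start is clamped so the last tile reaches the
    bounding box maximum.  Requires 1 <= stride <= output_side (otherwise
    gaps would be possible).  Returns an (n, 3) array of tile centers.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot plan tiles over an empty mask")
    if not 1 <= stride <= output_side:
        raise ValueError(f"stride must be in [1, {output_side}], got {stride}")
    half = output_side // 2
    axes_centers = []
    nz = np.nonzero(mask)
    for ax in range(3):
        lo, hi = int(nz[ax].min()), int(nz[ax].max())
        extent = hi - lo + 1
        n_steps = 0 if extent <= output_side else -(-(extent - output_side) // stride)
        centers_ax = []
        for k in range(n_steps + 1):
            # regular grid from the bbox minimum; centers clamped into the
            # volume (a clamped final tile still reaches the bbox maximum
            # because stride <= output_side)
            c = min(lo + stride * k + half, mask.shape[ax] - 1 - half)
            if not centers_ax or c != centers_ax[-1]:
                centers_ax.append(c)
        axes_centers.append(np.asarray(centers_ax))
    centers = np.stack(
        np.meshgrid(*axes_centers, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    return centers


def predict_volume(
    net: Network,
    volume: CommonSpaceVolume,
    tile_centers: np.ndarray,
    config: InferenceConfig,
    coordinates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Overlap-averaged class probabilities over the planned tiles.

    Each tile's input patch is extracted around its center (zero-filled
    outside the volume), the appearance channel is per-patch normalized, and
    coordinate channels are appended unmodified when given.  Returns
    (probabilities (C, X, Y, Z), counts (X, Y, Z)); voxels with count 0 carry
    no estimate.
    """
    shape = volume.shape
    n_classes = net.spec.n_classes
    out_side = 9  # the architecture's output tile side
    input_side = net.spec.required_input_side(out_side)
    half = out_side // 2

    acc = np.zeros((n_classes, *shape), dtype=np.float64)
    counts = np.zeros(shape, dtype=np.int32)

    for i in range(0, len(tile_centers), config.batch_size):
        batch_centers = tile_centers[i : i + config.batch_size]
        xs = []
        for center in batch_centers:
            app = extract_patch(volume.data, tuple(center), input_side).channels[0]
            channels = [normalize_appearance(app)]
            if coordinates is not None:
                channels.extend(extract_patch(coordinates, tuple(center), input_side).channels)
            xs.append(np.moveaxis(np.stack(channels), 0, -1))
        probs = net.forward(np.stack(xs), training=False)  # (b, o, o, o, C)
        for center, p in zip(batch_centers, probs):
            lo = [int(c) - half for c in center]
            src = []
            dst = []
            for ax in range(3):
                a, b = lo[ax], lo[ax] + out_side
                dst.append(slice(max(a, 0), min(b, shape[ax])))
                src.append(slice(max(a, 0) - a, out_side - (b - min(b, shape[ax]))))
            acc[(slice(None), *dst)] += np.moveaxis(p, -1, 0)[(slice(None), *src)]
            counts[tuple(dst)] += 1

    covered = counts > 0
    acc[:, covered] /= counts[covered]
    return acc, counts


def merge_with_priors(
    probabilities: np.ndarray,
    priors: PriorSet | None,
    counts: np.ndarray | None = None,
    n_classes: int | None = None,
) -> LabelMap:
    """Combine averaged probabilities with the positive volumes.

    With priors: voxels of B (that received an estimate) take the argmax
    class (ties to the lowest index), every voxel of P^c is set to c
    regardless of the network output, and everything else is background.
    Without priors (prior-free baseline): plain argmax wherever an estimate
    exists.
    """
    probabilities = np.asarray(probabilities)
    if n_classes is None:
        n_classes = probabilities.shape[0]
    argmax = probabilities.argmax(axis=0).astype(np.int32)
    estimated = counts > 0 if counts is not None else np.ones(probabilities.shape[1:], dtype=bool)
    out = np.zeros(probabilities.shape[1:], dtype=np.int32)
    if priors is None:
        out[estimated] = argmax[estimated]
        return LabelMap(out, n_classes=n_classes)
    occupied = np.zeros(out.shape, dtype=bool)
    for c in priors.classes:
        pc = priors.positive_volumes[c]
        if (pc & occupied).any():
            raise ValueError(f"positive volume of class {c} overlaps another class")
        occupied |= pc
    inside = priors.global_volume & estimated
    out[inside] = argmax[inside]
    for c in priors.classes:
        out[priors.positive_volumes[c]] = c
    return LabelMap(out, n_classes=n_classes)


def keep_largest_component(labelmap: LabelMap, connectivity: int = 26) -> LabelMap:
    """For each class independently, keep only the largest connected
    component (ties broken by lowest component id in scan order)."""
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    data = labelmap.data.copy()
    for c in range(1, labelmap.n_classes):
        mask = data == c
        if not mask.any():
            continue
        comp, n = ndimage.label(mask, structure=structure)
        if n <= 1:
            continue
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        keep = int(np.argmax(sizes))  # lowest id wins ties
        data[mask & (comp != keep)] = 0
    return LabelMap(data, n_classes=labelmap.n_classes, voxel_size=labelmap.voxel_size, affine=labelmap.affine)


@dataclass
class SegmentationResult:
    """Probabilities, contribution counts, and hard label maps (before and
    after largest-component postprocessing)."""

    probabilities: np.ndarray
    counts: np.ndarray
    labels: LabelMap
    labels_before_postprocessing: LabelMap


def segment_subject(
    net: Network,
    volume: CommonSpaceVolume,
    priors: PriorSet | None,
    config: InferenceConfig | None = None,
    use_coordinates: bool = True,
) -> SegmentationResult:
    """End-to-end segmentation of one subject: plan tiles over the working
    volume (or the whole grid without priors), predict with overlap
    averaging, merge with positive volumes, optionally keep the largest
    component per class.  Deterministic for fixed weights."""
    config = config or InferenceConfig()
    out_side = 9
    if priors is not None:
        region = priors.global_volume
        coords = priors.coordinates if use_coordinates else None
    else:
        region = np.ones(volume.shape, dtype=bool)
        coords = coordinate_images(volume.shape) if use_coordinates else None
    centers = plan_tiles(region, out_side, config.stride)
    probs, counts = predict_volume(net, volume, centers, config, coords)
    raw = merge_with_priors(probs, priors, counts, n_classes=net.spec.n_classes)
    raw.voxel_size = volume.voxel_size
    final = keep_largest_component(raw, config.connectivity) if config.apply_postprocessing else raw
    return SegmentationResult(
        probabilities=probs, counts=counts, labels=final, labels_before_postprocessing=raw
    )
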