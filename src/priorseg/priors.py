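"""Registration-derived spatial priors.

Given the label maps of the non-test subjects of a cohort that is already
linearly aligned to a common space, three priors are derived per structure
class c >= 1:

* the *working volume* ``B^c = D (+) (U^c - I^c)`` - the binary dilation
  (3x3x3 structuring element D, one iteration) of the union-minus-
  intersection of the subjects' class-c masks, i.e. the region where the
  presence of the structure is uncertain across subjects;
* the *positive volume* ``P^c = I^c - (I^c n B^c)`` - voxels inside every
  subject's mask and outside the working volume, labeled c at test time
  without evaluating the network;
* the *global working volume* ``B = U_c B^c`` - the only region where the
  network is trained and applied.

Coordinate images give every voxel its own (x, y, z) position so a
patch-based network can tell mirrored structures apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volumes import LabelMap

__all__ = [
    "PriorSet",
    "class_working_volume",
    "positive_volume",
    "global_working_volume",
    "coordinate_images",
    "build_priors",
    "save_priors",
    "load_priors",
]

#: 3x3x3 all-ones structuring element (26-connectivity), one dilation pass.
DILATION_ELEMENT = np.ones((3, 3, 3), dtype=bool)


def _check_shapes(masks: Sequence[np.ndarray]) -> tuple[int, ...]:
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    for i, m in enumerate(masks):
        if m.shape != shape:
            raise ValueError(f"mask {i} has shape {m.shape}, expected {shape}")
    return shape


def class_working_volume(
    masks: Sequence[np.ndarray], dilation_element: np.ndarray = DILATION_ELEMENT
) -> np.ndarray:
    """Working volume ``B^c``: dilated union-minus-intersection of masks."""
    _check_shapes(masks)
    union = np.zeros(masks[0].shape, dtype=bool)
    inter = np.ones(masks[0].shape, dtype=bool)
    for m in masks:
        m = m.astype(bool)
        union |= m
        inter &= m
    uncertain = union & ~inter
    if not uncertain.any():
        return uncertain
    return ndimage.binary_dilation(uncertain, structure=dilation_element)


def positive_volume(masks: Sequence[np.ndarray], working_volume: np.ndarray) -> np.ndarray:
    """Positive volume ``P^c = I^c - (I^c n B^c)``."""
    shape = _check_shapes(masks)
    if working_volume.shape != shape:
        raise ValueError(
            f"working volume shape {working_volume.shape} does not match masks {shape}"
        )
    inter = np.ones(shape, dtype=bool)
    for m in masks:
        inter &= m.astype(bool)
    return inter & ~working_volume.astype(bool)


def global_working_volume(class_working_volumes: Sequence[np.ndarray]) -> np.ndarray:
    """Global working volume ``B``: voxelwise union over classes."""
    if len(class_working_volumes) == 0:
        raise ValueError("need at least one class working volume")
    _check_shapes(class_working_volumes)
    out = np.zeros(class_working_volumes[0].shape, dtype=bool)
    for b in class_working_volumes:
        out |= b.astype(bool)
    return out


def coordinate_images(shape: tuple[int, int, int], mode: str = "normalized") -> np.ndarray:
    """Three scalar volumes holding each voxel's x, y and z coordinate.

    ``raw`` mode stores the 0-based voxel index itself; ``normalized`` mode
    rescales each axis linearly onto [-1, 1] across the grid (a single-voxel
    axis maps to 0).  Returned as an array of shape (3, X, Y, Z), float32.
    """
    if len(shape) != 3:
        raise ValueError("shape must be 3D")
    if mode not in ("raw", "normalized"):
        raise ValueError(f"mode must be 'raw' or 'normalized', got {mode!r}")
    coords = np.indices(shape, dtype=np.float32)
    if mode == "normalized":
        for ax, s in enumerate(shape):
            if s > 1:
                coords[ax] = coords[ax] * (2.0 / (s - 1)) - 1.0
            else:
                coords[ax] = 0.0
    return coords


@dataclass
class PriorSet:
    """Per-class working/positive volumes, the global working volume and
    coordinate images for one training cohort.

    Invariants (checked at construction): ``P^c n B^c`` is empty for every
    class, distinct classes' positive volumes are disjoint, and
    ``B = U_c B^c`` exactly.
    """

    working_volumes: dict[int, np.ndarray]
    positive_volumes: dict[int, np.ndarray]
    global_volume: np.ndarray
    coordinates: np.ndarray
    coordinate_mode: str = "normalized"
    source_subject_ids: list[str] = field(default_factory=list)
    dilation_element: np.ndarray = field(default_factory=lambda: DILATION_ELEMENT.copy())

    def __post_init__(self) -> None:
        union = np.zeros(self.global_volume.shape, dtype=bool)
        occupied = np.zeros(self.global_volume.shape, dtype=bool)
        for c, bc in self.working_volumes.items():
            pc = self.positive_volumes[c]
            if (pc & bc).any():
                raise ValueError(f"positive volume of class {c} intersects its working volume")
            if (pc & occupied).any():
                raise ValueError(f"positive volume of class {c} overlaps another class")
            occupied |= pc
            union |= bc
        if not np.array_equal(union, self.global_volume.astype(bool)):
            raise ValueError("global working volume is not the union of class working volumes")

    @property
    def classes(self) -> list[int]:
        return sorted(self.working_volumes)

    @property
    def n_classes(self) -> int:
        """Number of classes including background."""
        return len(self.working_volumes) + 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.global_volume.shape


def build_priors(
    labelmaps: Sequence[LabelMap],
    coordinate_mode: str = "normalized",
    subject_ids: Sequence[str] | None = None,
    dilation_element: np.ndarray = DILATION_ELEMENT,
) -> PriorSet:
    """Build the full prior set from the label maps of the non-test subjects.

    All label maps must share shape and class vocabulary; classes are
    ``1..C-1`` (0 is background and receives no prior).
    """
    if len(labelmaps) < 1:
        raise ValueError("need at least one label map")
    shape = labelmaps[0].shape
    n_classes = labelmaps[0].n_classes
    for lm in labelmaps:
        if lm.shape != shape or lm.n_classes != n_classes:
            raise ValueError("label maps differ in shape or class vocabulary")
    if n_classes < 2:
        raise ValueError("need at least one foreground class")

    working: dict[int, np.ndarray] = {}
    positive: dict[int, np.ndarray] = {}
    for c in range(1, n_classes):
        masks = [lm.class_mask(c) for lm in labelmaps]
        bc = class_working_volume(masks, dilation_element)
        working[c] = bc
        positive[c] = positive_volume(masks, bc)
    global_b = global_working_volume([working[c] for c in sorted(working)])
    ids = list(subject_ids) if subject_ids is not None else [f"subject{i:03d}" for i in range(len(labelmaps))]
    return PriorSet(
        working_volumes=working,
        positive_volumes=positive,
        global_volume=global_b,
        coordinates=coordinate_images(shape, coordinate_mode),
        coordinate_mode=coordinate_mode,
        source_subject_ids=ids,
        dilation_element=np.asarray(dilation_element, dtype=bool),
    )


def save_priors(priors: PriorSet, out_dir: str | Path) -> None:
    """Serialize a prior set as a directory of NIfTI masks plus a manifest."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    for c in priors.classes:
        nib.save(
            nib.Nifti1Image(priors.working_volumes[c].astype(np.uint8), aff),
            str(out / f"working_c{c}.nii.gz"),
        )
        nib.save(
            nib.Nifti1Image(priors.positive_volumes[c].astype(np.uint8), aff),
            str(out / f"positive_c{c}.nii.gz"),
        )
    nib.save(nib.Nifti1Image(priors.global_volume.astype(np.uint8), aff), str(out / "working_global.nii.gz"))
    manifest = {
        "classes": priors.classes,
        "coordinate_mode": priors.coordinate_mode,
        "source_subject_ids": priors.source_subject_ids,
        "shape": list(priors.shape),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_priors(in_dir: str | Path) -> PriorSet:
    import nibabel as nib

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    working = {}
    positive = {}
    for c in manifest["classes"]:
        working[c] = np.asarray(nib.load(str(src / f"working_c{c}.nii.gz")).dataobj).astype(bool)
        positive[c] = np.asarray(nib.load(str(src / f"positive_c{c}.nii.gz")).dataobj).astype(bool)
    global_b = np.asarray(nib.load(str(src / "working_global.nii.gz")).dataobj).astype(bool)
    shape = tuple(manifest["shape"])
    return PriorSet(
        working_volumes=working,
        positive_volumes=positive,
        global_volume=global_b,
        coordinates=coordinate_images(shape, manifest["coordinate_mode"]),
        coordinate_mode=manifest["coordinate_mode"],
        source_subject_ids=list(manifest["source_subject_ids"]),
    )
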