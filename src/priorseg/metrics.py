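"""Dice overlap, modified Hausdorff distance, label median filtering and
report assembly.

Dice is reported as a percentage: ``100 * 2|A n R| / (|A| + |R|)``.  The
modified Hausdorff distance (MHD) is ``max(h(A,R), h(R,A))`` where ``h(A,R)``
is the mean, over *all* labeled voxels of A (not only boundary voxels), of
the Euclidean distance to the nearest labeled voxel of R, in mm; overlapping
voxels therefore contribute zero, which keeps MHD values small for largely
overlapping masks.  Anisotropic voxel sizes are respected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelMap

__all__ = ["dice", "mhd", "median_filter_labels", "MetricsReport", "evaluate"]


def dice(a: np.ndarray, r: np.ndarray) -> float:
    """Dice overlap of two binary masks, in percent.

    Both masks empty scores 100 (with a warning); exactly one empty scores 0.
    """
    a = np.asarray(a).astype(bool)
    r = np.asarray(r).astype(bool)
    if a.shape != r.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {r.shape}")
    na, nr = int(a.sum()), int(r.sum())
    if na == 0 and nr == 0:
        warnings.warn("Dice of two empty masks defined as 100", stacklevel=2)
        return 100.0
    return 100.0 * 2.0 * int((a & r).sum()) / (na + nr)


def mhd(
    a: np.ndarray,
    r: np.ndarray,
    voxel_size: float | tuple[float, float, float] = 1.0,
) -> float:
    """Modified Hausdorff distance between two nonempty binary masks, in mm.

    h(A,R) is computed with an exact Euclidean distance transform of the
    complement of R (sampling = voxel size), averaged over all voxels of A.
    """
    a = np.asarray(a).astype(bool)
    r = np.asarray(r).astype(bool)
    if a.shape != r.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {r.shape}")
    if not a.any() or not r.any():
        raise ValueError("MHD undefined for empty mask")
    if np.isscalar(voxel_size):
        sampling = (float(voxel_size),) * 3
    else:
        sampling = tuple(float(v) for v in voxel_size)

    def h(src: np.ndarray, dst: np.ndarray) -> float:
        dist_to_dst = ndimage.distance_transform_edt(~dst, sampling=sampling)
        return float(dist_to_dst[src].mean())

    return max(h(a, r), h(r, a))


def median_filter_labels(labelmap: np.ndarray | LabelMap) -> np.ndarray:
    """Modal (majority) label over each voxel's 3x3x3 neighborhood.

    The neighborhood is truncated at volume edges; ties retain the original
    voxel label when it participates in the tie, otherwise the lowest tied
    label wins.  Never introduces a label absent from the input.
    """
    if isinstance(labelmap, LabelMap):
        data = labelmap.data
    else:
        data = np.asarray(labelmap)
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError("label map must be integer")
    labels_present = np.unique(data)
    kernel = np.ones((3, 3, 3))
    counts = np.stack(
        [
            ndimage.correlate((data == lab).astype(np.float32), kernel, mode="constant", cval=0.0)
            for lab in labels_present
        ]
    )
    counts = np.rint(counts).astype(np.int32)
    max_count = counts.max(axis=0)
    out = np.empty_like(data)
    # lowest label reaching the max count
    first_max = np.argmax(counts == max_count, axis=0)
    out[...] = labels_present[first_max]
    # ties retain the original label when it is among the maxima
    n_max = (counts == max_count).sum(axis=0)
    orig_idx = np.searchsorted(labels_present, data)
    orig_count = np.take_along_axis(counts, orig_idx[None], axis=0)[0]
    tie_keep = (n_max > 1) & (orig_count == max_count)
    out[tie_keep] = data[tie_keep]
    return out


@dataclass
class MetricsReport:
    """Per-structure Dice (percent) and MHD (mm) for a set of subjects.

    ``table`` has one row per (subject, structure); MHD is NaN where either
    mask was empty (flagged in the ``mhd_defined`` column).
    """

    table: pd.DataFrame

    @classmethod
    def from_records(cls, records: list[dict]) -> "MetricsReport":
        return cls(pd.DataFrame.from_records(
            records, columns=["subject", "structure", "dice_pct", "mhd_mm", "mhd_defined"]
        ))

    @property
    def mean_dice(self) -> float:
        return float(self.table["dice_pct"].mean())

    @property
    def mean_mhd(self) -> float:
        return float(self.table["mhd_mm"].dropna().mean())

    def by_structure(self) -> pd.DataFrame:
        return self.table.groupby("structure").agg(
            dice_mean=("dice_pct", "mean"),
            dice_sd=("dice_pct", "std"),
            mhd_mean=("mhd_mm", "mean"),
            mhd_sd=("mhd_mm", "std"),
        )

    def summary(self) -> str:
        lines = ["structure  dice_mean  dice_sd  mhd_mean  mhd_sd"]
        for structure, row in self.by_structure().iterrows():
            lines.append(
                f"{structure:>9}  {row.dice_mean:9.2f}  {row.dice_sd if np.isfinite(row.dice_sd) else 0.0:7.2f}"
                f"  {row.mhd_mean:8.3f}  {row.mhd_sd if np.isfinite(row.mhd_sd) else 0.0:6.3f}"
            )
        lines.append(f"overall mean Dice = {self.mean_dice:.2f}%  mean MHD = {self.mean_mhd:.3f} mm")
        return "\n".join(lines)


def evaluate(
    pred: LabelMap,
    ref: LabelMap,
    voxel_size: float | tuple[float, float, float] | None = None,
    subject: str = "subject",
) -> MetricsReport:
    """Per-class Dice and MHD between a predicted and a reference label map.

    Classes are compared as independent binary masks (background excluded).
    A class empty in exactly one of the two maps scores Dice 0 and an
    undefined (NaN, flagged) MHD.
    """
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    if pred.n_classes != ref.n_classes:
        raise ValueError(
            f"class vocabularies differ: pred has {pred.n_classes}, ref has {ref.n_classes}"
        )
    if voxel_size is None:
        voxel_size = ref.voxel_size
    records = []
    for c in range(1, ref.n_classes):
        a = pred.class_mask(c)
        r = ref.class_mask(c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = dice(a, r)
        if a.any() and r.any():
            m, defined = mhd(a, r, voxel_size), True
        else:
            m, defined = np.nan, False
        records.append(
            {"subject": subject, "structure": c, "dice_pct": d, "mhd_mm": m, "mhd_defined": defined}
        )
    return MetricsReport.from_records(records)
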