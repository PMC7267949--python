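"""Synthetic cohorts of common-space volumes with mirrored lateralized structures.

Each phantom subject is a head ellipsoid containing one or more pairs of
bright superellipsoid structures placed mirror-symmetrically about the
mid-plane of the mirror axis.  Left and right structures share identical
intensity statistics, so - as for left/right hippocampi in linearly
registered T1-weighted scans - hemisphere is distinguishable only by
location, the condition under which a patch-based network without spatial
priors confuses the two sides.

Anatomy varies across subjects through a smooth random deformation drawn
from the same elastic field sampler used for training augmentation; additive
Gaussian noise models acquisition noise.  Intensities live on a 0-100 scale
(background 0, head 40, structures 60, noise SD 5 by default).  The cohort
is a stand-in for a linearly registered 1x1x1 mm^3 dataset: bit-identical
regeneration from (config, subject index) is guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augment import DeformationConfig, sample_field, warp_labels, warp_scalar
from .volumes import CommonSpaceVolume, LabelMap, write_labels, write_volume

__all__ = ["PhantomConfig", "PhantomSubject", "generate_subject", "generate_cohort"]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom cohort generator.

    grid_side must be >= 32 so the baseline 25^3 input patch fits.  The
    intersubject sigma/alpha pair (mm) controls the smoothness and magnitude
    of per-subject anatomical variability; tissue_means are the background,
    head and structure intensity levels on a 0-100 scale.
    """

    grid_side: int = 64
    voxel_size: float = 1.0
    n_structures_per_side: int = 1
    structure_radius: float = 6.0
    mirror_axis: int = 0
    intersubject_sigma: float = 6.0
    intersubject_alpha: float = 3.0
    noise_sd: float = 5.0
    tissue_means: tuple[float, float, float] = (0.0, 40.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_side < 32:
            raise ValueError("grid_side must be >= 32 (the 25^3 input patch must fit)")
        if self.structure_radius <= 0:
            raise ValueError("structure_radius must be > 0")
        if self.mirror_axis not in (0, 1, 2):
            raise ValueError("mirror_axis must be 0, 1 or 2")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.n_structures_per_side < 1:
            raise ValueError("n_structures_per_side must be >= 1")
        if self.noise_sd < 0 or self.intersubject_alpha < 0 or self.intersubject_sigma <= 0:
            raise ValueError("noise_sd/intersubject_alpha must be >= 0, intersubject_sigma > 0")

    @property
    def n_classes(self) -> int:
        return 1 + 2 * self.n_structures_per_side


@dataclass
class PhantomSubject:
    """One synthetic subject: noisy image, label map, and the noise-free image."""

    subject_id: str
    image: CommonSpaceVolume
    labels: LabelMap
    noiseless: np.ndarray | None = None


def _head_mask(shape: tuple[int, int, int]) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.45 * s for s in shape]
    coords = np.indices(shape, dtype=np.float64)
    q = sum(((coords[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return q <= 1.0


def _superellipsoid(shape, center, semi_axes, exponent=2.5) -> np.ndarray:
    coords = np.indices(shape, dtype=np.float64)
    q = sum((np.abs(coords[a] - center[a]) / semi_axes[a]) ** exponent for a in range(3))
    return q <= 1.0


def _canonical_masks(config: PhantomConfig) -> list[np.ndarray]:
    """Structure masks in canonical (undeformed) anatomy, left/right interleaved:
    labels 2k+1 (left) and 2k+2 (its mirror image), k = 0..n-1."""
    s = config.grid_side
    shape = (s, s, s)
    r = config.structure_radius / config.voxel_size
    semi = [r, 0.7 * r, 0.85 * r]
    center = [(s - 1) / 2.0] * 3
    masks: list[np.ndarray] = []
    spread_axis = (config.mirror_axis + 2) % 3  # stack multiple pairs along this axis
    for k in range(config.n_structures_per_side):
        c = list(center)
        c[config.mirror_axis] = (s - 1) / 2.0 - 0.25 * s
        if config.n_structures_per_side > 1:
            offset = (k - (config.n_structures_per_side - 1) / 2.0) * 2.4 * r
            c[spread_axis] = center[spread_axis] + offset
        left = _superellipsoid(shape, c, semi)
        right = np.flip(left, axis=config.mirror_axis)  # exact mirror by construction
        masks.extend([left, right])
    return masks


def generate_subject(config: PhantomConfig, subject_index: int, session: int = 0) -> PhantomSubject:
    """Generate one subject deterministically from (config, subject_index).

    ``session`` selects the acquisition-noise realization only: sessions of
    one subject share the same anatomy (a scan-rescan pair is sessions 0 and
    1 of the same index).  If the per-subject deformation pushes a structure
    outside the head, a fresh sub-seed is tried (at most 10 attempts).
    """
    s = config.grid_side
    shape = (s, s, s)
    bg, head_mean, struct_mean = config.tissue_means
    head = _head_mask(shape)
    masks = _canonical_masks(config)
    for m in masks:
        if not (m & head).sum() == m.sum() or m.sum() == 0:
            raise ValueError("structure_radius places structures outside the head mask")

    canonical = np.full(shape, bg, dtype=np.float32)
    canonical[head] = head_mean
    for m in masks:
        canonical[m] = struct_mean

    # tissue map for crisp label warping: 0 bg, 1 head, 2.. structures
    tissue = np.zeros(shape, dtype=np.int32)
    tissue[head] = 1
    for i, m in enumerate(masks):
        tissue[m] = 2 + i

    deform_cfg = DeformationConfig(
        sigma_e=config.intersubject_sigma,
        alpha_i=config.intersubject_alpha,
        voxel_size=config.voxel_size,
    )
    for attempt in range(10):
        rng = np.random.default_rng([config.seed, subject_index, attempt])
        if config.intersubject_alpha > 0:
            fld = sample_field(shape, deform_cfg, rng)
            image = warp_scalar(canonical, fld)
            soft = warp_labels(tissue, fld, n_classes=2 + len(masks))
            warped_tissue = soft.argmax(axis=0)
        else:
            image = canonical.copy()
            warped_tissue = tissue.copy()
        warped_head = warped_tissue >= 1
        ok = True
        for i in range(len(masks)):
            m = warped_tissue == 2 + i
            if m.sum() == 0 or (m & ~warped_head).any() or _touches_boundary(m):
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError(
            f"subject {subject_index}: structures left the head mask in 10 attempts; "
            "reduce intersubject_alpha or structure_radius"
        )

    labels = np.zeros(shape, dtype=np.int32)
    for i in range(len(masks)):
        labels[warped_tissue == 2 + i] = i + 1

    noiseless = image.copy()
    if config.noise_sd > 0:
        noise_rng = np.random.default_rng([config.seed, subject_index, 1000 + session])
        image = image + noise_rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)

    vs = (config.voxel_size,) * 3
    sid = f"sub{subject_index:03d}" + (f"_ses{session}" if session else "")
    return PhantomSubject(
        subject_id=sid,
        image=CommonSpaceVolume(image.astype(np.float32), vs),
        labels=LabelMap(labels, n_classes=config.n_classes, voxel_size=vs),
        noiseless=noiseless,
    )


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


def generate_cohort(
    config: PhantomConfig,
    n_subjects: int,
    out_dir: str | Path | None = None,
    session: int = 0,
) -> list[PhantomSubject]:
    """Generate ``n_subjects`` subjects (sub-seeded by index); optionally write
    image/label NIfTI pairs to ``out_dir``.

    At least two subjects are required: the working-volume priors are defined
    by inter-subject label disagreement, which needs a cohort.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (priors need inter-subject disagreement)")
    subjects = [generate_subject(config, i, session=session) for i in range(n_subjects)]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sub in subjects:
            write_volume(sub.image, out / f"{sub.subject_id}_image.nii.gz")
            write_labels(sub.labels, out / f"{sub.subject_id}_labels.nii.gz")
    return subjects
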