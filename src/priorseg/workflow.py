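"""Cross-validation, the spatial-prior ablation, and scan-rescan reliability.

These orchestrators run whole experiments on a cohort: k-fold
cross-validation of one variant, the four-arm ablation (baseline,
coordinates only, working volume only, both priors) with and without
postprocessing, and scan-rescan reliability where one trained model
segments two noise realizations of the same anatomy.  All randomness
derives from a master seed through named substreams, so a configuration
reproduces its report exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .api import SpatialPriorNet, SpatialPriorNetResults
from .augment import DeformationConfig, sample_field, warp_labels
from .inference import InferenceConfig, keep_largest_component
from .metrics import MetricsReport, evaluate
from .training import TrainConfig
from .volumes import LabelMap

__all__ = [
    "RunConfig",
    "assign_folds",
    "run_crossvalidation",
    "AblationResult",
    "run_ablation",
    "count_lateral_confusions",
    "ReliabilityResult",
    "run_reliability",
]


@dataclass
class RunConfig:
    """Experiment-level configuration.

    ``variant`` resolves to the prior/depth/augmentation flags (see
    :mod:`priorseg.api`); the master ``seed`` feeds every random stream.
    """

    variant: str = "CNN-SP"
    fold_count: int = 5
    n_test_subjects: int = 4
    width: int = 32
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: DeformationConfig | None = None
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    manual_jitter_sigma: float = 4.0
    manual_jitter_alpha: float = 1.0

    def model_for(self, subjects: Sequence, variant: str | None = None) -> SpatialPriorNet:
        v = variant or self.variant
        train_cfg = replace(self.train, seed=self.seed)
        return SpatialPriorNet.from_variant(
            subjects,
            v,
            width=self.width,
            train_config=train_cfg,
            augment_config=self.augment,
            inference_config=self.inference,
        )


def assign_folds(subject_ids: Sequence[str], k: int, seed: int) -> dict[str, int]:
    """Deterministic, balanced subject-to-fold assignment (sizes differ <= 1)."""
    ids = list(subject_ids)
    if k < 2 or k > len(ids):
        raise ValueError("fold count must be in [2, n_subjects]")
    order = np.random.default_rng([seed, 101]).permutation(len(ids))
    return {ids[idx]: i % k for i, idx in enumerate(order)}


def run_crossvalidation(subjects: Sequence, config: RunConfig) -> tuple[MetricsReport, pd.DataFrame]:
    """k-fold cross-validation: per fold, priors and training use only the
    non-test subjects; every subject is segmented exactly once as test.

    Returns the pooled per-(subject, structure) report and a per-fold
    summary table.
    """
    folds = assign_folds([s.subject_id for s in subjects], config.fold_count, config.seed)
    tables = []
    fold_rows = []
    for fold in range(config.fold_count):
        test = [s for s in subjects if folds[s.subject_id] == fold]
        rest = [s for s in subjects if folds[s.subject_id] != fold]
        if len(rest) < 2:
            raise ValueError(f"fold {fold} leaves fewer than 2 non-test subjects")
        results = config.model_for(rest).fit()
        for s in test:
            seg = results.segment(s.image)
            rep = evaluate(seg.labels, s.labels, subject=s.subject_id)
            tables.append(rep.table.assign(fold=fold))
        fold_rows.append(
            {
                "fold": fold,
                "n_train": len(rest),
                "n_test": len(test),
                "best_val_loss": results.train_state.best_val_loss,
                "iterations": results.train_state.iteration + 1,
            }
        )
    pooled = MetricsReport(pd.concat(tables, ignore_index=True))
    return pooled, pd.DataFrame(fold_rows)


def count_lateral_confusions(
    pred: LabelMap, ref: LabelMap, pairs: Sequence[tuple[int, int]] | None = None
) -> int:
    """Count connected components of a predicted structure lying in the
    territory of its mirror partner.

    A component of predicted class c counts as a left/right confusion when
    it intersects the reference mask of the mirrored class but not the
    reference mask of c itself.  Pairs default to the interleaved left/right
    labeling (1, 2), (3, 4), ...
    """
    if pairs is None:
        pairs = [(c, c + 1) for c in range(1, ref.n_classes - 1, 2)]
    structure = np.ones((3, 3, 3), dtype=bool)
    n_conf = 0
    for left, right in pairs:
        for c, mirror in ((left, right), (right, left)):
            mask = pred.data == c
            if not mask.any():
                continue
            comp, n = ndimage.label(mask, structure=structure)
            own = ref.data == c
            other = ref.data == mirror
            for i in range(1, n + 1):
                member = comp == i
                if (member & other).any() and not (member & own).any():
                    n_conf += 1
    return n_conf


@dataclass
class AblationResult:
    """Comparison table plus per-variant artifacts."""

    table: pd.DataFrame
    reports: dict[str, dict[bool, MetricsReport]]
    confusions: dict[str, int]
    fits: dict[str, SpatialPriorNetResults]


def run_ablation(
    subjects: Sequence,
    config: RunConfig,
    variants: Sequence[str] = ("CNN-B", "CNN-SC", "CNN-WV", "CNN-SP"),
) -> AblationResult:
    """Train and evaluate the prior-ablation arms with shared seeds and a
    shared train/test split.

    The last ``n_test_subjects`` of the fold assignment are held out as the
    test set for every arm; each arm is scored with postprocessing on and
    off (two table rows per arm).  Left/right confusion components are
    counted on the pre-postprocessing test segmentations.
    """
    ids = [s.subject_id for s in subjects]
    order = np.random.default_rng([config.seed, 202]).permutation(len(ids))
    test_ids = {ids[i] for i in order[: config.n_test_subjects]}
    test = [s for s in subjects if s.subject_id in test_ids]
    rest = [s for s in subjects if s.subject_id not in test_ids]
    if len(rest) < 2:
        raise ValueError("too few non-test subjects for the ablation")

    rows = []
    reports: dict[str, dict[bool, MetricsReport]] = {}
    confusions: dict[str, int] = {}
    fits: dict[str, SpatialPriorNetResults] = {}
    for variant in variants:
        results = config.model_for(rest, variant).fit()
        fits[variant] = results
        reports[variant] = {}
        conf = 0
        tables = {True: [], False: []}
        for s in test:
            seg = results.segment(s.image)
            conf += count_lateral_confusions(seg.labels_before_postprocessing, s.labels)
            for post, labels in (
                (True, seg.labels),
                (False, seg.labels_before_postprocessing),
            ):
                tables[post].append(
                    evaluate(labels, s.labels, subject=s.subject_id).table
                )
        confusions[variant] = conf
        for post in (True, False):
            rep = MetricsReport(pd.concat(tables[post], ignore_index=True))
            reports[variant][post] = rep
            rows.append(
                {
                    "variant": variant,
                    "postprocessing": post,
                    "dice_mean": rep.mean_dice,
                    "dice_sd": float(rep.table["dice_pct"].std()),
                    "mhd_mean": rep.mean_mhd,
                    "mhd_sd": float(rep.table["mhd_mm"].dropna().std()),
                    "confusion_components": conf,
                }
            )
    return AblationResult(
        table=pd.DataFrame(rows), reports=reports, confusions=confusions, fits=fits
    )


@dataclass
class ReliabilityResult:
    automated: MetricsReport
    simulated_manual: MetricsReport

    @property
    def automated_mean_dice(self) -> float:
        return self.automated.mean_dice

    @property
    def manual_mean_dice(self) -> float:
        return self.simulated_manual.mean_dice


def run_reliability(
    session1: Sequence,
    session2: Sequence,
    config: RunConfig,
) -> ReliabilityResult:
    """Scan-rescan reliability on paired sessions of the same anatomies.

    One model (the configured variant) is trained on the session-1 subjects
    that are not in the test set, then segments both sessions of the test
    subjects; the two segmentations of each subject are compared per
    structure.  As a comparator, 'simulated manual' raters are built by
    independently jittering each test subject's true labels with two small
    random deformations and comparing those.
    """
    by_id1 = {s.subject_id: s for s in session1}
    by_id2 = {_base_id(s.subject_id): s for s in session2}
    missing = [i for i in by_id1 if i not in by_id2]
    if missing:
        raise ValueError(f"unpaired subjects (no session 2): {sorted(missing)}")

    ids = [s.subject_id for s in session1]
    order = np.random.default_rng([config.seed, 303]).permutation(len(ids))
    test_ids = [ids[i] for i in order[: config.n_test_subjects]]
    rest = [s for s in session1 if s.subject_id not in set(test_ids)]
    results = config.model_for(rest).fit()

    auto_tables = []
    manual_tables = []
    jitter_cfg = DeformationConfig(
        sigma_e=config.manual_jitter_sigma, alpha_i=config.manual_jitter_alpha
    )
    for k, sid in enumerate(sorted(test_ids)):
        s1, s2 = by_id1[sid], by_id2[sid]
        seg1 = results.segment(s1.image)
        seg2 = results.segment(s2.image)
        auto_tables.append(evaluate(seg1.labels, seg2.labels, subject=sid).table)
        raters = []
        for r in range(2):
            rng = np.random.default_rng([config.seed, 404, k, r])
            fld = sample_field(s1.labels.shape, jitter_cfg, rng)
            soft = warp_labels(s1.labels.data, fld, n_classes=s1.labels.n_classes)
            raters.append(
                LabelMap(soft.argmax(axis=0).astype(np.int32), s1.labels.n_classes,
                         voxel_size=s1.labels.voxel_size)
            )
        manual_tables.append(evaluate(raters[0], raters[1], subject=sid).table)
    return ReliabilityResult(
        automated=MetricsReport(pd.concat(auto_tables, ignore_index=True)),
        simulated_manual=MetricsReport(pd.concat(manual_tables, ignore_index=True)),
    )


def _base_id(subject_id: str) -> str:
    return subject_id.split("_ses")[0]


def scaled_down_ablation(
    seed: int = 1,
    variants: Sequence[str] = ("CNN-B", "CNN-SP"),
    n_subjects: int = 14,
    n_test: int = 4,
) -> AblationResult:
    """Desk-scale spatial-prior ablation on a mirrored phantom cohort.

    This is the package's reference experiment: a 14-subject cohort of 48^3
    phantoms (10 non-test / 4 test), the depth-8 architecture at width 8,
    about 120 class-balanced voxels per iteration for at most 30 iterations
    with early stopping (patience 8), and stride-4 overlap-averaged testing.
    The mirrored structures have identical intensities, so the prior-free
    baseline must confuse left and right from local appearance alone, while
    the coordinate channels plus working volume resolve the ambiguity.
    """
    from .phantoms import PhantomConfig, generate_cohort

    phantom = PhantomConfig(grid_side=48, seed=seed)
    cohort = generate_cohort(phantom, n_subjects)
    config = RunConfig(
        n_test_subjects=n_test,
        width=8,
        seed=seed,
        train=TrainConfig(
            voxels_per_iteration=120,
            batch_size=32,
            max_iterations=30,
            patience=8,
            validation_patches_per_subject=32,
            seed=seed,
        ),
        inference=InferenceConfig(stride=4, batch_size=64),
    )
    return run_ablation(cohort, config, variants=variants)
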