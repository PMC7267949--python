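"""Model/results interface over the training and inference machinery.

`SpatialPriorNet` is constructed from a cohort of labeled subjects plus the
architecture/prior choices; ``fit()`` trains the network and returns a
`SpatialPriorNetResults` carrying the trained weights, the loss curves and
the early-stopping diagnostics, with ``summary()``, ``segment()`` and
``evaluate()`` methods.  The named variants mirror the ablation arms:

========  ====================  ==============  =====
variant   coordinate channels   working volume  depth
========  ====================  ==============  =====
CNN-B     off                   off             8
CNN-SC    on                    off             8
CNN-WV    off                   on              8
CNN-SP    on                    on              8
CNN-SP-D  on                    on              16
========  ====================  ==============  =====

A ``+DA`` suffix enables elastic-deformation augmentation during training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .augment import DeformationConfig
from .inference import InferenceConfig, SegmentationResult, segment_subject
from .metrics import MetricsReport, evaluate
from .model import Network, build_network, count_parameters
from .priors import PriorSet, build_priors
from .training import TrainConfig, TrainState, train
from .volumes import CommonSpaceVolume, LabelMap

__all__ = ["SpatialPriorNet", "SpatialPriorNetResults", "VARIANTS"]

VARIANTS = {
    # (use_coordinates, use_working_volume, depth)
    "CNN-B": (False, False, 8),
    "CNN-SC": (True, False, 8),
    "CNN-WV": (False, True, 8),
    "CNN-SP": (True, True, 8),
    "CNN-SP-D": (True, True, 16),
}


class SpatialPriorNet:
    """Spatial-prior-augmented segmentation network for one training cohort.

    Parameters
    ----------
    subjects : sequence
        Training cohort entries with ``subject_id``, ``image`` and
        ``labels`` attributes; all non-test subjects (the training and
        validation split both sample inside the working volume).
    use_coordinates, use_working_volume : bool
        The two spatial priors; both on reproduces the full method.
    depth, width : int
        Number of 3x3x3 convolution layers and filters per layer.
    train_config, augment_config, inference_config : optional
        Hyperparameter blocks; augmentation is off when ``augment_config``
        is None.
    """

    def __init__(
        self,
        subjects: Sequence,
        use_coordinates: bool = True,
        use_working_volume: bool = True,
        depth: int = 8,
        width: int = 32,
        train_config: TrainConfig | None = None,
        augment_config: DeformationConfig | None = None,
        inference_config: InferenceConfig | None = None,
        priors: PriorSet | None = None,
    ):
        if len(subjects) < 2:
            raise ValueError("need at least 2 subjects")
        self.subjects = list(subjects)
        self.use_coordinates = use_coordinates
        self.use_working_volume = use_working_volume
        self.depth = depth
        self.width = width
        self.train_config = train_config or TrainConfig()
        self.augment_config = augment_config
        self.inference_config = inference_config or InferenceConfig()
        self.n_classes = subjects[0].labels.n_classes
        in_channels = 1 + (3 if use_coordinates else 0)
        self.spec = build_network(depth, width, in_channels, self.n_classes)
        if use_working_volume:
            self.priors = priors if priors is not None else build_priors(
                [s.labels for s in subjects], subject_ids=[s.subject_id for s in subjects]
            )
        else:
            self.priors = None

    @classmethod
    def from_variant(cls, subjects: Sequence, variant: str, **kwargs) -> "SpatialPriorNet":
        """Construct one of the named ablation arms (optionally ``+DA``)."""
        name = variant
        augment = False
        if name.endswith("+DA"):
            augment = True
            name = name[: -len("+DA")].rstrip()
        if name not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; known: {sorted(VARIANTS)}")
        use_coords, use_wv, depth = VARIANTS[name]
        kwargs.setdefault("depth", depth)
        if augment and "augment_config" not in kwargs:
            kwargs["augment_config"] = DeformationConfig()
        return cls(subjects, use_coordinates=use_coords, use_working_volume=use_wv, **kwargs)

    def fit(self) -> "SpatialPriorNetResults":
        """Train with class-balanced sampling, on-the-fly augmentation and
        early stopping; returns the best-validation-iteration weights."""
        net, state = train(
            self.spec,
            self.subjects,
            self.priors,
            self.train_config,
            self.augment_config,
            self.use_coordinates,
        )
        return SpatialPriorNetResults(model=self, network=net, train_state=state)


@dataclass
class SpatialPriorNetResults:
    """Fitted segmentation network plus training diagnostics."""

    model: SpatialPriorNet
    network: Network
    train_state: TrainState

    @property
    def n_parameters(self) -> int:
        return self.network.n_parameters()

    def segment(self, volume: CommonSpaceVolume) -> SegmentationResult:
        return segment_subject(
            self.network,
            volume,
            self.model.priors,
            self.model.inference_config,
            self.model.use_coordinates,
        )

    def evaluate(self, subjects: Sequence) -> MetricsReport:
        """Segment each subject and score against its reference labels."""
        import pandas as pd

        tables = []
        for s in subjects:
            seg = self.segment(s.image)
            rep = evaluate(seg.labels, s.labels, subject=s.subject_id)
            tables.append(rep.table)
        return MetricsReport(pd.concat(tables, ignore_index=True))

    def summary(self) -> str:
        m, st = self.model, self.train_state
        priors_str = []
        if m.use_coordinates:
            priors_str.append("coordinates")
        if m.use_working_volume:
            priors_str.append("working volume")
        lines = [
            "Spatial-prior 3D FCN segmentation",
            "=================================",
            f"architecture        depth {m.depth} x width {m.width}, "
            f"{m.spec.in_channels} input channel(s), {m.n_classes} classes",
            f"parameters          {count_parameters(m.spec):,}",
            f"spatial priors      {', '.join(priors_str) or 'none'}",
            f"augmentation        "
            + (
                f"sigma_e={m.augment_config.sigma_e} mm, alpha_i={m.augment_config.alpha_i} mm"
                if m.augment_config is not None and m.augment_config.enabled
                else "off"
            ),
            f"iterations run      {st.iteration + 1}"
            + (" (early stop)" if st.stopped_early else ""),
            f"best val loss       {st.best_val_loss:.4f} at iteration {st.best_iteration}",
            f"final train loss    {st.train_losses[-1]:.4f}" if st.train_losses else "",
        ]
        return "\n".join(l for l in lines if l)
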