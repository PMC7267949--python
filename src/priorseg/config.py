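"""Structured YAML configuration: one document, one block per module.

Example::

    phantoms:   {grid_side: 48, noise_sd: 5.0, seed: 7}
    model:      {variant: CNN-SP, width: 32}
    training:   {voxels_per_iteration: 2000, batch_size: 128}
    augmentation: {enabled: true, sigma_e_mm: 4.0, alpha_i_mm: 2.0}
    inference:  {stride: 4, connectivity: 26, apply_postprocessing: true}
    workflow:   {fold_count: 5, n_test_subjects: 4, seed: 0}

Every block is optional; omitted values fall back to the module defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .augment import DeformationConfig
from .inference import InferenceConfig
from .phantoms import PhantomConfig
from .training import TrainConfig
from .workflow import RunConfig

__all__ = [
    "load_config",
    "phantom_config",
    "train_config",
    "augment_config",
    "inference_config",
    "run_config",
]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    doc = yaml.safe_load(Path(path).read_text())
    return doc or {}


def phantom_config(doc: dict) -> PhantomConfig:
    block = dict(doc.get("phantoms", {}))
    if "tissue_means" in block:
        block["tissue_means"] = tuple(block["tissue_means"])
    return PhantomConfig(**block)


def train_config(doc: dict) -> TrainConfig:
    return TrainConfig(**doc.get("training", {}))


def augment_config(doc: dict) -> DeformationConfig | None:
    block = dict(doc.get("augmentation", {}))
    if not block.pop("enabled", False):
        return None
    block.setdefault("sigma_e_mm", 4.0)
    block.setdefault("alpha_i_mm", 2.0)
    return DeformationConfig(
        sigma_e=block["sigma_e_mm"], alpha_i=block["alpha_i_mm"],
        voxel_size=block.get("voxel_size_mm", 1.0),
    )


def inference_config(doc: dict) -> InferenceConfig:
    return InferenceConfig(**doc.get("inference", {}))


def run_config(doc: dict) -> RunConfig:
    wf = dict(doc.get("workflow", {}))
    model = dict(doc.get("model", {}))
    return RunConfig(
        variant=model.get("variant", "CNN-SP"),
        width=model.get("width", 32),
        fold_count=wf.get("fold_count", 5),
        n_test_subjects=wf.get("n_test_subjects", 4),
        seed=wf.get("seed", 0),
        train=train_config(doc),
        augment=augment_config(doc),
        inference=inference_config(doc),
    )
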