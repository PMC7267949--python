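"""Patch sampling and the training loop.

At each training iteration approximately ``voxels_per_iteration`` centers
are drawn, an equal number from each training subject and, within a subject,
an equal number from each class (background included) - patch-based networks
are sensitive to class imbalance.  When working-volume priors are in use the
centers are restricted to the global working volume B; without priors the
whole grid is eligible.  Input patches carry the per-patch-normalized
appearance channel and, optionally, the three coordinate channels (which are
*not* per-patch normalized - their absolute values are the information).
Each sample is elastically deformed on the fly, shuffled, and consumed in
minibatches by RMSProp with Nesterov momentum.  A fixed validation set,
sampled uniformly (no class balancing, so that its class mix matches the
working volume) from held-out validation subjects, drives early stopping:
the returned weights are those of the iteration with the lowest validation
cross-entropy, and training stops once that minimum has not improved for
``patience`` iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .augment import DeformationConfig, augment_sample
from .model import LossConfig, Network, NetworkSpec, cross_entropy, required_input_side
from .optim import RMSPropNesterov
from .priors import PriorSet, coordinate_images
from .volumes import extract_patch, normalize_appearance

#: spatial side of the network's output tile used throughout training/inference
_OUTPUT_SIDE = 9

__all__ = [
    "TrainConfig",
    "TrainState",
    "EarlyStopping",
    "split_subjects",
    "sample_iteration_batch",
    "build_validation_set",
    "train",
]


class Subject(Protocol):
    subject_id: str
    image: object  # CommonSpaceVolume
    labels: object  # LabelMap


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the full-scale regime (about 2000 voxels per iteration,
    minibatches of 128, static learning rate 2.5e-4, Nesterov momentum 0.9,
    RMSProp decay 0.9, patience 30 iterations); scaled-down experiments pass
    smaller values.
    """

    voxels_per_iteration: int = 2000
    batch_size: int = 128
    learning_rate: float = 2.5e-4
    momentum: float = 0.9
    rmsprop_decay: float = 0.9
    rmsprop_eps: float = 1e-6
    patience: int = 30
    max_iterations: int = 300
    validation_fraction: float = 0.2
    validation_patches_per_subject: int = 1000
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_iterations < 1 or self.batch_size < 1 or self.voxels_per_iteration < 1:
            raise ValueError("iteration/batch sizes must be >= 1")


def split_subjects(
    subject_ids: Sequence[str], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Random, seeded train/validation split; validation gets
    ``round(fraction * n)`` subjects (at least 1, at most n-1)."""
    ids = list(subject_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 subjects to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_val = min(max(int(round(fraction * n)), 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    val = sorted(ids[i] for i in order[:n_val])
    tr = sorted(ids[i] for i in order[n_val:])
    return tr, val


class EarlyStopping:
    """Keep the argmin-validation weights; stop after ``patience``
    non-improving iterations."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_iteration = -1
        self.since_best = 0

    def update(self, iteration: int, val_loss: float) -> bool:
        """Record one validation loss; returns True if it improved the best."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_iteration = iteration
            self.since_best = 0
            return True
        self.since_best += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self.since_best >= self.patience


@dataclass
class TrainState:
    """Bookkeeping for one training run."""

    iteration: int = 0
    best_val_loss: float = np.inf
    best_iteration: int = -1
    iterations_since_best: int = 0
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    stopped_early: bool = False


def _one_hot_patch(label_patch: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((n_classes, *label_patch.shape), dtype=np.float32)
    for c in range(n_classes):
        out[c] = label_patch == c
    return out


def _center_crop(stack: np.ndarray, out_side: int) -> np.ndarray:
    side = stack.shape[1]
    off = (side - out_side) // 2
    sl = slice(off, off + out_side)
    return stack[:, sl, sl, sl]


def _assemble_sample(
    subject,
    center: tuple[int, int, int],
    input_side: int,
    out_side: int,
    n_classes: int,
    coords: np.ndarray | None,
    augment_config: DeformationConfig | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Build one (channels-last input patch, soft target) pair."""
    app = extract_patch(subject.image.data, center, input_side).channels[0]
    channels = [normalize_appearance(app)]
    if coords is not None:
        channels.extend(extract_patch(coords, center, input_side).channels)
    chan = np.stack(channels)
    lab = extract_patch(subject.labels.data, center, input_side).channels[0]
    onehot = _one_hot_patch(lab, n_classes)
    if augment_config is not None and augment_config.enabled and augment_config.alpha_i > 0:
        chan, onehot = augment_sample(chan, onehot, augment_config, rng)
    target = _center_crop(onehot, out_side)
    x = np.moveaxis(chan, 0, -1)  # (side, side, side, N)
    t = np.moveaxis(target, 0, -1)  # (out, out, out, C)
    return x, t


def _region_mask(subject, priors: PriorSet | None) -> np.ndarray:
    if priors is not None:
        return priors.global_volume
    return np.ones(subject.labels.shape, dtype=bool)


def sample_iteration_batch(
    subjects: Sequence[Subject],
    priors: PriorSet | None,
    config: TrainConfig,
    input_side: int,
    out_side: int,
    rng: np.random.Generator,
    use_coordinates: bool = True,
    augment_config: DeformationConfig | None = None,
    return_centers: bool = False,
):
    """One iteration's class-balanced training sample.

    Per (subject, class) quota = floor(voxels_per_iteration / (n_subjects*C));
    centers are drawn uniformly from the class-c voxels of the sampling
    region (the working volume B when priors are given), with replacement
    when a stratum is smaller than its quota.  A class with no voxels in any
    subject's region is an error; subjects missing a stratum are skipped.
    Returns shuffled, channels-last arrays (n, s, s, s, N), (n, o, o, o, C).
    """
    n_classes = subjects[0].labels.n_classes
    quota = config.voxels_per_iteration // (len(subjects) * n_classes)
    quota = max(quota, 1)
    coords = (
        coordinate_images(subjects[0].labels.shape, priors.coordinate_mode)
        if (use_coordinates and priors is not None)
        else coordinate_images(subjects[0].labels.shape) if use_coordinates else None
    )
    xs, ts, centers = [], [], []
    for c in range(n_classes):
        class_seen = False
        for subject in subjects:
            region = _region_mask(subject, priors)
            stratum = np.argwhere(region & (subject.labels.data == c))
            if len(stratum) == 0:
                continue
            class_seen = True
            picks = stratum[rng.integers(0, len(stratum), size=quota)]
            for center in picks:
                x, t = _assemble_sample(
                    subject, tuple(center), input_side, out_side, n_classes,
                    coords, augment_config, rng,
                )
                xs.append(x)
                ts.append(t)
                centers.append(tuple(int(v) for v in center))
    if not xs:
        raise ValueError("no samples drawn: empty sampling region")
    for c in range(n_classes):
        if not any(
            (_region_mask(s, priors) & (s.labels.data == c)).any() for s in subjects
        ):
            raise ValueError(f"class {c} has no voxels in the sampling region of any subject")
    order = rng.permutation(len(xs))
    X = np.stack(xs)[order]
    T = np.stack(ts)[order]
    if return_centers:
        return X, T, [centers[i] for i in order]
    return X, T


def build_validation_set(
    subjects: Sequence[Subject],
    priors: PriorSet | None,
    config: TrainConfig,
    input_side: int,
    out_side: int,
    rng: np.random.Generator,
    use_coordinates: bool = True,
    return_centers: bool = False,
):
    """Fixed validation sample: ``validation_patches_per_subject`` centers per
    subject drawn uniformly from the sampling region (no class balancing, so
    the class mix approximates the region's own), built once before training
    and never resampled.  No augmentation is applied."""
    if len(subjects) == 0:
        raise ValueError("validation subject set is empty")
    n_classes = subjects[0].labels.n_classes
    coords = (
        coordinate_images(subjects[0].labels.shape, priors.coordinate_mode)
        if (use_coordinates and priors is not None)
        else coordinate_images(subjects[0].labels.shape) if use_coordinates else None
    )
    xs, ts, centers = [], [], []
    for subject in subjects:
        region = _region_mask(subject, priors)
        candidates = np.argwhere(region)
        if len(candidates) == 0:
            raise ValueError(f"sampling region empty for subject {subject.subject_id}")
        picks = candidates[rng.integers(0, len(candidates), size=config.validation_patches_per_subject)]
        for center in picks:
            x, t = _assemble_sample(
                subject, tuple(center), input_side, out_side, n_classes, coords, None, rng
            )
            xs.append(x)
            ts.append(t)
            centers.append(tuple(int(v) for v in center))
    X, T = np.stack(xs), np.stack(ts)
    if return_centers:
        return X, T, centers
    return X, T


def _validation_loss(net: Network, X: np.ndarray, T: np.ndarray, batch_size: int) -> float:
    """Mean categorical cross-entropy over the fixed validation set."""
    total, n = 0.0, 0
    for i in range(0, len(X), batch_size):
        xb, tb = X[i : i + batch_size], T[i : i + batch_size]
        probs = net.forward(xb, training=False)
        total += cross_entropy(probs, tb) * len(xb)
        n += len(xb)
    return total / n


def train(
    spec: NetworkSpec,
    subjects: Sequence[Subject],
    priors: PriorSet | None,
    config: TrainConfig,
    augment_config: DeformationConfig | None = None,
    use_coordinates: bool = True,
    callback=None,
) -> tuple[Network, TrainState]:
    """Train a network on a cohort and return the best-validation weights.

    The cohort is split (seeded) into training and validation subjects; each
    iteration samples a fresh class-balanced batch from the training
    subjects, augments it on the fly, takes minibatch RMSProp/Nesterov steps
    on L = J + alpha*||W||^2, then measures the validation cross-entropy.
    Training stops at ``max_iterations`` or when the best validation loss has
    not improved for ``patience`` iterations; the weights returned are those
    of the best-validation iteration.
    """
    ids = [s.subject_id for s in subjects]
    train_ids, val_ids = split_subjects(ids, config.validation_fraction, config.seed)
    by_id = {s.subject_id: s for s in subjects}
    train_subjects = [by_id[i] for i in train_ids]
    val_subjects = [by_id[i] for i in val_ids]

    # the output tile is fixed at 9^3; the input side follows from the depth
    out_side = _OUTPUT_SIDE
    input_side = required_input_side(out_side, spec.depth)

    init_rng = np.random.default_rng([config.seed, 1])
    sample_rng = np.random.default_rng([config.seed, 2])
    val_rng = np.random.default_rng([config.seed, 3])
    drop_rng = np.random.default_rng([config.seed, 4])

    net = Network(spec, init_rng)
    opt = RMSPropNesterov(
        net.parameters(),
        learning_rate=config.learning_rate,
        rho=config.rmsprop_decay,
        momentum=config.momentum,
        eps=config.rmsprop_eps,
    )
    loss_cfg = LossConfig(weight_decay=config.weight_decay)
    Xv, Tv = build_validation_set(
        val_subjects, priors, config, input_side, out_side, val_rng, use_coordinates
    )

    stopper = EarlyStopping(config.patience)
    state = TrainState()
    best_weights = net.state_dict()
    for iteration in range(config.max_iterations):
        X, T = sample_iteration_batch(
            train_subjects, priors, config, input_side, out_side, sample_rng,
            use_coordinates, augment_config,
        )
        iter_losses = []
        for i in range(0, len(X), config.batch_size):
            xb, tb = X[i : i + config.batch_size], T[i : i + config.batch_size]
            probs = net.forward(xb, training=True, rng=drop_rng)
            j = cross_entropy(probs, tb, loss_cfg.prob_clip)
            reg = loss_cfg.weight_decay * sum(float((w.astype(np.float64) ** 2).sum()) for w in net.filter_weights())
            total = j + reg
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite training loss {total} at iteration {iteration}"
                )
            net.backward(tb)
            net.add_weight_decay_gradients(loss_cfg.weight_decay)
            opt.step(net.gradients())
            iter_losses.append(total)
        val_loss = _validation_loss(net, Xv, Tv, config.batch_size)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at iteration {iteration}")
        state.train_losses.append(float(np.mean(iter_losses)))
        state.val_losses.append(val_loss)
        state.iteration = iteration
        if stopper.update(iteration, val_loss):
            best_weights = net.state_dict()
        state.best_val_loss = stopper.best_loss
        state.best_iteration = stopper.best_iteration
        state.iterations_since_best = stopper.since_best
        if callback is not None:
            callback(state)
        if stopper.should_stop:
            state.stopped_early = True
            break
    net.load_state_dict(best_weights)
    return net, state
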