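import numpy as np
import pytest

from priorseg.model import build_network
from priorseg.priors import build_priors
from priorseg.training import (
    EarlyStopping,
    TrainConfig,
    build_validation_set,
    sample_iteration_batch,
    split_subjects,
    train,
)
from priorseg.volumes import CommonSpaceVolume, LabelMap


class TestSplitSubjects:
    def test_20_subjects_at_20_percent_gives_16_4(self):
        ids = [f"s{i}" for i in range(20)]
        tr, val = split_subjects(ids, 0.2, seed=0)
        assert len(tr) == 16 and len(val) == 4

    def test_seeded_and_reproducible(self):
        ids = [f"s{i}" for i in range(10)]
        assert split_subjects(ids, 0.2, 5) == split_subjects(ids, 0.2, 5)
        assert split_subjects(ids, 0.2, 5) != split_subjects(ids, 0.2, 6)

    def test_partition_covers_and_is_disjoint(self):
        ids = [f"s{i}" for i in range(13)]
        tr, val = split_subjects(ids, 0.3, seed=1)
        assert sorted(tr + val) == sorted(ids)
        assert not set(tr) & set(val)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            split_subjects(["only"], 0.2, 0)


class TestEarlyStopping:
    def test_scripted_sequence_with_patience_two(self):
        """Losses [5, 4, 3, 3.1, 3.1]: stops after two non-improving
        iterations and keeps the weights of the third (the argmin)."""
        stopper = EarlyStopping(patience=2)
        stops_at = None
        for i, val in enumerate([5.0, 4.0, 3.0, 3.1, 3.1]):
            stopper.update(i, val)
            if stopper.should_stop:
                stops_at = i
                break
        assert stops_at == 4
        assert stopper.best_iteration == 2
        assert stopper.best_loss == 3.0

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopping(patience=3)
        for i, val in enumerate(np.linspace(5, 1, 50)):
            stopper.update(i, val)
            assert not stopper.should_stop
        assert stopper.best_iteration == 49

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_returns_argmin_of_any_scripted_sequence(self, seed):
        rng = np.random.default_rng(seed)
        losses = rng.uniform(0, 10, size=40)
        stopper = EarlyStopping(patience=5)
        seen = []
        for i, val in enumerate(losses):
            seen.append(val)
            stopper.update(i, val)
            if stopper.should_stop:
                break
        assert stopper.best_iteration == int(np.argmin(seen))
        assert stopper.best_loss == min(seen)


@pytest.fixture(scope="module")
def tiny_setup():
    from priorseg.phantoms import PhantomConfig, generate_cohort

    cohort = generate_cohort(PhantomConfig(grid_side=32, structure_radius=4.0, seed=3), 4)
    priors = build_priors([s.labels for s in cohort])
    return cohort, priors


class TestSampling:
    def test_class_balance_and_quota(self, tiny_setup):
        cohort, priors = tiny_setup
        cfg = TrainConfig(voxels_per_iteration=120, validation_patches_per_subject=10)
        rng = np.random.default_rng(0)
        X, T, centers = sample_iteration_batch(
            cohort, priors, cfg, input_side=13, out_side=9, rng=rng, return_centers=True
        )
        quota = 120 // (len(cohort) * 3)
        assert len(X) == quota * len(cohort) * 3
        # class of each sample = label at its center; balanced by construction
        counts = {0: 0, 1: 0, 2: 0}
        idx = 0
        # recover per-class counts from the target patches' center voxel
        for t in T:
            counts[int(np.argmax(t[4, 4, 4]))] += 1
        assert len(set(counts.values())) == 1

    def test_all_centers_inside_working_volume(self, tiny_setup):
        cohort, priors = tiny_setup
        cfg = TrainConfig(voxels_per_iteration=60)
        _, _, centers = sample_iteration_batch(
            cohort, priors, cfg, 13, 9, np.random.default_rng(1), return_centers=True
        )
        for c in centers:
            assert priors.global_volume[c]

    def test_empty_class_everywhere_is_an_error(self):
        shape = (32, 32, 32)
        labels = np.zeros(shape, dtype=np.int32)
        labels[10:14, 10:14, 10:14] = 1  # class 2 never occurs

        class Stub:
            def __init__(self, i):
                self.subject_id = f"stub{i}"
                self.image = CommonSpaceVolume(np.zeros(shape, dtype=np.float32))
                self.labels = LabelMap(labels, n_classes=3)

        with pytest.raises(ValueError, match="class 2"):
            sample_iteration_batch(
                [Stub(0), Stub(1)], None, TrainConfig(voxels_per_iteration=30),
                13, 9, np.random.default_rng(0),
            )

    def test_appearance_channel_is_patch_normalized(self, tiny_setup):
        cohort, priors = tiny_setup
        X, _ = sample_iteration_batch(
            cohort, priors, TrainConfig(voxels_per_iteration=30), 13, 9,
            np.random.default_rng(2),
        )
        means = X[..., 0].reshape(len(X), -1).mean(axis=1)
        sds = X[..., 0].reshape(len(X), -1).std(axis=1)
        assert np.allclose(means, 0.0, atol=1e-4)
        assert np.allclose(sds, 1.0, atol=1e-3)

    def test_coordinate_channels_not_patch_normalized(self, tiny_setup):
        cohort, priors = tiny_setup
        X, _, centers = sample_iteration_batch(
            cohort, priors, TrainConfig(voxels_per_iteration=30), 13, 9,
            np.random.default_rng(3), return_centers=True,
        )
        # the x-coordinate channel's center value equals the normalized center
        side = cohort[0].labels.shape[0]
        for x, c in zip(X, centers):
            expected = c[0] * 2.0 / (side - 1) - 1.0
            assert x[6, 6, 6, 1] == pytest.approx(expected, abs=1e-6)


class TestValidationSet:
    def test_fixed_given_one_seed(self, tiny_setup):
        cohort, priors = tiny_setup
        cfg = TrainConfig(validation_patches_per_subject=20)
        X1, T1 = build_validation_set(cohort[:2], priors, cfg, 13, 9, np.random.default_rng(7))
        X2, T2 = build_validation_set(cohort[:2], priors, cfg, 13, 9, np.random.default_rng(7))
        assert np.array_equal(X1, X2) and np.array_equal(T1, T2)

    def test_class_mix_tracks_working_volume_not_uniform(self, tiny_setup):
        cohort, priors = tiny_setup
        cfg = TrainConfig(validation_patches_per_subject=500)
        _, T, centers = build_validation_set(
            cohort, priors, cfg, 13, 9, np.random.default_rng(8), return_centers=True
        )
        sampled = np.zeros(3)
        for t in T:
            sampled[int(np.argmax(t[4, 4, 4]))] += 1
        sampled /= sampled.sum()
        # true class proportions inside B, pooled over subjects
        true = np.zeros(3)
        for s in cohort:
            for c in range(3):
                true[c] += ((s.labels.data == c) & priors.global_volume).sum()
        true /= true.sum()
        assert np.allclose(sampled, true, atol=0.05)
        assert not np.allclose(sampled, 1.0 / 3.0, atol=0.05)  # not class-balanced

    def test_centers_inside_working_volume(self, tiny_setup):
        cohort, priors = tiny_setup
        _, _, centers = build_validation_set(
            cohort[:1], priors, TrainConfig(validation_patches_per_subject=30),
            13, 9, np.random.default_rng(9), return_centers=True,
        )
        assert all(priors.global_volume[c] for c in centers)


class TestTrainLoop:
    def test_loss_descends_on_tiny_phantom_cohort(self, tiny_setup):
        cohort, priors = tiny_setup
        spec = build_network(2, 4, 4, 3)
        cfg = TrainConfig(
            voxels_per_iteration=36, batch_size=18, max_iterations=6, patience=10,
            validation_patches_per_subject=15, seed=0,
        )
        net, state = train(spec, cohort, priors, cfg)
        assert state.train_losses[-1] < state.train_losses[0]
        assert len(state.val_losses) == 6
        assert state.best_val_loss == min(state.val_losses)

    def test_run_is_reproducible(self, tiny_setup):
        cohort, priors = tiny_setup
        spec = build_network(1, 3, 4, 3)
        cfg = TrainConfig(
            voxels_per_iteration=24, batch_size=12, max_iterations=2, patience=5,
            validation_patches_per_subject=10, seed=4,
        )
        _, s1 = train(spec, cohort, priors, cfg)
        _, s2 = train(spec, cohort, priors, cfg)
        assert s1.train_losses == s2.train_losses
        assert s1.val_losses == s2.val_losses

    def test_returns_best_iteration_weights(self, tiny_setup):
        """The returned network's validation loss equals the recorded best."""
        cohort, priors = tiny_setup
        spec = build_network(1, 3, 4, 3)
        cfg = TrainConfig(
            voxels_per_iteration=24, batch_size=12, max_iterations=4, patience=10,
            validation_patches_per_subject=10, seed=2,
        )
        net, state = train(spec, cohort, priors, cfg)
        from priorseg.training import _validation_loss, build_validation_set, split_subjects

        ids = [s.subject_id for s in cohort]
        _, val_ids = split_subjects(ids, cfg.validation_fraction, cfg.seed)
        val_subjects = [s for s in cohort if s.subject_id in val_ids]
        Xv, Tv = build_validation_set(
            val_subjects, priors, cfg, 11, 9, np.random.default_rng([cfg.seed, 3])
        )
        assert _validation_loss(net, Xv, Tv, cfg.batch_size) == pytest.approx(
            state.best_val_loss, abs=1e-6
        )
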