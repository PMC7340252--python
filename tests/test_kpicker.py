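import numpy as np
import pytest

from conftest import noise_crop, template_crop
from cryopick.io_core import Micrograph, extract_crop
from cryopick.kpicker import (
    Candidate,
    PickModelConfig,
    augment_batch,
    build_model,
    kpick,
    load_model,
    make_training_set,
    nms,
    save_model,
    scan_micrograph,
    train_model,
)
from cryopick.nn import SmallCNN
from cryopick.simdata import SceneParams, generate_micrograph


@pytest.fixture(scope="module")
def quick_model(small_scene_module):
    """A model trained briefly on one scene: enough to separate disk/noise."""
    mic, truth = small_scene_module
    crops, labels = make_training_set(
        [mic], [truth.centers], particle_size=48, box_px=72, seed=0
    )
    model = build_model(PickModelConfig(epochs=6, seed=0))
    model, history = train_model(model, crops, labels, seed=0)
    return model, history


@pytest.fixture(scope="module")
def small_scene_module():
    params = SceneParams(size=512, n_particles=20, diameter_px=48, pixel_size_A=6.25,
                         snr=1.5, seed=21)
    return generate_micrograph(params)


class TestBuildModel:
    def test_probabilities_sum_to_one(self):
        model = build_model(PickModelConfig(seed=0))
        rng = np.random.default_rng(0)
        crops = rng.standard_normal((5, 64, 64)).astype(np.float32)
        probs = model.predict_proba(crops)
        assert probs.shape == (5, 2)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_initial_predictions(self):
        rng = np.random.default_rng(1)
        crops = rng.standard_normal((3, 64, 64)).astype(np.float32)
        p1 = build_model(PickModelConfig(seed=7)).predict_proba(crops)
        p2 = build_model(PickModelConfig(seed=7)).predict_proba(crops)
        np.testing.assert_array_equal(p1, p2)

    def test_architecture_requires_three_conv_blocks(self):
        with pytest.raises(ValueError):
            PickModelConfig(conv_filters=(32, 64))


class TestBackprop:
    def test_numerical_gradient_check_on_tiny_network(self):
        net = SmallCNN(input_hw=8, conv_filters=(2, 3, 2), dense_hidden=4, seed=0)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 8, 8)).astype(np.float32)
        y = np.array([0, 1])

        def loss_at(param, flat_idx, value):
            old = param.flat[flat_idx]
            param.flat[flat_idx] = value
            from cryopick.nn import cross_entropy, softmax

            loss = cross_entropy(softmax(net.logits(x)), y)
            param.flat[flat_idx] = old
            return loss

        # analytic gradients
        from cryopick.nn import cross_entropy, softmax

        probs = softmax(net.logits(x))
        grad = probs.copy()
        grad[np.arange(2), y] -= 1.0
        grad /= 2
        g = grad
        for layer in reversed(net.layers):
            g = layer.backward(g)

        eps = 1e-3
        checked = 0
        for layer in net.layers:
            for name, param, dparam in layer.params():
                for flat_idx in (0, param.size // 2):
                    num = (loss_at(param, flat_idx, param.flat[flat_idx] + eps)
                           - loss_at(param, flat_idx, param.flat[flat_idx] - eps)) / (2 * eps)
                    assert num == pytest.approx(float(dparam.flat[flat_idx]), abs=2e-3)
                    checked += 1
        assert checked >= 8


class TestMakeTrainingSet:
    def test_balanced_set_with_distance_constraint(self, small_scene_module):
        mic, truth = small_scene_module
        crops, labels = make_training_set([mic], [truth.centers], 48, box_px=72, seed=0)
        n_pos = int((labels == 1).sum())
        assert n_pos == len(truth.centers)
        assert (labels == 0).sum() == n_pos
        assert crops.shape[1:] == (64, 64)

    def test_negatives_far_from_all_positives(self, small_scene_module):
        mic, truth = small_scene_module
        crops, labels, centers = make_training_set(
            [mic], [truth.centers], 48, box_px=72, seed=3, return_centers=True
        )
        neg = [(x, y) for (mid, x, y), lab in zip(centers, labels) if lab == 0]
        for x, y in neg:
            d = np.hypot(truth.centers.x - x, truth.centers.y - y)
            assert d.min() >= 48  # one particle diameter

    def test_negatives_avoid_true_particle_cores(self, small_scene_module):
        mic, truth = small_scene_module
        crops, labels, centers = make_training_set(
            [mic], [truth.centers], 48, box_px=72, seed=5, return_centers=True
        )
        neg = [(x, y) for (mid, x, y), lab in zip(centers, labels) if lab == 0]
        clean = sum(
            np.hypot(truth.centers.x - x, truth.centers.y - y).min() >= 24 for x, y in neg
        )
        assert clean / len(neg) >= 0.95

    def test_overcrowded_micrograph_fails_informatively(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((128, 128)).astype(np.float32)
        mic = Micrograph(img, 5.0, "crowded")
        from cryopick.io_core import CoordinateSet

        xs, ys = np.meshgrid(np.arange(32, 128, 16), np.arange(32, 128, 16))
        coords = CoordinateSet(xs.ravel().astype(float), ys.ravel().astype(float))
        with pytest.raises(RuntimeError, match="negatives"):
            make_training_set([mic], [coords], particle_size=64, box_px=64, seed=0,
                              max_attempts_per_negative=20)


class TestAugment:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        crops = np.stack([template_crop("disk", rng, 0.3) for _ in range(4)])
        np.testing.assert_array_equal(augment_batch(crops, seed=9), augment_batch(crops, seed=9))

    def test_zero_angle_no_flips_is_identity(self):
        rng = np.random.default_rng(1)
        crops = np.stack([noise_crop(rng) for _ in range(3)])
        out = augment_batch(crops, seed=0, max_angle=0.0, flips=False)
        np.testing.assert_array_equal(out, crops)

    def test_double_flip_equals_180_degree_rotation(self):
        rng = np.random.default_rng(2)
        crop = noise_crop(rng)
        np.testing.assert_array_equal(crop[::-1, ::-1], np.rot90(crop, 2))


class TestTrainModel:
    def test_learns_disk_vs_noise_quickly(self, quick_model):
        _, history = quick_model
        assert len(history) == 6
        assert history.train_accuracy[-1] > 0.8
        assert all(0 <= a <= 1 for a in history.val_accuracy)
        assert all(l >= 0 for l in history.train_loss)

    def test_single_class_labels_rejected(self):
        rng = np.random.default_rng(0)
        crops = rng.standard_normal((10, 64, 64)).astype(np.float32)
        model = build_model(PickModelConfig(epochs=1, seed=0))
        with pytest.raises(ValueError):
            train_model(model, crops, np.ones(10, dtype=int), seed=0)

    def test_learned_signal_separates_held_out_crops(self, quick_model, small_scene):
        model, _ = quick_model
        mic, truth = small_scene  # a scene the model never saw
        pos, pos_labels, centers = make_training_set(
            [mic], [truth.centers], 48, box_px=72, seed=13, return_centers=True
        )
        probs = model.predict_proba(pos)[:, 1]
        gap = probs[pos_labels == 1].mean() - probs[pos_labels == 0].mean()
        assert gap >= 0.5

    def test_few_positives_warns_but_trains(self):
        rng = np.random.default_rng(1)
        crops = np.concatenate(
            [np.stack([template_crop("disk", rng, 0.3) for _ in range(20)]),
             np.stack([noise_crop(rng) for _ in range(20)])]
        )
        labels = np.array([1] * 20 + [0] * 20)
        model = build_model(PickModelConfig(epochs=1, seed=0))
        with pytest.warns(UserWarning, match="100"):
            train_model(model, crops, labels, seed=0)


class TestScan:
    def test_threshold_off_returns_full_grid(self, small_scene_module):
        mic, _ = small_scene_module
        model = build_model(PickModelConfig(seed=0))
        cands = scan_micrograph(model, mic, particle_size=48, stride=32, p_min=0.0, box_px=72)
        half = 36
        nx = len(np.arange(half, 512 - half + 1, 32))
        assert len(cands) == nx * nx

    def test_grid_covers_every_true_center(self, small_scene_module):
        mic, truth = small_scene_module
        model = build_model(PickModelConfig(seed=0))
        stride = 12
        cands = scan_micrograph(model, mic, 48, stride=stride, p_min=0.0, box_px=72)
        cx = np.array([c.x for c in cands])
        cy = np.array([c.y for c in cands])
        for x, y, _ in truth.centers:
            d = np.hypot(cx - x, cy - y)
            assert d.min() <= stride * np.sqrt(2) / 2 + 1e-6

    def test_scan_window_matches_training_extraction(self, small_scene_module):
        mic, _ = small_scene_module
        model = build_model(PickModelConfig(seed=0))
        cands = scan_micrograph(model, mic, 48, stride=64, p_min=0.0, box_px=72)
        c = cands[3]
        crop = extract_crop(mic.image, c.x, c.y, 72, 4)
        prob = model.predict_proba(crop[None])[0, 1]
        assert prob == pytest.approx(c.prob, abs=1e-6)

    def test_micrograph_smaller_than_box_rejected(self):
        rng = np.random.default_rng(0)
        mic = Micrograph(rng.standard_normal((64, 64)).astype(np.float32), 5.0)
        model = build_model(PickModelConfig(seed=0))
        with pytest.raises(ValueError):
            scan_micrograph(model, mic, particle_size=128)

    def test_trained_model_silent_on_blank_noise(self, quick_model):
        model, _ = quick_model
        rng = np.random.default_rng(3)
        blank = Micrograph(rng.standard_normal((256, 256)).astype(np.float32), 6.25, "blank")
        cands = scan_micrograph(model, blank, 48, stride=16, p_min=0.9, box_px=72)
        assert len(cands) == 0


class TestNms:
    def test_keeps_higher_probability_of_close_pair(self):
        cands = [Candidate(0.0, 0.0, 0.95), Candidate(5.0, 0.0, 0.92)]
        kept = nms(cands, min_dist=10.0)
        assert len(kept) == 1 and kept[0].prob == 0.95

    def test_identity_when_no_pair_close(self):
        cands = [Candidate(0, 0, 0.9), Candidate(50, 0, 0.8), Candidate(0, 50, 0.7)]
        assert len(nms(cands, 10.0)) == 3

    def test_matches_reference_greedy_on_200_random_candidates(self):
        rng = np.random.default_rng(0)
        cands = [
            Candidate(float(x), float(y), float(p))
            for x, y, p in zip(rng.random(200) * 500, rng.random(200) * 500, rng.random(200))
        ]
        kept = nms(cands, 40.0)

        order = sorted(range(200), key=lambda i: (-cands[i].prob, cands[i].x, cands[i].y))
        accepted = []
        for i in order:
            ok = all(
                np.hypot(cands[i].x - cands[j].x, cands[i].y - cands[j].y) >= 40.0
                for j in accepted
            )
            if ok:
                accepted.append(i)
        assert [(c.x, c.y, c.prob) for c in kept] == [
            (cands[i].x, cands[i].y, cands[i].prob) for i in accepted
        ]

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(1)
        cands = [
            Candidate(float(x), float(y), float(p))
            for x, y, p in zip(rng.random(60) * 300, rng.random(60) * 300, rng.random(60))
        ]
        kept1 = nms(cands, 30.0)
        kept2 = nms(list(reversed(cands)), 30.0)
        assert [(c.x, c.y) for c in kept1] == [(c.x, c.y) for c in kept2]


class TestKpick:
    def test_picks_separated_by_particle_size_even_untrained(self, small_scene_module):
        mic, _ = small_scene_module
        model = build_model(PickModelConfig(seed=0))
        picks = kpick(model, mic, 48, p_min=0.0, stride=16, box_px=72)
        xy = np.stack([picks.x, picks.y], axis=1)
        if len(xy) > 1:
            d = np.hypot(*(xy[:, None] - xy[None, :]).transpose(2, 0, 1))
            d[np.diag_indices(len(xy))] = np.inf
            assert d.min() >= 48

    def test_trained_model_recovers_particles_and_is_deterministic(
        self, quick_model, small_scene_module
    ):
        model, _ = quick_model
        mic, truth = small_scene_module
        p1 = kpick(model, mic, 48, p_min=0.9, stride=12, box_px=72)
        p2 = kpick(model, mic, 48, p_min=0.9, stride=12, box_px=72)
        np.testing.assert_array_equal(p1.x, p2.x)
        np.testing.assert_array_equal(p1.score, p2.score)
        from cryopick.simdata import evaluate_picks

        m = evaluate_picks(p1, truth.centers, tolerance_px=24)
        assert m.recall >= 0.8


class TestPersistence:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path, quick_model):
        model, _ = quick_model
        rng = np.random.default_rng(0)
        crops = rng.standard_normal((4, 64, 64)).astype(np.float32)
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        np.testing.assert_array_equal(model.predict_proba(crops), back.predict_proba(crops))
        assert back.config == model.config
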