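"""Preprocessing, training orchestration, evaluation, CLI plumbing."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from pestnet.engine import (
    IMAGENET_MEAN, TrainConfig, evaluate, load_checkpoint, preprocess_eval,
    preprocess_train, save_checkpoint, train,
)
from pestnet.labels import read_hierarchy
from pestnet.model import build_model
from pestnet.nn import Tensor
from pestnet.synthetic import DatasetSpec, generate_dataset


@pytest.fixture
def tiny_config():
    return TrainConfig(input_size=32, batch_size=16, max_epochs=2,
                       early_stop_patience=2, warmup_epochs=1,
                       arch="reduced", seed=0)


# -- preprocessing -----------------------------------------------------------


def test_preprocess_train_shape_and_resize_target(rng):
    img = Image.fromarray(np.zeros((300, 400, 3), dtype=np.uint8))
    out = preprocess_train(img, 224, rng)
    assert out.shape == (3, 224, 224)
    # shorter side resized to round(1.1 * 224) = 246
    resized = img.resize((int(round(400 * 246 / 300)), 246))
    assert resized.size[1] == 246


def test_preprocess_gray_at_channel_means_is_near_zero(rng):
    gray = (IMAGENET_MEAN * 255).round().astype(np.uint8)
    img = Image.fromarray(np.tile(gray, (100, 100, 1)))
    out = preprocess_train(img, 64, rng)
    assert np.abs(out).max() < 0.02


def test_preprocess_train_seeded_crops_identical():
    img = Image.fromarray(
        np.random.default_rng(0).integers(0, 255, (90, 120, 3)).astype(np.uint8))
    a = preprocess_train(img, 64, np.random.default_rng(5))
    b = preprocess_train(img, 64, np.random.default_rng(5))
    np.testing.assert_array_equal(a, b)


def test_preprocess_eval_deterministic_and_centered():
    arr = np.random.default_rng(1).integers(0, 255, (80, 80, 3)).astype(np.uint8)
    img = Image.fromarray(arr)
    a = preprocess_eval(img, 64)
    b = preprocess_eval(img, 64)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (3, 64, 64)
    # square input: crop is centered exactly
    resized = np.asarray(img.resize((70, 70), Image.BILINEAR))
    expected = resized[3:67, 3:67]
    np.testing.assert_allclose(
        a, ((expected / 255.0 - IMAGENET_MEAN) /
            [0.229, 0.224, 0.225]).transpose(2, 0, 1).astype(np.float32),
        atol=1e-5)


def test_preprocess_undecodable_file_names_path(tmp_path):
    bad = tmp_path / "broken.png"
    bad.write_text("not an image")
    with pytest.raises(OSError, match="broken.png"):
        preprocess_eval(bad, 64)


# -- config ------------------------------------------------------------------


def test_config_yaml_roundtrip(tmp_path):
    path = tmp_path / "c.yaml"
    path.write_text("input_size: 64\nlearning_rate: 0.002\narch: reduced\n")
    cfg = TrainConfig.from_yaml(path)
    assert cfg.input_size == 64 and cfg.learning_rate == 0.002


def test_config_unknown_key_rejected(tmp_path):
    path = tmp_path / "c.yaml"
    path.write_text("input_size: 64\nlerning_rate: 0.002\n")
    with pytest.raises(ValueError, match="lerning_rate"):
        TrainConfig.from_yaml(path)


def test_config_validation():
    with pytest.raises(ValueError, match="patience"):
        TrainConfig(max_epochs=10, early_stop_patience=11)
    with pytest.raises(ValueError, match="positive"):
        TrainConfig(batch_size=0)


# -- training ----------------------------------------------------------------


def test_early_stop_with_unimprovable_validation(tmp_path):
    """Single-species data: val accuracy is 1.0 from epoch 0, so patience=1
    stops training at epoch 2."""
    spec = DatasetSpec(n_species=1, base_count=10, clutter_level=0.0,
                       occlusion_prob=0.0, image_size=32, seed=0)
    paths = generate_dataset(spec, tmp_path / "d")
    cfg = TrainConfig(input_size=32, batch_size=8, max_epochs=10,
                      early_stop_patience=1, warmup_epochs=1,
                      arch="reduced", seed=0)
    result = train(cfg, paths.train, paths.val, paths.hierarchy,
                   data_root=tmp_path / "d")
    assert len(result.logs) == 2
    assert result.best_epoch == 0
    assert result.best_val_accuracy == 1.0


def test_lambda_logged_from_lambda_max(tmp_path, tiny_config):
    spec = DatasetSpec(n_species=2, base_count=8, image_size=32,
                       clutter_level=0.0, seed=0)
    paths = generate_dataset(spec, tmp_path / "d")
    result = train(tiny_config, paths.train, paths.val, paths.hierarchy,
                   data_root=tmp_path / "d")
    assert result.logs[0].lam == tiny_config.lambda_max
    assert result.logs[0].epoch == 0
    # warm-up: first epoch runs at lr/100
    assert result.logs[0].learning_rate == pytest.approx(
        tiny_config.learning_rate / 100)


def test_training_reproducible(tmp_path, tiny_config):
    spec = DatasetSpec(n_species=2, base_count=10, image_size=32, seed=4)
    paths = generate_dataset(spec, tmp_path / "d")
    r1 = train(tiny_config, paths.train, paths.val, paths.hierarchy,
               data_root=tmp_path / "d")
    r2 = train(tiny_config, paths.train, paths.val, paths.hierarchy,
               data_root=tmp_path / "d")
    assert [vars(a) for a in r1.logs] == [vars(b) for b in r2.logs]


def test_train_inconsistent_hierarchy_errors(tmp_path, tiny_config):
    spec = DatasetSpec(n_species=4, base_count=6, image_size=32, seed=4)
    paths = generate_dataset(spec, tmp_path / "d")
    small = DatasetSpec(n_species=2, base_count=6, image_size=32, seed=4)
    small_paths = generate_dataset(small, tmp_path / "e")
    with pytest.raises(ValueError, match="inconsistent"):
        train(tiny_config, paths.train, paths.val, small_paths.hierarchy,
              data_root=tmp_path / "d")


# -- evaluation --------------------------------------------------------------


@pytest.fixture(scope="module")
def trained(tmp_path_factory):
    root = tmp_path_factory.mktemp("trainrun")
    spec = DatasetSpec(n_species=3, base_count=30, clutter_level=0.05,
                       occlusion_prob=0.0, image_size=32, min_count=2, seed=2)
    paths = generate_dataset(spec, root / "d")
    cfg = TrainConfig(input_size=32, batch_size=16, max_epochs=4,
                      early_stop_patience=4, warmup_epochs=1,
                      learning_rate=2e-3, arch="reduced", seed=0)
    result = train(cfg, paths.train, paths.val, paths.hierarchy,
                   data_root=root / "d", out_dir=root / "run")
    return root, paths, cfg, result


def test_species_accuracy_at_least_refined(trained):
    root, paths, cfg, result = trained
    species_rep, refined_rep = evaluate(result.model, cfg, paths.train,
                                        paths.hierarchy, data_root=root / "d")
    assert species_rep.accuracy >= refined_rep.accuracy
    assert paths.space.n_refined > paths.space.n_species


def test_one_sample_manifest_binary_accuracy(trained, tmp_path):
    root, paths, cfg, result = trained
    df = pd.read_csv(paths.test)
    one = tmp_path / "one.csv"
    df.head(1).to_csv(one, index=False)
    rep, _ = evaluate(result.model, cfg, one, paths.hierarchy,
                      data_root=root / "d")
    assert rep.accuracy in (0.0, 1.0)
    assert rep.n_samples == 1


def test_evaluate_twice_identical(trained, tmp_path):
    root, paths, cfg, result = trained
    a, _ = evaluate(result.model, cfg, paths.val, paths.hierarchy,
                    data_root=root / "d", out_dir=tmp_path / "r1")
    b, _ = evaluate(result.model, cfg, paths.val, paths.hierarchy,
                    data_root=root / "d", out_dir=tmp_path / "r2")
    assert a.to_dict() == b.to_dict()
    assert (tmp_path / "r1" / "confusion.csv").read_text() == \
        (tmp_path / "r2" / "confusion.csv").read_text()


def test_evaluate_class_count_mismatch(trained, tmp_path):
    root, paths, cfg, result = trained
    other = generate_dataset(DatasetSpec(n_species=40, base_count=2,
                                         image_size=32, seed=3),
                             tmp_path / "other")
    with pytest.raises(ValueError, match="classes"):
        evaluate(result.model, cfg, paths.val, other.hierarchy,
                 data_root=root / "d")


def test_checkpoint_roundtrip(trained, tmp_path):
    root, paths, cfg, result = trained
    ckpt = root / "run" / "best.ckpt.npz"
    assert ckpt.exists()
    model, cfg2 = load_checkpoint(ckpt)
    a, _ = evaluate(result.model, cfg, paths.val, paths.hierarchy,
                    data_root=root / "d")
    b, _ = evaluate(model, cfg2, paths.val, paths.hierarchy,
                    data_root=root / "d")
    assert a.to_dict() == b.to_dict()


def test_epoch_log_written(trained):
    root, _, _, result = trained
    lines = (root / "run" / "epochs.log").read_text().strip().splitlines()
    assert len(lines) == len(result.logs)
    assert lines[0].startswith("epoch=0 lambda=1.0000")


# -- BCSA-off equivalence ----------------------------------------------------


def test_zero_gain_bcsa_equals_no_bcsa_model(rng):
    """With alpha=beta=0 the attention is an exact pass-through: forward
    equals the attention-free model under shared weights."""
    with_bcsa = build_model(5, arch="reduced", alpha=0.0, beta=0.0, seed=1)
    without = build_model(5, arch="reduced", use_bcsa=False, seed=2)
    shared = {k: v for k, v in with_bcsa.state_dict().items()
              if not k.startswith("backbone.attn")}
    loaded, missing, unexpected = without.load_state_dict(shared, strict=False)
    assert not missing and not unexpected
    with_bcsa.eval(), without.eval()
    x = Tensor(rng.standard_normal((2, 3, 64, 64)).astype(np.float32))
    np.testing.assert_array_equal(with_bcsa(x).numpy(), without(x).numpy())
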