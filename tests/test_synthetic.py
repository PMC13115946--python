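"""Synthetic pest-scene generator: determinism, morphology, learnability."""

from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from PIL import Image
from scipy import ndimage
from sklearn.linear_model import LogisticRegression

from pestnet.bcsa import sobel_edges
from pestnet.labels import AnnotatedSample, StageTag, build_refined_label_space
from pestnet.synthetic import (
    DatasetSpec, SpecimenParams, complex_background_subset, generate_dataset,
    render_scene, render_specimen, species_archetype,
)

A, L, P, E = (StageTag.ADULT, StageTag.LARVA, StageTag.PUPA, StageTag.EGG)


def sprite_mask_stats(sprite: np.ndarray):
    mask = sprite[..., 3] > 0.5
    ys, xs = np.nonzero(mask)
    h, w = np.ptp(ys) + 1, np.ptp(xs) + 1
    aspect = max(h, w) / min(h, w)
    _, ncomp = ndimage.label(mask)
    return aspect, ncomp


def params_for(stage, angle=0.0):
    hue, aspect, freq = species_archetype(1, 4)
    return SpecimenParams(hue=hue, aspect=aspect, pattern_freq=freq,
                          stage=stage, angle=angle)


# -- specimens ---------------------------------------------------------------


def test_specimen_deterministic():
    s1 = render_specimen(params_for(E), np.random.default_rng(42))
    s2 = render_specimen(params_for(E), np.random.default_rng(42))
    assert s1.tobytes() == s2.tobytes()


def test_larva_more_elongated_than_adult():
    adult, _ = sprite_mask_stats(render_specimen(params_for(A),
                                                 np.random.default_rng(0)))
    larva, _ = sprite_mask_stats(render_specimen(params_for(L),
                                                 np.random.default_rng(0)))
    assert larva > adult


def test_egg_cluster_has_at_least_three_components():
    _, ncomp = sprite_mask_stats(render_specimen(params_for(E),
                                                 np.random.default_rng(0)))
    assert ncomp >= 3


def test_stage_morphologies_distinct():
    masks = {st: render_specimen(params_for(st),
                                 np.random.default_rng(0))[..., 3] > 0.5
             for st in (A, L, P, E)}
    areas = {st: m.sum() for st, m in masks.items()}
    assert len(set(areas.values())) == 4  # no two stages share a silhouette


# -- scenes ------------------------------------------------------------------


def test_scene_flat_background_at_zero_clutter():
    sprite = render_specimen(params_for(P), np.random.default_rng(1))
    img = render_scene(sprite, 0.0, 0.0, np.random.default_rng(1),
                       image_size=64).astype(np.float64)
    border = np.concatenate([img[:4].reshape(-1, 3), img[-4:].reshape(-1, 3)])
    assert border.var(axis=0).max() < 1.0  # flat field up to uint8 rounding


def test_scene_clutter_raises_edge_energy():
    sprite = render_specimen(params_for(P), np.random.default_rng(1))
    def energy(level):
        img = render_scene(sprite, level, 0.0, np.random.default_rng(7),
                           image_size=64).astype(np.float64) / 255.0
        edges = sobel_edges(img.transpose(2, 0, 1))
        return np.abs(edges.ex).sum() + np.abs(edges.ey).sum()
    assert energy(1.0) > energy(0.0)


def test_scene_deterministic():
    sprite = render_specimen(params_for(A), np.random.default_rng(2))
    img1 = render_scene(sprite, 0.5, 0.5, np.random.default_rng(9))
    img2 = render_scene(sprite, 0.5, 0.5, np.random.default_rng(9))
    assert img1.tobytes() == img2.tobytes()


def test_scene_rejects_bad_clutter():
    sprite = render_specimen(params_for(A), np.random.default_rng(2))
    with pytest.raises(ValueError):
        render_scene(sprite, 1.5, 0.0, np.random.default_rng(0))


# -- dataset generation ------------------------------------------------------


def test_generated_hierarchy_matches_subgroup_oracle(tmp_path):
    spec = DatasetSpec(
        n_species=6, base_count=10, min_count=30, seed=3,
        stages_per_species={0: {A: 40, L: 35},
                            **{s: {StageTag.UNSPECIFIED: 10}
                               for s in range(1, 6)}})
    paths = generate_dataset(spec, tmp_path / "d")
    df = pd.read_csv(paths.manifest)
    # oracle over the training rows (the hierarchy is built from train)
    train = df[df.split == "train"]
    expected = 0
    for sp in range(6):
        sub = Counter(StageTag.parse(s) for s in
                      train[train.species_id == sp].stage.fillna(""))
        split = [st for st in (A, L, P, E) if sub[st] > 30]
        residual = sum(sub.values()) - sum(sub[st] for st in split)
        expected += len(split) + (1 if residual > 0 or not split else 0)
    assert paths.space.n_refined == expected
    # the full manifest (40 Adult + 35 Larva) splits species 0 twice; with
    # every sample staged the residual class is empty and not created, so
    # the subgroup-counting oracle gives 2 + 5x1 = 7 refined classes
    full_samples = [AnnotatedSample(r.image_path, int(r.species_id),
                                    StageTag.parse(r.stage))
                    for r in df.itertuples(index=False)]
    full_space = build_refined_label_space(full_samples, 30, n_species=6)
    assert full_space.children_of[0] == [0, 1]
    assert [full_space.stage_of[r] for r in full_space.children_of[0]] == [A, L]
    assert full_space.n_refined == 7


def test_zero_imbalance_gives_equal_counts(tmp_path):
    spec = DatasetSpec(n_species=4, base_count=12, imbalance_exponent=0.0,
                       seed=1)
    paths = generate_dataset(spec, tmp_path / "d")
    counts = pd.read_csv(paths.manifest).groupby("species_id").size()
    assert counts.max() - counts.min() <= 1


def test_imbalance_ratio_at_exponent_1_5(tmp_path):
    spec = DatasetSpec(n_species=6, base_count=40, imbalance_exponent=1.5,
                       seed=1)
    paths = generate_dataset(spec, tmp_path / "d")
    counts = pd.read_csv(paths.manifest).groupby("species_id").size()
    assert counts.max() / counts.min() >= 5


def test_same_spec_identical_manifests(tmp_path):
    spec = DatasetSpec(n_species=3, base_count=8, seed=12)
    p1 = generate_dataset(spec, tmp_path / "a")
    p2 = generate_dataset(spec, tmp_path / "b")
    assert p1.manifest.read_text() == p2.manifest.read_text()
    img = "images/img_00000.png"
    assert (tmp_path / "a" / img).read_bytes() == \
        (tmp_path / "b" / img).read_bytes()


def test_split_is_stratified(small_dataset):
    _, paths = small_dataset
    df = pd.read_csv(paths.manifest)
    for sp, group in df.groupby("species_id"):
        frac = (group.split == "train").mean()
        assert 0.5 < frac < 0.7


# -- complex-background subset ----------------------------------------------


def test_subset_counts(tmp_path):
    spec = DatasetSpec(n_species=6, base_count=10, clutter_level=0.5, seed=2)
    paths = generate_dataset(spec, tmp_path / "d")
    sub = complex_background_subset(paths.manifest, 5)
    assert len(sub) == 30
    assert set(sub.species_id) == set(range(6))


def test_subset_zero_k_and_determinism(small_dataset):
    _, paths = small_dataset
    assert len(complex_background_subset(paths.manifest, 0)) == 0
    s1 = complex_background_subset(paths.manifest, 4)
    s2 = complex_background_subset(paths.manifest, 4)
    pd.testing.assert_frame_equal(s1, s2)


def test_subset_picks_highest_clutter(small_dataset):
    _, paths = small_dataset
    df = pd.read_csv(paths.manifest)
    sub = complex_background_subset(df, 3)
    for sp, group in sub.groupby("species_id"):
        threshold = group.clutter.min()
        rest = df[(df.species_id == sp) &
                  (~df.image_path.isin(group.image_path))]
        assert (rest.clutter <= threshold + 1e-9).all()


def test_subset_insufficient_samples_raises(small_dataset):
    _, paths = small_dataset
    with pytest.raises(ValueError, match="only"):
        complex_background_subset(paths.manifest, 10_000)


# -- learnability invariants -------------------------------------------------


def _hue_image(arr: np.ndarray) -> np.ndarray:
    """Vectorized RGB->hue in [0,1)."""
    mx, mn = arr.max(2), arr.min(2)
    delta = np.where(mx - mn > 0, mx - mn, 1.0)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    hue = np.select(
        [mx == r, mx == g],
        [((g - b) / delta) % 6, (b - r) / delta + 2],
        default=(r - g) / delta + 4) / 6.0
    return hue % 1.0


def _descriptors(root: Path, df: pd.DataFrame):
    hues, shapes = [], []
    for p in df.image_path:
        arr = np.asarray(Image.open(root / p), dtype=np.float64) / 255.0
        mx, mn = arr.max(2), arr.min(2)
        sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-6), 0.0)
        fg = sat > 0.45
        hist = np.histogram(_hue_image(arr)[fg], bins=12, range=(0, 1))[0]
        hues.append(hist / max(hist.sum(), 1))
        _, ncomp = ndimage.label(fg)
        ys, xs = np.nonzero(fg)
        if len(ys) > 4:
            evals = np.sort(np.linalg.eigvalsh(np.cov(np.stack([ys, xs]))))
            elong = evals[1] / max(evals[0], 1e-6)
            fill = len(ys) / max((np.ptp(ys) + 1) * (np.ptp(xs) + 1), 1)
        else:
            elong, fill = 0.0, 0.0
        shapes.append([ncomp, elong, fg.mean() * 100, fill])
    return np.asarray(hues), np.asarray(shapes)


@pytest.fixture(scope="module")
def learnability_dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("learn")
    spec = DatasetSpec(n_species=4, base_count=100, clutter_level=0.1,
                       occlusion_prob=0.05, min_count=10, seed=1,
                       unspecified_frac=0.0)
    paths = generate_dataset(spec, root)
    df = pd.read_csv(paths.manifest)
    hues, shapes = _descriptors(root, df)
    return df, hues, shapes


def test_species_learnable(learnability_dataset):
    df, hues, _ = learnability_dataset
    tr, te = df.split == "train", df.split == "test"
    clf = LogisticRegression(max_iter=3000).fit(hues[tr], df.species_id[tr])
    assert clf.score(hues[te], df.species_id[te]) >= 0.95


def test_stages_learnable(learnability_dataset):
    df, hues, shapes = learnability_dataset
    X = np.hstack([hues, shapes])
    staged = df.stage.notna()
    tr = staged & (df.split == "train")
    te = staged & (df.split == "test")
    clf = LogisticRegression(max_iter=3000).fit(X[tr], df.stage[tr])
    assert clf.score(X[te], df.stage[te]) >= 0.90
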