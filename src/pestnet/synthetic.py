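"""Procedural generator of stage-structured insect-scene datasets.

Produces small RGB scenes of insect-like specimens over textured, cluttered
backgrounds, with a long-tailed species frequency distribution, growth-stage
tags, partial occlusion and illumination jitter.  Serves as the fully
seeded, offline stand-in for a field-collected pest benchmark in tests and
smoke training runs.

Every stochastic choice flows from ``DatasetSpec.seed``; per-image
generators are derived from (seed, image counter), so datasets are
reproducible and extensible.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .labels import (
    AnnotatedSample, RefinedLabelSpace, StageTag, build_refined_label_space,
    write_hierarchy,
)

__all__ = [
    "SpecimenParams", "DatasetSpec", "DatasetPaths", "species_archetype",
    "render_specimen", "render_scene", "generate_dataset",
    "complex_background_subset",
]

_STAGES = (StageTag.ADULT, StageTag.LARVA, StageTag.PUPA, StageTag.EGG)


@dataclass(frozen=True)
class SpecimenParams:
    """Archetype + stage morphology + per-image jitters."""
    hue: float                    # shared across stages of one species
    aspect: float                 # body length/width of the adult form
    pattern_freq: float           # stripe frequency along the body axis
    stage: StageTag = StageTag.ADULT
    angle: float = 0.0            # pose jitter, radians
    scale: float = 1.0
    canvas: int = 48


@dataclass
class DatasetSpec:
    n_species: int = 6
    stages_per_species: dict[int, dict[StageTag, int]] | None = None
    imbalance_exponent: float = 0.0
    clutter_level: float = 0.3
    occlusion_prob: float = 0.1
    image_size: int = 64
    seed: int = 0
    base_count: int = 40          # per-species sample budget before imbalance
    min_count: int = 30           # stage-split threshold for the hierarchy
    unspecified_frac: float = 0.2  # fraction of samples left without a stage tag

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0.0 <= self.clutter_level <= 1.0:
            raise ValueError("clutter_level must lie in [0, 1]")
        if self.imbalance_exponent < 0:
            raise ValueError("imbalance_exponent must be >= 0")


@dataclass
class DatasetPaths:
    root: Path
    images_dir: Path
    manifest: Path
    train: Path
    val: Path
    test: Path
    hierarchy: Path
    space: RefinedLabelSpace


def species_archetype(species: int, n_species: int) -> tuple[float, float, float]:
    """Deterministic (hue, aspect, pattern_freq) for a species index.

    Hues are spread over the 0.40-1.24 (mod 1) band so no species falls in
    the leaf-green background range used by :func:`render_scene`.
    """
    hue = (0.40 + 0.84 * species / max(n_species, 1)) % 1.0
    aspect = 1.4 + 0.5 * ((species * 7) % 5) / 4.0
    pattern_freq = 2.0 + ((species * 3) % 4)
    return hue, aspect, pattern_freq


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    return (y - c) / size, (x - c) / size


def _rotate(u: np.ndarray, v: np.ndarray, angle: float):
    ca, sa = np.cos(angle), np.sin(angle)
    return ca * u - sa * v, sa * u + ca * v


def _ellipse(u, v, cu, cv, ru, rv):
    return ((u - cu) / ru) ** 2 + ((v - cv) / rv) ** 2 <= 1.0


def render_specimen(params: SpecimenParams, rng: np.random.Generator) -> np.ndarray:
    """Render an RGBA sprite, float32 in [0, 1], shape (canvas, canvas, 4).

    The four stage morphologies are geometrically distinct: winged adult
    (ellipse body + wing lobes), smooth capsule pupa, elongated segmented
    larva, and an egg cluster of several separated discs.
    """
    size = params.canvas
    v0, u0 = _grid(size)                      # v: vertical, u: horizontal
    u, v = _rotate(u0, v0, params.angle)
    s = 0.30 * params.scale
    mask = np.zeros((size, size), dtype=bool)
    axial = u.copy()                          # along-body coordinate for stripes

    if params.stage == StageTag.ADULT:
        half_w = s / params.aspect
        mask |= _ellipse(u, v, 0.0, 0.0, s, half_w)
        wing = 0.55 * s
        mask |= _ellipse(u, v, -0.15 * s, -1.1 * half_w, wing, 0.9 * half_w)
        mask |= _ellipse(u, v, -0.15 * s, 1.1 * half_w, wing, 0.9 * half_w)
        mask |= _ellipse(u, v, 1.05 * s, 0.0, 0.35 * s, 0.35 * s)  # head
    elif params.stage == StageTag.PUPA:
        mask |= _ellipse(u, v, 0.0, 0.0, 1.1 * s, 0.45 * s)
    elif params.stage == StageTag.LARVA:
        n_seg = 6
        seg_r = 0.30 * s
        length = 1.45 * s
        for i in range(n_seg):
            cu = -length + 2 * length * i / (n_seg - 1)
            cv = 0.12 * s * np.sin(2.2 * i)
            mask |= _ellipse(u, v, cu, cv, 1.15 * seg_r, seg_r)
    elif params.stage == StageTag.EGG:
        egg_r = 0.22 * s
        ring = 0.95 * s
        n_eggs = 5
        for i in range(n_eggs):
            theta = 2 * np.pi * i / n_eggs + 0.3
            cu = ring * np.cos(theta) + rng.uniform(-0.08, 0.08) * s
            cv = ring * np.sin(theta) + rng.uniform(-0.08, 0.08) * s
            mask |= _ellipse(u, v, cu, cv, egg_r, 0.8 * egg_r)
        axial = np.hypot(u, v)
    else:
        raise ValueError(f"cannot render stage {params.stage}")

    sat = 0.9 if params.stage != StageTag.EGG else 0.45
    val = 0.85
    r, g, b = colorsys.hsv_to_rgb(params.hue, sat, val)
    stripes = 0.78 + 0.22 * np.sin(2 * np.pi * params.pattern_freq * axial / (2 * s))
    shade = 1.0 - 0.25 * np.hypot(u, v) / s
    intensity = np.clip(stripes * shade, 0.0, 1.2)
    sprite = np.zeros((size, size, 4), dtype=np.float32)
    sprite[..., 0] = np.clip(r * intensity, 0, 1)
    sprite[..., 1] = np.clip(g * intensity, 0, 1)
    sprite[..., 2] = np.clip(b * intensity, 0, 1)
    sprite[..., 3] = mask.astype(np.float32)
    return sprite


def render_scene(sprite: np.ndarray, clutter_level: float, occlusion_prob: float,
                 rng: np.random.Generator, image_size: int = 64) -> np.ndarray:
    """Composite a sprite over a procedural background; uint8 RGB output.

    At ``clutter_level`` 0 the background is perfectly flat; higher levels
    add leaf-like sinusoidal gratings and blotches whose edge energy grows
    with the level.  With probability ``occlusion_prob`` a foreground band
    covers up to 40% of the sprite.
    """
    if not 0.0 <= clutter_level <= 1.0:
        raise ValueError("clutter_level must lie in [0, 1]")
    h = w = image_size
    base_hue = rng.uniform(0.22, 0.34)        # leaf-green band
    base_val = rng.uniform(0.35, 0.55)
    br, bg, bb = colorsys.hsv_to_rgb(base_hue, 0.35, base_val)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[..., 0], img[..., 1], img[..., 2] = br, bg, bb

    if clutter_level > 0:
        y, x = np.mgrid[0:h, 0:w] / image_size
        texture = np.zeros((h, w))
        for _ in range(4):
            fy, fx = rng.uniform(2, 9, size=2)
            phase = rng.uniform(0, 2 * np.pi)
            texture += rng.uniform(0.4, 1.0) * np.sin(
                2 * np.pi * (fy * y + fx * x) + phase)
        texture += 0.8 * rng.standard_normal((h, w))
        texture *= clutter_level * 0.18
        img += texture[..., None]

    # composite the sprite, scaled to fill ~50-72% of the frame
    target = int(image_size * rng.uniform(0.50, 0.72))
    sp = np.asarray(Image.fromarray(
        (np.clip(sprite, 0, 1) * 255).astype(np.uint8)).resize(
            (target, target), Image.BILINEAR), dtype=np.float64) / 255.0
    max_off = image_size - target
    oy = int(rng.integers(max_off // 4, max(max_off * 3 // 4, max_off // 4) + 1))
    ox = int(rng.integers(max_off // 4, max(max_off * 3 // 4, max_off // 4) + 1))
    alpha = sp[..., 3:4]
    region = img[oy:oy + target, ox:ox + target]
    region[...] = alpha * sp[..., :3] + (1 - alpha) * region

    if rng.uniform() < occlusion_prob:
        band = max(1, int(0.4 * target * rng.uniform(0.5, 1.0)))
        start = int(rng.integers(0, max(target - band, 1)))
        occ_color = np.array(colorsys.hsv_to_rgb(
            rng.uniform(0.05, 0.15), 0.5, 0.3))
        if rng.uniform() < 0.5:
            img[oy + start:oy + start + band, ox:ox + target] = occ_color
        else:
            img[oy:oy + target, ox + start:ox + start + band] = occ_color

    img *= rng.uniform(0.8, 1.25)             # illumination jitter
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def _species_counts(spec: DatasetSpec) -> list[int]:
    counts = []
    for s in range(spec.n_species):
        c = spec.base_count * (s + 1.0) ** (-spec.imbalance_exponent)
        counts.append(max(1, int(round(c))))
    return counts


def _stage_plan(spec: DatasetSpec, rng: np.random.Generator
                ) -> list[tuple[int, StageTag]]:
    """Expand the spec into a flat, deterministic (species, stage) list."""
    plan: list[tuple[int, StageTag]] = []
    if spec.stages_per_species is not None:
        for species in sorted(spec.stages_per_species):
            if not 0 <= species < spec.n_species:
                raise ValueError(f"species {species} out of range")
            for stage in list(StageTag):
                n = spec.stages_per_species[species].get(stage, 0)
                plan.extend([(species, stage)] * n)
        return plan
    for species, total in enumerate(_species_counts(spec)):
        n_unspec = int(round(total * spec.unspecified_frac))
        weights = rng.dirichlet(np.ones(4) * 2.0)
        staged = total - n_unspec
        alloc = np.floor(weights * staged).astype(int)
        for i in np.argsort(-(weights * staged - alloc))[:staged - alloc.sum()]:
            alloc[i] += 1
        for stage, n in zip(_STAGES, alloc):
            plan.extend([(species, stage)] * int(n))
        plan.extend([(species, StageTag.UNSPECIFIED)] * n_unspec)
    return plan


def generate_dataset(spec: DatasetSpec, out_dir: str | Path) -> DatasetPaths:
    """Write PNG scenes, a CSV manifest, split manifests and the hierarchy.

    The manifest has columns ``image_path,species_id,species_name,stage``
    plus ``clutter`` (per-image clutter level) and ``split``; the
    train/val/test split is 60/10/30, stratified by species.  The
    ground-truth hierarchy is built from the training rows with the spec's
    ``min_count`` threshold.
    """
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    try:
        images_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}") from exc

    master = np.random.default_rng(spec.seed)
    plan = _stage_plan(spec, master)
    rows = []
    for idx, (species, stage) in enumerate(plan):
        rng = np.random.default_rng([spec.seed, idx])
        hue, aspect, freq = species_archetype(species, spec.n_species)
        clutter = 0.0 if spec.clutter_level == 0 else float(
            np.clip(spec.clutter_level * rng.uniform(0.6, 1.4), 0.0, 1.0))
        render_stage = stage if stage != StageTag.UNSPECIFIED else \
            _STAGES[int(rng.integers(0, 4))]
        params = SpecimenParams(
            hue=hue, aspect=aspect, pattern_freq=freq, stage=render_stage,
            angle=float(rng.uniform(-0.35, 0.35)),
            scale=float(rng.uniform(0.85, 1.15)),
        )
        sprite = render_specimen(params, rng)
        scene = render_scene(sprite, clutter, spec.occlusion_prob, rng,
                             image_size=spec.image_size)
        name = f"img_{idx:05d}.png"
        Image.fromarray(scene).save(images_dir / name)
        rows.append({
            "image_path": f"images/{name}",
            "species_id": species,
            "species_name": f"species_{species:03d}",
            "stage": "" if stage == StageTag.UNSPECIFIED else stage.value,
            "clutter": round(clutter, 4),
        })

    df = pd.DataFrame(rows)
    # stratified 60/10/30 split, deterministic given the spec seed
    split_rng = np.random.default_rng([spec.seed, 999_983])
    df["split"] = "train"
    for species in range(spec.n_species):
        idxs = df.index[df["species_id"] == species].to_numpy()
        perm = split_rng.permutation(idxs)
        n = len(perm)
        n_train = int(round(n * 0.6))
        n_val = int(round(n * 0.1))
        df.loc[perm[n_train:n_train + n_val], "split"] = "val"
        df.loc[perm[n_train + n_val:], "split"] = "test"

    manifest = out_dir / "manifest.csv"
    df.to_csv(manifest, index=False)
    split_paths = {}
    for split in ("train", "val", "test"):
        p = out_dir / f"{split}.csv"
        df[df["split"] == split].drop(columns="split").to_csv(p, index=False)
        split_paths[split] = p

    train_df = df[df["split"] == "train"]
    train_samples = [
        AnnotatedSample(image_id=str(r.image_path), species=int(r.species_id),
                        stage=StageTag.parse(r.stage))
        for r in train_df.itertuples(index=False)
    ]
    space = build_refined_label_space(
        train_samples, min_count=spec.min_count, n_species=spec.n_species,
        names=[f"species_{s:03d}" for s in range(spec.n_species)])
    hierarchy = out_dir / "hierarchy.json"
    write_hierarchy(space, hierarchy)
    return DatasetPaths(root=out_dir, images_dir=images_dir, manifest=manifest,
                        train=split_paths["train"], val=split_paths["val"],
                        test=split_paths["test"], hierarchy=hierarchy,
                        space=space)


def complex_background_subset(manifest: "str | Path | pd.DataFrame",
                              k_per_class: int) -> pd.DataFrame:
    """The k highest-clutter rows per species (ties broken by image path)."""
    df = manifest if isinstance(manifest, pd.DataFrame) else pd.read_csv(manifest)
    if "clutter" not in df.columns:
        raise ValueError("manifest lacks per-image clutter metadata")
    if k_per_class < 0:
        raise ValueError("k_per_class must be >= 0")
    parts = []
    for species, group in df.groupby("species_id", sort=True):
        if len(group) < k_per_class:
            raise ValueError(
                f"species {species} has only {len(group)} samples, "
                f"need {k_per_class}")
        ordered = group.sort_values(
            ["clutter", "image_path"], ascending=[False, True])
        parts.append(ordered.head(k_per_class))
    if not parts or k_per_class == 0:
        return df.iloc[0:0].copy()
    return pd.concat(parts, ignore_index=True)
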