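"""Growth-stage refined label spaces.

A species class is split into stage-specific training classes (Adult, Larva,
Pupa, Egg) whenever a (species, stage) subgroup holds strictly more than
``min_count`` samples.  All remaining samples of the species — unannotated
ones and under-threshold stages — share a single residual class, created
only when it would be non-empty.  Predictions over the refined classes are
collapsed back to species level for evaluation.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StageTag", "AnnotatedSample", "RefinedLabelSpace",
    "build_refined_label_space", "refine_labels", "collapse_predictions",
    "write_hierarchy", "read_hierarchy", "read_manifest",
]

#: deterministic ordering used for refined-index assignment
STAGE_ORDER = ("Adult", "Larva", "Pupa", "Egg")


class StageTag(str, Enum):
    ADULT = "Adult"
    LARVA = "Larva"
    PUPA = "Pupa"
    EGG = "Egg"
    UNSPECIFIED = "Unspecified"

    @classmethod
    def parse(cls, value) -> "StageTag":
        if isinstance(value, StageTag):
            return value
        if value is None or (not isinstance(value, str) and pd.isna(value)):
            return cls.UNSPECIFIED
        text = str(value).strip()
        if not text or text.lower() == "nan":
            return cls.UNSPECIFIED
        try:
            return cls(text.capitalize())
        except ValueError as exc:
            raise ValueError(f"unknown growth stage tag: {value!r}") from exc


@dataclass(frozen=True)
class AnnotatedSample:
    image_id: str
    species: int
    stage: StageTag = StageTag.UNSPECIFIED


@dataclass
class RefinedLabelSpace:
    n_species: int
    n_refined: int
    min_count: int
    parent_of: list[int]
    #: stage tag of each refined class; residual classes are Unspecified
    stage_of: list[StageTag]
    names: list[str] | None = None
    children_of: dict[int, list[int]] = field(init=False)

    def __post_init__(self):
        if len(self.parent_of) != self.n_refined:
            raise ValueError("parent_of length must equal n_refined")
        if len(self.stage_of) != self.n_refined:
            raise ValueError("stage_of length must equal n_refined")
        children: dict[int, list[int]] = {s: [] for s in range(self.n_species)}
        for refined, species in enumerate(self.parent_of):
            if not 0 <= species < self.n_species:
                raise ValueError(f"parent_of[{refined}]={species} out of range")
            children[species].append(refined)
        for species, kids in children.items():
            if not kids:
                raise ValueError(f"species {species} has no refined child")
        self.children_of = children

    def map_to_parent(self, refined: int) -> int:
        return self.parent_of[refined]

    def refined_index(self, species: int, stage: StageTag) -> int:
        """Training class for a (species, stage) pair; falls back to residual."""
        if not 0 <= species < self.n_species:
            raise ValueError(f"species index {species} out of range "
                             f"[0, {self.n_species})")
        for refined in self.children_of[species]:
            if self.stage_of[refined] == stage:
                return refined
        for refined in self.children_of[species]:
            if self.stage_of[refined] == StageTag.UNSPECIFIED:
                return refined
        # no residual class exists (every sample of this species was staged
        # and split at build time); deterministic fallback to the first child
        return self.children_of[species][0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, RefinedLabelSpace):
            return NotImplemented
        return (self.n_species == other.n_species
                and self.n_refined == other.n_refined
                and self.min_count == other.min_count
                and self.parent_of == other.parent_of
                and self.stage_of == other.stage_of)


def build_refined_label_space(samples: Sequence[AnnotatedSample],
                              min_count: int,
                              n_species: int | None = None,
                              names: Sequence[str] | None = None,
                              ) -> RefinedLabelSpace:
    """Create a refined label space from stage-annotated samples.

    A (species, stage) subgroup becomes its own refined class iff it has
    strictly more than ``min_count`` samples.  Refined indices are assigned
    by ascending species, stages in Adult < Larva < Pupa < Egg order, with
    the residual class (if any) last.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("sample list is empty")
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if n_species is None:
        n_species = max(s.species for s in samples) + 1
    counts: Counter[tuple[int, StageTag]] = Counter()
    species_totals: Counter[int] = Counter()
    for s in samples:
        if not 0 <= s.species < n_species:
            raise ValueError(f"species index {s.species} out of range "
                             f"[0, {n_species}) for sample {s.image_id!r}")
        species_totals[s.species] += 1
        counts[(s.species, StageTag.parse(s.stage))] += 1

    parent_of: list[int] = []
    stage_of: list[StageTag] = []
    for species in range(n_species):
        split_total = 0
        for stage_name in STAGE_ORDER:
            stage = StageTag(stage_name)
            if counts.get((species, stage), 0) > min_count:
                parent_of.append(species)
                stage_of.append(stage)
                split_total += counts[(species, stage)]
        residual = species_totals.get(species, 0) - split_total
        if residual > 0 or split_total == 0:
            parent_of.append(species)
            stage_of.append(StageTag.UNSPECIFIED)
    return RefinedLabelSpace(
        n_species=n_species,
        n_refined=len(parent_of),
        min_count=min_count,
        parent_of=parent_of,
        stage_of=stage_of,
        names=list(names) if names is not None else None,
    )


def refine_labels(samples: Iterable[AnnotatedSample],
                  space: RefinedLabelSpace) -> list[int]:
    """Map each sample to its refined training class."""
    return [space.refined_index(s.species, StageTag.parse(s.stage))
            for s in samples]


def collapse_predictions(scores: np.ndarray, space: RefinedLabelSpace,
                         mode: str = "argmax_then_map"):
    """Collapse refined-class scores to a species prediction.

    ``scores`` may be a single vector of length ``n_refined`` or a batch
    (n, n_refined); ties break toward the lowest class index (argmax
    semantics of numpy).
    """
    scores = np.asarray(scores, dtype=np.float64)
    single = scores.ndim == 1
    if single:
        scores = scores[None, :]
    if scores.shape[1] != space.n_refined:
        raise ValueError(f"score length {scores.shape[1]} != n_refined "
                         f"{space.n_refined}")
    if np.any(scores < 0):
        raise ValueError("scores must be non-negative")
    parent = np.asarray(space.parent_of)
    if mode == "argmax_then_map":
        out = parent[scores.argmax(axis=1)]
    elif mode == "sum_probs":
        sums = np.zeros((scores.shape[0], space.n_species))
        np.add.at(sums.T, parent, scores.T)
        out = sums.argmax(axis=1)
    else:
        raise ValueError(f"unknown collapse mode: {mode!r}")
    return int(out[0]) if single else out


def write_hierarchy(space: RefinedLabelSpace, path: str | Path) -> None:
    payload = {
        "n_species": space.n_species,
        "n_refined": space.n_refined,
        "min_count": space.min_count,
        "parent_of": list(space.parent_of),
        "stages": [st.value for st in space.stage_of],
    }
    if space.names is not None:
        payload["names"] = list(space.names)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_hierarchy(path: str | Path) -> RefinedLabelSpace:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed hierarchy JSON in {path}: {exc}") from exc
    for key in ("n_species", "n_refined", "min_count", "parent_of"):
        if key not in payload:
            raise ValueError(f"hierarchy file {path} is missing key '{key}'")
    parent_of = [int(x) for x in payload["parent_of"]]
    stages = payload.get("stages")
    if stages is None:
        stages = [StageTag.UNSPECIFIED.value] * len(parent_of)
    return RefinedLabelSpace(
        n_species=int(payload["n_species"]),
        n_refined=int(payload["n_refined"]),
        min_count=int(payload["min_count"]),
        parent_of=parent_of,
        stage_of=[StageTag.parse(s) for s in stages],
        names=payload.get("names"),
    )


def read_manifest(path: str | Path) -> tuple[list[AnnotatedSample], pd.DataFrame]:
    """Read a dataset manifest CSV (`image_path,species_id,species_name,stage`).

    Extra columns (e.g. clutter, split) are preserved in the returned frame.
    """
    df = pd.read_csv(path, dtype={"stage": "string"})
    required = {"image_path", "species_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns {sorted(missing)}")
    stage_col = df["stage"] if "stage" in df.columns else [""] * len(df)
    samples = [
        AnnotatedSample(image_id=str(row.image_path),
                        species=int(row.species_id),
                        stage=StageTag.parse(stage))
        for row, stage in zip(df.itertuples(index=False), stage_col)
    ]
    return samples, df
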