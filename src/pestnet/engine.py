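"""Training and evaluation orchestration.

Wires the refined label space, backbone+attention+pooling model, scheduled
mixed loss, AdamW with linear warm-up, early stopping on validation
species-level accuracy, and species-level reporting of all metrics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .labels import (
    RefinedLabelSpace, collapse_predictions, read_hierarchy, read_manifest,
    refine_labels,
)
from .losses import MixedLoss, lambda_at, softmax
from .metrics import MetricsReport, confusion, metrics_report
from .model import PestNet, build_model
from .nn import AdamW, Tensor, warmup_lr

__all__ = [
    "TrainConfig", "EpochLog", "preprocess_train", "preprocess_eval",
    "load_dataset", "train", "evaluate", "save_checkpoint", "load_checkpoint",
    "IMAGENET_MEAN", "IMAGENET_STD",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class TrainConfig:
    input_size: int = 224
    batch_size: int = 32
    max_epochs: int = 500
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    weight_decay: float = 5e-4
    label_smoothing: float = 0.1
    early_stop_patience: int = 30
    warmup_epochs: int = 5
    lambda_max: float = 1.0
    gamma: float = 2.0
    alpha: float = 1.0
    beta: float = 1.0
    seed: int = 0
    collapse_mode: str = "argmax_then_map"
    arch: str = "vovnet57"
    use_bcsa: bool = True

    def __post_init__(self):
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        for name in ("input_size", "batch_size", "max_epochs", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class EpochLog:
    epoch: int
    lam: float
    train_loss: float
    val_species_accuracy: float
    val_macro_f1: float
    learning_rate: float

    def as_line(self) -> str:
        return (f"epoch={self.epoch} lambda={self.lam:.4f} "
                f"loss={self.train_loss:.4f} "
                f"val_acc={self.val_species_accuracy:.4f} "
                f"val_macro_f1={self.val_macro_f1:.4f} lr={self.learning_rate:.6f}")


# -- preprocessing -----------------------------------------------------------


def _load_rgb(path: str | Path) -> Image.Image:
    try:
        return Image.open(path).convert("RGB")
    except Exception as exc:
        raise OSError(f"cannot decode image file {path}: {exc}") from exc


def _resize_shorter(img: Image.Image, target: int) -> Image.Image:
    w, h = img.size
    if w <= h:
        nw, nh = target, max(target, int(round(h * target / w)))
    else:
        nw, nh = max(target, int(round(w * target / h))), target
    return img.resize((nw, nh), Image.BILINEAR)


def _normalize(arr: np.ndarray) -> np.ndarray:
    arr = arr.astype(np.float32) / 255.0
    arr = (arr - IMAGENET_MEAN) / IMAGENET_STD
    return arr.transpose(2, 0, 1)


def preprocess_train(image: "str | Path | Image.Image", input_size: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Resize shorter side to round(1.1 * input_size), random-crop, normalize."""
    img = image if isinstance(image, Image.Image) else _load_rgb(image)
    img = _resize_shorter(img, int(round(1.1 * input_size)))
    arr = np.asarray(img)
    h, w = arr.shape[:2]
    oy = int(rng.integers(0, h - input_size + 1))
    ox = int(rng.integers(0, w - input_size + 1))
    return _normalize(arr[oy:oy + input_size, ox:ox + input_size])


def preprocess_eval(image: "str | Path | Image.Image", input_size: int) -> np.ndarray:
    """Deterministic resize + center crop + normalize."""
    img = image if isinstance(image, Image.Image) else _load_rgb(image)
    img = _resize_shorter(img, int(round(1.1 * input_size)))
    arr = np.asarray(img)
    h, w = arr.shape[:2]
    oy = (h - input_size) // 2
    ox = (w - input_size) // 2
    return _normalize(arr[oy:oy + input_size, ox:ox + input_size])


# -- data --------------------------------------------------------------------


@dataclass
class LoadedSplit:
    images: list[Image.Image]
    species: np.ndarray
    refined: np.ndarray
    paths: list[str]


def load_dataset(manifest_path: str | Path, space: RefinedLabelSpace,
                 root: str | Path | None = None) -> LoadedSplit:
    samples, df = read_manifest(manifest_path)
    root = Path(root) if root is not None else Path(manifest_path).parent
    for s in samples:
        if not 0 <= s.species < space.n_species:
            raise ValueError(
                f"manifest species {s.species} inconsistent with hierarchy "
                f"(n_species={space.n_species})")
    images = [_load_rgb(root / s.image_id) for s in samples]
    species = np.array([s.species for s in samples], dtype=np.int64)
    refined = np.array(refine_labels(samples, space), dtype=np.int64)
    return LoadedSplit(images=images, species=species, refined=refined,
                       paths=[s.image_id for s in samples])


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(model: PestNet, config: TrainConfig, path: str | Path) -> None:
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"config": asdict(config), "n_classes": model.n_classes}, indent=1))


def load_checkpoint(path: str | Path) -> tuple[PestNet, TrainConfig]:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    config = TrainConfig(**meta["config"])
    model = build_model(meta["n_classes"], arch=config.arch,
                        alpha=config.alpha, beta=config.beta,
                        seed=config.seed, use_bcsa=config.use_bcsa)
    with np.load(path if path.suffix == ".npz" else str(path)) as archive:
        state = {k: archive[k] for k in archive.files}
    model.load_state_dict(state, strict=True)
    return model, config


# -- training ----------------------------------------------------------------


def _forward_logits(model: PestNet, batch: np.ndarray) -> Tensor:
    return model(Tensor(batch))


def _predict_species(model: PestNet, split: LoadedSplit, config: TrainConfig,
                     space: RefinedLabelSpace) -> tuple[np.ndarray, np.ndarray]:
    """Refined argmax predictions and collapsed species predictions."""
    model.eval()
    refined_preds, species_preds = [], []
    arrays = [preprocess_eval(img, config.input_size) for img in split.images]
    for start in range(0, len(arrays), config.batch_size):
        batch = np.stack(arrays[start:start + config.batch_size])
        logits = _forward_logits(model, batch).numpy()
        probs = softmax(logits, axis=1)
        refined_preds.append(probs.argmax(axis=1))
        species_preds.append(np.asarray(
            collapse_predictions(probs, space, mode=config.collapse_mode)))
    return np.concatenate(refined_preds), np.concatenate(species_preds)


@dataclass
class TrainResult:
    model: PestNet
    logs: list[EpochLog]
    best_val_accuracy: float
    best_epoch: int
    best_state: dict = field(repr=False, default_factory=dict)


def train(config: TrainConfig, train_manifest: str | Path,
          val_manifest: str | Path, hierarchy: "str | Path | RefinedLabelSpace",
          data_root: str | Path | None = None,
          out_dir: str | Path | None = None) -> TrainResult:
    """Optimize the refined-class objective with the scheduled mixed loss.

    Early stopping monitors validation species-level accuracy; the best
    checkpoint (by that metric) is retained and restored into the returned
    model.  Fully deterministic given the config seed.
    """
    space = hierarchy if isinstance(hierarchy, RefinedLabelSpace) \
        else read_hierarchy(hierarchy)
    train_split = load_dataset(train_manifest, space, root=data_root)
    val_split = load_dataset(val_manifest, space, root=data_root)

    rng = np.random.default_rng(config.seed)
    model = build_model(space.n_refined, arch=config.arch, alpha=config.alpha,
                        beta=config.beta, seed=config.seed,
                        use_bcsa=config.use_bcsa)
    optimizer = AdamW(model.parameters(), lr=config.learning_rate,
                      betas=(config.adam_beta1, config.adam_beta2),
                      weight_decay=config.weight_decay)
    criterion = MixedLoss(lambda_max=config.lambda_max, gamma=config.gamma,
                          epsilon=config.label_smoothing)

    n = len(train_split.images)
    logs: list[EpochLog] = []
    best_acc, best_epoch, best_state = -1.0, -1, model.state_dict()
    epochs_since_best = 0
    for epoch in range(config.max_epochs):
        lam = lambda_at(epoch, config.max_epochs, config.lambda_max)
        lr = warmup_lr(epoch, config.learning_rate, config.warmup_epochs)
        optimizer.lr = lr
        model.train()
        order = rng.permutation(n)
        total_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = np.stack([
                preprocess_train(train_split.images[i], config.input_size, rng)
                for i in idx])
            targets = train_split.refined[idx]
            logits = _forward_logits(model, batch)
            loss = criterion(logits, targets, epoch, config.max_epochs)
            model.zero_grad()
            loss.backward()
            optimizer.step()
            total_loss += loss.item()
            n_batches += 1

        _, species_pred = _predict_species(model, val_split, config, space)
        report = metrics_report(val_split.species, species_pred, space.n_species)
        logs.append(EpochLog(
            epoch=epoch, lam=lam, train_loss=total_loss / max(n_batches, 1),
            val_species_accuracy=report.accuracy, val_macro_f1=report.macro_f1,
            learning_rate=lr))
        if report.accuracy > best_acc:
            best_acc, best_epoch = report.accuracy, epoch
            best_state = model.state_dict()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.early_stop_patience:
                break

    model.load_state_dict(best_state, strict=True)
    result = TrainResult(model=model, logs=logs, best_val_accuracy=best_acc,
                         best_epoch=best_epoch, best_state=best_state)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, config, out_dir / "best.ckpt.npz")
        (out_dir / "epochs.log").write_text(
            "\n".join(log.as_line() for log in logs) + "\n")
    return result


def evaluate(model: PestNet, config: TrainConfig, manifest: str | Path,
             hierarchy: "str | Path | RefinedLabelSpace",
             data_root: str | Path | None = None,
             out_dir: str | Path | None = None
             ) -> tuple[MetricsReport, MetricsReport]:
    """Species-level and refined-level reports for a manifest.

    Optionally writes the species-level confusion matrix CSV and a JSON
    report under ``out_dir``.
    """
    space = hierarchy if isinstance(hierarchy, RefinedLabelSpace) \
        else read_hierarchy(hierarchy)
    if model.n_classes != space.n_refined:
        raise ValueError(
            f"checkpoint has {model.n_classes} classes but hierarchy defines "
            f"{space.n_refined} refined classes")
    split = load_dataset(manifest, space, root=data_root)
    refined_pred, species_pred = _predict_species(model, split, config, space)
    species_rep = metrics_report(split.species, species_pred, space.n_species)
    refined_rep = metrics_report(split.refined, refined_pred, space.n_refined)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cm = confusion(split.species, species_pred, space.n_species)
        header = [str(i) for i in range(space.n_species)]
        pd.DataFrame(cm.counts, index=header, columns=header).to_csv(
            out_dir / "confusion.csv")
        (out_dir / "report.json").write_text(json.dumps({
            "species": species_rep.to_dict(),
            "refined": refined_rep.to_dict(),
        }, indent=1))
    return species_rep, refined_rep
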