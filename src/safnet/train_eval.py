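"""Cross-validation harness: fold splitting, augmentation, training loop,
evaluation and checkpointing.

The training recipe follows the reference protocol for this task: Adam
(initial learning rate 1e-3, weight decay 1e-4), batch size 8, 50 epochs,
a reduce-on-plateau scheduler (mode max on the validation metric, factor
0.5, patience 10) and best-validation checkpointing. "Validation accuracy"
is defined as the mean foreground Dice on the validation split. Fold
splitting is Monte-Carlo style: each fold reshuffles all identifiers
independently and takes the configured train/val/test sizes (138/4/30 for
the nominal 172-sample dataset) — with those sizes a classic disjoint
five-fold partition is impossible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_preprocess import LabelMap, SpineSample, Volume
from .loss_metrics import ScoreTable, aggregate, dsc, msd, one_hot, \
    pixelwise_ce_tensor
from .model import SAFNet, SAFNetConfig
from .nn import Adam, ReduceLROnPlateau

__all__ = [
    "FoldSplit", "AugmentParams", "TrainConfig", "TrainHistory",
    "make_folds", "augment", "train", "evaluate", "cross_validate",
    "mean_foreground_dsc", "save_checkpoint", "load_checkpoint",
    "model_from_checkpoint",
]

logger = logging.getLogger("safnet")


@dataclass
class FoldSplit:
    fold_index: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("fold partitions must be pairwise disjoint")


@dataclass
class AugmentParams:
    """Ranges of the three augmentations; zero magnitudes give the exact
    identity transform."""

    rotation_deg: float = 10.0        # in-sagittal-plane rotation, U(-r, r)
    contrast_jitter: float = 0.2      # intensity scale exp(U(-j, j))
    elastic_alpha: float = 2.0        # displacement amplitude, voxels
    elastic_sigma: float = 4.0        # Gaussian smoothing of the field


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 8
    epochs: int = 50
    scheduler_factor: float = 0.5
    scheduler_patience: int = 10
    augment: AugmentParams = field(default_factory=AugmentParams)
    seed: int = 0
    max_iters: int | None = None   # optional hard cap on update steps

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0.0 < self.scheduler_factor < 1.0):
            raise ValueError("scheduler factor must be in (0, 1)")
        if self.scheduler_patience < 1:
            raise ValueError("scheduler patience must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val: float = -np.inf
    checkpoint_path: str | None = None


# -- folds --------------------------------------------------------------------

def make_folds(ids: list[str], k: int = 5,
               sizes: tuple[int, int, int] = (138, 4, 30),
               seed: int = 0) -> list[FoldSplit]:
    """Monte-Carlo cross-validation folds: an independent shuffle per fold,
    partitioned into the configured train/val/test sizes."""
    n_train, n_val, n_test = sizes
    if len(ids) < n_train + n_val + n_test:
        raise ValueError(
            f"need at least {n_train + n_val + n_test} ids, got {len(ids)}")
    folds = []
    for i in range(k):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        perm = [ids[j] for j in rng.permutation(len(ids))]
        folds.append(FoldSplit(
            fold_index=i,
            train_ids=perm[:n_train],
            val_ids=perm[n_train:n_train + n_val],
            test_ids=perm[n_train + n_val:n_train + n_val + n_test],
        ))
    return folds


# -- augmentation -------------------------------------------------------------

def augment(sample: SpineSample, rng: np.random.Generator,
            params: AugmentParams | None = None) -> SpineSample:
    """Random rotation + contrast + elastic deformation, volume and labels
    transformed with identical geometry (labels nearest-neighbor only)."""
    params = params or AugmentParams()
    vol = np.asarray(sample.volume.data, dtype=np.float32)
    lab = sample.labels.data if sample.labels is not None else None

    if params.rotation_deg > 0:
        angle = float(rng.uniform(-params.rotation_deg, params.rotation_deg))
        vol = ndimage.rotate(vol, angle, axes=(1, 2), reshape=False,
                             order=1, mode="nearest")
        if lab is not None:
            lab = ndimage.rotate(lab, angle, axes=(1, 2), reshape=False,
                                 order=0, mode="nearest")

    if params.contrast_jitter > 0:
        vol = vol * float(np.exp(rng.uniform(-params.contrast_jitter,
                                             params.contrast_jitter)))

    if params.elastic_alpha > 0:
        shape = vol.shape
        # smooth in-plane displacement field shared by volume and labels
        disp_h = ndimage.gaussian_filter(
            rng.uniform(-1, 1, shape), params.elastic_sigma) * params.elastic_alpha
        disp_w = ndimage.gaussian_filter(
            rng.uniform(-1, 1, shape), params.elastic_sigma) * params.elastic_alpha
        dd, hh, ww = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        coords = [dd, hh + disp_h, ww + disp_w]
        vol = ndimage.map_coordinates(vol, coords, order=1, mode="nearest")
        if lab is not None:
            lab = ndimage.map_coordinates(lab, coords, order=0, mode="nearest")

    labels = None
    if lab is not None:
        labels = LabelMap(lab.astype(np.int32),
                          num_classes=sample.labels.num_classes)
    return SpineSample(
        volume=Volume(vol, spacing=sample.volume.spacing, id=sample.volume.id),
        labels=labels, sample_id=sample.sample_id,
        provenance=sample.provenance)


# -- metrics over samples -----------------------------------------------------

def mean_foreground_dsc(model: SAFNet, ids: list[str],
                        data: dict[str, SpineSample]) -> float:
    """Mean DSC over all foreground classes and samples (eval mode)."""
    num_classes = model.cfg.num_classes
    vals = []
    for sid in ids:
        sample = data[sid]
        pred = model.predict_labels(
            sample.volume.data[None, None].astype(np.float32))[0]
        truth = sample.labels.data
        vals.extend(dsc(pred, truth, c) for c in range(1, num_classes))
    return float(np.mean(vals))


# -- training -----------------------------------------------------------------

def _batch_arrays(samples: list[SpineSample], num_classes: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([np.asarray(s.volume.data, dtype=np.float32)
                  for s in samples])[:, None]
    y = np.stack([one_hot(s.labels.data, num_classes) for s in samples])
    return x, y


def train(model: SAFNet, fold: FoldSplit, cfg: TrainConfig,
          data: dict[str, SpineSample],
          checkpoint_path: str | Path | None = None) -> TrainHistory:
    """Train on the fold's train split, checkpointing on the best validation
    mean foreground DSC; returns the full per-epoch history."""
    if not fold.train_ids or not fold.val_ids:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, mode="max", factor=cfg.scheduler_factor,
                              patience=cfg.scheduler_patience)
    history = TrainHistory()
    num_classes = model.cfg.num_classes
    iters = 0
    for epoch in range(cfg.epochs):
        model.train()
        order = [fold.train_ids[j]
                 for j in rng.permutation(len(fold.train_ids))]
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch_ids = order[start:start + cfg.batch_size]
            samples = [augment(data[sid], rng, cfg.augment)
                       for sid in batch_ids]
            x, y = _batch_arrays(samples, num_classes)
            probs = model(x).softmax(axis=1)
            loss = pixelwise_ce_tensor(probs, y)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, iter {iters}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            iters += 1
            if cfg.max_iters is not None and iters >= cfg.max_iters:
                break

        val = mean_foreground_dsc(model, fold.val_ids, data)
        sched.step(val)
        history.train_loss.append(float(np.mean(losses)))
        history.val_dsc.append(val)
        history.lr.append(opt.lr)
        logger.info("epoch=%d loss=%.4f val_dsc=%.4f lr=%.2e",
                    epoch, history.train_loss[-1], val, opt.lr)
        if val > history.best_val:
            history.best_val = val
            history.best_epoch = epoch
            if checkpoint_path is not None:
                save_checkpoint(checkpoint_path, model,
                                {"val_dsc": val, "epoch": epoch,
                                 "train_config": asdict(cfg)})
                history.checkpoint_path = str(checkpoint_path)
        if cfg.max_iters is not None and iters >= cfg.max_iters:
            break
    return history


def evaluate(model: SAFNet, ids: list[str], data: dict[str, SpineSample],
             include_msd: bool = False) -> ScoreTable:
    """Eval-mode per-(sample, foreground class) DSC rows, aggregated."""
    if not ids:
        raise ValueError("no ids to evaluate")
    rows = []
    for sid in ids:
        sample = data[sid]
        pred = model.predict_labels(
            sample.volume.data[None, None].astype(np.float32))[0]
        truth = sample.labels.data
        for c in range(1, model.cfg.num_classes):
            row = {"sample_id": sid, "class_id": c,
                   "class_name": f"class_{c}", "dsc": dsc(pred, truth, c)}
            if include_msd:
                row["msd"] = msd(pred, truth, c)
            rows.append(row)
    return aggregate(rows)


def cross_validate(model_cfg: SAFNetConfig, train_cfg: TrainConfig,
                   data: dict[str, SpineSample], k: int = 5,
                   sizes: tuple[int, int, int] = (138, 4, 30),
                   seed: int = 0, outdir: str | Path | None = None
                   ) -> tuple[list[ScoreTable], dict]:
    """Train and evaluate each fold with a fresh model; returns per-fold
    score tables plus a summary with the across-fold mean of fold means."""
    folds = make_folds(sorted(data.keys()), k=k, sizes=sizes, seed=seed)
    tables = []
    fold_means = []
    for fold in folds:
        model = SAFNet(model_cfg, seed=seed + fold.fold_index)
        ckpt = None
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            ckpt = outdir / f"fold{fold.fold_index}.npz"
        train(model, fold, train_cfg, data, checkpoint_path=ckpt)
        if ckpt is not None and ckpt.exists():
            state, _ = load_checkpoint(ckpt)
            model.load_state_dict(state)
        table = evaluate(model, fold.test_ids, data)
        tables.append(table)
        fold_means.append(table.overall()[0])
    summary = {
        "fold_mean_dsc": fold_means,
        "mean_of_fold_means": float(np.mean(fold_means)),
    }
    if outdir is not None:
        for i, t in enumerate(tables):
            t.to_csv(Path(outdir) / f"fold{i}_scores.csv")
        (Path(outdir) / "summary.json").write_text(
            json.dumps(summary, indent=2))
    return tables, summary


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(path: str | Path, model: SAFNet,
                    extra: dict | None = None) -> None:
    """Write weights + running stats + a JSON echo of the model config."""
    meta = {"model_config": asdict(model.cfg)}
    if extra:
        meta.update(extra)
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8),
        **{f"state::{k}": v for k, v in state.items()})


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Return (state_dict, metadata) from a checkpoint file."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[len("state::"):]: z[k] for k in z.files
                 if k.startswith("state::")}
    return state, meta


def model_from_checkpoint(path: str | Path, seed: int = 0) -> SAFNet:
    """Rebuild a SAFNet from a checkpoint's config echo and load weights."""
    state, meta = load_checkpoint(path)
    cfg_d = dict(meta["model_config"])
    for key in ("aspp_dilations", "fusion_dilations", "input_shape"):
        cfg_d[key] = tuple(cfg_d[key])
    model = SAFNet(SAFNetConfig(**cfg_d), seed=seed)
    model.load_state_dict(state)
    model.eval()
    return model
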