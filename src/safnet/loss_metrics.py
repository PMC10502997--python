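"""Training loss and evaluation metrics.

The loss is the per-voxel-per-class *binary* cross-entropy mean

    L = -sum_{i,j,k,c} [ Y log P + (1 - Y) log(1 - P) ] / (H W D C)

evaluated on softmax class probabilities P against one-hot labels Y, with P
clipped to [eps, 1 - eps]. A categorical cross-entropy variant is also
provided. Segmentation quality is scored with the Dice similarity
coefficient (DSC) and the mean surface distance (MSD), aggregated per class
and overall as mean +/- sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import Tensor

__all__ = [
    "LossValue", "ScoreTable", "one_hot",
    "pixelwise_ce", "pixelwise_ce_tensor", "categorical_ce_tensor",
    "dsc", "msd", "aggregate",
]

EPS = 1e-7


@dataclass
class LossValue:
    value: float
    voxel_count: int

    def __post_init__(self):
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"loss must be finite and >= 0, got {self.value}")


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """(..., ) integer labels -> (C, ...) one-hot float array."""
    labels = np.asarray(labels)
    out = np.zeros((num_classes,) + labels.shape, dtype=np.float32)
    for c in range(num_classes):
        out[c] = labels == c
    return out


def _check_probs_labels(p: np.ndarray, y: np.ndarray) -> None:
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: P {p.shape} vs Y {y.shape}")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("Y must be binary one-hot indicators")


def pixelwise_ce_tensor(probs: Tensor, onehot: np.ndarray,
                        eps: float = EPS) -> Tensor:
    """Differentiable binary-CE-per-class mean on an autograd tensor."""
    _check_probs_labels(probs.data, np.asarray(onehot))
    y = np.asarray(onehot, dtype=probs.dtype)
    p = probs.clip(eps, 1.0 - eps)
    terms = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -terms.mean()


def pixelwise_ce(P: np.ndarray | Tensor, Y: np.ndarray,
                 eps: float = EPS) -> LossValue:
    """Binary cross-entropy mean over every voxel and class.

    ``P`` holds class probabilities and ``Y`` the matching one-hot labels,
    shaped (C, D, H, W) or (B, C, D, H, W).
    """
    p = P.data if isinstance(P, Tensor) else np.asarray(P)
    loss = pixelwise_ce_tensor(Tensor(np.asarray(p, dtype=np.float64)),
                               np.asarray(Y))
    return LossValue(value=loss.item(), voxel_count=int(np.asarray(p).size))


def categorical_ce_tensor(probs: Tensor, onehot: np.ndarray,
                          eps: float = EPS) -> Tensor:
    """Categorical cross-entropy (mean over voxels of -log P_true)."""
    _check_probs_labels(probs.data, np.asarray(onehot))
    y = np.asarray(onehot, dtype=probs.dtype)
    p = probs.clip(eps, 1.0 - eps)
    axis = 0 if probs.ndim == 4 else 1
    return -(Tensor(y) * p.log()).sum(axis=axis).mean()


# -- metrics ------------------------------------------------------------------

def dsc(pred: np.ndarray, truth: np.ndarray, cls: int) -> float:
    """Dice similarity coefficient for one class: 2|A&B| / (|A| + |B|).

    Both masks empty -> 1.0 (the structure is correctly absent); exactly one
    empty -> 0.0.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    a = pred == cls
    b = truth == cls
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def _surface(mask: np.ndarray) -> np.ndarray:
    """Surface voxels: class voxels with a six-connected non-class neighbor
    (voxels at the array border count as surface)."""
    eroded = ndimage.binary_erosion(mask, structure=_SIX_CONN, border_value=0)
    return mask & ~eroded


def msd(pred: np.ndarray, truth: np.ndarray, cls: int,
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float | None:
    """Symmetric mean surface distance for one class.

    Pools the nearest-opposite-surface distance of every surface voxel of
    both masks and averages. Returns None (missing, not 0) when the class is
    absent from either map.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    a = pred == cls
    b = truth == cls
    if not a.any() or not b.any():
        return None
    sa = _surface(a)
    sb = _surface(b)
    # EDT of the complement gives, at every voxel, the distance to the
    # nearest surface voxel of the other mask.
    dt_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    d_ab = dt_b[sa]
    d_ba = dt_a[sb]
    return float((d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size))


# -- aggregation --------------------------------------------------------------

_COLUMNS = ["sample_id", "class_id", "class_name", "dsc", "msd"]


@dataclass
class ScoreTable:
    """Per-(sample, class) DSC/MSD rows plus mean +/- sd aggregates."""

    rows: pd.DataFrame

    def __post_init__(self):
        self.rows = pd.DataFrame(self.rows)
        for col in _COLUMNS:
            if col not in self.rows.columns:
                self.rows[col] = np.nan if col == "msd" else ""
        self.rows = self.rows[_COLUMNS].reset_index(drop=True)
        d = self.rows["dsc"].to_numpy(dtype=float)
        if len(d) == 0:
            raise ValueError("score table needs at least one row")
        if np.any((d < 0) | (d > 1)):
            raise ValueError("DSC entries must lie in [0, 1]")
        m = self.rows["msd"].to_numpy(dtype=float)
        if np.any(m[~np.isnan(m)] < 0):
            raise ValueError("MSD entries must be >= 0")

    @staticmethod
    def _mean_sd(values: np.ndarray) -> tuple[float, float]:
        values = np.asarray(values, dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        return mean, sd

    def overall(self) -> tuple[float, float]:
        """(mean, sample sd) of all DSC rows, as fractions."""
        return self._mean_sd(self.rows["dsc"].to_numpy())

    def per_class(self) -> pd.DataFrame:
        recs = []
        for cls, grp in self.rows.groupby("class_id"):
            mean, sd = self._mean_sd(grp["dsc"].to_numpy())
            recs.append({"class_id": cls,
                         "class_name": grp["class_name"].iloc[0],
                         "n": len(grp), "dsc_mean": mean, "dsc_sd": sd})
        return pd.DataFrame(recs)

    def format_percent(self) -> str:
        """'80.32 +/- 5.00 %' style summary of the overall DSC."""
        mean, sd = self.overall()
        return f"{100 * mean:.2f} ± {100 * sd:.2f} %"

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False, columns=_COLUMNS)

    def to_json(self, path: str | Path) -> None:
        self.rows.to_json(path, orient="records", indent=2)


def aggregate(rows) -> ScoreTable:
    """Build a ScoreTable from an iterable of row dicts or a DataFrame."""
    df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ValueError("no rows to aggregate")
    return ScoreTable(rows=df)
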