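"""Volume / label-map containers, NIfTI I/O and the preprocessing chain.

The preprocessing pipeline mirrors the standard recipe for sagittal spine
MRI: (1) crop a centered bounding box spanning the full depth and height but
only the central fraction of the width (the spine sits mid-image
antero-posteriorly), (2) rescale isotropically and zero-pad symmetrically to
a fixed grid of 18 x 256 x 128 voxels, (3) z-score the intensities per
volume. Axis convention throughout: (depth, height, width) = (sagittal slice
index, cranio-caudal, antero-posterior), 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume", "LabelMap", "SpineSample", "PreprocessSpec",
    "load_sample", "save_sample", "crop_center_width", "resample_pad",
    "normalize_zscore", "preprocess",
]


@dataclass
class Volume:
    """A 3D scalar intensity grid with optional voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] | None = None
    id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with positive dims, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)
            if any(s <= 0 for s in self.spacing):
                raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMap:
    """A 3D integer grid; 0 = background, 1..num_classes-1 = structures."""

    data: np.ndarray
    num_classes: int

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label map must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded, atol=1e-6):
                raise ValueError("label map contains non-integer values")
            self.data = rounded.astype(np.int32)
        if self.data.min() < 0 or self.data.max() >= self.num_classes:
            raise ValueError(
                f"label values must lie in [0, {self.num_classes}), found "
                f"range [{self.data.min()}, {self.data.max()}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SpineSample:
    """A paired volume + optional label map with provenance."""

    volume: Volume
    labels: LabelMap | None = None
    sample_id: str = ""
    provenance: str = "real"  # "real" | "phantom"

    def __post_init__(self):
        if self.labels is not None and self.labels.shape != self.volume.shape:
            raise ValueError(
                f"label shape {self.labels.shape} != volume shape "
                f"{self.volume.shape}")


@dataclass
class PreprocessSpec:
    """Target grid and crop fraction of the preprocessing chain."""

    target_shape: tuple[int, int, int] = (18, 256, 128)
    crop_width_fraction: float = 0.5

    def __post_init__(self):
        if any(t < 1 for t in self.target_shape):
            raise ValueError("target dims must be >= 1")
        if not (0.0 < self.crop_width_fraction <= 1.0):
            raise ValueError("crop_width_fraction must be in (0, 1]")


# -- I/O ----------------------------------------------------------------------

def load_sample(volume_path: str | Path, label_path: str | Path | None = None,
                num_classes: int | None = None) -> SpineSample:
    """Load a NIfTI volume (and optionally its label map) into a SpineSample.

    Labels are cast to integers without changing values; non-integral label
    voxels raise. ``num_classes`` defaults to ``labels.max() + 1``.
    """
    volume_path = Path(volume_path)
    if not volume_path.exists():
        raise FileNotFoundError(volume_path)
    img = nib.load(str(volume_path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    vol = Volume(data=data, spacing=spacing, id=volume_path.stem)

    labels = None
    if label_path is not None:
        label_path = Path(label_path)
        if not label_path.exists():
            raise FileNotFoundError(label_path)
        lab_img = nib.load(str(label_path))
        lab = np.asanyarray(lab_img.dataobj)
        if lab.shape != data.shape:
            raise ValueError(
                f"volume {data.shape} and labels {lab.shape} differ in shape")
        nc = num_classes if num_classes is not None else int(np.rint(lab.max())) + 1
        labels = LabelMap(data=lab, num_classes=nc)
    return SpineSample(volume=vol, labels=labels, sample_id=vol.id)


def save_sample(sample: SpineSample, volume_path: str | Path,
                label_path: str | Path | None = None) -> None:
    """Write a sample as NIfTI; labels are stored integer-typed."""
    spacing = sample.volume.spacing or (1.0, 1.0, 1.0)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(sample.volume.data, dtype=np.float32),
                             affine), str(volume_path))
    if label_path is not None:
        if sample.labels is None:
            raise ValueError("sample has no labels to save")
        nib.save(nib.Nifti1Image(
            np.asarray(sample.labels.data, dtype=np.int16), affine),
            str(label_path))


# -- preprocessing steps ------------------------------------------------------

def crop_center_width(v: Volume, labels: LabelMap | None = None,
                      fraction: float = 0.5) -> tuple[Volume, LabelMap | None]:
    """Crop the central width fraction (full depth and height retained).

    The crop window is centered; when the discarded width is odd, the extra
    voxel is dropped from the high-index side. Width rounds half-to-even.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    w0 = v.shape[2]
    crop_w = int(np.rint(w0 * fraction))
    if crop_w < 1:
        raise ValueError(f"crop width degenerates to {crop_w} voxels")
    start = (w0 - crop_w) // 2
    sl = slice(start, start + crop_w)
    out_v = Volume(v.data[:, :, sl], spacing=v.spacing, id=v.id)
    out_l = None
    if labels is not None:
        out_l = LabelMap(labels.data[:, :, sl], num_classes=labels.num_classes)
    return out_v, out_l


def resample_pad(v: Volume, labels: LabelMap | None = None,
                 spec: PreprocessSpec | None = None
                 ) -> tuple[Volume, LabelMap | None]:
    """Isotropically rescale to fit the target grid, then zero-pad.

    One shared scale factor ``f = min_i(target_i / size_i)`` is applied to
    all three axes (aspect ratio preserved), intensities with trilinear and
    labels with nearest-neighbor interpolation, followed by symmetric
    padding (background label 0 for label maps). An input already at the
    target shape passes through voxel-identically.
    """
    spec = spec or PreprocessSpec()
    target = spec.target_shape
    shape = v.shape
    f = min(t / s for t, s in zip(target, shape))
    new_shape = tuple(
        int(min(t, max(1, np.rint(s * f)))) for t, s in zip(target, shape))

    if new_shape == shape:
        vol_data = v.data.copy()
        lab_data = labels.data.copy() if labels is not None else None
    else:
        zoom = [n / s for n, s in zip(new_shape, shape)]
        vol_data = ndimage.zoom(np.asarray(v.data, dtype=np.float32), zoom,
                                order=1, mode="nearest")
        assert vol_data.shape == new_shape
        lab_data = None
        if labels is not None:
            lab_data = ndimage.zoom(labels.data, zoom, order=0, mode="nearest")
            assert lab_data.shape == new_shape

    pads = []
    for t, n in zip(target, new_shape):
        before = (t - n) // 2
        pads.append((before, t - n - before))
    vol_data = np.pad(vol_data, pads)
    out_v = Volume(vol_data, spacing=None, id=v.id)
    out_l = None
    if labels is not None:
        lab_data = np.pad(lab_data, pads)
        out_l = LabelMap(lab_data, num_classes=labels.num_classes)
    return out_v, out_l


def normalize_zscore(v: Volume) -> Volume:
    """Per-volume z-score over all voxels; a constant volume maps to zeros."""
    if v.data.size < 2:
        raise ValueError("z-score needs at least 2 voxels")
    x = np.asarray(v.data, dtype=np.float32)
    sd = float(x.std())
    if sd < 1e-12:
        warnings.warn(f"volume {v.id!r} is constant; z-score output is all "
                      "zeros", stacklevel=2)
        return Volume(np.zeros_like(x), spacing=v.spacing, id=v.id)
    return Volume((x - float(x.mean())) / sd, spacing=v.spacing, id=v.id)


def preprocess(sample: SpineSample,
               spec: PreprocessSpec | None = None) -> SpineSample:
    """Full chain: crop -> resample/pad -> z-score, labels transformed in
    lockstep with the identical geometry."""
    spec = spec or PreprocessSpec()
    v, lab = crop_center_width(sample.volume, sample.labels,
                               spec.crop_width_fraction)
    v, lab = resample_pad(v, lab, spec)
    v = normalize_zscore(v)
    return SpineSample(volume=v, labels=lab, sample_id=sample.sample_id,
                       provenance=sample.provenance)
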