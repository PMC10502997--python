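"""Synthetic sagittal spine phantoms.

A phantom emulates the statistical structure of multi-class spine MRI
without any anatomy: a cranio-caudal stack of bright, boxy "vertebral
bodies" alternating with thin, dimmer "intervertebral discs", each carrying
its own integer label in top-to-bottom order (matching how spine-parsing
datasets label T/L/S structures). Two properties of the real task are
reproduced deliberately:

* **inter-class similarity** — within a sample, every vertebra shares one
  intensity and every disc another, so adjacent distinct structures are
  distinguishable only by position;
* **intra-class variation** — a per-sample multiplicative contrast factor
  and a per-sample curvature of the stack make the same class look
  different across samples.

Generation is fully deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .io_preprocess import LabelMap, SpineSample, Volume, save_sample

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset",
           "write_dataset"]


@dataclass
class PhantomConfig:
    """Geometry, intensity and noise settings of the phantom generator.

    Heights are fractions of the volume height; the structures are laid out
    with equal gaps inside a 6% top/bottom margin and must fit, otherwise
    generation raises. Intensity means are (background, vertebra, disc) in
    arbitrary MR-like units.
    """

    shape: tuple[int, int, int] = (18, 256, 128)
    n_vertebrae: int = 9
    n_discs: int = 8
    vertebra_height_frac: float = 0.06
    disc_height_frac: float = 0.02
    intensity_means: tuple[float, float, float] = (0.0, 0.8, 0.5)
    noise_sd: float = 0.05
    contrast_jitter: float = 0.2
    curvature_amp: float = 0.05
    margin_frac: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if self.n_vertebrae < 1 or self.n_discs < 0:
            raise ValueError("need at least one vertebra")
        if self.n_discs not in (self.n_vertebrae - 1, self.n_vertebrae):
            # interleaved stack: V D V D ... V (or ending in a disc)
            if self.n_discs > self.n_vertebrae:
                raise ValueError("discs cannot outnumber vertebrae in an "
                                 "interleaved stack")

    @property
    def num_classes(self) -> int:
        return self.n_vertebrae + self.n_discs + 1

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "PhantomConfig":
        """Small profile (12x64x32, 3 vertebrae + 2 discs = 5 foreground)."""
        return cls(shape=(12, 64, 32), n_vertebrae=3, n_discs=2,
                   vertebra_height_frac=0.14, disc_height_frac=0.05,
                   seed=seed)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


def _layout(cfg: PhantomConfig) -> list[tuple[int, str, float, float]]:
    """Return (label, kind, center_h, half_height) for each structure,
    cranio-caudal, alternating vertebra/disc."""
    d_, h, w_ = cfg.shape
    usable = h * (1.0 - 2.0 * cfg.margin_frac)
    n = cfg.n_vertebrae + cfg.n_discs
    vh = cfg.vertebra_height_frac * h
    dh = cfg.disc_height_frac * h
    occupied = cfg.n_vertebrae * vh + cfg.n_discs * dh
    gap = (usable - occupied) / max(n - 1, 1)
    if gap < 0:
        raise ValueError(
            f"structures do not fit: need {occupied:.1f} voxels of height, "
            f"have {usable:.1f}")
    out = []
    pos = h * cfg.margin_frac
    for i in range(n):
        kind = "vertebra" if i % 2 == 0 else "disc"
        extent = vh if kind == "vertebra" else dh
        out.append((i + 1, kind, pos + extent / 2.0, extent / 2.0))
        pos += extent + gap
    return out


def generate_phantom(cfg: PhantomConfig | None = None) -> SpineSample:
    """Render one phantom sample (volume + label map), seeded by the config."""
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    d, h, w = cfg.shape
    labels = np.zeros(cfg.shape, dtype=np.int32)
    dd, hh, ww = np.ogrid[0:d, 0:h, 0:w]

    contrast = float(np.exp(rng.uniform(-cfg.contrast_jitter,
                                        cfg.contrast_jitter)))
    curve_phase = float(rng.uniform(0.0, np.pi))

    for label, kind, ch, rh in _layout(cfg):
        t = ch / h
        cw = w * (0.5 + cfg.curvature_amp * np.sin(np.pi * t + curve_phase))
        cd = d / 2.0
        if kind == "vertebra":
            rd, rw = 0.30 * d, 0.18 * w
        else:
            rd, rw = 0.32 * d, 0.22 * w
        rh_eff = max(rh, 0.6)
        # superellipsoid (exponent 4 in-plane keeps vertebrae boxy)
        dist = ((np.abs(dd - cd) / rd) ** 4
                + (np.abs(hh - ch) / rh_eff) ** 2
                + (np.abs(ww - cw) / rw) ** 4)
        labels[dist <= 1.0] = label
        # construction guarantee: every class occupies at least one voxel
        labels[int(round(cd)) % d, int(round(ch)) % h, int(round(cw)) % w] = label

    means = np.zeros(cfg.num_classes, dtype=np.float32)
    for label, kind, _, _ in _layout(cfg):
        means[label] = cfg.intensity_means[1 if kind == "vertebra" else 2]
    means[0] = cfg.intensity_means[0]

    vol = means[labels] * contrast
    if cfg.noise_sd > 0:
        vol = vol + rng.normal(0.0, cfg.noise_sd, cfg.shape)
    vol = vol.astype(np.float32)

    sample_id = f"phantom_seed{cfg.seed}"
    return SpineSample(
        volume=Volume(vol, spacing=(4.4, 0.5, 0.5), id=sample_id),
        labels=LabelMap(labels, num_classes=cfg.num_classes),
        sample_id=sample_id,
        provenance="phantom",
    )


def generate_dataset(n: int, cfg: PhantomConfig | None = None,
                     master_seed: int = 0) -> list[SpineSample]:
    """Generate ``n`` phantoms with per-sample seeds derived from
    ``master_seed``; identical label topology, varying contrast/curvature."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or PhantomConfig()
    seeds = np.random.SeedSequence(master_seed).generate_state(n) % (2 ** 31)
    samples = []
    for i, s in enumerate(seeds):
        sample = generate_phantom(replace(cfg, seed=int(s)))
        sample.sample_id = f"phantom_{i:03d}"
        sample.volume.id = sample.sample_id
        samples.append(sample)
    return samples


def write_dataset(samples: list[SpineSample], outdir: str | Path,
                  cfg: PhantomConfig | None = None) -> Path:
    """Write NIfTI pairs plus a JSON manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sample in samples:
        vpath = outdir / f"{sample.sample_id}_volume.nii.gz"
        lpath = outdir / f"{sample.sample_id}_labels.nii.gz"
        save_sample(sample, vpath, lpath)
        entries.append({"id": sample.sample_id,
                        "volume": vpath.name, "labels": lpath.name})
    manifest = {
        "samples": entries,
        "config_digest": (cfg or PhantomConfig()).digest(),
        "config": asdict(cfg or PhantomConfig()),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    return mpath
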