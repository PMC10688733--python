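"""Seeded generator of synthetic OCT-B-scan-like images.

Real retinal OCT B-scans show a bright, gently curved band of retinal layers
over a dark vitreous/choroid background, corrupted by multiplicative speckle.
The four classes carry distinct lesion morphology:

* NORMAL — the unmodified band.
* CNV    — one wide dome elevation of the band with a bright sub-band mass
           (neovascular membrane lifting the retina).
* DME    — dark elliptical cysts inside the band (intraretinal fluid).
* DRUSEN — several small bumps on the band's lower boundary (sub-RPE
           deposits).

The generator emulates the ``<split>/<class>/<image>.png`` folder layout of
the public retinal-OCT datasets so every pipeline stage can be exercised
without any download.  It emulates geometry and speckle only — not the
intensity statistics, device artefacts, or anatomical variability of real
scans.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from PIL import Image

CLASSES = ("CNV", "DME", "DRUSEN", "NORMAL")

__all__ = ["CLASSES", "SceneParams", "DatasetManifest", "render_scan", "generate_dataset"]


@dataclass(frozen=True)
class SceneParams:
    """Geometry, intensity and noise parameters of a synthetic B-scan.

    Fractions are relative to image height/width; intensities in [0, 1].
    """

    image_size: tuple[int, int] = (48, 48)
    band_center_frac: float = 0.55
    band_thickness_frac: float = 0.28
    band_intensity: float = 0.75
    background_intensity: float = 0.12
    curvature_amp_frac: float = 0.04
    edge_softness_px: float = 1.0
    speckle_sigma: float = 0.15
    # CNV: one wide dome elevation with a bright sub-band mass
    dome_height_frac: float = 0.18
    dome_width_frac: float = 0.45
    mass_intensity: float = 0.20
    # DME: dark elliptical cysts inside the band
    cyst_count: tuple[int, int] = (1, 3)
    cyst_radius_frac: float = 0.09
    cyst_darkness: float = 0.55
    # DRUSEN: small bumps on the band's lower boundary
    bump_count: tuple[int, int] = (2, 5)
    bump_height_frac: float = 0.10
    bump_width_frac: float = 0.06

    def __post_init__(self):
        for name in ("band_center_frac", "band_thickness_frac"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if not self.background_intensity < self.band_intensity:
            raise ValueError("require background_intensity < band_intensity")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be >= 0")


@dataclass
class DatasetManifest:
    """What `generate_dataset` wrote: per-split/class counts and file paths."""

    root: str
    seed: int
    counts: dict = field(default_factory=dict)  # split -> class -> n
    frame: pd.DataFrame | None = None

    @property
    def total(self):
        return sum(n for split in self.counts.values() for n in split.values())


def _band_boundaries(params: SceneParams, rng):
    """Smoothly curved top/bottom boundary row (in pixels) per column."""
    H, W = params.image_size
    x = np.arange(W) / max(W - 1, 1)
    amp = params.curvature_amp_frac * H
    freq = rng.uniform(0.6, 1.6)
    phase = rng.uniform(0, 2 * np.pi)
    curve = amp * np.sin(2 * np.pi * freq * x + phase)
    center = params.band_center_frac * H + curve
    half = 0.5 * params.band_thickness_frac * H
    return center - half, center + half


def _soft_band(top, bottom, H, softness):
    """Band mask per column via sigmoids of signed row distance."""
    y = np.arange(H)[:, None]
    s = max(softness, 1e-6)
    return 1.0 / (1.0 + np.exp(-(y - top[None, :]) / s)) * (
        1.0 / (1.0 + np.exp((y - bottom[None, :]) / s))
    )


def render_scan(class_label, params: SceneParams = SceneParams(), rng=None):
    """Render one synthetic B-scan as an (H, W, 3) float array in [0, 1].

    The grayscale scene is built from the class geometry, multiplicative
    log-normal speckle is applied last, and the result is replicated to
    three channels.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {CLASSES}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    H, W = params.image_size
    top, bottom = _band_boundaries(params, rng)
    extra = np.zeros((H, W))
    shade = np.ones((H, W))

    if class_label == "CNV":
        x0 = rng.uniform(0.35, 0.65) * W
        width = params.dome_width_frac * W
        dome = params.dome_height_frac * H * np.exp(
            -(((np.arange(W) - x0) / (0.5 * width)) ** 2)
        )
        top = top - dome  # elevation: the band's top edge moves up
        # bright neovascular mass tucked under the elevated band
        yy = np.arange(H)[:, None]
        mass_c = top + 0.35 * (bottom - top)
        extra += params.mass_intensity * np.exp(
            -(((np.arange(W) - x0) / (0.35 * width)) ** 2)
            - ((yy - mass_c[None, :]) / (0.18 * (bottom - top)[None, :])) ** 2
        )
    elif class_label == "DME":
        n_cysts = rng.integers(params.cyst_count[0], params.cyst_count[1] + 1)
        yy = np.arange(H)[:, None]
        xx = np.arange(W)[None, :]
        for _ in range(n_cysts):
            cx = rng.uniform(0.15, 0.85) * W
            frac = rng.uniform(0.3, 0.7)
            cy = top + frac * (bottom - top)  # per-column center row
            rx = params.cyst_radius_frac * W * rng.uniform(0.8, 1.4)
            ry = params.cyst_radius_frac * H * rng.uniform(0.6, 1.0)
            d2 = ((xx - cx) / rx) ** 2 + ((yy - cy[None, :]) / ry) ** 2
            shade *= 1.0 - params.cyst_darkness * np.exp(-(d2**1.5))
    elif class_label == "DRUSEN":
        n_bumps = rng.integers(params.bump_count[0], params.bump_count[1] + 1)
        centers = rng.uniform(0.1, 0.9, size=n_bumps) * W
        for cx in centers:
            h = params.bump_height_frac * H * rng.uniform(0.7, 1.3)
            w = params.bump_width_frac * W * rng.uniform(0.8, 1.5)
            bottom = bottom + h * np.exp(-(((np.arange(W) - cx) / w) ** 2))

    band = _soft_band(top, bottom, H, params.edge_softness_px)
    img = params.background_intensity + (
        params.band_intensity - params.background_intensity
    ) * band
    img = img * shade + extra
    if params.speckle_sigma > 0:
        img = img * np.exp(rng.normal(0.0, params.speckle_sigma, size=img.shape))
    img = np.clip(img, 0.0, 1.0)
    return np.repeat(img[:, :, None], 3, axis=2)


def _image_rng(seed, split_i, class_i, index):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(split_i, class_i, index))
    )


def generate_dataset(
    out_dir,
    n_train=100,
    n_test=25,
    n_val=25,
    params: SceneParams = SceneParams(),
    seed=0,
    force=False,
):
    """Write a balanced PNG dataset under ``out_dir/<split>/<CLASS>/``.

    Splits are ``train``, ``test``, ``val`` with the requested images per
    class; a CSV manifest (``manifest.csv``) records every file.  The output
    is fully determined by ``seed`` (each image gets its own child RNG, so
    counts can change without reshuffling existing images).

    Raises if ``out_dir`` exists non-empty unless ``force`` is set.
    """
    out_dir = str(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force=True)")
    os.makedirs(out_dir, exist_ok=True)

    splits = (("train", n_train), ("test", n_test), ("val", n_val))
    rows = []
    counts = {}
    for split_i, (split, n) in enumerate(splits):
        counts[split] = {}
        for class_i, cls in enumerate(CLASSES):
            d = os.path.join(out_dir, split, cls)
            os.makedirs(d, exist_ok=True)
            for i in range(int(n)):
                rng = _image_rng(seed, split_i, class_i, i)
                img = render_scan(cls, params, rng)
                u8 = np.round(img * 255.0).astype(np.uint8)
                rel = os.path.join(split, cls, f"{cls}-{seed}-{i:05d}.png")
                Image.fromarray(u8).save(os.path.join(out_dir, rel))
                rows.append({"split": split, "class": cls, "path": rel, "index": i})
            counts[split][cls] = int(n)

    frame = pd.DataFrame(rows, columns=["split", "class", "path", "index"])
    frame.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    with open(os.path.join(out_dir, "params.txt"), "w") as fh:
        fh.write(f"seed={seed}\n")
        for k, v in asdict(params).items():
            fh.write(f"{k}={v}\n")
    return DatasetManifest(root=out_dir, seed=int(seed), counts=counts, frame=frame)
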