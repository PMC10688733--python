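"""Contrast-limited adaptive histogram equalization (CLAHE).

The classic tile-based scheme: per-tile histograms, clip-and-redistribute to
cap noise amplification, CDF lookup tables, and 4-neighbour bilinear blending
between tile centers.  Implemented from scratch because the same operator
doubles as a non-trainable in-network enhancement layer applied to feature
maps, which needs exact mass-conservation semantics and a vectorised
batch/channel path (`clahe_batch`) that off-the-shelf single-image
implementations do not provide.

All single-image entry points take intensities in [0, 1]; `clahe_layer`
handles arbitrary-range feature maps by per-channel min-max normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClaheParams",
    "tile_histograms",
    "clip_redistribute",
    "tile_mappings",
    "clahe2d",
    "clahe_batch",
    "clahe_layer",
]


@dataclass(frozen=True)
class ClaheParams:
    """Parameters of the CLAHE operator.

    tile_grid : (rows, cols) of the tile partition.
    clip_limit : histogram clip threshold as a multiple of the uniform
        histogram height (tile_pixels / n_bins); ``np.inf`` disables clipping.
        Must be >= 1 (below 1 the clipped histogram could not hold the mass).
    n_bins : number of intensity bins (>= 2).
    pad_mode : how the image is padded so tiles partition it evenly.
    """

    tile_grid: tuple[int, int] = (8, 8)
    clip_limit: float = 2.0
    n_bins: int = 256
    pad_mode: str = "reflect"

    def __post_init__(self):
        r, c = self.tile_grid
        if r < 1 or c < 1:
            raise ValueError("tile_grid entries must be positive")
        if self.clip_limit < 1:
            raise ValueError("clip_limit must be >= 1 (inf disables clipping)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.pad_mode not in ("reflect", "edge"):
            raise ValueError("pad_mode must be 'reflect' or 'edge'")


def _check_image(img):
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D single-channel image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    return img


def _pad_to_grid(imgs, grid, mode):
    """Pad (N, H, W) on the bottom/right so the grid partitions evenly."""
    rows, cols = grid
    H, W = imgs.shape[1], imgs.shape[2]
    if rows > H or cols > W:
        raise ValueError("tile grid exceeds image size")
    ph = (-H) % rows
    pw = (-W) % cols
    if ph or pw:
        imgs = np.pad(imgs, ((0, 0), (0, ph), (0, pw)), mode=mode)
    return imgs


def _bin_indices(imgs, n_bins):
    # quantisation rule: nearest of n_bins levels spanning [0, 1]
    return np.floor(imgs * (n_bins - 1) + 0.5).astype(np.intp)


def _batch_histograms(imgs, params: ClaheParams):
    """Per-tile histograms for a padded batch (N, Hp, Wp) -> (N, R, C, n_bins)."""
    N, Hp, Wp = imgs.shape
    R, C = params.tile_grid
    th, tw = Hp // R, Wp // C
    nb = params.n_bins
    bins = _bin_indices(imgs, nb)
    tr = np.arange(Hp) // th
    tc = np.arange(Wp) // tw
    tile_of = tr[:, None] * C + tc[None, :]
    flat = (
        np.arange(N)[:, None, None] * (R * C * nb) + tile_of[None, :, :] * nb + bins
    )
    hist = np.bincount(flat.ravel(), minlength=N * R * C * nb)
    return hist.reshape(N, R, C, nb).astype(np.float64)


def tile_histograms(img, params: ClaheParams = ClaheParams()):
    """Histogram of each tile of a single-channel image in [0, 1].

    The image is padded (``params.pad_mode``) so the tile grid partitions it
    evenly; returns an array of shape (rows, cols, n_bins) whose tile sums
    each equal the tile pixel count.
    """
    img = _check_image(img)
    padded = _pad_to_grid(img[None], params.tile_grid, params.pad_mode)
    return _batch_histograms(padded, params)[0]


def clip_redistribute(hist, clip_limit):
    """Clip histogram bins at ``clip_limit`` times the uniform height and
    redistribute the excess, conserving total mass.

    The clip threshold is ``t = clip_limit * total / n_bins``.  Excess mass is
    shared uniformly among the bins still below ``t`` and the process is
    iterated until the excess is absorbed (if every bin reaches ``t`` — only
    possible at clip_limit == 1 — the remainder is spread uniformly).  Works on
    any (..., n_bins) stack of histograms at once.
    """
    if clip_limit < 1:
        raise ValueError("clip_limit must be >= 1")
    h = np.asarray(hist, dtype=np.float64).copy()
    if np.isinf(clip_limit):
        return h
    nb = h.shape[-1]
    total = h.sum(axis=-1, keepdims=True)
    t = clip_limit * total / nb
    excess = np.clip(h - t, 0.0, None).sum(axis=-1, keepdims=True)
    h = np.minimum(h, t)
    tol = 1e-12 * np.maximum(total, 1.0)
    for _ in range(64):
        if np.all(excess <= tol):
            break
        under = h < t
        nunder = under.sum(axis=-1, keepdims=True)
        share = excess / np.maximum(nunder, 1)
        give = np.minimum((t - h) * under, share * under)
        h += give
        excess = excess - give.sum(axis=-1, keepdims=True)
        saturated = (nunder == 0) & (excess > tol)
        if np.any(saturated):
            h += saturated * excess / nb
            excess = np.where(saturated, 0.0, excess)
    else:  # pragma: no cover - defensive: dump any numerical residue uniformly
        h += excess / nb
    return h


def tile_mappings(clipped_hists):
    """CDF-based monotone lookup tables rescaled to [0, 1].

    Accepts any (..., n_bins) stack.  An all-zero histogram maps to the
    identity ramp.
    """
    h = np.asarray(clipped_hists, dtype=np.float64)
    if np.any(h < 0):
        raise ValueError("histograms must be non-negative")
    nb = h.shape[-1]
    cdf = np.cumsum(h, axis=-1)
    total = cdf[..., -1:]
    identity = np.broadcast_to(np.arange(nb) / (nb - 1), h.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        lut = np.where(total > 0, cdf / np.where(total > 0, total, 1.0), identity)
    return lut


def clahe_batch(imgs, params: ClaheParams = ClaheParams()):
    """CLAHE on a batch of single-channel images (N, H, W) in [0, 1]."""
    imgs = np.asarray(imgs, dtype=np.float64)
    if imgs.ndim != 3 or imgs.size == 0:
        raise ValueError("expected a non-empty (N, H, W) batch")
    if not np.all(np.isfinite(imgs)):
        raise ValueError("batch contains non-finite pixels")
    N, H, W = imgs.shape
    R, C = params.tile_grid
    padded = _pad_to_grid(imgs, params.tile_grid, params.pad_mode)
    Hp, Wp = padded.shape[1], padded.shape[2]
    th, tw = Hp // R, Wp // C

    hists = _batch_histograms(padded, params)
    luts = tile_mappings(clip_redistribute(hists, params.clip_limit))

    bins = _bin_indices(padded, params.n_bins)
    # tile-center coordinates in tile units; edge pixels collapse to the
    # nearest center (reduced neighbour set)
    ty = (np.arange(Hp) + 0.5) / th - 0.5
    tx = (np.arange(Wp) + 0.5) / tw - 0.5
    r0 = np.floor(ty).astype(np.intp)
    c0 = np.floor(tx).astype(np.intp)
    fy = (ty - r0)[None, :, None]
    fx = (tx - c0)[None, None, :]
    r1 = np.clip(r0 + 1, 0, R - 1)
    c1 = np.clip(c0 + 1, 0, C - 1)
    r0 = np.clip(r0, 0, R - 1)
    c0 = np.clip(c0, 0, C - 1)

    n = np.arange(N)[:, None, None]
    r0 = r0[None, :, None]
    r1 = r1[None, :, None]
    c0 = c0[None, None, :]
    c1 = c1[None, None, :]
    v00 = luts[n, r0, c0, bins]
    v01 = luts[n, r0, c1, bins]
    v10 = luts[n, r1, c0, bins]
    v11 = luts[n, r1, c1, bins]
    out = (
        (1 - fy) * ((1 - fx) * v00 + fx * v01) + fy * ((1 - fx) * v10 + fx * v11)
    )
    return np.clip(out[:, :H, :W], 0.0, 1.0)


def clahe2d(img, params: ClaheParams = ClaheParams()):
    """CLAHE-enhance a single-channel image in [0, 1]; output in [0, 1]."""
    img = _check_image(img)
    lo, hi = float(img.min()), float(img.max())
    if lo < -1e-9 or hi > 1 + 1e-9:
        raise ValueError("clahe2d expects intensities in [0, 1]")
    return clahe_batch(img[None], params)[0]


def clahe_layer(features, params: ClaheParams = ClaheParams()):
    """Channel-wise CLAHE for arbitrary-range feature maps; shape-preserving.

    Accepts (H, W, C) or (B, H, W, C).  Each channel is min-max normalised to
    [0, 1], enhanced, and rescaled back to its original (min, max); constant
    channels pass through unchanged.  Adds no trainable parameters.
    """
    x = np.asarray(features, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if x.ndim != 4:
        raise ValueError("expected (H, W, C) or (B, H, W, C) features")
    B, H, W, C = x.shape
    flat = x.transpose(0, 3, 1, 2).reshape(B * C, H, W)
    lo = flat.min(axis=(1, 2), keepdims=True)
    hi = flat.max(axis=(1, 2), keepdims=True)
    span = hi - lo
    live = (span > 0).ravel()
    out = flat.copy()
    if np.any(live):
        norm = (flat[live] - lo[live]) / span[live]
        enhanced = clahe_batch(norm, params)
        out[live] = enhanced * span[live] + lo[live]
    out = out.reshape(B, C, H, W).transpose(0, 2, 3, 1)
    return out[0] if squeeze else out
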