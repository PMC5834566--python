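"""Synthetic histology slide renderer.

Produces RGB tumour-section images with stain-coloured structures on an
eosin-like counterstained tissue ellipse over a white background, plus the
exact ground-truth masks, so the stain-segmentation routine can be tested
against known truth.

Stain fractions are enforced by thresholding a smoothed random field at the
per-image quantile of the requested fraction, so the ground-truth mask
covers the requested share of tissue pixels to within one pixel while still
looking blobby.  Microvessels are small disjoint disks.  Colours are fixed
reference RGB values with per-pixel jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["STAIN_RGB", "Slide", "render_histology_slide"]

# reference stain colours (RGB, 0-255)
STAIN_RGB = {
    "tissue": (228, 178, 192),          # eosin-like counterstain
    "picrosirius_red": (178, 32, 48),   # collagen I/III
    "dab": (126, 84, 36),               # DAB (pimonidazole / CD31)
    "background": (252, 252, 252),
}


@dataclass
class Slide:
    image: np.ndarray                    # (H, W, 3) uint8
    tissue_mask: np.ndarray              # bool
    collagen_mask: np.ndarray            # bool, subset of tissue
    hypoxia_mask: np.ndarray             # bool, subset of tissue
    vessel_mask: np.ndarray              # bool, subset of tissue
    px_per_mm: float


def _blob_mask(tissue: np.ndarray, fraction: float, rng, smooth: float = 6.0,
               exclude: np.ndarray | None = None) -> np.ndarray:
    """Mask covering ``fraction`` of tissue pixels, chosen by quantile of a
    smoothed noise field (exact to 1 pixel)."""
    if fraction <= 0:
        return np.zeros_like(tissue)
    field = gaussian_filter(rng.standard_normal(tissue.shape), smooth)
    avail = tissue if exclude is None else (tissue & ~exclude)
    n_target = int(round(fraction * tissue.sum()))
    if n_target > avail.sum():
        raise ValueError("requested stain fraction exceeds available tissue")
    if n_target == 0:
        return np.zeros_like(tissue)
    vals = field[avail]
    thresh = np.partition(vals, -n_target)[-n_target]
    mask = avail & (field >= thresh)
    # resolve ties at the threshold so the count is exact
    extra = mask.sum() - n_target
    if extra > 0:
        ii = np.flatnonzero(mask.ravel() & (field.ravel() == thresh))[:extra]
        flat = mask.ravel()
        flat[ii] = False
        mask = flat.reshape(mask.shape)
    return mask


def render_histology_slide(collagen_fraction: float = 0.0,
                           hypoxia_fraction: float = 0.0,
                           n_vessels: int = 0,
                           size: tuple[int, int] = (384, 384),
                           seed: int = 0,
                           px_per_mm: float = 192.0,
                           colour_jitter: float = 5.0) -> Slide:
    """Render one synthetic slide; fractions are shares of tissue pixels."""
    for name, frac in (("collagen", collagen_fraction), ("hypoxia", hypoxia_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name}_fraction must be in [0, 1]")
    if collagen_fraction + hypoxia_fraction > 0.95:
        raise ValueError("combined stain fractions exceed canvas capacity")
    rng = np.random.default_rng(seed)
    h, w = size

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    tissue = (((yy - cy) / (0.45 * h)) ** 2 + ((xx - cx) / (0.45 * w)) ** 2) <= 1.0

    collagen = _blob_mask(tissue, collagen_fraction, rng, smooth=max(h, w) / 60)
    hypoxia = _blob_mask(tissue, hypoxia_fraction, rng, smooth=max(h, w) / 50,
                         exclude=collagen)

    # vessels: small disjoint disks inside tissue, clear of the slide border
    vessel = np.zeros_like(tissue)
    r_vessel = max(2, int(round(px_per_mm * 0.012)))
    placed = 0
    attempts = 0
    centres: list[tuple[int, int]] = []
    while placed < n_vessels and attempts < 20000:
        attempts += 1
        y = rng.integers(r_vessel + 1, h - r_vessel - 1)
        x = rng.integers(r_vessel + 1, w - r_vessel - 1)
        if not tissue[y, x]:
            continue
        if any((y - yc) ** 2 + (x - xc) ** 2 < (4 * r_vessel) ** 2
               for yc, xc in centres):
            continue
        disk = (yy - y) ** 2 + (xx - x) ** 2 <= r_vessel ** 2
        if not np.all(tissue[disk]):
            continue
        vessel |= disk
        centres.append((y, x))
        placed += 1
    if placed < n_vessels:
        raise ValueError(f"could only place {placed} of {n_vessels} vessels")

    img = np.empty((h, w, 3), dtype=float)
    img[:] = STAIN_RGB["background"]
    img[tissue] = STAIN_RGB["tissue"]
    img[collagen] = STAIN_RGB["picrosirius_red"]
    img[hypoxia] = STAIN_RGB["dab"]
    img[vessel] = STAIN_RGB["dab"]
    img += rng.normal(0.0, colour_jitter, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    return Slide(img, tissue, collagen, hypoxia, vessel, px_per_mm)
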