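"""Microwell grid identification in the transmitted-light channel.

The well lattice is known a priori from the chip layout, so detection is
template matching: a binary wall/floor template is correlated against the
transmitted channel (normalized cross-correlation) over a translation
search, with optional small-angle rotation sweep and subpixel refinement of
the correlation peak by quadratic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template
from skimage.transform import rotate as _rotate

from .layout import ChipLayout, WellROI, nominal_well_rois, tile_shape

__all__ = ["GridFit", "GridNotFoundError", "grid_template", "fit_grid", "extract_well_rois"]


class GridNotFoundError(RuntimeError):
    """Raised when no well grid can be located in a tile."""


@dataclass(frozen=True)
class GridFit:
    """Result of fitting the well lattice to one tile."""

    offset: tuple[float, float]  # (dy, dx) pixels relative to nominal
    rotation: float = 0.0  # radians
    pitch_px: float = 0.0
    score: float = 0.0  # normalized cross-correlation at the optimum

    def __post_init__(self) -> None:
        if not -1.0 <= self.score <= 1.0:
            raise ValueError("score must be in [-1, 1]")


def grid_template(layout: ChipLayout) -> np.ndarray:
    """Binary wall(1)/floor(0) template of the well lattice, margin excluded."""
    h, w = tile_shape(layout)
    m = layout.tile_margin_px
    tpl = np.ones((h - 2 * m, w - 2 * m), dtype=np.float64)
    for roi in nominal_well_rois(layout):
        r0, c0, r1, c1 = roi.bbox
        tpl[r0 - m : r1 - m, c0 - m : c1 - m] = 0.0
    return tpl


def _subpixel_peak(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Quadratic interpolation of a correlation peak, one axis at a time."""
    out = []
    for ax, p in enumerate(peak):
        if p == 0 or p == corr.shape[ax] - 1:
            out.append(float(p))
            continue
        sl = list(peak)
        sl[ax] = slice(p - 1, p + 2)
        y0, y1, y2 = corr[tuple(sl)]
        denom = y0 - 2 * y1 + y2
        out.append(float(p) if denom == 0 else float(p) + 0.5 * (y0 - y2) / denom)
    return out[0], out[1]


def fit_grid(
    trans_image: np.ndarray,
    layout: ChipLayout,
    min_score: float = 0.2,
    rotations_deg: tuple[float, ...] = (0.0,),
    max_rotation_deg: float = 2.0,
) -> GridFit:
    """Locate the well grid in a transmitted-light tile.

    Returns the translation (and the best angle from ``rotations_deg``)
    maximizing normalized cross-correlation with the layout template.  The
    template excludes the tile margin, so offsets up to ``tile_margin_px``
    in either direction are recoverable.
    """
    img = np.asarray(trans_image, dtype=np.float64)
    th, tw = tile_shape(layout)
    if img.shape[0] < th - 2 * layout.tile_margin_px or img.shape[1] < tw - 2 * layout.tile_margin_px:
        raise GridNotFoundError("image smaller than the nominal subunit extent")
    if np.ptp(img) == 0:
        raise GridNotFoundError("no grid found: featureless image")
    tpl = grid_template(layout)
    m = layout.tile_margin_px

    # Correlating the full template is wasteful: the offset cannot exceed the
    # tile margin, so a central sub-template matched over a small search
    # window sees every admissible shift at a fraction of the cost.
    sub = min(tpl.shape[0], tpl.shape[1], max(3 * layout.pitch_px, 64))
    a0 = (tpl.shape[0] - sub) // 2
    a1 = (tpl.shape[1] - sub) // 2
    subtpl = tpl[a0 : a0 + sub, a1 : a1 + sub]
    # nominal top-left of the sub-template inside the image
    ny, nx = m + a0, m + a1
    s = m  # admissible |offset|
    wy0, wx0 = max(0, ny - s), max(0, nx - s)
    wy1 = min(img.shape[0], ny + sub + s)
    wx1 = min(img.shape[1], nx + sub + s)

    best = None
    for ang in rotations_deg:
        if abs(ang) > max_rotation_deg:
            raise ValueError(f"rotation candidate {ang} exceeds max {max_rotation_deg} deg")
        probe = img if ang == 0.0 else _rotate(img, -ang, preserve_range=True, mode="edge")
        corr = match_template(probe[wy0:wy1, wx0:wx1], subtpl, pad_input=False)
        corr = np.nan_to_num(corr, nan=-1.0)
        peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
        score = float(corr[peak])
        if best is None or score > best[0]:
            py, px = _subpixel_peak(corr, (int(peak[0]), int(peak[1])))
            best = (score, ang, py + wy0 - ny, px + wx0 - nx)

    score, ang, dy, dx = best
    if score < min_score:
        raise GridNotFoundError(f"no grid found: best correlation {score:.3f} < {min_score}")
    return GridFit(
        offset=(dy, dx),
        rotation=float(np.deg2rad(ang)),
        pitch_px=float(layout.pitch_px),
        score=min(score, 1.0),
    )


def extract_well_rois(fit: GridFit, layout: ChipLayout, field: tuple[int, int] = (0, 0)) -> list[WellROI]:
    """Turn a grid fit into the numbered map of well ROIs for one field.

    Deterministic given the fit; the fitted offset is rounded to whole
    pixels for ROI cropping.
    """
    off = (int(round(fit.offset[0])), int(round(fit.offset[1])))
    return nominal_well_rois(layout, field=field, offset=off)
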