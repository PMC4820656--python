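"""Per-well cell detection and the figure of goodness.

Target cells are round, so they are found by a circular Hough transform on
the union evidence of the calcein-green and DDAO channels (dead targets
lose calcein but keep DDAO, so the union sees both classes).  NK cells are
irregular and are counted as connected components of the thresholded
calcein-orange channel.  Every well also receives a heuristic figure of
goodness in [0, 1] — the product of penalties for crowding, large merged
objects, bright unidentified signal and overlapping detections — and wells
scoring below 0.5 are flagged for manual review.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.transform import hough_circle

from .layout import WellIndex

__all__ = [
    "DetectionParams",
    "DetectedCell",
    "WellRecord",
    "preprocess_channel",
    "estimate_threshold",
    "detect_targets",
    "detect_nk",
    "goodness_score",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detection parameters (pixel units).

    Thresholds default to background mean + 4 SD, estimated per tile from
    well-floor pixels; the Gaussian scale defaults to about half the target
    radius so smoothing is of the order of the cell size.
    """

    radius_min_px: int = 4
    radius_max_px: int = 9
    sigma_px: float = 2.75
    min_separation_px: float = 6.0
    hough_threshold: float = 0.32
    evidence_level: float = 0.3
    max_cells_per_well: int = 16
    measure_radius_frac: float = 0.75
    min_cell_intensity: float = 12.0
    min_fill_fraction: float = 0.6
    nk_min_area_px: float = 20.0
    nk_typical_area_px: float = 75.0
    nk_max_area_px: float = 130.0
    # per-tile intensity calibration (filled by estimate_threshold)
    threshold_green: float = 40.0
    threshold_ddao: float = 40.0
    threshold_orange: float = 40.0
    background_green: float = 20.0
    background_ddao: float = 20.0
    background_orange: float = 20.0
    # goodness
    count_soft_cap: int = 10
    large_penalty: float = 0.7
    bright_area_tol: float = 0.02
    overlap_tol: float = 0.05


@dataclass(frozen=True)
class DetectedCell:
    """One segmented cell; coordinates are local to the well crop unless
    the caller rebases them to tile coordinates."""

    cell_class: str  # 'target' | 'nk'
    y: float
    x: float
    radius_px: float = 0.0
    area_px: float = 0.0
    mean_green: float = 0.0
    mean_ddao: float = 0.0
    mean_orange: float = 0.0
    multiplicity: int = 1  # >1 for a large merged NK component
    well: WellIndex | None = None


@dataclass
class WellRecord:
    """Per-well counts, quality score and QC flags."""

    well: WellIndex
    n_nk: int = 0
    n_target_live: int = 0
    n_target_dead: int = 0
    goodness: float = 1.0
    flags: set[str] = dc_field(default_factory=set)

    def __post_init__(self) -> None:
        if not 0.0 <= self.goodness <= 1.0:
            raise ValueError("goodness must be in [0, 1]")


def preprocess_channel(channel: np.ndarray, threshold: float, sigma_px: float) -> np.ndarray:
    """Zero sub-threshold pixels, then convolve with an isotropic Gaussian.

    The smoothing scale is chosen to be of roughly the cell size, which
    rounds objects and helps separate clustered cells.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be > 0")
    out = np.asarray(channel, dtype=np.float64).copy()
    out[out < threshold] = 0.0
    return ndimage.gaussian_filter(out, sigma_px)


def estimate_threshold(channel: np.ndarray, n_sd: float = 4.0) -> tuple[float, float]:
    """Robust (background, threshold) from a channel's floor-dominated pixels.

    Uses the median and MAD so cells (a minority of pixels) do not bias the
    estimate; returns ``(median, median + n_sd * sigma)``.
    """
    px = np.asarray(channel, dtype=np.float64).ravel()
    med = float(np.median(px))
    sigma = 1.4826 * float(np.median(np.abs(px - med)))
    return med, med + n_sd * max(sigma, 1e-6)


def _disk_mean(channel: np.ndarray, y: float, x: float, r: float, background: float) -> float:
    h, w = channel.shape
    yy, xx = np.ogrid[0:h, 0:w]
    mask = (yy - y) ** 2 + (xx - x) ** 2 <= r * r
    if not mask.any():
        return 0.0
    return max(0.0, float(channel[mask].mean()) - background)


def detect_targets(
    green: np.ndarray,
    ddao: np.ndarray,
    params: DetectionParams,
    well: WellIndex | None = None,
    pre_green: np.ndarray | None = None,
    pre_ddao: np.ndarray | None = None,
) -> list[DetectedCell]:
    """Circular-Hough detection of target cells in one well crop.

    Both channels are thresholded, smoothed and max-normalized; the Hough
    accumulator runs on the boundary of their union mask so detection is
    invariant to global intensity scaling above threshold.  Mean cell
    intensities are then measured on the *original* background-subtracted
    channels inside a concentric disk of ``measure_radius_frac * r``;
    candidate circles whose measured intensity stays below
    ``min_cell_intensity`` in both channels (accumulator artefacts in the
    gaps between cells) are discarded.

    ``pre_green``/``pre_ddao`` optionally supply already-preprocessed crops
    (e.g. when the whole tile was filtered at once); they must equal
    ``preprocess_channel`` output for the same parameters.
    """
    gp = pre_green if pre_green is not None else preprocess_channel(
        green, params.threshold_green, params.sigma_px)
    dp = pre_ddao if pre_ddao is not None else preprocess_channel(
        ddao, params.threshold_ddao, params.sigma_px)
    ev = np.zeros_like(gp)
    for ch in (gp, dp):
        m = ch.max()
        if m > 0:
            np.maximum(ev, ch / m, out=ev)
    mask = ev >= params.evidence_level
    if not mask.any():
        return []
    edges = mask & ~ndimage.binary_erosion(mask)
    radii = np.arange(params.radius_min_px, params.radius_max_px + 1)
    acc = hough_circle(edges, radii, normalize=True)
    # non-maximum suppression on the radius-collapsed accumulator
    best_v = acc.max(axis=0)
    best_r = radii[acc.argmax(axis=0)]
    size = 2 * int(params.min_separation_px) + 1
    is_peak = (best_v >= params.hough_threshold) & (
        best_v == ndimage.maximum_filter(best_v, size=size)
    )
    ys, xs = np.nonzero(is_peak)
    # greedy radial merge of detections closer than min_separation
    order = np.argsort(best_v[ys, xs])[::-1][: 4 * params.max_cells_per_well]
    kept: list[tuple[float, float, float]] = []
    for i in order:
        if len(kept) >= params.max_cells_per_well:
            break
        y, x = float(ys[i]), float(xs[i])
        r = float(best_r[ys[i], xs[i]])
        if all(np.hypot(y - ky, x - kx) >= params.min_separation_px for ky, kx, _ in kept):
            kept.append((y, x, r))
    g_raw = np.asarray(green, dtype=np.float64)
    d_raw = np.asarray(ddao, dtype=np.float64)
    union = (g_raw > params.threshold_green) | (d_raw > params.threshold_ddao)
    yy, xx = np.ogrid[0 : union.shape[0], 0 : union.shape[1]]
    cells = []
    for y, x, r in kept:
        mr = r * params.measure_radius_frac
        mg = _disk_mean(g_raw, y, x, mr, params.background_green)
        md = _disk_mean(d_raw, y, x, mr, params.background_ddao)
        if max(mg, md) < params.min_cell_intensity:
            continue
        # a genuine cell fills its fitted disk with above-threshold signal;
        # gap artefacts and small debris do not
        dmask = (yy - y) ** 2 + (xx - x) ** 2 <= mr * mr
        if dmask.any() and union[dmask].mean() < params.min_fill_fraction:
            continue
        cells.append(
            DetectedCell(
                cell_class="target",
                y=y,
                x=x,
                radius_px=r,
                area_px=float(np.pi * r * r),
                mean_green=mg,
                mean_ddao=md,
                well=well,
            )
        )
    return cells


def detect_nk(
    orange: np.ndarray,
    params: DetectionParams,
    well: WellIndex | None = None,
) -> list[DetectedCell]:
    """Connected-component NK detection in one well crop of the orange channel.

    Components with area in ``[nk_min_area, nk_max_area]`` count as one NK;
    larger components (merged cells) count as ``round(area / typical_area)``
    with multiplicity recorded on a single detection.
    """
    raw = np.asarray(orange, dtype=np.float64)
    mask = raw > params.threshold_orange
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    cells = []
    for comp in ndimage.find_objects(labels):
        sub = labels[comp]
        lab = sub[sub > 0][0]
        m = labels == lab
        area = float(m.sum())
        if area < params.nk_min_area_px:
            continue
        cy_, cx_ = ndimage.center_of_mass(m)
        mult = 1
        if area > params.nk_max_area_px:
            mult = max(1, int(round(area / params.nk_typical_area_px)))
        cells.append(
            DetectedCell(
                cell_class="nk",
                y=float(cy_),
                x=float(cx_),
                area_px=area,
                mean_orange=max(0.0, float(raw[m].mean()) - params.background_orange),
                multiplicity=mult,
                well=well,
            )
        )
    return cells


def _circle_overlap_area(d: float, r1: float, r2: float) -> float:
    """Intersection area of two circles with centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return np.pi * r * r
    a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    k = 0.5 * np.sqrt((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    return float(a1 + a2 - k)


def goodness_score(
    targets: list[DetectedCell],
    nks: list[DetectedCell],
    channels: dict[str, np.ndarray],
    params: DetectionParams,
) -> tuple[float, set[str]]:
    """Figure of goodness for one well: product of four penalties in (0, 1].

    Factors: many cells in the well, large contiguous (merged) objects,
    bright above-threshold signal not assigned to any detection, and
    overlap between detected cells.  The score is 1.0 iff no penalty is
    active; wells below 0.5 additionally get the ``manual_review`` flag.
    """
    flags: set[str] = set()
    n_cells = len(targets) + sum(c.multiplicity for c in nks)

    p_count = 1.0
    if n_cells > params.count_soft_cap:
        p_count = params.count_soft_cap / n_cells
        flags.add("many_cells")

    n_large = sum(1 for c in nks if c.multiplicity > 1)
    p_large = params.large_penalty ** n_large
    if n_large:
        flags.add("large_contiguous")

    # bright pixels outside every detection, as a fraction of the well area
    shape = next(iter(channels.values())).shape
    assigned = np.zeros(shape, dtype=bool)
    yy, xx = np.ogrid[0 : shape[0], 0 : shape[1]]
    for c in targets:
        assigned |= (yy - c.y) ** 2 + (xx - c.x) ** 2 <= (c.radius_px + 1.5) ** 2
    thr = {
        "green": params.threshold_green,
        "ddao": params.threshold_ddao,
        "orange": params.threshold_orange,
    }
    bright = np.zeros(shape, dtype=bool)
    for name, img in channels.items():
        bright |= np.asarray(img) > thr.get(name, np.inf)
    for c in nks:
        assigned |= (yy - c.y) ** 2 + (xx - c.x) ** 2 <= (
            1.5 * np.sqrt(c.area_px * c.multiplicity / np.pi)
        ) ** 2
    f_bright = float((bright & ~assigned).sum()) / bright.size
    p_bright = 1.0
    if f_bright > params.bright_area_tol:
        p_bright = float(np.exp(-(f_bright - params.bright_area_tol) * 25.0))
        flags.add("bright_unidentified")

    # pairwise overlap among detected target disks
    total_area = sum(c.area_px for c in targets)
    shared = 0.0
    for i in range(len(targets)):
        for j in range(i + 1, len(targets)):
            a, b = targets[i], targets[j]
            shared += _circle_overlap_area(np.hypot(a.y - b.y, a.x - b.x), a.radius_px, b.radius_px)
    f_overlap = shared / total_area if total_area > 0 else 0.0
    p_overlap = 1.0
    if f_overlap > params.overlap_tol:
        p_overlap = float(np.exp(-(f_overlap - params.overlap_tol) * 8.0))
        flags.add("overlap")

    score = float(np.clip(p_count * p_large * p_bright * p_overlap, 0.0, 1.0))
    if score < 0.5:
        flags.add("manual_review")
    return score, flags
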