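"""Live/dead classification of target cells.

A target's viability is read from its calcein-green versus DDAO intensity:
death releases calcein (green drops) while the amine-reactive DDAO label
persists and appears brighter.  Cells are ordered by the log-ratio
discriminant ``d = log((green + eps) / (ddao + eps))`` and labelled live
above a threshold that is set either manually or automatically.

The automatic threshold maximizes the mean pairwise Euclidean distance
between the live and the dead group in standardized (green, ddao) space,
over the finite candidate set of midpoints between consecutive sorted
discriminant values.  Per-channel standardization keeps the objective from
being dominated by the brighter channel, and thresholds should be computed
per screen because photobleaching shifts intensities between screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ViabilityCall", "discriminant", "classify", "auto_threshold"]

DEFAULT_EPS = 1.0


class DegeneratePopulationError(ValueError):
    """All discriminant values identical, or too few cells to threshold."""


@dataclass(frozen=True)
class ViabilityCall:
    cell_id: int
    discriminant: float
    label: str  # 'live' | 'dead'
    threshold_used: float
    method: str  # 'manual' | 'auto'


def discriminant(green, ddao, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Log-ratio viability discriminant; large means green-dominated (live)."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    g = np.asarray(green, dtype=float)
    d = np.asarray(ddao, dtype=float)
    return np.log((g + eps) / (d + eps))


def classify(
    green,
    ddao,
    threshold: float,
    cell_ids=None,
    method: str = "manual",
    eps: float = DEFAULT_EPS,
) -> list[ViabilityCall]:
    """Deterministic labelling: live iff discriminant > threshold."""
    d = discriminant(green, ddao, eps)
    ids = range(len(d)) if cell_ids is None else cell_ids
    return [
        ViabilityCall(
            cell_id=int(i),
            discriminant=float(di),
            label="live" if di > threshold else "dead",
            threshold_used=float(threshold),
            method=method,
        )
        for i, di in zip(ids, d)
    ]


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def cross_pair_objective(feats: np.ndarray, live_mask: np.ndarray) -> float:
    """Mean Euclidean distance over all (live, dead) cross pairs."""
    if live_mask.all() or not live_mask.any():
        return -np.inf
    diff = feats[live_mask][:, None, :] - feats[~live_mask][None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).mean())


def threshold_candidates(
    green,
    ddao,
    eps: float = DEFAULT_EPS,
    max_cells: int = 3000,
) -> tuple[np.ndarray, np.ndarray]:
    """All candidate thresholds with their separation objective.

    Candidates are midpoints between consecutive distinct sorted
    discriminant values.  A candidate's objective is the mean pairwise
    Euclidean distance between the induced live and dead groups in
    standardized (green, ddao) space, weighted by the balanced group-size
    factor sqrt(n_live * n_dead) / n.  The weight matters: the unweighted
    per-pair mean is maximized by peeling a single extreme cell off a tight
    cluster (a 6%-dead population gets thresholded inside its dead
    cluster), while the raw distance sum is maximized by cutting the large
    cluster in half once dye-loading spread is realistic; the geometric
    weight suppresses both failure modes.  Populations beyond ``max_cells``
    are thinned deterministically (every k-th cell in discriminant order).
    Returns ``(thresholds, objectives)``.
    """
    g = np.asarray(green, dtype=float)
    r = np.asarray(ddao, dtype=float)
    if g.size < 2:
        raise DegeneratePopulationError("need at least 2 cells")
    d = discriminant(g, r, eps)
    if np.ptp(d) == 0:
        raise DegeneratePopulationError("degenerate population: identical discriminants")

    order = np.argsort(d, kind="stable")
    g, r, d = g[order], r[order], d[order]
    if d.size > max_cells:
        step = int(np.ceil(d.size / max_cells))
        g, r, d = g[::step], r[::step], d[::step]

    feats = np.column_stack([_standardize(g), _standardize(r)])
    # cumulative row sums of the pairwise distance matrix give an O(n^2) scan
    dist = np.sqrt(((feats[:, None, :] - feats[None, :, :]) ** 2).sum(-1))
    n = d.size
    csum = np.cumsum(dist, axis=1)
    thrs: list[float] = []
    objs: list[float] = []
    C = 0.0  # sum of distances between dead = [0..i] and live = [i+1..]
    for i in range(n - 1):
        row_tail = csum[i, -1] - csum[i, i]
        row_head = csum[i, i - 1] if i > 0 else 0.0
        C += row_tail - row_head
        if d[i] >= d[i + 1]:  # tied values leave no midpoint
            continue
        n_dead, n_live = i + 1, n - 1 - i
        thrs.append(0.5 * (d[i] + d[i + 1]))
        objs.append(C / (n_dead * n_live) * np.sqrt(n_dead * n_live) / n)
    if not thrs:
        raise DegeneratePopulationError("degenerate population: identical discriminants")
    return np.asarray(thrs), np.asarray(objs)


def auto_threshold(
    green,
    ddao,
    eps: float = DEFAULT_EPS,
    max_cells: int = 3000,
) -> float:
    """Automatic threshold on the log-ratio discriminant.

    Returns the candidate maximizing the live-dead pairwise-distance
    objective of :func:`threshold_candidates`; exact ties break toward the
    candidate nearest the discriminant median.
    """
    thrs, objs = threshold_candidates(green, ddao, eps, max_cells)
    jmax = objs.max()
    tied = thrs[objs >= jmax - 1e-12 * max(1.0, abs(jmax))]
    med = float(np.median(discriminant(np.asarray(green, float), np.asarray(ddao, float), eps)))
    return float(tied[np.argmin(np.abs(tied - med))])
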