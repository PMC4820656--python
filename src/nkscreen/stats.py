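"""Population statistics for cytotoxicity screens.

Covers the study-level summaries: fraction of cytotoxic NK cells (with
Wilson intervals, an addition for usability), the kill-count distribution,
the killing share of high-kill classes, the Yates continuity-corrected
chi-square test with star annotation, and a spontaneous-death-corrected
kill-distribution estimator.

The correction exists because screen counting cannot tell an NK kill from
a spontaneous target death inside the same well.  Under the assay model,
the deaths ``D`` observed in a single-NK well with ``n`` live targets at
baseline decompose as ``D = K + Binomial(n - K, q)`` where ``K`` is the NK
kill count and ``q`` the per-target spontaneous death probability over the
scoring window, measurable in NK-free wells.  ``corrected_kill_distribution``
inverts this mixture by maximum likelihood (EM), returning the distribution
of ``K`` free of the spontaneous background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SignificanceMark",
    "significance_mark",
    "yates_chi_square",
    "fraction_cytotoxic",
    "kill_distribution",
    "corrected_kill_distribution",
    "killing_share",
    "killing_share_from_distribution",
]


@dataclass(frozen=True)
class SignificanceMark:
    p_value: float
    stars: str  # 'n.s.' | '*' | '**' | '***'


def significance_mark(p: float) -> SignificanceMark:
    """Star annotation: p > 0.05 n.s.; * to 0.01; ** to 0.001; *** below."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p > 0.05:
        stars = "n.s."
    elif p > 0.01:
        stars = "*"
    elif p >= 0.001:
        stars = "**"
    else:
        stars = "***"
    return SignificanceMark(p_value=float(p), stars=stars)


def yates_chi_square(a: int, b: int, c: int, d: int) -> tuple[float, float, SignificanceMark]:
    """Yates continuity-corrected chi-square for a 2x2 table [[a, b], [c, d]].

    chi2 = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)) with the
    correction clamped at |ad - bc| so the statistic is never negative;
    p from the chi-square(1) survival function.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n == 0 or any(m == 0 for m in margins):
        raise ValueError("undefined test: zero margin")
    det = abs(a * d - b * c)
    corrected = max(0.0, det - n / 2.0)
    chi2 = n * corrected ** 2 / np.prod([float(m) for m in margins])
    p = float(special.chdtrc(1, chi2))
    return float(chi2), p, significance_mark(p)


def fraction_cytotoxic(scores: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Fraction of cytotoxic NK cells, per group and pooled.

    ``scores`` needs a boolean ``cytotoxic`` column (one row per selected
    single-NK well); ``group`` optionally names a grouping column such as a
    donor label.  Wilson 95% intervals accompany each fraction.
    """
    if not len(scores):
        raise ValueError("empty selection")

    def _one(name, df):
        k, n = int(df["cytotoxic"].sum()), len(df)
        lo, hi = proportion_confint(k, n, method="wilson")
        return dict(group=name, n_cytotoxic=k, n_total=n, fraction=k / n,
                    wilson_low=float(lo), wilson_high=float(hi))

    rows = [_one("pooled", scores)]
    if group is not None:
        for g, df in scores.groupby(group):
            if len(df):
                rows.append(_one(g, df))
    return pd.DataFrame(rows).set_index("group")


def kill_distribution(total_kills, k_max: int = 3) -> np.ndarray:
    """Frequencies over kill counts 0..k_max with an open >=k_max top bin."""
    k = np.asarray(total_kills, dtype=int)
    if k.size == 0:
        raise ValueError("empty selection")
    binned = np.minimum(k, k_max)
    freq = np.bincount(binned, minlength=k_max + 1).astype(float)
    return freq / freq.sum()


def _mixture_kernel(n: int, k: int, d: int, q: float) -> float:
    """P(D = d | K = k, n live at baseline) for D = k + Binomial(n-k, q)."""
    if d < k or d > n:
        return 0.0
    return float(special.comb(n - k, d - k) * q ** (d - k) * (1 - q) ** (n - d))


def corrected_kill_distribution(
    baseline_live,
    deaths,
    q: float,
    k_support: int | None = None,
    n_iter: int = 500,
    tol: float = 1e-10,
) -> np.ndarray:
    """Maximum-likelihood kill distribution deconvolved of spontaneous death.

    Parameters
    ----------
    baseline_live, deaths
        Per selected single-NK well: live targets at baseline and deaths
        scored over the assay.
    q
        Per-target spontaneous death probability over the same window,
        estimated from NK-free wells.
    k_support
        Largest kill count modelled; defaults to the largest observed
        death count.

    Returns P(K = k) for k = 0..k_support, fitted by EM on the exact
    mixture ``D = K + Binomial(n - K, q)``.
    """
    n = np.asarray(baseline_live, dtype=int)
    d = np.asarray(deaths, dtype=int)
    if n.size == 0 or n.size != d.size:
        raise ValueError("baseline_live and deaths must be equal-length, nonempty")
    if np.any(d > n) or np.any(d < 0):
        raise ValueError("deaths must lie in [0, baseline_live]")
    if not 0 <= q < 1:
        raise ValueError("q must be in [0, 1)")
    kmax = int(d.max()) if k_support is None else int(k_support)
    kmax = max(kmax, 1)

    # collapse to unique (n, d) cells with counts
    cells, counts = np.unique(np.column_stack([n, d]), axis=0, return_counts=True)
    kern = np.zeros((len(cells), kmax + 1))
    for i, (ni, di) in enumerate(cells):
        for k in range(min(di, kmax) + 1):
            kern[i, k] = _mixture_kernel(int(ni), k, int(di), q)

    p = np.full(kmax + 1, 1.0 / (kmax + 1))
    w = counts / counts.sum()
    for _ in range(n_iter):
        joint = kern * p  # (cells, k)
        denom = joint.sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        resp = joint / denom
        p_new = (w[:, None] * resp).sum(axis=0)
        s = p_new.sum()
        if s <= 0:
            break
        p_new /= s
        if np.abs(p_new - p).max() < tol:
            p = p_new
            break
        p = p_new
    return p


def killing_share(total_kills, k: int) -> float:
    """Fraction of all scored kills committed by NK cells with >= k kills."""
    t = np.asarray(total_kills, dtype=float)
    total = t.sum()
    if total <= 0:
        raise ValueError("zero total kills")
    return float(t[t >= k].sum() / total)


def killing_share_from_distribution(p, k: int) -> float:
    """Killing share of the >=k class implied by a kill-count distribution."""
    p = np.asarray(p, dtype=float)
    kk = np.arange(p.size, dtype=float)
    total = float(np.dot(kk, p))
    if total <= 0:
        raise ValueError("zero expected kills")
    return float(np.dot(kk[k:], p[k:]) / total)


def cytotoxic_contingency(scores_a: pd.DataFrame, scores_b: pd.DataFrame):
    """2x2 (condition x cytotoxic/non-cytotoxic) table and its Yates test."""
    a = int(scores_a["cytotoxic"].sum())
    b = len(scores_a) - a
    c = int(scores_b["cytotoxic"].sum())
    d = len(scores_b) - c
    chi2, p, mark = yates_chi_square(a, b, c, d)
    table = pd.DataFrame(
        [[a, b], [c, d]], index=["condition_a", "condition_b"],
        columns=["cytotoxic", "non_cytotoxic"],
    )
    return table, chi2, p, mark


def gof_chi_square(observed_counts, expected_probs) -> tuple[float, float]:
    """Goodness-of-fit chi-square of histogram counts against probabilities."""
    obs = np.asarray(observed_counts, dtype=float)
    exp = np.asarray(expected_probs, dtype=float) * obs.sum()
    keep = exp > 0
    stat, p = sps.chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
    return float(stat), float(p)
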