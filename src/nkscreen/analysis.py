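"""Time-course assembly, well selection and kill scoring.

Per-screen well records are aligned into per-well time courses, filtered by
the study's selection criteria, and scored: the kills in an interval are
the decrease in live-target count between consecutive screens, and in
single-NK wells all kills are attributed to that NK.  Baselines differ by
analysis: the standard screens score from ``T_0h``, while the serial-killing
assay scores from the target-only prescreen ``T_minusNK`` so that killing
before the first post-mixing screen is captured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .synthetic import timepoint_minutes

__all__ = [
    "ScreenTimepoint",
    "KillScore",
    "align_screens",
    "select_wells",
    "score_kills",
    "score_all_kills",
    "spontaneous_rate",
    "CRITERIA",
]

log = logging.getLogger(__name__)

SERIAL_KILLER_MIN_KILLS = 3  # >=3 kills within one assay


@dataclass(frozen=True)
class ScreenTimepoint:
    """One screen of the incubate-image cycle."""

    label: str
    screen_index: int

    @property
    def time_min(self) -> float:
        return timepoint_minutes(self.label)


@dataclass(frozen=True)
class KillScore:
    """Kills attributed to the single NK of one selected well."""

    well_id: int
    kills_per_interval: tuple[int, ...]
    total_kills: int
    baseline_live: int = 0

    def __post_init__(self) -> None:
        if self.total_kills != sum(self.kills_per_interval):
            raise ValueError("total_kills must equal the interval sum")

    @property
    def cytotoxic(self) -> bool:
        return self.total_kills >= 1

    @property
    def serial_killer(self) -> bool:
        return self.total_kills >= SERIAL_KILLER_MIN_KILLS


def align_screens(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Join per-screen well tables into one wide time-course frame.

    ``tables`` maps a timepoint label to a frame indexed by ``well_id`` with
    columns ``n_nk``, ``n_target_live``, ``n_target_dead``, ``goodness``.
    Only wells present in every screen are kept; the rest are logged.
    Output columns are ``<col>_<label>``, ordered by screen time.
    """
    if not tables:
        raise ValueError("no screens to align")
    labels = sorted(tables, key=timepoint_minutes)
    common = None
    for lab in labels:
        idx = tables[lab].index
        common = idx if common is None else common.intersection(idx)
    dropped = set().union(*(set(tables[lab].index) for lab in labels)) - set(common)
    if dropped:
        log.info("align_screens: %d wells missing from some screen, excluded", len(dropped))
    parts = []
    for lab in labels:
        t = tables[lab].loc[common, ["n_nk", "n_target_live", "n_target_dead", "goodness"]]
        parts.append(t.add_suffix(f"_{lab}"))
    out = pd.concat(parts, axis=1)
    out.attrs["timepoints"] = labels
    return out


def _labels(tcs: pd.DataFrame) -> list[str]:
    labels = tcs.attrs.get("timepoints")
    if labels:
        return list(labels)
    labels = sorted(
        {c.split("_", 1)[1] for c in tcs.columns if c.startswith("n_nk_")},
        key=timepoint_minutes,
    )
    return labels


def _qc_mask(tcs: pd.DataFrame, labels: list[str], min_goodness: float) -> pd.Series:
    ok = pd.Series(True, index=tcs.index)
    for lab in labels:
        ok &= tcs[f"goodness_{lab}"] >= min_goodness
    return ok


CRITERIA = ("fig2", "fig3", "fig4", "spontaneous")


def select_wells(tcs: pd.DataFrame, criterion: str, min_goodness: float = 0.5) -> pd.DataFrame:
    """Apply a named well-selection criterion to aligned time courses.

    - ``fig2``: single NK and >=1 live target at ``T_0h``.
    - ``fig3``: single NK and >=3 live targets at ``T_0h``.
    - ``fig4``: >=5 live targets at ``T_minusNK``, a single NK at ``T_0h``
      and <=1 NK at every later screen.
    - ``spontaneous``: no NK at any screen (background death control).

    Wells whose goodness drops below ``min_goodness`` at any screen are
    excluded everywhere (the automated stand-in for manual recounting).
    """
    labels = _labels(tcs)
    ok = _qc_mask(tcs, labels, min_goodness)
    post = [lab for lab in labels if lab != "T_minusNK"]
    if criterion == "fig2":
        sel = ok & (tcs["n_nk_T_0h"] == 1) & (tcs["n_target_live_T_0h"] >= 1)
    elif criterion == "fig3":
        sel = ok & (tcs["n_nk_T_0h"] == 1) & (tcs["n_target_live_T_0h"] >= 3)
    elif criterion == "fig4":
        if "T_minusNK" not in labels:
            raise ValueError("fig4 selection requires a T_minusNK prescreen")
        sel = ok & (tcs["n_target_live_T_minusNK"] >= 5) & (tcs["n_nk_T_0h"] == 1)
        for lab in post[1:]:
            sel &= tcs[f"n_nk_{lab}"] <= 1
    elif criterion == "spontaneous":
        sel = ok
        for lab in post:
            sel &= tcs[f"n_nk_{lab}"] == 0
    else:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    out = tcs[sel].copy()
    out.attrs["timepoints"] = labels
    out.attrs["criterion"] = criterion
    return out


def score_kills(row: pd.Series, labels: list[str], baseline: str = "T_0h") -> KillScore | None:
    """Score one well's kills from its live-count decreases.

    Wells with inconsistent counts are rejected (return None): dead counts
    decreasing by more than 1 between screens, or summed interval kills
    exceeding the live targets present at baseline (a live count cannot
    rebound; both indicate miscounting).
    """
    if baseline not in labels:
        raise ValueError(f"baseline {baseline!r} not among screens {labels}")
    seq = labels[labels.index(baseline):]
    live = [int(row[f"n_target_live_{lab}"]) for lab in seq]
    dead = [int(row[f"n_target_dead_{lab}"]) for lab in seq]
    if any(d1 < d0 - 1 for d0, d1 in zip(dead[:-1], dead[1:])):
        return None
    kills = tuple(max(0, a - b) for a, b in zip(live[:-1], live[1:]))
    if sum(kills) > live[0]:
        return None
    return KillScore(
        well_id=int(row.name),
        kills_per_interval=kills,
        total_kills=sum(kills),
        baseline_live=live[0],
    )


def score_all_kills(tcs: pd.DataFrame, baseline: str = "T_0h") -> pd.DataFrame:
    """Kill scores for every well of an aligned/selected frame.

    Returns a frame indexed by well_id with columns ``total_kills``,
    ``baseline_live``, ``cytotoxic``, ``serial_killer`` plus one column per
    interval; inconsistent wells are dropped.
    """
    labels = _labels(tcs)
    seq = labels[labels.index(baseline):]
    rows = []
    for _, row in tcs.iterrows():
        ks = score_kills(row, labels, baseline)
        if ks is None:
            continue
        rec = {
            "well_id": ks.well_id,
            "total_kills": ks.total_kills,
            "baseline_live": ks.baseline_live,
            "cytotoxic": ks.cytotoxic,
            "serial_killer": ks.serial_killer,
        }
        for (a, b), k in zip(zip(seq[:-1], seq[1:]), ks.kills_per_interval):
            rec[f"kills_{a}_to_{b}"] = k
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("well_id")
    return out


def spontaneous_rate(tcs: pd.DataFrame, baseline: str | None = None) -> dict:
    """Spontaneous target death measured in NK-free wells.

    Returns both granularities with their numerators and denominators:
    the fraction of NK-free wells showing >=1 death after baseline
    (``well_rate``) and the per-target death probability over the same
    window (``cell_rate``).
    """
    labels = _labels(tcs)
    nkfree = select_wells(tcs, "spontaneous")
    if not len(nkfree):
        raise ValueError("no NK-free wells in selection")
    base = baseline or labels[0]
    last = labels[-1]
    live0 = nkfree[f"n_target_live_{base}"]
    live1 = nkfree[f"n_target_live_{last}"]
    deaths = (live0 - live1).clip(lower=0)
    withtargets = live0 > 0
    n_wells = int(withtargets.sum())
    if n_wells == 0:
        raise ValueError("no NK-free wells with live targets at baseline")
    return {
        "well_rate": float((deaths[withtargets] > 0).mean()),
        "well_numerator": int((deaths[withtargets] > 0).sum()),
        "well_denominator": n_wells,
        "cell_rate": float(deaths.sum() / live0.sum()),
        "cell_numerator": int(deaths.sum()),
        "cell_denominator": int(live0.sum()),
    }
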