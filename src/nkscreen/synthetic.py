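"""Ground-truthed synthetic cytotoxicity screens.

This module simulates the whole microwell assay: Poisson seeding of target
and NK cells into wells, NK-mediated kill events drawn from a per-cell
kill-count distribution, spontaneous target death, and rendering of
four-channel fluorescence tiles (transmitted light, calcein-orange NK,
calcein-green target, DDAO target) with photobleaching, late-screen debris
and additive noise.  Every simulation returns an :class:`AssayTruth` with
per-cell positions, viability trajectories and per-NK kill counts, so the
downstream segmentation/classification/scoring stages can be validated
against exact ground truth.

Timeline convention: minutes relative to the first post-mixing screen
(``T_0h``).  The target-only prescreen ``T_minusNK`` sits at -45 min (one
whole-chip screen takes about 45 min); NK cells are seeded immediately
after the prescreen, so kills may occur in the (-45, 0] window before the
first screen with NK present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import ChipLayout, nominal_well_rois, tile_shape

__all__ = [
    "KillDistribution",
    "OpticsModel",
    "AssayConfig",
    "AssayTruth",
    "SimulatedScreen",
    "RESTING_KILL_DIST",
    "SERIAL_KILL_DIST",
    "preset_config",
    "sample_occupancy",
    "sample_kills",
    "render_screen",
    "simulate_assay",
    "timepoint_minutes",
]

CHANNELS = ("trans", "orange", "green", "ddao")

_CANONICAL_MIN = {"T_minusNK": -45.0, "T_0h": 0.0, "T_6h": 360.0, "T_12h": 720.0}


def timepoint_minutes(label: str) -> float:
    """Time of a screen label in minutes relative to ``T_0h``."""
    if label in _CANONICAL_MIN:
        return _CANONICAL_MIN[label]
    if label.startswith("t+") and label.endswith("m"):
        return float(label[2:-1])
    raise ValueError(f"unknown timepoint label {label!r}")


class KillDistribution:
    """Probability distribution over per-NK kill counts 0..k_max."""

    def __init__(self, probabilities) -> None:
        p = np.asarray(probabilities, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("probabilities must be a 1-D non-empty sequence")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {p.sum()!r})")
        self.p = p

    @property
    def k_max(self) -> int:
        return self.p.size - 1

    def mean(self) -> float:
        return float(np.dot(np.arange(self.p.size), self.p))

    def tail(self, k: int) -> float:
        """P(kills >= k)."""
        return float(self.p[k:].sum())

    def expected_share(self, k: int) -> float:
        """Expected fraction of all kills committed by cells with >= k kills."""
        kk = np.arange(self.p.size)
        return float(np.dot(kk[k:], self.p[k:]) / np.dot(kk, self.p))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(self.p.size, size=size, p=self.p)


# Resting (non-activated) NK against K562: 72% kill nothing, ~1% are serial
# killers (>=3 kills in 12 h); the 1/2-kill split is a calibration default.
RESTING_KILL_DIST = KillDistribution([0.72, 0.20, 0.07, 0.01])

# IL-2-activated NK in the serial-killing assay (doubled target density):
# calibrated so >=3-killers commit 70% of all kills and >=5-killers ~22%.
SERIAL_KILL_DIST = KillDistribution([0.30, 0.27, 0.12, 0.14, 0.10, 0.05, 0.02])


@dataclass(frozen=True)
class OpticsModel:
    """Rendering model: cell sizes, channel intensity levels, bleaching,
    late-screen debris and imaging noise (intensities in arbitrary units)."""

    target_radius_um: float = 5.5
    target_radius_sd_um: float = 0.45
    nk_radius_um: float = 4.0
    live_green_level: float = 150.0
    live_ddao_level: float = 25.0
    dead_green_level: float = 15.0
    dead_ddao_level: float = 160.0
    nk_orange_level: float = 150.0
    trans_wall_level: float = 200.0
    trans_floor_level: float = 90.0
    bleach_factor_per_screen: float = 0.85
    nk_extra_bleach: float = 0.92
    debris_rate_late: float = 0.3
    noise_sd: float = 5.0
    background: float = 20.0
    level_jitter_sd: float = 0.10  # per-cell dye-loading heterogeneity (lognormal)

    def __post_init__(self) -> None:
        if not self.live_green_level > self.dead_green_level:
            raise ValueError("live_green_level must exceed dead_green_level")
        if not self.dead_ddao_level > self.live_ddao_level:
            raise ValueError("dead_ddao_level must exceed live_ddao_level")
        for name in (
            "target_radius_um",
            "nk_radius_um",
            "live_green_level",
            "live_ddao_level",
            "dead_green_level",
            "dead_ddao_level",
            "nk_orange_level",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.bleach_factor_per_screen <= 1:
            raise ValueError("bleach_factor_per_screen must be in (0, 1]")
        if not 0 < self.nk_extra_bleach <= 1:
            raise ValueError("nk_extra_bleach must be in (0, 1]")


@dataclass(frozen=True)
class AssayConfig:
    """Assay conditions: seeding densities, schedule and death rates.

    ``et_ratio`` is effector:target, so the per-well NK mean is
    ``mean_targets_per_well * et_ratio``.  ``spontaneous_death_per_interval``
    is the per-target death probability per 6-h incubation interval;
    it is rescaled by interval length for uneven schedules.
    """

    et_ratio: float = 1.0 / 3.0
    mean_targets_per_well: float = 3.0
    timepoints: tuple[str, ...] = ("T_0h", "T_6h", "T_12h")
    prescreen: bool = False
    scenario: str = "resting"
    initial_dead_fraction: float = 0.06
    spontaneous_death_per_interval: float = 0.02
    pre_t0_kill_window_min: float = 0.0
    max_targets_per_well: int = 8
    max_nk_per_well: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.et_ratio < 0:
            raise ValueError("et_ratio must be >= 0")
        for name in ("initial_dead_fraction", "spontaneous_death_per_interval"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        times = [timepoint_minutes(t) for t in self.timepoints]
        if sorted(times) != times or len(set(times)) != len(times):
            raise ValueError("timepoints must be strictly increasing")
        if self.prescreen and self.timepoints[0] != "T_minusNK":
            raise ValueError("prescreen requires T_minusNK as first timepoint")

    @property
    def times_min(self) -> tuple[float, ...]:
        return tuple(timepoint_minutes(t) for t in self.timepoints)


_PRESETS = {
    # Time-lapse of resting NK + K562 at E:T ~1:3; imaging starts at mixing,
    # so there is no unobserved pre-T_0h window.
    "resting": dict(
        et_ratio=1.0 / 3.0,
        mean_targets_per_well=3.0,
        timepoints=("T_0h", "T_6h", "T_12h"),
        prescreen=False,
        pre_t0_kill_window_min=0.0,
        scenario="resting",
    ),
    # IL-2-activated NK screening; first screen completes ~45 min after
    # mixing, so some kills precede T_0h and are invisible to a T_0h baseline.
    "il2_activated": dict(
        et_ratio=1.0 / 3.0,
        mean_targets_per_well=3.0,
        timepoints=("T_0h", "T_6h", "T_12h"),
        prescreen=False,
        pre_t0_kill_window_min=45.0,
        scenario="il2_activated",
    ),
    # Serial-killing assay: target density doubled at unchanged NK density,
    # plus a target-only prescreen before NK seeding.
    "serial_assay": dict(
        et_ratio=1.0 / 6.0,
        mean_targets_per_well=6.0,
        timepoints=("T_minusNK", "T_0h", "T_6h", "T_12h"),
        prescreen=True,
        pre_t0_kill_window_min=45.0,
        scenario="serial_assay",
    ),
}

_PRESET_DISTS = {
    "resting": RESTING_KILL_DIST,
    "il2_activated": SERIAL_KILL_DIST,
    "serial_assay": SERIAL_KILL_DIST,
}


def preset_config(name: str, **overrides) -> tuple[AssayConfig, KillDistribution]:
    """Named assay preset -> (config, kill distribution)."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return AssayConfig(**params), _PRESET_DISTS[name]


@dataclass
class AssayTruth:
    """Ground truth of one simulated assay.

    ``cells`` has one row per cell with columns: cell_id, well_id,
    subunit_row/col, well_row/col, cell_class ('target'|'nk'), y_px, x_px
    (nominal tile coordinates), radius_px, nk_dy1/dx1/dy2/dx2 (NK lobe
    offsets), death_time_min (+inf alive throughout, -inf dead before the
    prescreen), killer_id (-1 if not NK-killed), kill_count (NK rows only).
    """

    layout: ChipLayout
    config: AssayConfig
    cells: pd.DataFrame
    field_offsets: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)

    def alive_at(self, label: str) -> pd.Series:
        return self.cells["death_time_min"] > timepoint_minutes(label)

    def well_counts(self, label: str) -> pd.DataFrame:
        """Per-well truth counts (n_nk, n_target_live, n_target_dead) at a screen."""
        t = timepoint_minutes(label)
        df = self.cells
        is_t = df["cell_class"] == "target"
        alive = df["death_time_min"] > t
        # NK cells are seeded only after the target-only prescreen
        nk_present = (df["cell_class"] == "nk") & (label != "T_minusNK")
        out = pd.DataFrame(
            {
                "n_nk": nk_present.groupby(df["well_id"]).sum(),
                "n_target_live": (is_t & alive).groupby(df["well_id"]).sum(),
                "n_target_dead": (is_t & ~alive).groupby(df["well_id"]).sum(),
            }
        )
        return out.astype(int)

    def nk_kill_counts(self) -> pd.Series:
        nk = self.cells[self.cells["cell_class"] == "nk"]
        return nk.set_index("cell_id")["kill_count"].astype(int)


# ---------------------------------------------------------------------------
# occupancy and kill sampling
# ---------------------------------------------------------------------------


def _placement_sites(layout: ChipLayout, optics: OpticsModel) -> np.ndarray:
    """Well-local lattice of candidate cell centres (sedimented cells spread
    across the well floor without large overlaps)."""
    side = layout.well_side_px
    r = optics.target_radius_um / layout.pixel_size_um
    margin = r + 2.0
    pitch_min = 2.6 * r
    n_axis = max(1, int((side - 2 * margin) // pitch_min) + 1)
    coords = np.linspace(margin, side - margin, n_axis)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    return np.column_stack([yy.ravel(), xx.ravel()])


def sample_occupancy(
    layout: ChipLayout,
    config: AssayConfig,
    rng: np.random.Generator,
    optics: OpticsModel | None = None,
) -> AssayTruth:
    """Seed cells into wells: Poisson occupancy, jittered-lattice placement,
    and an ``initial_dead_fraction`` of targets dead before the prescreen."""
    optics = optics or OpticsModel()
    sites = _placement_sites(layout, optics)
    n_sites = len(sites)
    jitter = 2.0
    px = layout.pixel_size_um

    rows: list[dict] = []
    cell_id = 0
    for sr in range(layout.subunit_rows):
        for sc in range(layout.subunit_cols):
            rois = nominal_well_rois(layout, field=(sr, sc))
            n_t = np.minimum(
                rng.poisson(config.mean_targets_per_well, size=len(rois)),
                config.max_targets_per_well,
            )
            n_k = np.minimum(
                rng.poisson(config.mean_targets_per_well * config.et_ratio, size=len(rois)),
                config.max_nk_per_well,
            )
            for roi, nt, nk in zip(rois, n_t, n_k):
                n = int(nt) + int(nk)
                if n == 0:
                    continue
                if n > n_sites:  # physically cannot fit; clip targets first
                    nt = max(0, n_sites - int(nk))
                    n = int(nt) + int(nk)
                picks = rng.choice(n_sites, size=n, replace=False)
                pos = sites[picks] + rng.uniform(-jitter, jitter, size=(n, 2))
                r0, c0 = roi.bbox[0], roi.bbox[1]
                gid = roi.index.global_id(layout)
                for i in range(int(nt)):
                    dead0 = rng.random() < config.initial_dead_fraction
                    rows.append(
                        dict(
                            cell_id=cell_id,
                            well_id=gid,
                            subunit_row=sr,
                            subunit_col=sc,
                            well_row=roi.index.well_row,
                            well_col=roi.index.well_col,
                            cell_class="target",
                            y_px=r0 + pos[i, 0],
                            x_px=c0 + pos[i, 1],
                            radius_px=float(
                                np.clip(
                                    rng.normal(
                                        optics.target_radius_um / px,
                                        optics.target_radius_sd_um / px,
                                    ),
                                    4.2,
                                    7.5,
                                )
                            ),
                            nk_dy1=0.0,
                            nk_dx1=0.0,
                            nk_dy2=0.0,
                            nk_dx2=0.0,
                            level_scale=float(rng.lognormal(0.0, optics.level_jitter_sd)),
                            death_time_min=-np.inf if dead0 else np.inf,
                            killer_id=-1,
                            kill_count=0,
                        )
                    )
                    cell_id += 1
                for i in range(int(nt), n):
                    ang = rng.uniform(0, 2 * np.pi, size=2)
                    off = optics.nk_radius_um / px * 0.8
                    rows.append(
                        dict(
                            cell_id=cell_id,
                            well_id=gid,
                            subunit_row=sr,
                            subunit_col=sc,
                            well_row=roi.index.well_row,
                            well_col=roi.index.well_col,
                            cell_class="nk",
                            y_px=r0 + pos[i, 0],
                            x_px=c0 + pos[i, 1],
                            radius_px=optics.nk_radius_um / px,
                            nk_dy1=off * np.sin(ang[0]),
                            nk_dx1=off * np.cos(ang[0]),
                            nk_dy2=off * np.sin(ang[1]),
                            nk_dx2=off * np.cos(ang[1]),
                            level_scale=float(rng.lognormal(0.0, optics.level_jitter_sd)),
                            death_time_min=np.inf,
                            killer_id=-1,
                            kill_count=0,
                        )
                    )
                    cell_id += 1
    cols = [
        "cell_id", "well_id", "subunit_row", "subunit_col", "well_row", "well_col",
        "cell_class", "y_px", "x_px", "radius_px",
        "nk_dy1", "nk_dx1", "nk_dy2", "nk_dx2", "level_scale",
        "death_time_min", "killer_id", "kill_count",
    ]
    cells = pd.DataFrame(rows, columns=cols)
    return AssayTruth(layout=layout, config=config, cells=cells)


def sample_kills(
    truth: AssayTruth,
    dist: KillDistribution,
    config: AssayConfig,
    rng: np.random.Generator,
) -> AssayTruth:
    """Draw NK kill events and spontaneous target deaths; fill viability.

    Each NK draws an intended kill count from ``dist``; realised kills are
    truncated at the live targets available in its well (shared among the
    well's NK cells).  Kill times are uniform between NK seeding (which
    precedes ``T_0h`` by ``pre_t0_kill_window_min``) and the last screen.
    Targets never NK-killed die spontaneously, independently per interval,
    at a hazard matching ``spontaneous_death_per_interval`` per 6 h.
    """
    cells = truth.cells.copy()
    times = np.asarray(config.times_min, dtype=float)
    t_end = times[-1]
    t_kill_start = -config.pre_t0_kill_window_min

    targets = cells["cell_class"] == "target"
    killable = targets & np.isposinf(cells["death_time_min"])

    nk_df = cells[cells["cell_class"] == "nk"]
    intended = dist.sample(rng, len(nk_df))
    kill_counts = np.zeros(len(nk_df), dtype=int)

    # per-well victim assignment
    avail: dict[int, list[int]] = {}
    for wid, grp in cells[killable].groupby("well_id"):
        ids = list(grp.index)
        rng.shuffle(ids)
        avail[wid] = ids
    killed_rows: list[int] = []
    killer_ids: list[int] = []
    for j, (row_idx, nk) in enumerate(nk_df.iterrows()):
        pool = avail.get(nk["well_id"], [])
        k = min(int(intended[j]), len(pool))
        kill_counts[j] = k
        for _ in range(k):
            victim = pool.pop()
            killed_rows.append(victim)
            killer_ids.append(int(nk["cell_id"]))
    if killed_rows:
        kt = rng.uniform(t_kill_start, t_end, size=len(killed_rows))
        # ensure kill strictly after seeding start and not exactly at a screen
        cells.loc[killed_rows, "death_time_min"] = np.nextafter(kt, -np.inf)
        cells.loc[killed_rows, "killer_id"] = killer_ids
    cells.loc[nk_df.index, "kill_count"] = kill_counts
    cells.loc[nk_df.index, "intended_kills"] = intended

    # spontaneous death of never-killed live targets, interval by interval
    surv = killable.copy()
    surv.loc[killed_rows] = False
    surv_idx = cells.index[surv]
    if len(surv_idx) and config.spontaneous_death_per_interval > 0 and len(times) > 1:
        alive = np.ones(len(surv_idx), dtype=bool)
        death_t = np.full(len(surv_idx), np.inf)
        for t0, t1 in zip(times[:-1], times[1:]):
            p = 1.0 - (1.0 - config.spontaneous_death_per_interval) ** ((t1 - t0) / 360.0)
            u = rng.random(len(surv_idx))
            die = alive & (u < p)
            death_t[die] = rng.uniform(t0, t1, size=int(die.sum()))
            alive &= ~die
        cells.loc[surv_idx, "death_time_min"] = np.nextafter(death_t, -np.inf)
    return replace(truth, cells=cells)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _add_disk(img: np.ndarray, y: float, x: float, r: float, level: float) -> None:
    """Add an anti-aliased disk of peak ``level`` (max-composited)."""
    h, w = img.shape
    s = int(np.ceil(r)) + 2
    iy, ix = int(round(y)), int(round(x))
    y0, y1 = max(0, iy - s), min(h, iy + s + 1)
    x0, x1 = max(0, ix - s), min(w, ix + s + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - y, xx - x)
    prof = np.clip(r + 0.5 - d, 0.0, 1.0) * level
    np.maximum(img[y0:y1, x0:x1], prof, out=img[y0:y1, x0:x1])


def render_screen(
    layout: ChipLayout,
    truth: AssayTruth,
    optics: OpticsModel,
    timepoint: str,
    field: tuple[int, int] = (0, 0),
    rng: np.random.Generator | None = None,
    screen_index: int = 0,
    offset: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Render one field at one screen as a (4, H, W) float32 stack
    (channel order: trans, orange, green, ddao).

    Fluorophore levels decay as ``bleach_factor_per_screen ** screen_index``
    with extra decay on the NK channel; screens after the first also gain
    small bright non-circular debris from dying targets.
    """
    rng = rng or np.random.default_rng(0)
    h, w = tile_shape(layout)
    t = timepoint_minutes(timepoint)
    dy, dx = offset
    b = optics.bleach_factor_per_screen ** screen_index
    b_nk = b * optics.nk_extra_bleach ** screen_index

    trans = np.full((h, w), optics.trans_wall_level, dtype=np.float32)
    orange = np.zeros((h, w), dtype=np.float32)
    green = np.zeros((h, w), dtype=np.float32)
    ddao = np.zeros((h, w), dtype=np.float32)

    rois = nominal_well_rois(layout, field=field, offset=(dy, dx))
    for roi in rois:
        r0, c0, r1, c1 = roi.bbox
        trans[r0:r1, c0:c1] = optics.trans_floor_level

    sr, sc = field
    df = truth.cells
    sel = (df["subunit_row"] == sr) & (df["subunit_col"] == sc)
    prescreen = timepoint == "T_minusNK"
    for row in df[sel].itertuples(index=False):
        y, x = row.y_px + dy, row.x_px + dx
        if row.cell_class == "nk":
            if prescreen:
                continue
            lvl = optics.nk_orange_level * b_nk * row.level_scale
            _add_disk(orange, y, x, row.radius_px, lvl)
            _add_disk(orange, y + row.nk_dy1, x + row.nk_dx1, row.radius_px * 0.7, lvl)
            _add_disk(orange, y + row.nk_dy2, x + row.nk_dx2, row.radius_px * 0.7, lvl)
        else:
            dead = row.death_time_min <= t
            g = (optics.dead_green_level if dead else optics.live_green_level) * b * row.level_scale
            d = (optics.dead_ddao_level if dead else optics.live_ddao_level) * b * row.level_scale
            _add_disk(green, y, x, row.radius_px, g)
            _add_disk(ddao, y, x, row.radius_px, d)

    if screen_index > 0 and optics.debris_rate_late > 0:
        side = layout.well_side_px
        for roi in rois:
            n_debris = rng.poisson(optics.debris_rate_late)
            for _ in range(n_debris):
                yy = roi.bbox[0] + rng.uniform(3, side - 3)
                xx = roi.bbox[1] + rng.uniform(3, side - 3)
                a = rng.uniform(0, 2 * np.pi)
                for ch in (green, ddao):
                    _add_disk(ch, yy, xx, 1.4, optics.live_green_level * b)
                    _add_disk(
                        ch, yy + 2.2 * np.sin(a), xx + 2.2 * np.cos(a), 1.2,
                        optics.live_green_level * b,
                    )

    stack = np.stack([trans, orange, green, ddao])
    stack += optics.background
    if optics.noise_sd > 0:
        stack += rng.normal(0.0, optics.noise_sd, size=stack.shape).astype(np.float32)
    np.clip(stack, 0.0, None, out=stack)
    return stack.astype(np.float32)


@dataclass
class SimulatedScreen:
    """A full simulated screening run: tiles indexed by (field, timepoint)."""

    layout: ChipLayout
    config: AssayConfig
    optics: OpticsModel
    truth: AssayTruth
    tiles: dict[tuple[tuple[int, int], str], np.ndarray]

    def tile(self, field: tuple[int, int], timepoint: str) -> np.ndarray:
        return self.tiles[(field, timepoint)]


def simulate_assay(
    layout: ChipLayout,
    config: AssayConfig,
    dist: KillDistribution | None = None,
    optics: OpticsModel | None = None,
    rng: np.random.Generator | None = None,
    max_field_offset: int = 3,
) -> SimulatedScreen:
    """Simulate occupancy, kills and rendered tiles for every field and screen.

    Each field gets a small random integer stage offset (shared across its
    screens, as the stage revisits the same positions) that the grid-fitting
    stage must recover.  Deterministic given the generator state.
    """
    dist = dist or _PRESET_DISTS.get(config.scenario, RESTING_KILL_DIST)
    optics = optics or OpticsModel()
    rng = rng or np.random.default_rng(config.rng_seed)

    truth = sample_occupancy(layout, config, rng, optics)
    truth = sample_kills(truth, dist, config, rng)
    offsets = {
        (sr, sc): (
            int(rng.integers(-max_field_offset, max_field_offset + 1)),
            int(rng.integers(-max_field_offset, max_field_offset + 1)),
        )
        for sr in range(layout.subunit_rows)
        for sc in range(layout.subunit_cols)
    }
    truth.field_offsets = offsets

    tiles: dict[tuple[tuple[int, int], str], np.ndarray] = {}
    for fld, off in offsets.items():
        for si, label in enumerate(config.timepoints):
            tiles[(fld, label)] = render_screen(
                layout, truth, optics, label,
                field=fld, rng=rng, screen_index=si, offset=off,
            )
    return SimulatedScreen(layout=layout, config=config, optics=optics, truth=truth, tiles=tiles)
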