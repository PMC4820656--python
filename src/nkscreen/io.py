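"""File formats: multipage TIFF tiles, sidecar metadata, CSV tables, configs.

A simulation run directory contains::

    config.json                      layout/assay/optics/seed + channel order
    tile_r{R}_c{C}_{label}.tif       one page per channel (trans, orange,
                                     green, ddao)
    truth_cells.csv / truth_kills.csv  generator ground truth

CSV files are UTF-8, comma-separated, '.' decimal, with ``#``-prefixed
header comments recording the seed and config hash; all coordinates are
0-based pixels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect import DetectionParams
from .layout import ChipLayout
from .synthetic import CHANNELS, AssayConfig, OpticsModel, SimulatedScreen

__all__ = [
    "write_run",
    "load_run",
    "read_tile",
    "write_csv",
    "read_csv",
    "load_run_config",
    "config_hash",
]


def _asdict(obj) -> dict:
    return dataclasses.asdict(obj)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def tile_name(field: tuple[int, int], label: str) -> str:
    return f"tile_r{field[0]:02d}_c{field[1]:02d}_{label}.tif"


def write_csv(df: pd.DataFrame, path: Path, meta: dict | None = None, index: bool = True) -> None:
    """CSV with ``# key=value`` header comments (seed, config hash, ...)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=index)


def read_csv(path: Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    try:
        return pd.read_csv(path, comment="#", **kwargs)
    except Exception as exc:  # pragma: no cover - pandas reports line numbers
        raise ValueError(f"malformed CSV {path}: {exc}") from exc


def write_run(
    sim: SimulatedScreen,
    outdir: Path,
    seed: int | None = None,
    detection: DetectionParams | None = None,
) -> Path:
    """Write a simulated screen to disk: config, TIFF tiles, truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = {
        "layout": _asdict(sim.layout),
        "assay": _asdict(sim.config),
        "optics": _asdict(sim.optics),
        "channels": list(CHANNELS),
        "seed": sim.config.rng_seed if seed is None else seed,
        "timepoints": list(sim.config.timepoints),
        "fields": sorted(sim.truth.field_offsets),
    }
    if detection is not None:
        cfg["detection"] = _asdict(detection)
    cfg["config_hash"] = config_hash(cfg)
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2, default=str))

    for (field, label), stack in sim.tiles.items():
        tifffile.imwrite(
            outdir / tile_name(field, label),
            stack.astype(np.float32),
            photometric="minisblack",
            metadata={"axes": "CYX", "channels": list(CHANNELS), "timepoint": label},
        )

    meta = {"seed": cfg["seed"], "config_hash": cfg["config_hash"]}
    cells = sim.truth.cells.copy()
    for label in sim.config.timepoints:
        cells[f"alive_{label}"] = sim.truth.alive_at(label)
        if label == "T_minusNK":
            cells.loc[cells["cell_class"] == "nk", f"alive_{label}"] = False
    write_csv(cells, outdir / "truth_cells.csv", meta, index=False)

    nk = cells[cells["cell_class"] == "nk"]
    kills = cells[cells["killer_id"] >= 0]
    kt = kills.groupby("killer_id")["death_time_min"].apply(
        lambda s: ";".join(f"{v:.1f}" for v in sorted(s))
    )
    truth_kills = pd.DataFrame(
        {
            "nk_id": nk["cell_id"].to_numpy(),
            "well_id": nk["well_id"].to_numpy(),
            "kill_count": nk["kill_count"].to_numpy(dtype=int),
            "kill_times_min": [kt.get(int(i), "") for i in nk["cell_id"]],
        }
    )
    write_csv(truth_kills, outdir / "truth_kills.csv", meta, index=False)
    return outdir


def load_run(outdir: Path) -> dict:
    """Load a run directory's configuration (raises if absent)."""
    path = Path(outdir) / "config.json"
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path} (run `simulate` first)")
    cfg = json.loads(path.read_text())
    cfg["layout_obj"] = ChipLayout(**cfg["layout"])
    cfg["assay_obj"] = AssayConfig(**{**cfg["assay"], "timepoints": tuple(cfg["assay"]["timepoints"])})
    cfg["optics_obj"] = OpticsModel(**cfg["optics"])
    cfg["detection_obj"] = DetectionParams(**cfg["detection"]) if "detection" in cfg else None
    return cfg


def read_tile(path: Path) -> np.ndarray:
    """Read a (4, H, W) tile stack; accepts page-per-channel or interleaved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[0] == len(CHANNELS):
        return np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] == len(CHANNELS):  # interleaved
        return np.moveaxis(np.asarray(arr), -1, 0)
    raise ValueError(f"{path}: expected {len(CHANNELS)}-channel stack, got shape {arr.shape}")


_BLOCKS = {
    "layout": ChipLayout,
    "assay": AssayConfig,
    "optics": OpticsModel,
    "detection": DetectionParams,
}


def load_run_config(path: Path) -> dict:
    """Parse a YAML run configuration into typed blocks.

    Recognized top-level keys: the dataclass blocks in ``_BLOCKS`` plus
    ``analysis`` (criterion, baseline, min_goodness), ``seed`` and
    ``outdir``.  Unknown keys anywhere raise, so typos cannot silently
    fall back to defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(_BLOCKS) | {"analysis", "seed", "outdir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out: dict = {}
    for name, cls in _BLOCKS.items():
        block = raw.get(name, {}) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(block) - fields
        if bad:
            raise ValueError(f"unknown keys in {name!r} block: {sorted(bad)}")
        if name == "assay" and "timepoints" in block:
            block["timepoints"] = tuple(block["timepoints"])
        out[name] = cls(**block)
    analysis = raw.get("analysis", {}) or {}
    bad = set(analysis) - {"criterion", "baseline", "min_goodness"}
    if bad:
        raise ValueError(f"unknown keys in 'analysis' block: {sorted(bad)}")
    out["analysis"] = analysis
    out["seed"] = int(raw.get("seed", 0))
    out["outdir"] = raw.get("outdir")
    return out
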