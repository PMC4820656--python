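"""Geometric model of the microwell array.

The chip is a rectangular grid of *subunits*; each subunit is a square block
of microwells and corresponds to one microscope field of view (one image
tile).  The default layout is a 20 x 20 grid of subunits, each holding
9 x 9 wells of ~50 um x 50 um, i.e. 32,400 wells imaged in 400 tiles of 81
wells each.

All pixel coordinates are 0-based, row-major; bounding boxes are half-open
``(row0, col0, row1, col1)`` rectangles.  Well depth and glass thickness are
carried as metadata only -- rendering and analysis are strictly 2D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChipLayout",
    "WellIndex",
    "WellROI",
    "build_layout",
    "count_wells",
    "count_fields",
    "tile_shape",
    "nominal_well_rois",
    "pixel_to_well",
]


class LayoutError(ValueError):
    """Invalid chip-layout parameter."""


@dataclass(frozen=True)
class ChipLayout:
    """Static geometry of the well array and its imaging tiles.

    Parameters
    ----------
    subunit_rows, subunit_cols
        Number of subunits (imaging fields) along each chip axis.
    wells_per_subunit_row, wells_per_subunit_col
        Wells along each axis of one subunit.
    well_side_um
        Side of the square well opening, in micrometres.
    well_depth_um
        Well depth; metadata only (deep wells keep cells from escaping).
    wall_um
        Silicon wall thickness between adjacent wells.
    pixel_size_um
        Image sampling, micrometres per pixel.
    tile_margin_px
        Blank border around the well grid in each rendered/imaged tile.
    """

    subunit_rows: int = 20
    subunit_cols: int = 20
    wells_per_subunit_row: int = 9
    wells_per_subunit_col: int = 9
    well_side_um: float = 50.0
    well_depth_um: float = 300.0
    glass_um: float = 175.0
    wall_um: float = 20.0
    subunit_gap_um: float | None = None
    pixel_size_um: float = 1.0
    tile_margin_px: int = 12

    def __post_init__(self) -> None:
        for name in (
            "subunit_rows",
            "subunit_cols",
            "wells_per_subunit_row",
            "wells_per_subunit_col",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise LayoutError(f"{name} must be a positive integer, got {v!r}")
        for name in ("well_side_um", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise LayoutError(f"{name} must be > 0")
        if self.wall_um < 0:
            raise LayoutError("wall_um must be >= 0")
        if self.tile_margin_px < 0:
            raise LayoutError("tile_margin_px must be >= 0")

    # -- derived pixel geometry -------------------------------------------
    @property
    def well_side_px(self) -> int:
        return int(round(self.well_side_um / self.pixel_size_um))

    @property
    def wall_px(self) -> int:
        return int(round(self.wall_um / self.pixel_size_um))

    @property
    def pitch_px(self) -> int:
        """Centre-to-centre well spacing in pixels."""
        return self.well_side_px + self.wall_px

    @property
    def n_wells(self) -> int:
        return (
            self.subunit_rows
            * self.subunit_cols
            * self.wells_per_subunit_row
            * self.wells_per_subunit_col
        )

    @property
    def n_fields(self) -> int:
        return self.subunit_rows * self.subunit_cols

    @property
    def wells_per_field(self) -> int:
        return self.wells_per_subunit_row * self.wells_per_subunit_col


@dataclass(frozen=True, order=True)
class WellIndex:
    """Four-level index of one well; bijective with a global row-major id."""

    subunit_row: int
    subunit_col: int
    well_row: int
    well_col: int

    def global_id(self, layout: ChipLayout) -> int:
        self.validate(layout)
        return (
            (
                (self.subunit_row * layout.subunit_cols + self.subunit_col)
                * layout.wells_per_subunit_row
                + self.well_row
            )
            * layout.wells_per_subunit_col
            + self.well_col
        )

    @staticmethod
    def from_global(gid: int, layout: ChipLayout) -> "WellIndex":
        if not 0 <= gid < layout.n_wells:
            raise LayoutError(f"global well id {gid} out of range")
        gid, wc = divmod(gid, layout.wells_per_subunit_col)
        gid, wr = divmod(gid, layout.wells_per_subunit_row)
        sr, sc = divmod(gid, layout.subunit_cols)
        return WellIndex(sr, sc, wr, wc)

    def validate(self, layout: ChipLayout) -> None:
        if not (
            0 <= self.subunit_row < layout.subunit_rows
            and 0 <= self.subunit_col < layout.subunit_cols
            and 0 <= self.well_row < layout.wells_per_subunit_row
            and 0 <= self.well_col < layout.wells_per_subunit_col
        ):
            raise LayoutError(f"well index {self} outside layout")


@dataclass(frozen=True)
class WellROI:
    """Pixel rectangle of one well within its tile (half-open bbox)."""

    index: WellIndex
    bbox: tuple[int, int, int, int]
    center: tuple[float, float] = field(default=(0.0, 0.0))

    def contains(self, row: float, col: float) -> bool:
        r0, c0, r1, c1 = self.bbox
        return r0 <= row < r1 and c0 <= col < c1


def build_layout(**kwargs) -> ChipLayout:
    """Validate layout parameters and return a :class:`ChipLayout`.

    Defaults reproduce the reference chip: 20 x 20 subunits of 9 x 9 wells,
    50 um wells, 300 um deep, at 1 um/pixel.
    """
    return ChipLayout(**kwargs)


def count_wells(layout: ChipLayout) -> int:
    return layout.n_wells


def count_fields(layout: ChipLayout) -> int:
    """Number of imaging fields; one field covers exactly one subunit."""
    return layout.n_fields


def tile_shape(layout: ChipLayout) -> tuple[int, int]:
    """Pixel shape of one field tile: margin + wall/well lattice + margin."""
    h = (
        2 * layout.tile_margin_px
        + layout.wells_per_subunit_row * layout.pitch_px
        + layout.wall_px
    )
    w = (
        2 * layout.tile_margin_px
        + layout.wells_per_subunit_col * layout.pitch_px
        + layout.wall_px
    )
    return h, w


def _well_origin(layout: ChipLayout, well_row: int, well_col: int) -> tuple[int, int]:
    r0 = layout.tile_margin_px + layout.wall_px + well_row * layout.pitch_px
    c0 = layout.tile_margin_px + layout.wall_px + well_col * layout.pitch_px
    return r0, c0


def nominal_well_rois(
    layout: ChipLayout,
    field: tuple[int, int] = (0, 0),
    offset: tuple[int, int] = (0, 0),
) -> list[WellROI]:
    """Regular-pitch well ROIs for one field, translated by ``offset`` pixels.

    ROIs are pairwise disjoint (walls separate them) and tagged with the full
    :class:`WellIndex` of the field's subunit.
    """
    sr, sc = field
    if not (0 <= sr < layout.subunit_rows and 0 <= sc < layout.subunit_cols):
        raise LayoutError(f"field {field} outside layout")
    dr, dc = offset
    if not (np.isfinite(dr) and np.isfinite(dc)):
        raise LayoutError("offset must be finite")
    dr, dc = int(round(dr)), int(round(dc))
    h, w = tile_shape(layout)
    side = layout.well_side_px
    rois: list[WellROI] = []
    bad: list[WellIndex] = []
    for i in range(layout.wells_per_subunit_row):
        for j in range(layout.wells_per_subunit_col):
            r0, c0 = _well_origin(layout, i, j)
            r0, c0 = r0 + dr, c0 + dc
            idx = WellIndex(sr, sc, i, j)
            if r0 < 0 or c0 < 0 or r0 + side > h or c0 + side > w:
                bad.append(idx)
                continue
            rois.append(
                WellROI(
                    index=idx,
                    bbox=(r0, c0, r0 + side, c0 + side),
                    center=(r0 + (side - 1) / 2.0, c0 + (side - 1) / 2.0),
                )
            )
    if bad:
        raise LayoutError(f"ROIs exceed tile bounds for well indices: {bad}")
    return rois


def pixel_to_well(
    layout: ChipLayout,
    row: float,
    col: float,
    field: tuple[int, int] = (0, 0),
    offset: tuple[int, int] = (0, 0),
) -> WellIndex | None:
    """Map a tile pixel to the well whose ROI contains it, or None (wall/margin)."""
    dr, dc = int(round(offset[0])), int(round(offset[1]))
    r = row - dr - layout.tile_margin_px - layout.wall_px
    c = col - dc - layout.tile_margin_px - layout.wall_px
    if r < 0 or c < 0:
        return None
    i, ri = divmod(r, layout.pitch_px)
    j, ci = divmod(c, layout.pitch_px)
    if ri >= layout.well_side_px or ci >= layout.well_side_px:
        return None
    i, j = int(i), int(j)
    if i >= layout.wells_per_subunit_row or j >= layout.wells_per_subunit_col:
        return None
    return WellIndex(field[0], field[1], i, j)
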