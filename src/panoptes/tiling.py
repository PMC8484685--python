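"""Matched-resolution tile-set extraction from a slide.

The slide is partitioned into a non-overlapping grid of 299x299 cells at
2.5x equivalent magnification.  Each cell ideally yields 16 tile sets: the
4x4 lattice of 10x tiles inside it, each paired with its enclosing 5x tile
(one of the cell's 2x2) and the cell's own 2.5x tile, so that each
higher-resolution tile covers exactly one fourth of the area of the next
lower-resolution tile.  Tiles dominated by white background or dark
contaminants are discarded; a tile set is kept only when all three members
pass.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import stain as stain_mod
from .errors import UnstainableTileError
from .slide_io import RegionRequest, SlidePyramid, footprint_side, read_region

MAGNIFICATIONS = (10.0, 5.0, 2.5)


@dataclass(frozen=True)
class TileFilterConfig:
    """Tile geometry and the background/contaminant exclusion rule.

    A pixel counts as background or contaminant when all three RGB channels
    fall below ``low_rgb_bound`` (dark debris) or all three exceed
    ``high_rgb_bound`` (white background).  A tile is discarded when *more
    than* ``max_background_fraction`` of its pixels are such.
    """

    tile_px: int = 299
    max_background_fraction: float = 0.40
    low_rgb_bound: int = 50
    high_rgb_bound: int = 200

    def __post_init__(self):
        if not (0 < self.max_background_fraction < 1):
            raise ValueError("max_background_fraction must be in (0, 1)")
        if not (0 <= self.low_rgb_bound < self.high_rgb_bound <= 255):
            raise ValueError("need 0 <= low_rgb_bound < high_rgb_bound <= 255")
        if self.tile_px <= 0:
            raise ValueError("tile_px must be positive")


@dataclass
class TileSet:
    """Three co-registered tiles of one region at 10x / 5x / 2.5x."""

    slide_id: str
    patient_id: str
    anchor_xy_level0: tuple[int, int]       # level-0 origin of the 10x tile
    images: dict[float, np.ndarray]         # magnification -> (t, t, 3) uint8
    parent_cell_index: tuple[int, int]      # (row, col) of the 2.5x grid cell
    normalized: bool = False

    @property
    def tile_set_id(self) -> str:
        x, y = self.anchor_xy_level0
        return f"{self.slide_id}:{x}:{y}"

    def footprints_level0(self, slide: SlidePyramid, tile_px: int) -> dict[float, tuple[int, int, int]]:
        """(x, y, side) level-0 footprint per magnification, for geometry checks."""
        out = {}
        side10 = footprint_side(tile_px, slide.base_magnification, 10.0)
        ax, ay = self.anchor_xy_level0
        for mag in MAGNIFICATIONS:
            side = footprint_side(tile_px, slide.base_magnification, mag)
            # each coarser tile is anchored on its own lattice containing the anchor
            out[mag] = ((ax // side) * side, (ay // side) * side, side)
        return out


@dataclass(frozen=True)
class GridCell:
    row: int
    col: int
    origin_xy_level0: tuple[int, int]
    side_level0: int


@dataclass
class TilingSummary:
    slide_id: str
    n_cells: int = 0
    n_candidates: int = 0
    n_kept: int = 0
    n_discarded: int = 0
    n_unstainable: int = 0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def passes_filter(tile: np.ndarray, cfg: TileFilterConfig) -> tuple[bool, float]:
    """Apply the background/contaminant rule to one tile.

    Returns ``(passes, background_fraction)``; the tile is discarded iff the
    fraction strictly exceeds the threshold.
    """
    dark = np.all(tile < cfg.low_rgb_bound, axis=-1)
    white = np.all(tile > cfg.high_rgb_bound, axis=-1)
    frac = float(np.mean(dark | white))
    return frac <= cfg.max_background_fraction, frac


def plan_grid(slide: SlidePyramid, cfg: TileFilterConfig) -> list[GridCell]:
    """Non-overlapping 2.5x grid cells, row-major; partial edge cells dropped."""
    side0 = footprint_side(cfg.tile_px, slide.base_magnification, 2.5)
    w0, h0 = slide.dimensions
    n_cols = w0 // side0
    n_rows = h0 // side0
    return [
        GridCell(r, c, (c * side0, r * side0), side0)
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def enumerate_tile_sets(
    slide: SlidePyramid,
    cell: GridCell,
    cfg: TileFilterConfig,
    patient_id: str = "",
) -> list[TileSet]:
    """All tile sets of one cell whose three member tiles pass the filter.

    Candidate anchors are the 4x4 lattice of 10x tiles inside the cell; each
    pairs with its enclosing 5x tile (2x2 within the cell) and the cell's
    2.5x tile.  Filter decisions are made per member tile on raw (pre-
    normalization) pixels.
    """
    side10 = footprint_side(cfg.tile_px, slide.base_magnification, 10.0)
    side5 = footprint_side(cfg.tile_px, slide.base_magnification, 5.0)
    cx, cy = cell.origin_xy_level0

    tile25 = read_region(slide, RegionRequest((cx, cy), cfg.tile_px, 2.5))
    ok25, _ = passes_filter(tile25, cfg)
    if not ok25:
        return []

    tiles5: dict[tuple[int, int], Optional[np.ndarray]] = {}
    for qr in range(2):
        for qc in range(2):
            t5 = read_region(
                slide, RegionRequest((cx + qc * side5, cy + qr * side5), cfg.tile_px, 5.0)
            )
            ok5, _ = passes_filter(t5, cfg)
            tiles5[(qr, qc)] = t5 if ok5 else None

    out: list[TileSet] = []
    for ir in range(4):
        for ic in range(4):
            t5 = tiles5[(ir // 2, ic // 2)]
            if t5 is None:
                continue
            ax, ay = cx + ic * side10, cy + ir * side10
            t10 = read_region(slide, RegionRequest((ax, ay), cfg.tile_px, 10.0))
            ok10, _ = passes_filter(t10, cfg)
            if not ok10:
                continue
            out.append(
                TileSet(
                    slide_id=slide.slide_id,
                    patient_id=patient_id,
                    anchor_xy_level0=(ax, ay),
                    images={10.0: t10, 5.0: t5, 2.5: tile25},
                    parent_cell_index=(cell.row, cell.col),
                )
            )
    return out


def _normalize_set(
    ts: TileSet, profile: stain_mod.StainProfile, context=None
) -> TileSet:
    imgs = {}
    try:
        for mag, img in ts.images.items():
            imgs[mag] = stain_mod.normalize_tile(img, profile, source_basis=context)
        ts.images = imgs
        ts.normalized = True
    except UnstainableTileError:
        ts.normalized = False  # kept, but flagged un-normalized
    return ts


def tile_slide(
    slide: SlidePyramid,
    cfg: TileFilterConfig,
    stain_profile: Optional[stain_mod.StainProfile] = None,
    sink=None,
    patient_id: str = "",
    workers: int = 1,
    stain_mode: str = "tile",
) -> TilingSummary:
    """Tile a whole slide: grid -> tile sets -> stain-normalize -> sink.

    ``sink`` is any callable accepting a TileSet (e.g. a record writer).
    ``stain_mode`` selects per-tile basis estimation ("tile", the default),
    a single per-slide basis and scaling estimated from the coarsest pyramid
    level ("slide", much faster and color-consistent within a slide), or no
    normalization ("none").  Worker threads only parallelize per-cell
    extraction; results are emitted in cell order so the output is
    independent of the thread schedule.
    """
    if stain_mode not in ("tile", "slide", "none"):
        raise ValueError(f"unknown stain_mode {stain_mode!r}")
    profile = stain_profile or stain_mod.StainProfile()
    cells = plan_grid(slide, cfg)
    summary = TilingSummary(slide_id=slide.slide_id, n_cells=len(cells))
    context = None
    if stain_mode == "slide":
        try:
            context = stain_mod.slide_stain_context(
                slide.level_array(len(slide.levels) - 1), profile
            )
        except UnstainableTileError:
            stain_mode = "none"  # empty slide; nothing will pass the filter anyway

    def _process(cell: GridCell) -> list[TileSet]:
        kept = enumerate_tile_sets(slide, cell, cfg, patient_id)
        if stain_mode != "none":
            kept = [_normalize_set(ts, profile, context) for ts in kept]
        return kept

    if workers <= 1:
        per_cell = [_process(c) for c in cells]
    else:
        # slide.level_array is populated up-front so threads share read-only data
        for i in range(len(slide.levels)):
            slide.level_array(i)
        with ThreadPoolExecutor(max_workers=workers) as pool:
            per_cell = list(pool.map(_process, cells))

    for kept in per_cell:
        summary.n_candidates += 16
        summary.n_kept += len(kept)
        for ts in kept:
            if not ts.normalized and stain_mode != "none":
                summary.n_unstainable += 1
            if sink is not None:
                sink(ts)
    summary.n_discarded = summary.n_candidates - summary.n_kept
    return summary
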