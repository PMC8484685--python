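"""Feature-space embeddings and whole-slide prediction heatmaps.

Two views of what a trained model learned: a tSNE embedding of the
penultimate feature vectors of a random tile sample, colored by prediction
score; and the per-tile prediction scores reassembled onto the slide's 10x
grid and blended over a slide thumbnail.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import PanoptesError
from .slide_io import SlidePyramid, footprint_side


@dataclass
class EmbeddingResult:
    tile_ids: np.ndarray
    coords: np.ndarray          # (n, 2)
    scores: np.ndarray          # positive prediction score per sampled tile
    seed: int
    params: dict = field(default_factory=dict)


def embed_features(
    features: np.ndarray,
    scores: np.ndarray,
    tile_ids: Optional[np.ndarray] = None,
    sample_n: int = 20000,
    init_dims: int = 100,
    seed: int = 0,
    perplexity: float = 30.0,
    n_iter: int = 1000,
) -> EmbeddingResult:
    """tSNE of penultimate features for a random subsample of tiles.

    Features are first reduced to at most ``init_dims`` principal components,
    then embedded to 2-D; the whole procedure is deterministic per seed.
    Requesting more tiles than available clamps with a warning.
    """
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    features = np.asarray(features, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if features.shape[0] != scores.shape[0]:
        raise ValueError("features and scores are not row-aligned")
    n = features.shape[0]
    if n < 10:
        raise PanoptesError(f"embedding needs >= 10 tiles, got {n}")
    if tile_ids is None:
        tile_ids = np.arange(n)
    rng = np.random.default_rng(seed)
    if sample_n < n:
        pick = np.sort(rng.choice(n, sample_n, replace=False))
    else:
        if sample_n > n:
            warnings.warn(f"requested {sample_n} tiles, only {n} available")
        pick = np.arange(n)
    X = features[pick]
    k = min(init_dims, X.shape[1], len(pick) - 1)
    if X.shape[1] > k:
        X = PCA(n_components=k, random_state=seed).fit_transform(X)
    perp = min(perplexity, max((len(pick) - 1) / 3.0, 2.0))
    ts = TSNE(
        n_components=2,
        perplexity=perp,
        max_iter=n_iter,
        random_state=seed,
        init="pca",
    )
    coords = ts.fit_transform(X)
    return EmbeddingResult(
        tile_ids=np.asarray(tile_ids)[pick],
        coords=coords,
        scores=scores[pick],
        seed=seed,
        params={"init_dims": k, "perplexity": perp, "n_iter": n_iter},
    )


def render_embedding(
    result: EmbeddingResult,
    out_path: str,
    tiles: Optional[np.ndarray] = None,
    thumb_grid: int = 40,
    cmap: str = "coolwarm",
) -> dict:
    """Scatter (or tile-thumbnail mosaic) of the embedding, scores on 0-1.

    In thumbnail mode at most one tile image is placed per cell of a
    ``thumb_grid`` x ``thumb_grid`` collision grid.  Returns metadata about
    what was drawn (point count, mode).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    meta = {"n_points": int(len(result.coords)), "mode": "points"}
    if tiles is None:
        sc = ax.scatter(
            result.coords[:, 0],
            result.coords[:, 1],
            c=result.scores,
            cmap=cmap,
            vmin=0.0,
            vmax=1.0,
            s=8,
        )
        fig.colorbar(sc, ax=ax, label="positive prediction score")
    else:
        from matplotlib.offsetbox import AnnotationBbox, OffsetImage

        meta["mode"] = "thumbnails"
        xy = result.coords
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        span = np.where(hi - lo <= 0, 1.0, hi - lo)
        cells = set()
        placed = 0
        for i in range(len(xy)):
            cell = tuple(((xy[i] - lo) / span * (thumb_grid - 1)).astype(int))
            if cell in cells:
                continue
            cells.add(cell)
            ab = AnnotationBbox(OffsetImage(tiles[i], zoom=0.12), xy[i], frameon=False)
            ax.add_artist(ab)
            placed += 1
        ax.set_xlim(lo[0] - 0.05 * span[0], hi[0] + 0.05 * span[0])
        ax.set_ylim(lo[1] - 0.05 * span[1], hi[1] + 0.05 * span[1])
        meta["n_thumbnails"] = placed
    ax.set_xlabel("tSNE 1")
    ax.set_ylabel("tSNE 2")
    fig.savefig(out_path, dpi=120, metadata={"Description": json.dumps(meta)})
    plt.close(fig)
    return meta


# -- heatmaps ---------------------------------------------------------------


@dataclass
class Heatmap:
    """Prediction scores on the slide's 10x tile grid; NaN = filtered cell."""

    grid: np.ndarray                    # (rows, cols) float with NaN holes
    cell_px_level0: int                 # level-0 footprint side of one cell
    slide_id: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def cells(self) -> list[tuple[int, int, float]]:
        out = []
        rows, cols = self.grid.shape
        for r in range(rows):
            for c in range(cols):
                v = self.grid[r, c]
                if not np.isnan(v):
                    out.append((r, c, float(v)))
        return out

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.grid).to_csv(path, index=False, header=False)

    def geometry_json(self) -> str:
        return json.dumps(
            {
                "slide_id": self.slide_id,
                "rows": int(self.grid.shape[0]),
                "cols": int(self.grid.shape[1]),
                "cell_px_level0": int(self.cell_px_level0),
            }
        )


def assemble_heatmap(
    preds: pd.DataFrame,
    slide: SlidePyramid,
    anchors: Optional[dict[str, tuple[int, int]]] = None,
    tile_px: int = 299,
) -> Heatmap:
    """Write each tile set's score into the 10x grid cell of its anchor.

    The grid has ``floor(10x-extent / 299)`` cells per axis; cells with no
    surviving tile set stay missing.  ``anchors`` maps tile_set_id to its
    level-0 anchor; by default anchors are parsed from this package's
    ``slide:x:y`` tile-set ids.
    """
    side = footprint_side(tile_px, slide.base_magnification, 10.0)
    w0, h0 = slide.dimensions
    cols, rows = w0 // side, h0 // side
    grid = np.full((rows, cols), np.nan)
    sub = preds[preds["slide_id"] == slide.slide_id]
    for _, row in sub.iterrows():
        if anchors is not None:
            ax, ay = anchors[row["tile_set_id"]]
        else:
            parts = str(row["tile_set_id"]).rsplit(":", 2)
            ax, ay = int(parts[-2]), int(parts[-1])
        if not (0 <= ax < w0 and 0 <= ay < h0):
            raise PanoptesError(
                f"anchor ({ax}, {ay}) outside slide {slide.slide_id!r} bounds"
            )
        r, c = ay // side, ax // side
        if r < rows and c < cols:
            grid[r, c] = row["score"]
    return Heatmap(grid=grid, cell_px_level0=side, slide_id=slide.slide_id)


def disassemble_heatmap(hm: Heatmap) -> list[tuple[int, int, float]]:
    """Inverse of assembly: every (row, col, score) cell present."""
    return hm.cells()


def render_overlay(
    hm: Heatmap,
    slide: SlidePyramid,
    out_path: str,
    alpha: float = 0.45,
    cmap: str = "coolwarm",
    max_px: int = 1024,
) -> None:
    """Blend the colormapped score grid over a slide thumbnail.

    Missing cells stay fully transparent; the colormap is diverging with its
    midpoint at score 0.5.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    thumb = slide.thumbnail(max_px)
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(thumb, extent=(0, slide.dimensions[0], slide.dimensions[1], 0))
    rows, cols = hm.grid.shape
    side = hm.cell_px_level0
    masked = np.ma.masked_invalid(hm.grid)
    ax.imshow(
        masked,
        cmap=cmap,
        vmin=0.0,
        vmax=1.0,
        alpha=alpha,
        extent=(0, cols * side, rows * side, 0),
        interpolation="nearest",
    )
    ax.set_xlim(0, slide.dimensions[0])
    ax.set_ylim(slide.dimensions[1], 0)
    ax.set_title(f"{hm.slide_id}: prediction heatmap")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
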