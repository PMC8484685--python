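"""Uniform reader over pyramidal slides.

A whole-slide image is stored as a multi-resolution pyramid: level 0 holds the
full scan and deeper levels hold progressively downsampled copies.  All
coordinates in this package are 0-based pixel coordinates **at level 0**, with
half-open rectangles; requests name a target *magnification equivalent*
(2.5x / 5x / 10x) and the reader maps it onto the nearest finer pyramid level
and resamples the remainder.

Two backings are supported: pyramidal TIFF files (each page one level, level-0
page carrying a JSON ``ImageDescription`` with physical metadata) and
in-memory pyramids built directly from arrays, which is how the synthetic
generator hands slides to the tiler without touching disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import RegionBoundsError, SlideFormatError

#: mpp values conventionally equated with nominal objective powers.
MPP_40X = 0.25
MPP_20X = 0.50


@dataclass(frozen=True)
class PyramidLevel:
    width: int
    height: int
    downsample: float


@dataclass(frozen=True)
class RegionRequest:
    """A square region read: level-0 origin, output side, target power."""

    origin_xy: tuple[int, int]
    size_px: int
    target_magnification: float


class SlidePyramid:
    """Metadata plus lazily-loaded pixel levels of one pyramidal slide.

    Parameters
    ----------
    slide_id : str
        Identifier propagated into tiles and prediction tables.
    levels : sequence of PyramidLevel
        Ordered finest-to-coarsest; downsamples strictly increasing from 1.
    base_magnification : float
        Nominal objective power of level 0 (e.g. 40, 20, or 10 for the
        synthetic slides rendered directly at 10x equivalent).
    mpp_level0 : float, optional
        Microns per pixel at level 0.
    """

    def __init__(
        self,
        slide_id: str,
        levels: Sequence[PyramidLevel],
        base_magnification: float,
        mpp_level0: Optional[float] = None,
        *,
        arrays: Optional[Sequence[np.ndarray]] = None,
        path: Optional[str] = None,
    ):
        if base_magnification <= 0:
            raise SlideFormatError("base_magnification must be positive")
        levels = list(levels)
        if not levels:
            raise SlideFormatError("pyramid has no levels")
        if abs(levels[0].downsample - 1.0) > 1e-9:
            raise SlideFormatError("level 0 downsample must be 1.0")
        for prev, cur in zip(levels, levels[1:]):
            if cur.downsample <= prev.downsample:
                raise SlideFormatError("downsample factors must strictly increase")
        w0, h0 = levels[0].width, levels[0].height
        for lv in levels[1:]:
            if abs(lv.width - w0 / lv.downsample) > 1.0 or abs(lv.height - h0 / lv.downsample) > 1.0:
                raise SlideFormatError(
                    f"level dimensions {lv.width}x{lv.height} inconsistent with "
                    f"downsample {lv.downsample} of {w0}x{h0}"
                )
        self.slide_id = slide_id
        self.levels = levels
        self.base_magnification = float(base_magnification)
        self.mpp_level0 = mpp_level0
        self._path = path
        self._arrays: dict[int, np.ndarray] = {}
        if arrays is not None:
            for i, a in enumerate(arrays):
                self._arrays[i] = np.ascontiguousarray(a)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        slide_id: str,
        arrays: Sequence[np.ndarray],
        base_magnification: float,
        mpp_level0: Optional[float] = None,
    ) -> "SlidePyramid":
        levels = []
        w0, h0 = arrays[0].shape[1], arrays[0].shape[0]
        for a in arrays:
            h, w = a.shape[:2]
            levels.append(PyramidLevel(w, h, w0 / w))
        return cls(slide_id, levels, base_magnification, mpp_level0, arrays=arrays)

    # -- level access -------------------------------------------------------

    @property
    def dimensions(self) -> tuple[int, int]:
        """(width, height) at level 0."""
        return self.levels[0].width, self.levels[0].height

    def level_array(self, index: int) -> np.ndarray:
        """Pixel data of one pyramid level (H, W, 3) uint8, cached."""
        if index not in self._arrays:
            import tifffile

            with tifffile.TiffFile(self._path) as tf:
                self._arrays[index] = np.ascontiguousarray(tf.pages[index].asarray())
        return self._arrays[index]

    def thumbnail(self, max_px: int = 1024) -> np.ndarray:
        """Coarsest level, shrunk so its longer side is <= max_px."""
        arr = self.level_array(len(self.levels) - 1)
        h, w = arr.shape[:2]
        scale = max(h, w) / max_px
        if scale <= 1:
            return arr.copy()
        out = _sk_resize(arr, (int(round(h / scale)), int(round(w / scale))), order=1,
                         preserve_range=True, anti_aliasing=True)
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def write_pyramidal_tiff(
    path: str,
    arrays: Sequence[np.ndarray],
    slide_id: str,
    base_magnification: float,
    mpp_level0: Optional[float] = None,
) -> None:
    """Write a multi-page TIFF, one page per level, metadata in page 0."""
    import tifffile

    desc = json.dumps(
        {
            "slide_id": slide_id,
            "base_magnification": base_magnification,
            "mpp_level0": mpp_level0,
        },
        sort_keys=True,
    )
    with tifffile.TiffWriter(path) as tw:
        for i, arr in enumerate(arrays):
            tw.write(
                arr,
                description=desc if i == 0 else None,
                photometric="rgb",
                software=None,
                datetime=False,
            )


def open_slide(path: str, base_magnification: Optional[float] = None) -> SlidePyramid:
    """Open a pyramidal TIFF and return its metadata without pixel data.

    The nominal power of level 0 is resolved in order of preference from the
    JSON description written by this package, then from mpp metadata
    (0.25 um/px -> 40x, 0.5 -> 20x, nearest of the two), then from the
    ``base_magnification`` argument.  A file that states none of these is
    rejected: magnification-equivalent reads would be meaningless.
    """
    import tifffile

    try:
        tf = tifffile.TiffFile(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise SlideFormatError(f"cannot read slide file {path!r}: {exc}") from exc
    with tf:
        pages = list(tf.pages)
        if not pages:
            raise SlideFormatError(f"{path!r}: no image pages")
        meta: dict = {}
        desc = pages[0].description
        if desc:
            try:
                parsed = json.loads(desc)
                if isinstance(parsed, dict):
                    meta = parsed
            except (json.JSONDecodeError, TypeError):
                pass
        import os

        file_size = os.path.getsize(path)
        shapes = []
        for p in pages:
            shp = p.shape
            if len(shp) < 2:
                raise SlideFormatError(f"{path!r}: page with shape {shp} is not an image")
            # cheap truncation check: pixel data must lie within the file
            offsets = getattr(p, "dataoffsets", ()) or ()
            counts = getattr(p, "databytecounts", ()) or ()
            for off, cnt in zip(offsets, counts):
                if off + cnt > file_size:
                    raise SlideFormatError(
                        f"{path!r}: truncated file (page data extends past EOF)"
                    )
            shapes.append((shp[1], shp[0]))  # (width, height)

    mpp = meta.get("mpp_level0")
    base = meta.get("base_magnification")
    if base is None:
        if mpp is not None:
            base = 40.0 if abs(mpp - MPP_40X) <= abs(mpp - MPP_20X) else 20.0
        elif base_magnification is not None:
            base = base_magnification
        else:
            raise SlideFormatError(
                f"{path!r}: no magnification metadata; pass base_magnification explicitly"
            )

    w0, h0 = shapes[0]
    # pages must shrink; tolerate any strictly-decreasing pyramid
    levels = [PyramidLevel(w, h, w0 / w) for (w, h) in shapes]
    slide_id = meta.get("slide_id") or path
    return SlidePyramid(slide_id, levels, base, mpp, path=path)


# -- region reading ---------------------------------------------------------


def footprint_side(size_px: int, base_magnification: float, target_magnification: float) -> int:
    """Level-0 side length of a size_px read at target magnification."""
    return int(round(size_px * base_magnification / target_magnification))


def _box_downsample(arr: np.ndarray, k: int) -> np.ndarray:
    """Area-average an (H, W, C) array by an integer factor k."""
    h, w = arr.shape[:2]
    a = arr[: (h // k) * k, : (w // k) * k].astype(np.float64)
    a = a.reshape(h // k, k, w // k, k, -1).mean(axis=(1, 3))
    return a


def read_region(slide: SlidePyramid, req: RegionRequest) -> np.ndarray:
    """Read a square region at a magnification equivalent.

    The level-0 footprint is ``size_px * base/target`` on a side.  The nearest
    pyramid level at least as fine as the requested scale is cropped, then
    area-averaged down when the residual factor is an integer and linearly
    interpolated otherwise.  Returns (size_px, size_px, 3) uint8.
    """
    if req.target_magnification > slide.base_magnification + 1e-9:
        raise RegionBoundsError(
            f"target magnification {req.target_magnification} exceeds base "
            f"{slide.base_magnification}"
        )
    factor = slide.base_magnification / req.target_magnification
    side = footprint_side(req.size_px, slide.base_magnification, req.target_magnification)
    x0, y0 = req.origin_xy
    w0, h0 = slide.dimensions
    if x0 < 0 or y0 < 0 or x0 + side > w0 or y0 + side > h0:
        raise RegionBoundsError(
            f"footprint [{x0}:{x0 + side}, {y0}:{y0 + side}) outside level-0 "
            f"bounds {w0}x{h0} of slide {slide.slide_id!r}"
        )

    # nearest finer (or exact) level
    lev = 0
    for i, lv in enumerate(slide.levels):
        if lv.downsample <= factor + 1e-9:
            lev = i
    d = slide.levels[lev].downsample
    arr = slide.level_array(lev)
    xl0 = int(round(x0 / d))
    yl0 = int(round(y0 / d))
    side_l = int(round(side / d))
    crop = arr[yl0 : yl0 + side_l, xl0 : xl0 + side_l]
    if side_l == req.size_px:
        out = crop.astype(np.float64)
    else:
        ratio = side_l / req.size_px
        if abs(ratio - round(ratio)) < 1e-9:
            out = _box_downsample(crop, int(round(ratio)))
        else:
            out = _sk_resize(crop, (req.size_px, req.size_px), order=1,
                             preserve_range=True, anti_aliasing=ratio > 1)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
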