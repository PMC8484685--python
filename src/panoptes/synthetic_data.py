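"""Synthetic pyramidal slides with scale-controlled class signal.

The generator renders toy H&E-like tissue from the same two-dye Beer-Lambert
model the stain module assumes: smooth eosin stroma, Gaussian-profile "gland"
blobs of two types (hematoxylin-rich purple vs eosin-rich pink), and small
hematoxylin "nuclear" dots inside the glands.  White margins and dark
contaminant patches exercise the tile filter.  A ground-truth mask
(0 background / 1 tissue / 2 contaminant) ships with every slide.

Class signal is planted at a chosen spatial scale:

macro
    Blob *types* are spatially segregated into large (~800 um-scale) domains
    in class 1 and independently random in class 0, with the per-slide
    H-blob count drawn from the same Binomial(n, 1/2) in both classes so
    type composition carries no class information.  Any single 10x tile sees
    at most one blob whose type is a fair coin in either class, so 10x pixel
    statistics are class-indistinguishable by construction; only a 2.5x tile
    sees several blobs and their co-occurrence pattern.  ``effect``
    interpolates the type assignment between a pure domain-field ranking (1)
    and pure noise (0).
micro
    Nuclear-dot density inside glands is scaled by (1 + effect) in class 1
    with identical macro arrangement.
none / effect 0
    The two classes are identically distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, zoom

from .slide_io import SlidePyramid, write_pyramidal_tiff
from .stain import RUIFROK_HE


@dataclass
class SyntheticSlideSpec:
    """Everything needed to render one slide deterministically."""

    seed: int
    extent: tuple[int, int] = (1196, 1196)   # (width, height) at 10x-equivalent level 0
    margin_fraction: float = 0.0             # fraction of pixels in the white frame
    n_contaminants: int = 0
    label: int = 0
    signal_scale: str = "macro"              # macro | micro | none
    effect: float = 1.0
    stain_matrix: np.ndarray = field(default_factory=lambda: RUIFROK_HE.copy())
    # texture parameters (level-0 pixels at 10x equivalent)
    blob_spacing: float = 500.0
    blob_sigma: float = 60.0
    blob_amplitude: tuple[float, float] = (0.55, 0.85)
    domain_scale: float = 800.0              # macro-domain correlation length
    dot_density: float = 40.0                # mean nuclear dots per gland
    dot_sigma: float = 2.5
    stroma_od: float = 0.42
    slide_id: str = "synthetic"
    patient_id: str = "patient"

    def __post_init__(self):
        w, h = self.extent
        if w % 4 or h % 4:
            raise ValueError("extent must be divisible by 4 (3-level pyramid)")
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")
        if self.signal_scale not in ("macro", "micro", "none"):
            raise ValueError(f"unknown signal_scale {self.signal_scale!r}")


def _smooth_noise(rng, shape, scale, sigma_amp):
    """Low-frequency Gaussian field, mean 0, std ~sigma_amp."""
    h, w = shape
    coarse = rng.standard_normal((max(h // 50, 1) + 2, max(w // 50, 1) + 2))
    coarse = gaussian_filter(coarse, sigma=max(scale / 50.0, 0.5))
    coarse -= coarse.mean()  # center first: the raw mean is not noise scale
    sd = coarse.std()
    if sd > 0:
        coarse = coarse / sd * sigma_amp
    return zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)[:h, :w]


def _stamp(canvas: np.ndarray, cx: float, cy: float, sigma: float, amp: float) -> None:
    """Add a Gaussian bump in place, truncated at 3 sigma."""
    h, w = canvas.shape
    r = int(np.ceil(3 * sigma))
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys = np.arange(y0, y1)[:, None] - cy
    xs = np.arange(x0, x1)[None, :] - cx
    canvas[y0:y1, x0:x1] += amp * np.exp(-(xs**2 + ys**2) / (2 * sigma**2))


def _margin_thickness(w: int, h: int, frac: float) -> int:
    """Frame thickness whose area fraction is ~frac (exact quadratic root)."""
    if frac <= 0:
        return 0
    # 1 - (w - 2t)(h - 2t)/(w h) = frac  ->  4t^2 - 2(w+h)t + frac*w*h = 0
    a, b, c = 4.0, -2.0 * (w + h), frac * w * h
    disc = b * b - 4 * a * c
    t = (-b - np.sqrt(max(disc, 0.0))) / (2 * a)
    return int(round(t))


def render_slide(spec: SyntheticSlideSpec) -> tuple[SlidePyramid, np.ndarray]:
    """Render a 3-level pyramid and its ground-truth mask.

    Returns an in-memory :class:`SlidePyramid` (base magnification 10x,
    nominal 1.0 um/px) and a level-0 mask with 0 = background, 1 = tissue,
    2 = contaminant.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.extent
    ch = np.zeros((h, w), dtype=np.float64)
    ce = np.zeros((h, w), dtype=np.float64)

    # stroma: eosin base + gentle low-frequency variation (always class-neutral)
    ce += spec.stroma_od + _smooth_noise(rng, (h, w), 200.0, 0.05)

    # gland blob centers on a jittered lattice
    s = spec.blob_spacing
    gx = np.arange(s / 2, w - s / 4, s)
    gy = np.arange(s / 2, h - s / 4, s)
    centers = []
    for yy in gy:
        for xx in gx:
            centers.append(
                (
                    xx + rng.uniform(-0.15 * s, 0.15 * s),
                    yy + rng.uniform(-0.15 * s, 0.15 * s),
                )
            )
    centers = np.asarray(centers).reshape(-1, 2)
    n_blobs = len(centers)

    # macro domain field evaluated at blob centers
    grid = 64
    fh, fw = h // grid + 2, w // grid + 2
    fld = gaussian_filter(rng.standard_normal((fh, fw)), sigma=spec.domain_scale / grid)
    fld_c = fld[
        np.clip((centers[:, 1] // grid).astype(int), 0, fh - 1),
        np.clip((centers[:, 0] // grid).astype(int), 0, fw - 1),
    ]
    fld_c = (fld_c - fld_c.mean()) / (fld_c.std() + 1e-12)

    # The per-slide H-blob *count* is Binomial(n, 1/2) in both classes, so the
    # type-composition distribution is exactly class-identical; classes differ
    # only in *which* blobs are hematoxylin-rich.  A noisy ranking interpolates:
    # effect 1 sorts purely by the smooth domain field (spatial segregation),
    # effect 0 sorts by pure noise (independent random assignment).
    n_h = int(rng.binomial(n_blobs, 0.5))
    z = rng.standard_normal(n_blobs)
    e_eff = 0.0
    if spec.signal_scale == "macro" and spec.label == 1:
        e_eff = min(spec.effect, 1.0)
    rank_score = e_eff * fld_c + (1.0 - e_eff) * z
    blob_is_h = np.zeros(n_blobs, dtype=bool)
    blob_is_h[np.argsort(-rank_score)[:n_h]] = True

    dot_density = spec.dot_density
    if spec.signal_scale == "micro" and spec.label == 1:
        dot_density = spec.dot_density * (1.0 + spec.effect)

    for i, (cx, cy) in enumerate(centers):
        amp = rng.uniform(*spec.blob_amplitude)
        sigma = spec.blob_sigma * rng.uniform(0.9, 1.1)
        target = ch if blob_is_h[i] else ce
        _stamp(target, cx, cy, sigma, amp)
        # nuclear dots cluster inside the gland regardless of its type
        n_dots = rng.poisson(dot_density)
        dx = rng.normal(cx, 0.8 * sigma, n_dots)
        dy = rng.normal(cy, 0.8 * sigma, n_dots)
        damp = rng.uniform(1.0, 1.5, n_dots)
        for j in range(n_dots):
            _stamp(ch, dx[j], dy[j], spec.dot_sigma, damp[j])

    mask = np.ones((h, w), dtype=np.uint8)
    t = _margin_thickness(w, h, spec.margin_fraction)
    if t > 0:
        mask[:t, :] = 0
        mask[-t:, :] = 0
        mask[:, :t] = 0
        mask[:, -t:] = 0
        ch[mask == 0] = 0.0
        ce[mask == 0] = 0.0

    od = ch[..., None] * spec.stain_matrix[0] + ce[..., None] * spec.stain_matrix[1]
    rgb = np.clip(np.rint(256.0 * np.exp(-od) - 1.0), 0, 255).astype(np.uint8)

    for _ in range(spec.n_contaminants):
        side = int(rng.integers(80, 160))
        if w <= side + 2 * t or h <= side + 2 * t:
            continue
        x0 = int(rng.integers(t, w - side - t))
        y0 = int(rng.integers(t, h - side - t))
        rgb[y0 : y0 + side, x0 : x0 + side] = rng.integers(5, 45, size=3, dtype=np.uint8)
        mask[y0 : y0 + side, x0 : x0 + side] = 2

    def _box2(a):
        return (
            a[: a.shape[0] // 2 * 2, : a.shape[1] // 2 * 2]
            .reshape(a.shape[0] // 2, 2, a.shape[1] // 2, 2, 3)
            .mean(axis=(1, 3))
        )

    lvl1 = np.clip(np.rint(_box2(rgb.astype(np.float64))), 0, 255).astype(np.uint8)
    lvl2 = np.clip(np.rint(_box2(lvl1.astype(np.float64))), 0, 255).astype(np.uint8)
    slide = SlidePyramid.from_arrays(
        spec.slide_id, [rgb, lvl1, lvl2], base_magnification=10.0, mpp_level0=1.0
    )
    slide.patient_id = spec.patient_id
    # texture ground truth rides along so tests need no manual annotation
    slide.texture_truth = {
        "blob_centers": centers,
        "blob_is_hematoxylin": blob_is_h,
        "n_h": n_h,
    }
    return slide, mask


def generate_slide(spec: SyntheticSlideSpec, path: str) -> np.ndarray:
    """Render a slide, write it as a pyramidal TIFF, return the mask."""
    slide, mask = render_slide(spec)
    write_pyramidal_tiff(
        path,
        [slide.level_array(i) for i in range(len(slide.levels))],
        slide_id=spec.slide_id,
        base_magnification=10.0,
        mpp_level0=1.0,
    )
    return mask


def generate_cohort(
    n_patients: int,
    slides_per_patient: int = 1,
    class_balance: float = 0.5,
    signal_scale: str = "macro",
    effect: float = 1.0,
    seed: int = 0,
    extent: tuple[int, int] = (2392, 2392),
    margin_fraction: float = 0.0,
    n_contaminants: int = 0,
    clinical_shift: float = 0.0,
    cohort_b_fraction: float = 0.25,
    task: str = "subtype",
) -> tuple[list[SyntheticSlideSpec], pd.DataFrame]:
    """Slide specs plus a matching label table for a toy cohort.

    Slides are returned as specs (render lazily with :func:`render_slide` to
    keep memory flat).  Labels are constant across a patient's slides; age
    and BMI are drawn from cohort-realistic normals, optionally shifted by
    ``clinical_shift`` standard deviations for class-1 patients to exercise
    the clinical branch.  Patients are split between two source cohorts
    ("A" and "B") stratified by class so cohort-independent splits are
    testable.
    """
    if n_patients < 4:
        raise ValueError("need at least 4 patients")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_patients * class_balance))
    labels = np.zeros(n_patients, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    rows = []
    specs: list[SyntheticSlideSpec] = []
    # stratified cohort membership
    order_by_class = {c: [i for i in range(n_patients) if labels[i] == c] for c in (0, 1)}
    in_b = set()
    for c, idxs in order_by_class.items():
        k = int(round(len(idxs) * cohort_b_fraction))
        pick = rng.permutation(len(idxs))[:k]
        in_b.update(idxs[p] for p in pick)

    for i in range(n_patients):
        pid = f"P{i:04d}"
        lab = int(labels[i])
        age = float(np.clip(rng.normal(64 + 10 * clinical_shift * lab, 10), 30, 90))
        bmi = float(np.clip(rng.normal(30 + 6 * clinical_shift * lab, 6), 16, 55))
        for s_i in range(slides_per_patient):
            sid = f"{pid}-S{s_i}"
            specs.append(
                SyntheticSlideSpec(
                    seed=int(rng.integers(0, 2**31 - 1)),
                    extent=extent,
                    margin_fraction=margin_fraction,
                    n_contaminants=n_contaminants,
                    label=lab,
                    signal_scale=signal_scale,
                    effect=effect,
                    slide_id=sid,
                    patient_id=pid,
                )
            )
            rows.append(
                {
                    "patient_id": pid,
                    "slide_id": sid,
                    "cohort": "B" if i in in_b else "A",
                    task: lab,
                    "age": round(age, 1),
                    "bmi": round(bmi, 1),
                }
            )
    return specs, pd.DataFrame(rows)
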