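"""Structure-preserving H&E stain normalization (Vahadane-style).

Transmitted light through a stained section follows Beer-Lambert: optical
density ``OD = -log((I+1)/256)`` is linear in the per-pixel stain
concentrations, ``OD ≈ C^T S`` with ``S`` a 2x3 matrix of unit-norm,
nonnegative stain color vectors (hematoxylin and eosin) and ``C`` the
nonnegative concentration maps.  Normalization estimates the *source* basis
of a tile by sparse nonnegative factorization, rescales concentrations so the
robust (99th percentile) maxima match a reference profile, and recombines with
the reference basis — altering color while preserving structure.

The factorization is solved by alternating minimization of

    || OD - C^T S ||_F^2 + lambda * || C ||_1 + mu * || S - S_prior ||_F^2
    s.t. C >= 0, S >= 0, rows of S unit-norm,

with an exact nonnegative coordinate-descent lasso for the concentration
step and a ridge-tethered projected least-squares stain step, warm-started
at the Ruifrok H&E basis (= S_prior), which makes the estimate deterministic
without any random initialization.  The prior tether is negligible when the
tile contains near-pure pixels of both dyes and keeps the basis anchored to
a plausible H&E geometry on tiles where the factorization is ill-posed
(e.g. one dye never appearing unmixed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import UnstainableTileError

#: Ruifrok & Johnston H&E optical-density color vectors (rows renormalized).
RUIFROK_HE = np.array(
    [
        [0.650, 0.704, 0.286],  # hematoxylin
        [0.072, 0.990, 0.105],  # eosin
    ]
)
RUIFROK_HE = RUIFROK_HE / np.linalg.norm(RUIFROK_HE, axis=1, keepdims=True)

#: Conventional reference 99th-percentile concentrations (H, E).
DEFAULT_MAX_C = np.array([1.9705, 1.0308])


def _unit_rows(m: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(m, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return m / n


@dataclass
class StainProfile:
    """Reference stain basis and scaling used as the normalization target.

    Attributes
    ----------
    stain_matrix : (2, 3) array
        Unit-row OD color vectors; row 0 hematoxylin-like, row 1 eosin-like.
    max_concentrations : (2,) array
        Reference 99th-percentile stain concentrations.
    od_background_threshold : float
        Pixels whose max-channel OD falls below this are treated as
        background and excluded from basis estimation.
    sparsity_weight : float
        L1 penalty on concentrations during basis estimation.
    """

    stain_matrix: np.ndarray = field(default_factory=lambda: RUIFROK_HE.copy())
    max_concentrations: np.ndarray = field(default_factory=lambda: DEFAULT_MAX_C.copy())
    od_background_threshold: float = 0.15
    sparsity_weight: float = 0.10

    def __post_init__(self):
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (2, 3):
            raise ValueError("stain_matrix must be 2x3")
        if np.any(self.stain_matrix < 0):
            raise ValueError("stain vectors must be nonnegative")
        if not np.allclose(np.linalg.norm(self.stain_matrix, axis=1), 1.0, atol=1e-6):
            raise ValueError("stain vector rows must have unit norm")
        if np.any(self.max_concentrations <= 0):
            raise ValueError("max_concentrations must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "stain_matrix": self.stain_matrix.tolist(),
                "max_concentrations": self.max_concentrations.tolist(),
                "od_background_threshold": self.od_background_threshold,
                "sparsity_weight": self.sparsity_weight,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StainProfile":
        d = json.loads(text)
        return cls(
            stain_matrix=np.asarray(d["stain_matrix"]),
            max_concentrations=np.asarray(d["max_concentrations"]),
            od_background_threshold=d.get("od_background_threshold", 0.15),
            sparsity_weight=d.get("sparsity_weight", 0.10),
        )


def rgb_to_od(tile: np.ndarray) -> np.ndarray:
    """Beer-Lambert transform of an 8-bit RGB image to optical density."""
    return -np.log((tile.astype(np.float64) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse transform; clips to the 8-bit range."""
    intensity = 256.0 * np.exp(-od) - 1.0
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def concentrations(od_pixels: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Nonnegative least-squares stain concentrations for each OD pixel.

    With only two stains the NNLS solution has a closed form: solve the
    unconstrained 2x2 normal equations; where a coefficient goes negative,
    clamp it to zero and refit the other stain alone.
    """
    S = stain_matrix
    G = S @ S.T                       # 2x2 Gram
    b = od_pixels @ S.T               # (n, 2)
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    c = np.empty_like(b)
    c[:, 0] = (G[1, 1] * b[:, 0] - G[0, 1] * b[:, 1]) / det
    c[:, 1] = (G[0, 0] * b[:, 1] - G[0, 1] * b[:, 0]) / det
    neg0 = c[:, 0] < 0
    neg1 = c[:, 1] < 0
    c[neg0, 0] = 0.0
    c[neg0, 1] = np.maximum(b[neg0, 1] / G[1, 1], 0.0)
    c[neg1, 1] = 0.0
    c[neg1, 0] = np.maximum(b[neg1, 0] / G[0, 0], 0.0)
    return c


def _order_rows(S: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # hematoxylin-like first: larger blue (third channel) OD component
    if S[0, 2] < S[1, 2]:
        S = S[::-1].copy()
        C = C[:, ::-1].copy()
    return S, C


def estimate_stains(
    tile: np.ndarray,
    profile: Optional[StainProfile] = None,
    *,
    n_iter: int = 30,
    max_pixels: int = 2000,
    prior_weight: float = 30.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate a tile's 2x3 stain basis and full concentration map.

    Runs the alternating sparse-NMF described in the module docstring on a
    (seeded) subsample of tissue pixels, warm-started at the Ruifrok basis,
    then solves concentrations for every pixel against the estimated basis.

    Returns
    -------
    (stain_matrix, concentration_map)
        Basis rows unit-norm and nonnegative, hematoxylin-like first;
        concentrations shaped (n_pixels, 2) over the flattened tile.

    Raises
    ------
    UnstainableTileError
        Fewer than 100 pixels exceed the OD background threshold.
    """
    profile = profile or StainProfile()
    od = rgb_to_od(tile).reshape(-1, 3)
    tissue = od.max(axis=1) > profile.od_background_threshold
    n_tissue = int(tissue.sum())
    if n_tissue < 100:
        raise UnstainableTileError(
            f"only {n_tissue} tissue pixels above OD {profile.od_background_threshold}"
        )
    X = od[tissue]
    if len(X) > max_pixels:
        idx = np.random.default_rng(seed).choice(len(X), max_pixels, replace=False)
        X = X[idx]

    S = RUIFROK_HE.copy()
    S_prior = RUIFROK_HE
    lam = profile.sparsity_weight
    mu = prior_weight
    C = np.maximum(concentrations(X, S), 0.0)
    for _ in range(n_iter):
        # C step: exact nonnegative coordinate-descent lasso (2 stains)
        G = S @ S.T
        B = X @ S.T
        for _pass in range(3):
            C[:, 0] = np.maximum((B[:, 0] - C[:, 1] * G[0, 1] - lam / 2) / G[0, 0], 0.0)
            C[:, 1] = np.maximum((B[:, 1] - C[:, 0] * G[0, 1] - lam / 2) / G[1, 1], 0.0)
        # S step: ridge-tethered least squares, projected and renormalized
        H = C.T @ C + mu * np.eye(2)
        S = np.linalg.solve(H, C.T @ X + mu * S_prior)
        S = _unit_rows(np.maximum(S, 1e-12))
    C_full = np.maximum(concentrations(od, S), 0.0)
    S, C_full = _order_rows(S, C_full)
    return S, C_full


def normalize_tile(
    tile: np.ndarray,
    profile: Optional[StainProfile] = None,
    *,
    source_basis: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> np.ndarray:
    """Map a tile's colors onto the reference stain profile.

    Source concentrations are rescaled per stain by the ratio of reference to
    source 99th-percentile concentrations and recombined with the reference
    basis.  Pixels with no stain (background) stay near-white because their
    concentrations are ~0 in any basis.

    ``source_basis`` lets a caller reuse a per-slide estimate; by default the
    basis is estimated from the tile itself.
    """
    profile = profile or StainProfile()
    src_max = None
    if source_basis is None:
        S_src, C_src = estimate_stains(tile, profile)
    else:
        S_src, src_max = source_basis
        C_src = np.maximum(concentrations(rgb_to_od(tile).reshape(-1, 3), S_src), 0.0)
    if src_max is None:
        src_max = np.percentile(C_src, 99, axis=0)
        src_max = np.where(src_max <= 1e-8, 1.0, src_max)
    C_norm = C_src * (profile.max_concentrations / src_max)
    od_out = C_norm @ profile.stain_matrix
    return od_to_rgb(od_out.reshape(tile.shape))


def slide_stain_context(
    sample: np.ndarray, profile: Optional[StainProfile] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slide source basis and robust concentration maxima.

    Estimated once from a representative pixel sample (e.g. a central crop or
    a coarse pyramid level) and reused for every tile of the slide, giving a
    single consistent color mapping per slide.
    """
    profile = profile or StainProfile()
    S_src, C = estimate_stains(sample, profile)
    src_max = np.percentile(C, 99, axis=0)
    src_max = np.where(src_max <= 1e-8, 1.0, src_max)
    return S_src, src_max


def fit_reference_profile(tile: np.ndarray, base: Optional[StainProfile] = None) -> StainProfile:
    """Build a StainProfile from a user-supplied reference tile."""
    base = base or StainProfile()
    S, C = estimate_stains(tile, base)
    return StainProfile(
        stain_matrix=S,
        max_concentrations=np.percentile(C, 99, axis=0),
        od_background_threshold=base.od_background_threshold,
        sparsity_weight=base.sparsity_weight,
    )
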