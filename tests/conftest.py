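"""Shared fixtures: small rendered slides and reusable tile sets.

Everything is generated programmatically; session scope keeps the rendering
cost paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from panoptes.synthetic_data import SyntheticSlideSpec, render_slide
from panoptes.tiling import TileFilterConfig


@pytest.fixture(scope="session")
def filter_cfg() -> TileFilterConfig:
    return TileFilterConfig()


@pytest.fixture(scope="session")
def tissue_slide():
    """One-cell (1196 px) fully-tissue slide, class 1 macro signal."""
    spec = SyntheticSlideSpec(
        seed=7, extent=(1196, 1196), label=1, signal_scale="macro",
        slide_id="tissue-1", patient_id="PT1",
    )
    slide, mask = render_slide(spec)
    return slide, mask


@pytest.fixture(scope="session")
def four_cell_slide():
    """2x2-cell (2392 px) fully-tissue slide for grid/summary tests."""
    spec = SyntheticSlideSpec(
        seed=11, extent=(2392, 2392), label=0, signal_scale="macro",
        slide_id="tissue-4", patient_id="PT4",
    )
    slide, mask = render_slide(spec)
    return slide, mask


def make_tile(value, px: int = 100) -> np.ndarray:
    """Uniform RGB tile."""
    return np.full((px, px, 3), value, dtype=np.uint8)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
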