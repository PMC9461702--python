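"""Shared fixtures: phantoms are rendered once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

from spherofuse import microwell as mw
from spherofuse import phantom as ph
from spherofuse import segment as sg

KINETICS = (0.9, -0.3, 2.0)   # plateau, b, tau (h)
R_UM = 50.0                   # spheroid radius used in sequence phantoms


@pytest.fixture(scope="session")
def clean_cfg() -> ph.PhantomConfig:
    return ph.PhantomConfig.test_preset(n_frames=30)


@pytest.fixture(scope="session")
def clean_sequence(clean_cfg):
    """30-frame noiseless fusing doublet + ground truth."""
    return ph.render_doublet_sequence(clean_cfg, KINETICS, R_UM, R_UM)


@pytest.fixture(scope="session")
def clean_well(clean_sequence) -> mw.WellCircle:
    _, gt = clean_sequence
    return mw.WellCircle(*gt.well_center[0], gt.well_radius_px)


@pytest.fixture(scope="session")
def clean_segmentation(clean_sequence, clean_well) -> sg.SegmentationResult:
    stack, _ = clean_sequence
    return sg.segment_sequence(stack, clean_well)


@pytest.fixture(scope="session")
def noisy_sequence():
    """Same doublet at 5% of the dynamic range of Gaussian noise."""
    cfg = ph.PhantomConfig.test_preset(n_frames=30, noise_sd=0.05 * 200,
                                       rng_seed=3)
    return ph.render_doublet_sequence(cfg, KINETICS, R_UM, R_UM)


@pytest.fixture(scope="session")
def noisy_segmentation(noisy_sequence, clean_well):
    stack, _ = noisy_sequence
    return sg.segment_sequence(stack, clean_well)


def union_mask(r1: float, r2: float, d: float, pad: int = 8,
               angle_deg: float = 0.0) -> np.ndarray:
    """Rasterized two-disk union centred in a square array (test helper)."""
    import math
    n = int(2 * max(r1, r2) + d + 2 * pad) + 6
    cc = n / 2
    th = math.radians(angle_deg)
    u = (math.cos(th), math.sin(th))
    return ph._rasterize_union(
        (n, n), [(cc - u[0] * d / 2, cc - u[1] * d / 2, r1),
                 (cc + u[0] * d / 2, cc + u[1] * d / 2, r2)])
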