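import numpy as np
import pytest

import fundusrad as fr
from fundusrad.imaging import Contour


def circle_points(cx, cy, r, n=64):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def ellipse_points(cx, cy, a, b, theta_deg=0.0, n=64):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    th = np.radians(-theta_deg)  # screen-CCW convention (y-down frame)
    ex, ey = a * np.cos(t), b * np.sin(t)
    x = cx + ex * np.cos(th) - ey * np.sin(th)
    y = cy + ex * np.sin(th) + ey * np.cos(th)
    return np.column_stack([x, y])


@pytest.fixture(scope="session")
def phantom():
    """One deterministic severe-grade right-eye phantom."""
    return fr.generate_phantom(fr.PhantomConfig(), "MDCA", seed=7, laterality="right")


@pytest.fixture(scope="session")
def phantom_features(phantom):
    img, rois, _ = phantom
    return fr.extract_feature_vector(img, rois)


@pytest.fixture
def concentric_roiset():
    """Disc ellipse (60, 48) inside PPA outer ellipse (100, 80), 256x256."""
    disc = Contour(ellipse_points(128, 128, 60, 48, n=200))
    outer = Contour(ellipse_points(128, 128, 100, 80, n=200))
    return fr.RoiSet.from_contours(disc, outer, (240.0, 128.0), (256, 256))


@pytest.fixture(scope="session")
def random_quantized_rois():
    """Seeded small random quantized ROIs for oracle-equivalence checks."""
    out = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(3, 9, size=2)
        ng = int(rng.integers(2, 7))
        levels = rng.integers(1, ng + 1, size=(h, w)).astype(np.int32)
        mask = rng.random((h, w)) < 0.8
        if not mask.any():
            mask[0, 0] = True
        levels[~mask] = 0
        out.append((levels, mask, ng, seed))
    return out
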