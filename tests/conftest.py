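import math

import numpy as np
import pytest


def rasterize_disk(radius_px: int, pad: int = 6) -> np.ndarray:
    n = 2 * radius_px + 2 * pad + 1
    c = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius_px ** 2


def rasterize_square(side_px: int, pad: int = 6) -> np.ndarray:
    n = side_px + 2 * pad
    m = np.zeros((n, n), dtype=bool)
    m[pad:pad + side_px, pad:pad + side_px] = True
    return m


def rasterize_ellipse(a_px: float, b_px: float, pad: int = 6) -> np.ndarray:
    n = int(2 * max(a_px, b_px)) + 2 * pad + 1
    c = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    return ((cc - c) / a_px) ** 2 + ((rr - c) / b_px) ** 2 <= 1.0


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * float((a & b).sum()) / float(a.sum() + b.sum())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def px_scale():
    """Default physical sampling: a 6-mm field at 420 px."""
    return 6.0 / 420.0


def approx_pct(value, expected, pct):
    """True when value is within pct percent of expected."""
    return math.isclose(value, expected, rel_tol=pct / 100.0)
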