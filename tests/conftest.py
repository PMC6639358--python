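import numpy as np
import pytest

from nirlymph.core import AnalysisConfig
from nirlymph.simulate import TraceSimParams, simulate_packet_trace


@pytest.fixture
def clean_train():
    """Noise-free 5-pulse train with zero bleaching (analytically exact)."""
    params = TraceSimParams(
        duration_s=60.0,
        packet_frequency_per_min=5.0,
        packet_amplitude=8.0,
        packet_width_s=4.0,
        baseline_intensity=20.0,
        noise_sd=0.0,
        bleach_rate_per_s=0.0,
        jitter_frac=0.0,
        seed=0,
    )
    return simulate_packet_trace(params)


@pytest.fixture
def default_cfg():
    return AnalysisConfig()


def brute_force_point_in_polygon(xp, yp, poly):
    """Scalar even-odd ray-casting test (independent test oracle)."""
    inside = False
    n = len(poly)
    for k in range(n):
        x1, y1 = poly[k]
        x2, y2 = poly[(k + 1) % n]
        if (y1 <= yp) != (y2 <= yp):
            xint = x1 + (yp - y1) * (x2 - x1) / (y2 - y1)
            if xp < xint:
                inside = not inside
    return inside


def brute_force_otsu_split(values, n_candidates=256):
    """Exhaustive intra-class-variance minimization (independent oracle).

    Returns the boolean 'positive' labeling of ``values`` for the best
    split, scanning every candidate cut between min and max.
    """
    vals = np.asarray(values, dtype=float).ravel()
    lo, hi = vals.min(), vals.max()
    cuts = np.linspace(lo, hi, n_candidates, endpoint=False)[1:]
    best = None
    best_var = np.inf
    for c in cuts:
        low = vals[vals <= c]
        high = vals[vals > c]
        if low.size == 0 or high.size == 0:
            continue
        intra = low.size * low.var() + high.size * high.var()
        if intra < best_var - 1e-12:
            best_var = intra
            best = vals > c
    return best
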