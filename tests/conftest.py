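import numpy as np
import pytest

from colloid2d import PointPattern, RenderConfig, render_afm_image


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def single_bump_map():
    """One noiseless Gaussian bump (peak 2 nm, sigma 30 nm) on a flat field."""
    pattern = PointPattern(points=[[5000.0, 5000.0]], window=(10_000.0, 10_000.0))
    cfg = RenderConfig(pixel_size=20.0, bump_height=2.0, bump_sigma=30.0,
                       noise_sd=0.0)
    return render_afm_image(pattern, cfg), pattern


def brute_force_rdf(points, window, edges, edge_correction):
    """Reference g(r): explicit double loop over all pairs.

    Deliberately naive (no vectorisation over pairs) so it shares nothing
    with the production estimator beyond the weight formula.
    """
    from colloid2d.rdf import ripley_weight

    points = np.asarray(points, dtype=float)
    w, h = window
    n = len(points)
    n_bins = len(edges) - 1
    raw = np.zeros(n_bins, dtype=int)
    weighted = np.zeros(n_bins)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx = abs(points[i, 0] - points[j, 0])
            dy = abs(points[i, 1] - points[j, 1])
            if edge_correction == "periodic":
                dx = min(dx, w - dx)
                dy = min(dy, h - dy)
            d = np.hypot(dx, dy)
            if d >= edges[-1]:
                continue
            b = int(np.searchsorted(edges, d, side="right")) - 1
            if b < 0 or b >= n_bins:
                continue
            if i < j:
                raw[b] += 1
            if edge_correction == "isotropic":
                wgt = ripley_weight(np.array([points[i, 0]]),
                                    np.array([points[i, 1]]),
                                    np.array([d]), window)[0]
                weighted[b] += wgt
            else:
                weighted[b] += 1.0
    area = w * h
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    g = area * weighted / (n * (n - 1) * annulus)
    return g, raw
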