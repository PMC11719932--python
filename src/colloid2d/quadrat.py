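"""Quadrat-count density analysis against the Poisson law.

For particles adsorbed independently and uniformly, the number n falling in
a region of fixed area follows the Poisson distribution

    P(n) = λⁿ e^{−λ} / n!

whose variance equals its mean λ.  Comparing the sample variance of
quadrat counts with their mean therefore diagnoses interactions:
σ²_experimental < λ (sub-Poisson) signals repulsion — an exclusion region
around each particle; σ²_experimental > λ (super-Poisson) signals
clustering.  Two complementary tests are provided: a Pearson χ²
goodness-of-fit of the full count histogram, and the χ² index-of-dispersion
test used for regime classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .datatypes import PointPattern, ValidationError


@dataclass(frozen=True)
class QuadratResult:
    """Per-region counts and the derived dispersion statistics."""

    counts: np.ndarray
    region_area: float
    lambda_hat: float
    variance: float
    dispersion_index: float
    grid_shape: tuple[int, int]
    gof_pvalue: float | None = None
    confidence: float = 0.95
    regime: str | None = None


@dataclass(frozen=True)
class DensityDistribution:
    """Empirical count distribution next to its fitted Poisson reference."""

    n_values: np.ndarray
    empirical_prob: np.ndarray
    poisson_prob: np.ndarray


def poisson_pmf(n, lam: float):
    """Poisson probability P(n) = λⁿ e^{−λ} / n!.

    Evaluated in log space (via the log-gamma function) so large n and λ do
    not overflow.  Accepts scalar or array n.
    """
    n_arr = np.asarray(n)
    if not (lam > 0):
        raise ValidationError("lam must be positive")
    if np.any(n_arr < 0) or not np.all(np.equal(np.mod(n_arr, 1), 0)):
        raise ValidationError("n must be a non-negative integer")
    log_p = n_arr * np.log(lam) - lam - gammaln(n_arr + 1)
    out = np.exp(log_p)
    return float(out) if np.isscalar(n) or n_arr.ndim == 0 else out


def quadrat_counts(pattern: PointPattern, min_mean_count: float = 25.0) -> QuadratResult:
    """Tile the window into equal-area regions and count particles per region.

    The grid is the largest k×m tiling (near-square regions preferred) such
    that the mean count N/(k·m) is at least ``min_mean_count``; the default
    of 25 follows standard practice of keeping expected quadrat counts
    comfortably large.  Every particle falls in exactly one region; counts
    sum to N.
    """
    n = pattern.n
    if n == 0:
        raise ValidationError("pattern is empty")
    max_regions = int(n // min_mean_count)
    if max_regions < 1:
        raise ValidationError(
            "too few particles to form even one quadrat at the requested mean")
    w, h = pattern.window

    # choose k (rows) × m (cols) maximising k·m <= max_regions, preferring
    # near-square regions (aspect ratio of one region closest to 1)
    best = None
    for k in range(1, max_regions + 1):
        m = max_regions // k
        if m < 1:
            break
        aspect = abs(np.log((w / m) / (h / k)))
        key = (-(k * m), aspect)
        if best is None or key < best[0]:
            best = (key, (k, m))
    k, m = best[1]

    cell_w, cell_h = w / m, h / k
    pts = pattern.points
    col = np.minimum((pts[:, 0] // cell_w).astype(int), m - 1)
    row = np.minimum((pts[:, 1] // cell_h).astype(int), k - 1)
    counts = np.bincount(row * m + col, minlength=k * m)

    lam = counts.mean()
    var = counts.var(ddof=1) if counts.size > 1 else 0.0
    return QuadratResult(
        counts=counts,
        region_area=cell_w * cell_h,
        lambda_hat=float(lam),
        variance=float(var),
        dispersion_index=float(var / lam) if lam > 0 else 0.0,
        grid_shape=(k, m),
    )


def density_distribution(counts: Sequence[int]) -> DensityDistribution:
    """Observed count frequencies next to the fitted Poisson(λ̂) reference."""
    counts = np.asarray(counts, dtype=int)
    lam = counts.mean()
    n_max = int(counts.max())
    support = np.arange(n_max + 1)
    emp = np.bincount(counts, minlength=n_max + 1) / counts.size
    return DensityDistribution(
        n_values=support,
        empirical_prob=emp,
        poisson_prob=poisson_pmf(support, lam),
    )


def poisson_gof_test(counts: Sequence[int], confidence: float = 0.95
                     ) -> tuple[float, str]:
    """Pearson χ² goodness of fit of quadrat counts against Poisson(λ̂).

    Expected frequencies below 5 are pooled inward from both tails; one
    degree of freedom is spent on the estimated mean, so df = bins − 2.
    The verdict is ``"consistent"`` when the p-value exceeds 1 − confidence.
    """
    counts = np.asarray(counts, dtype=int)
    n_regions = counts.size
    if n_regions < 5:
        raise ValidationError("need at least 5 regions for the test")
    lam = counts.mean()
    if lam <= 0:
        raise ValidationError("mean count must be positive")

    n_max = int(counts.max())
    support = np.arange(n_max + 1)
    pmf = poisson_pmf(support, lam)
    probs = np.append(pmf, max(0.0, 1.0 - pmf.sum()))  # open upper tail
    observed = np.append(np.bincount(counts, minlength=n_max + 1), 0)
    expected = n_regions * probs

    obs_pooled, exp_pooled = _pool_tails(observed, expected, min_expected=5.0)
    if obs_pooled.size < 3:
        raise ValidationError("insufficient spread for a chi-squared test")
    chi2 = float(((obs_pooled - exp_pooled) ** 2 / exp_pooled).sum())
    df = obs_pooled.size - 1 - 1
    pvalue = float(stats.chi2.sf(chi2, df))
    verdict = "consistent" if pvalue > 1.0 - confidence else "inconsistent"
    return pvalue, verdict


def _pool_tails(observed: np.ndarray, expected: np.ndarray,
                min_expected: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge tail bins inward until every expected count reaches the floor."""
    obs = list(observed.astype(float))
    exp = list(expected.astype(float))
    while len(exp) > 1 and exp[0] < min_expected:
        exp[1] += exp[0]
        obs[1] += obs[0]
        del exp[0], obs[0]
    while len(exp) > 1 and exp[-1] < min_expected:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        del exp[-1], obs[-1]
    return np.array(obs), np.array(exp)


def classify_regime(lambda_hat: float, variance: float, counts_n: int,
                    confidence: float = 0.95) -> str:
    """Classify a count pattern by the χ² index-of-dispersion test.

    The statistic D = (n−1)·s²/λ̂ is χ²(n−1) under the Poisson null.
    Values below the lower two-sided bound signal sub-Poisson (repulsive)
    counts, above the upper bound super-Poisson (clustered); otherwise the
    counts are consistent with complete spatial randomness.
    """
    if counts_n < 5:
        raise ValidationError("need at least 5 regions to classify")
    if not (lambda_hat > 0):
        raise ValidationError("lambda_hat must be positive")
    alpha = 1.0 - confidence
    df = counts_n - 1
    d_stat = df * variance / lambda_hat
    lo = stats.chi2.ppf(alpha / 2, df)
    hi = stats.chi2.ppf(1 - alpha / 2, df)
    if d_stat < lo:
        return "sub_poisson"
    if d_stat > hi:
        return "super_poisson"
    return "poisson"


def analyze_quadrats(pattern: PointPattern, min_mean_count: float = 25.0,
                     confidence: float = 0.95) -> QuadratResult:
    """Full quadrat pipeline: counts, GOF p-value, and regime verdict."""
    base = quadrat_counts(pattern, min_mean_count=min_mean_count)
    pvalue, _ = poisson_gof_test(base.counts, confidence=confidence)
    regime = classify_regime(base.lambda_hat, base.variance,
                             base.counts.size, confidence=confidence)
    return QuadratResult(
        counts=base.counts, region_area=base.region_area,
        lambda_hat=base.lambda_hat, variance=base.variance,
        dispersion_index=base.dispersion_index, grid_shape=base.grid_shape,
        gof_pvalue=pvalue, confidence=confidence, regime=regime,
    )


def density_precision(expected_count: float) -> float:
    """Relative standard error of a Poisson count: 1/√(expected count).

    A region holding 100 particles pins the density to 10%; 10,000
    particles pin it to 1%.
    """
    if not (expected_count > 0):
        raise ValidationError("expected_count must be positive")
    return 1.0 / np.sqrt(expected_count)
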