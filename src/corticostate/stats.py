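"""Nonparametric comparisons used throughout the analyses.

Correlation-map group comparisons use entrywise two-sided Wilcoxon rank-sum
tests with Bonferroni correction over the unique upper-triangle entries (4186
for a 92-ROI map). Distribution comparisons use the two-sample
Kolmogorov-Smirnov test; probability densities are estimated with an
Epanechnikov kernel; Fisher-transformed correlation coefficients are compared
with one-way ANOVA / t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class MapComparison:
    """Entrywise rank-sum comparison of two groups of correlation maps.

    ``z_map`` follows the convention z > 0 ⟺ group B tends larger than group
    A. ``z_display`` zeroes insignificant entries (presentation convention);
    the raw z values are retained in ``z_map``.
    """

    z_map: np.ndarray
    p_map: np.ndarray
    significant_mask: np.ndarray
    alpha: float
    n_a: int
    n_b: int

    @property
    def z_display(self) -> np.ndarray:
        return np.where(self.significant_mask, self.z_map, 0.0)


def ranksum_map_compare(
    maps_a: np.ndarray, maps_b: np.ndarray, alpha: float = 0.05
) -> MapComparison:
    """Two-sided Wilcoxon rank-sum test per map entry, Bonferroni corrected.

    ``maps_a``/``maps_b`` are (n_maps, r, r) stacks. The Bonferroni family is
    the number of unique strict-upper-triangle entries; significance means
    ``p * family < alpha``. Exact p-values (permutation enumeration) are used
    when both group sizes are <= 10 and no ties; the normal approximation with
    tie correction otherwise.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("inputs must be (n_maps, r, r) stacks of equal map shape")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 maps per group")
    r = a.shape[1]
    iu = np.triu_indices(r, k=1)
    family = len(iu[0])
    z_map = np.zeros((r, r))
    p_map = np.ones((r, r))
    for i, j in zip(*iu):
        z, p = _ranksum(a[:, i, j], b[:, i, j])
        z_map[i, j] = z_map[j, i] = z
        p_map[i, j] = p_map[j, i] = p
    sig = (p_map * family < alpha)
    np.fill_diagonal(sig, False)
    return MapComparison(z_map=z_map, p_map=p_map, significant_mask=sig,
                         alpha=alpha, n_a=a.shape[0], n_b=b.shape[0])


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(z, p) with z > 0 ⟺ y tends larger than x."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    # z statistic from the normal approximation with tie correction
    ranks = sps.rankdata(pooled)
    ry = ranks[n1:].sum()
    mu = n2 * (n1 + n2 + 1) / 2.0
    tie_term = _tie_correction(pooled)
    sigma2 = n1 * n2 * (n1 + n2 + 1) / 12.0 * tie_term
    z = 0.0 if sigma2 == 0 else (ry - mu) / np.sqrt(sigma2)
    if max(n1, n2) <= 10 and not has_ties:
        p = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    else:
        p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def _tie_correction(pooled: np.ndarray) -> float:
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - np.sum(counts**3 - counts) / (n**3 - n)


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic (sup ECDF gap) and asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be nonempty")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def epanechnikov_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule scaled for the Epanechnikov kernel.

    ``h = (40 sqrt(pi) / n)^(1/5) * sigma`` (≈ 2.345 σ n^(-1/5)), with σ the
    smaller of the sample SD and IQR/1.349.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
    if sigma == 0:
        return 0.0
    return float((40.0 * np.sqrt(np.pi) / n) ** 0.2 * sigma)


def epanechnikov_kde(
    samples: np.ndarray,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel density with the Epanechnikov kernel K(u) = 0.75 (1 − u²), |u| ≤ 1.

    Returns (grid, density). Bandwidth defaults to the Epanechnikov-scaled
    Silverman rule; degenerate (zero-variance) samples yield a narrow spike
    with a warning.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 samples")
    if bandwidth is None:
        bandwidth = epanechnikov_bandwidth(x)
    if bandwidth <= 0:
        warnings.warn("zero-variance sample; returning a degenerate spike", stacklevel=2)
        bandwidth = max(1e-6, 1e-6 * max(1.0, abs(x[0])))
    if grid is None:
        lo, hi = x.min() - bandwidth, x.max() + bandwidth
        grid = np.linspace(lo, hi, n_grid)
    u = (grid[:, None] - x[None, :]) / bandwidth
    k = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)
    density = k.sum(axis=1) / (len(x) * bandwidth)
    return grid, density


def fisher_z_compare(r_groups: list[np.ndarray], alpha: float = 0.05) -> dict:
    """Compare groups of Pearson correlations on the Fisher-z (atanh) scale.

    One-way ANOVA across groups plus pairwise two-sample t-tests. Correlations
    at exactly ±1 are clipped to ±(1 − 1e−12) with a warning.
    """
    zs = []
    for g in r_groups:
        g = np.asarray(g, dtype=float)
        if np.any(np.abs(g) > 1):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.any(np.abs(g) == 1):
            warnings.warn("|r| = 1 clipped before Fisher transform", stacklevel=2)
            g = np.clip(g, -1 + 1e-12, 1 - 1e-12)
        zs.append(np.arctanh(g))
    f_stat, f_p = sps.f_oneway(*zs)
    pairwise = {}
    for i in range(len(zs)):
        for j in range(i + 1, len(zs)):
            t, p = sps.ttest_ind(zs[i], zs[j])
            pairwise[(i, j)] = {"t": float(t), "p": float(p), "significant": p < alpha}
    return {"F": float(f_stat), "p": float(f_p), "significant": f_p < alpha,
            "pairwise": pairwise}
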