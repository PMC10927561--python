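"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's analytic code paths: set
enumeration for the dissimilarities, permutation subsampling for the
rarefaction curve, a closed-form conjugate posterior for the sampler,
and a 1-D angle grid for the two-column varimax rotation.
"""

from __future__ import annotations

import numpy as np


def jaccard_by_enumeration(a: set, b: set) -> tuple[float, float, float]:
    """(J, J_t, J_n) by explicit set enumeration."""
    gain = sum(1 for s in b if s not in a)
    loss = sum(1 for s in a if s not in b)
    common = sum(1 for s in a if s in b)
    j = (gain + loss) / (gain + loss + common)
    m = 2 * min(gain, loss)
    jt = m / (common + m) if (common + m) else 0.0
    return j, jt, 1.0 - jt


def simpson_by_loops(pa: dict, pb: dict) -> float:
    """Simpson-based dissimilarity by explicit loops over the union pool."""
    pool = set(pa) | set(pb)
    ta = sum(pa.values())
    tb = sum(pb.values())
    num = den_a = den_b = cross = 0.0
    for s in pool:
        p = pa.get(s, 0.0) / ta
        q = pb.get(s, 0.0) / tb
        num += (p - q) ** 2
        den_a += p * p
        den_b += q * q
        cross += p * q
    return num / (den_a + den_b - cross)


def rarefaction_curve_mc(
    counts, n_rep: int = 2000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monte-Carlo subsampling estimates of the rarefaction curve.

    For subsample sizes m = 1..n-1 returns ``(sizes, coverage, richness)``
    where richness(m) is the mean species count of a size-m permutation
    prefix and coverage(m) uses the Good-Turing singleton relation:
    the rarefied coverage at size m equals 1 - E[f1(m+1)] / (m+1).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(counts, dtype=int)
    n = int(x.sum())
    k = len(x)
    offsets = np.concatenate([[0], np.cumsum(x)])
    pool = np.repeat(np.arange(k), x)
    first_hist = np.zeros(n + 2)
    second_hist = np.zeros(n + 2)
    for _ in range(n_rep):
        perm = rng.permutation(pool)
        order = np.argsort(perm, kind="stable")  # positions grouped by species
        first = order[offsets[:-1]]
        second = np.where(x >= 2, order[np.minimum(offsets[:-1] + 1, n - 1)], n)
        first_hist += np.bincount(first, minlength=n + 2)[: n + 2]
        second_hist += np.bincount(second, minlength=n + 2)[: n + 2]
    # cum[j] = number of occurrences at positions <= j
    cum_first = np.cumsum(first_hist)[: n + 1]
    cum_second = np.cumsum(second_hist)[: n + 1]
    sizes = np.arange(1, n)
    # prefix of size m covers positions 0..m-1
    richness = cum_first[sizes - 1] / n_rep               # E[S(m)]
    f1_next = (cum_first[sizes] - cum_second[sizes]) / n_rep  # E[f1(m+1)]
    coverage = 1.0 - f1_next / (sizes + 1)
    return sizes, coverage, richness


def richness_at_coverage_mc(
    counts, target: float, n_rep: int = 2000, seed: int = 0
) -> float:
    """Interpolate the MC rarefaction curve at a target coverage."""
    _, coverage, richness = rarefaction_curve_mc(counts, n_rep, seed)
    order = np.argsort(coverage)
    return float(np.interp(target, coverage[order], richness[order]))


def conjugate_posterior(X: np.ndarray, y: np.ndarray, resid_sd: float,
                        prior_var: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form posterior (mean, covariance) of a Gaussian linear model
    with known residual SD and independent N(0, prior_var) priors."""
    tau = 1.0 / resid_sd ** 2
    A = tau * X.T @ X + np.eye(X.shape[1]) / prior_var
    mean = np.linalg.solve(A, tau * X.T @ y)
    return mean, np.linalg.inv(A)


def varimax_by_angle_grid(loadings: np.ndarray, n_grid: int = 100_000) -> np.ndarray:
    """Best varimax rotation of a two-column loading matrix by brute-force
    search over the rotation angle."""
    L = np.asarray(loadings, dtype=float)
    assert L.shape[1] == 2
    best, best_val = None, -np.inf
    for theta in np.linspace(0, np.pi / 2, n_grid):
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        Lr = L @ R
        val = np.sum((Lr ** 2).var(axis=0))
        if val > best_val:
            best_val, best = val, Lr
    return best
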