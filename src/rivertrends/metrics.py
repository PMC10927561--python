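"""Per-survey community metrics and dissimilarities versus the first year.

For every annual community sample the pipeline computes total abundance,
raw and coverage-standardized species richness, the abundance and
richness shares of non-native species, and three dissimilarities against
the site's first sampled year:

* Jaccard dissimilarity ``J = (S_gain + S_loss) / S_tot`` on presences,
  partitioned into turnover ``J_t`` (species replacement) and nestedness
  ``J_n = 1 - J_t``;
* a Simpson-concentration-based dissimilarity ``H_d`` on relative
  abundances that weights changes among dominant species.

Richness is standardized to a fixed sample coverage (default 98.5%) via
rarefaction / extrapolation on integer counts; densities and CPUE are
first converted to pseudo-counts by dividing by the smallest density in
the sample, which guarantees at least one singleton.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

DEFAULT_COVERAGE = 0.985
#: extrapolation cap, as a multiple of the observed number of individuals
EXTRAPOLATION_CAP = 2.0


# ---------------------------------------------------------------------------
# presence/absence dissimilarity

def jaccard_dissimilarity(
    baseline: Sequence[str], current: Sequence[str]
) -> tuple[float, int, int, int, int]:
    """Jaccard dissimilarity between two species sets.

    Returns ``(J, S_gain, S_loss, S_tot, S_common)`` where gains are
    species present now but absent at baseline, losses the converse, and
    ``S_tot`` the union size.
    """
    a, b = set(baseline), set(current)
    if not a and not b:
        raise ValueError("Jaccard dissimilarity undefined for two empty communities")
    gain = len(b - a)
    loss = len(a - b)
    common = len(a & b)
    tot = gain + loss + common
    return (gain + loss) / tot, gain, loss, tot, common


def jaccard_partition(s_gain: int, s_loss: int, s_common: int) -> tuple[float, float]:
    """Split Jaccard dissimilarity into turnover and nestedness components.

    ``J_t = 2 min(gain, loss) / (common + 2 min(gain, loss))`` measures
    species replacement; ``J_n = 1 - J_t`` measures gains/losses from a
    nested pool.
    """
    if min(s_gain, s_loss, s_common) < 0:
        raise ValueError("species counts must be non-negative")
    if s_gain + s_loss + s_common == 0:
        raise ValueError("turnover undefined for empty communities")
    m = 2 * min(s_gain, s_loss)
    j_t = m / (s_common + m) if m > 0 else 0.0
    return j_t, 1.0 - j_t


def simpson_dissimilarity(
    baseline: Mapping[str, float], current: Mapping[str, float]
) -> float:
    """Simpson-based dissimilarity between two relative-abundance vectors.

    Both communities are expressed over the union species pool (absent
    species get 0).  The statistic is the squared-difference sum over the
    Simpson concentration cross-term,
    ``sum (p - p')^2 / (sum p^2 + sum p'^2 - sum p p')``: 0 for identical
    communities, 1 for fully disjoint ones, dominated by the abundant
    species.  Values are clamped to [0, 1] against rounding.
    """
    pool = sorted(set(baseline) | set(current))
    if not pool:
        raise ValueError("Simpson dissimilarity undefined for empty communities")
    p = np.array([baseline.get(s, 0.0) for s in pool], dtype=float)
    q = np.array([current.get(s, 0.0) for s in pool], dtype=float)
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("degenerate all-zero abundance vector")
    p = p / p.sum()
    q = q / q.sum()
    denom = (p ** 2).sum() + (q ** 2).sum() - (p * q).sum()
    h = ((p - q) ** 2).sum() / denom
    return float(min(max(h, 0.0), 1.0))


# ---------------------------------------------------------------------------
# coverage-standardized richness

def densities_to_pseudocounts(densities: Sequence[float]) -> np.ndarray:
    """Convert positive densities/CPUE to integer pseudo-counts.

    Each value is divided by the community minimum and rounded half away
    from zero, so the rarest species becomes a singleton and every count
    is >= 1 — the prerequisite for the coverage estimator.
    """
    x = np.asarray(densities, dtype=float)
    if x.size == 0:
        raise ValueError("empty density vector")
    if np.any(x <= 0):
        raise ValueError("densities must be strictly positive")
    ratio = x / x.min()
    counts = np.floor(ratio + 0.5).astype(int)  # half away from zero (ratios >= 1)
    counts[np.argmin(x)] = 1
    return np.maximum(counts, 1)


def _f1_f2(counts: np.ndarray) -> tuple[int, int]:
    return int((counts == 1).sum()), int((counts == 2).sum())


def sample_coverage(counts: Sequence[int]) -> float:
    """Estimated sample coverage from integer abundance counts.

    ``C = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)]`` with ``f1``/``f2``
    the numbers of singletons and doubletons and ``n`` the number of
    individuals.  1 when there are no singletons; ~0 when every species
    is a singleton.
    """
    x = np.asarray(counts, dtype=int)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("empty sample")
    n = int(x.sum())
    f1, f2 = _f1_f2(x)
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    a = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
    return float(1.0 - (f1 / n) * a)


def _log_binom(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _rarefied_richness(x: np.ndarray, m: int) -> float:
    """Expected richness of a size-``m`` subsample without replacement."""
    n = int(x.sum())
    if m >= n:
        return float((x > 0).sum())
    terms = np.zeros(x.size)
    ok = (n - x) >= m
    if ok.any():
        terms[ok] = np.exp(_log_binom(n - x[ok], m) - _log_binom(n, m))
    return float((1.0 - terms).sum())


def _rarefied_coverage(x: np.ndarray, m: int) -> float:
    """Expected coverage of a size-``m`` subsample without replacement."""
    n = int(x.sum())
    if m >= n:
        return sample_coverage(x)
    terms = np.zeros(x.size)
    ok = (n - x) >= m
    if ok.any():
        terms[ok] = np.exp(_log_binom(n - x[ok], m) - _log_binom(n - 1, m))
    return float(1.0 - ((x / n) * terms).sum())


def coverage_richness(
    counts: Sequence[int],
    target_coverage: float = DEFAULT_COVERAGE,
    cap: float = EXTRAPOLATION_CAP,
) -> tuple[float, bool]:
    """Species richness standardized to a fixed sample coverage.

    Rarefies (exact hypergeometric expectations, linear interpolation in
    coverage between integer subsample sizes) when the target lies below
    the observed coverage, and extrapolates with the asymptotic
    singleton/doubleton estimator when it lies above.  Extrapolation is
    capped at ``cap`` times the observed sample size; a capped estimate is
    returned with the flag set.

    Returns ``(richness, capped)``.
    """
    if not (0 < target_coverage < 1):
        raise ValueError("target coverage must be in (0, 1)")
    x = np.asarray(counts, dtype=int)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("empty sample")
    n = int(x.sum())
    s_obs = int((x > 0).sum())
    c_obs = sample_coverage(x)

    if abs(target_coverage - c_obs) < 1e-12:
        return float(s_obs), False

    if target_coverage < c_obs:
        # walk m down from n until coverage brackets the target
        lo, hi = 1, n
        c_hi = c_obs
        # binary search over integer sizes: coverage is non-decreasing in m
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if _rarefied_coverage(x, mid) >= target_coverage:
                hi = mid
            else:
                lo = mid
        c_lo = _rarefied_coverage(x, lo)
        c_hi = _rarefied_coverage(x, hi)
        s_lo = _rarefied_richness(x, lo)
        s_hi = _rarefied_richness(x, hi)
        if c_hi <= c_lo:
            return float(s_hi), False
        w = np.clip((target_coverage - c_lo) / (c_hi - c_lo), 0.0, 1.0)
        return float(s_lo + w * (s_hi - s_lo)), False

    # extrapolation beyond the observed sample
    f1, f2 = _f1_f2(x)
    if f1 == 0:  # c_obs == 1 > target handled above; defensive
        return float(s_obs), False
    if f2 > 0:
        f0 = (n - 1) / n * f1 ** 2 / (2 * f2)
        a = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
    else:
        f0 = (n - 1) / n * f1 * (f1 - 1) / 2
        a = (n - 1) * f1 / ((n - 1) * f1 + 2)
    # coverage at n + m*: 1 - (f1/n) a^(m*+1); solve for m* at the target
    m_star = np.log(n * (1 - target_coverage) / f1) / np.log(a) - 1 if a < 1 else np.inf
    m_cap = (cap - 1.0) * n
    capped = m_star > m_cap
    m_star = float(min(max(m_star, 0.0), m_cap))
    if f0 <= 0:
        return float(s_obs), capped
    s_ext = s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** m_star)
    return float(s_ext), bool(capped)


# ---------------------------------------------------------------------------
# non-native shares and the per-site metric series

def nonnative_proportions(
    abundances: Mapping[str, float], origins: Mapping[str, str]
) -> tuple[float, float]:
    """Shares of non-native species in total abundance and in richness.

    Species with unresolved origin count as native, which keeps the
    proportions defined and is conservative for invasion signals.
    """
    species = list(abundances)
    if not species:
        return 0.0, 0.0
    total = float(sum(abundances.values()))
    nn = [s for s in species if origins.get(s) == "nonnative"]
    prop_abund = sum(abundances[s] for s in nn) / total if total > 0 else 0.0
    return float(prop_abund), len(nn) / len(species)


def _to_counts(abundances: np.ndarray, unit: str) -> np.ndarray:
    if unit == "count":
        return np.maximum(np.round(abundances).astype(int), 1)
    return densities_to_pseudocounts(abundances)


def metrics_series(
    site_records: pd.DataFrame,
    target_coverage: float = DEFAULT_COVERAGE,
) -> pd.DataFrame:
    """Per-year metric rows for one site's filtered annual series.

    Dissimilarities are computed against the first sampled year; ``t`` is
    years since that first year.  Requires at least two sampled years.
    """
    years = np.sort(site_records["date"].dt.year.unique())
    if len(years) < 2:
        raise ValueError("metrics need a series of at least 2 years")
    site_id = site_records["site_id"].iloc[0]
    unit = site_records["unit"].iloc[0]
    has_origin = "origin" in site_records.columns

    by_year = {}
    for year in years:
        sub = site_records[site_records["date"].dt.year == year]
        ab = dict(zip(sub["species_id"], sub["abundance"].astype(float)))
        ab = {s: v for s, v in ab.items() if v > 0}
        origins = dict(zip(sub["species_id"], sub["origin"])) if has_origin else {}
        by_year[year] = (ab, origins)

    base_ab, _ = by_year[years[0]]
    rows = []
    for year in years:
        ab, origins = by_year[year]
        abund = np.array(list(ab.values()), dtype=float)
        counts = _to_counts(abund, unit)
        rich_cov, capped = coverage_richness(counts, target_coverage)
        if year == years[0]:
            j = j_t = j_n = h_d = 0.0
            gain = loss = 0
            tot = common = len(ab)
        else:
            j, gain, loss, tot, common = jaccard_dissimilarity(base_ab, ab)
            j_t, j_n = jaccard_partition(gain, loss, common)
            h_d = simpson_dissimilarity(base_ab, ab)
        p_ab, p_rich = nonnative_proportions(ab, origins) if has_origin else (np.nan, np.nan)
        rows.append(
            {
                "site_id": site_id,
                "year": int(year),
                "t": int(year - years[0]),
                "unit": unit,
                "total_abundance": float(abund.sum()),
                "richness_raw": int(len(ab)),
                "richness_cov": rich_cov,
                "richness_cov_capped": bool(capped),
                "prop_nn_abund": p_ab,
                "prop_nn_rich": p_rich,
                "jaccard": j,
                "turnover": j_t,
                "nestedness": j_n,
                "simpson_dissim": h_d,
                "s_gain": int(gain),
                "s_loss": int(loss),
                "s_tot": int(tot),
                "s_common": int(common),
            }
        )
    return pd.DataFrame(rows)


def metrics_table(
    records: pd.DataFrame, target_coverage: float = DEFAULT_COVERAGE
) -> pd.DataFrame:
    """Concatenate :func:`metrics_series` over all sites, with basin ids."""
    basin = records.groupby("site_id")["basin_id"].first()
    parts = []
    for site, grp in records.groupby("site_id", sort=True):
        part = metrics_series(grp, target_coverage)
        part.insert(1, "basin_id", basin[site])
        parts.append(part)
    if not parts:
        raise ValueError("no sites to compute metrics for")
    return pd.concat(parts, ignore_index=True)
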