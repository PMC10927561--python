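"""Hierarchical Bayesian trend models for the community metrics.

Each community metric Y observed at site i (nested in basin n) and time t
is modelled as a Gaussian linear mixed model

    Y_{i|n,t} = alpha + beta_0 * Time_t + [drivers] + eps_{i|n,t}

with Time_t = log(years since first survey + 1), a random intercept and a
random time-slope at both the basin and the site-within-basin level:

    alpha  = alpha_0 + a_n + a_{i|n}
    beta_0 = mu + b_n + b_{i|n}
    a_n, a_{i|n}, b_n, b_{i|n}, eps ~ N(0, sigma^2)   (independent)

The driver model adds three covariates X_k (past footprint, recent
footprint change, stream position) as main effects, two-way Time * X_k
interactions, and three-way Time * X_k * X_l interactions.

Inference is a blocked Gibbs sampler exploiting full conjugacy: Gaussian
updates for the fixed effects and each random-effect vector given the
precisions, gamma updates for the precisions given the effects.  Priors:
N(0, 1000) on fixed effects, Gamma(shape 1, rate 5e-5) on every
precision.  Per-site temporal trends are posterior means of
mu + b_n + b_{i|n}; evidence tiers come from 80/90/95% highest posterior
density intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

LOG_DECADE = np.log(10.0 + 1.0)

DRIVER_COLUMNS = ("X_past", "X_change", "X_stream")

#: responses analysed on the log scale (trends read as % change)
LOG_RESPONSES = ("total_abundance", "richness_cov", "richness_raw")
#: responses that are per-site dissimilarities versus the first year
DISSIMILARITY_RESPONSES = ("jaccard", "turnover", "nestedness", "simpson_dissim")
PROPORTION_RESPONSES = ("prop_nn_abund", "prop_nn_rich")


# ---------------------------------------------------------------------------
# model specification and design construction

@dataclass(frozen=True)
class ModelSpec:
    """What enters the linear predictor for one response."""

    response: str
    log_response: bool
    scale_response: bool = True
    include_intercept: bool = True
    include_unit_effects: bool = False
    include_driver_mains: bool = True
    drivers: tuple[str, ...] = ()
    random_intercepts: bool = True
    random_slopes: bool = True
    drop_baseline_rows: bool = False


def response_spec(response: str, with_drivers: bool = False) -> ModelSpec:
    """The model specification used for each community metric.

    Total abundance gets unit main effects and unit-by-time interactions
    (reference level: raw count).  Dissimilarity responses are 0 by
    construction at t = 0, so they lose the intercept (fixed and random),
    driver main effects and their deterministic baseline rows.
    """
    drivers = DRIVER_COLUMNS if with_drivers else ()
    if response == "total_abundance":
        return ModelSpec(response, log_response=True, include_unit_effects=True,
                         drivers=drivers)
    if response in LOG_RESPONSES:
        return ModelSpec(response, log_response=True, drivers=drivers)
    if response in PROPORTION_RESPONSES:
        return ModelSpec(response, log_response=False, drivers=drivers)
    if response in DISSIMILARITY_RESPONSES:
        return ModelSpec(
            response, log_response=False, include_intercept=False,
            include_driver_mains=False, random_intercepts=False,
            drop_baseline_rows=True, drivers=drivers,
        )
    raise ValueError(f"unknown response: {response}")


@dataclass
class Design:
    """Design matrices and grouping indices for one model fit."""

    X: np.ndarray
    names: list[str]
    y: np.ndarray
    time: np.ndarray                  # log(t+1), the random-slope covariate
    basin_idx: np.ndarray
    site_idx: np.ndarray
    site_basin: np.ndarray            # basin index of each site
    basin_ids: list
    site_ids: list
    y_sd: float
    spec: ModelSpec
    unit_levels: list[str] = field(default_factory=list)
    driver_medians: dict = field(default_factory=dict)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build fixed-effect columns and grouping indices from a joined
    metrics + drivers table (one row per site-year).

    Column order: intercept; unit dummies; Time; Time x unit; driver
    mains; Time x driver; Time x driver-pair products.
    """
    df = data.copy()
    for col in ("site_id", "basin_id", "t", spec.response):
        if col not in df.columns:
            raise ValueError(f"design needs column {col!r}")
    missing = [d for d in spec.drivers if d not in df.columns]
    if missing:
        raise ValueError(f"missing driver column(s) {missing}")
    if spec.drivers:
        bad = df.loc[df[list(spec.drivers)].isna().any(axis=1), "site_id"].unique()
        if len(bad):
            raise ValueError(f"sites without driver values: {sorted(bad)[:10]}")

    if spec.drop_baseline_rows:
        df = df[df["t"] > 0]
    y_raw = df[spec.response].to_numpy(dtype=float)
    if spec.log_response:
        if np.any(y_raw <= 0):
            raise ValueError(f"log response {spec.response} requires positive values")
        y = np.log(y_raw)
    else:
        y = y_raw.copy()
    y_sd = float(y.std(ddof=1)) if spec.scale_response else 1.0
    if y_sd == 0:
        raise ValueError(f"response {spec.response} is constant")
    y = y / y_sd

    time = np.log(df["t"].to_numpy(dtype=float) + 1.0)

    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.include_intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")

    unit_levels: list[str] = []
    if spec.include_unit_effects:
        units = df["unit"].astype(str)
        unit_levels = sorted(u for u in units.unique() if u != "count")
        for u in unit_levels:
            cols.append((units == u).to_numpy(dtype=float))
            names.append(f"unit[{u}]")

    cols.append(time)
    names.append("Time")

    for u in unit_levels:
        cols.append(time * (df["unit"].astype(str) == u).to_numpy(dtype=float))
        names.append(f"Time:unit[{u}]")

    drv = {d: df[d].to_numpy(dtype=float) for d in spec.drivers}
    if spec.include_driver_mains:
        for d in spec.drivers:
            cols.append(drv[d])
            names.append(d)
    for d in spec.drivers:
        cols.append(time * drv[d])
        names.append(f"Time:{d}")
    for i, d in enumerate(spec.drivers):
        for e in spec.drivers[i + 1:]:
            cols.append(time * drv[d] * drv[e])
            names.append(f"Time:{d}:{e}")

    X = np.column_stack(cols) if cols else np.empty((len(df), 0))

    site_codes, site_ids = pd.factorize(df["site_id"], sort=True)
    basin_codes, basin_ids = pd.factorize(df["basin_id"], sort=True)
    site_basin = np.zeros(len(site_ids), dtype=int)
    site_basin[site_codes] = basin_codes

    medians = {d: float(np.median(v)) for d, v in drv.items()}
    return Design(
        X=X, names=names, y=y, time=time,
        basin_idx=basin_codes, site_idx=site_codes, site_basin=site_basin,
        basin_ids=list(basin_ids), site_ids=list(site_ids),
        y_sd=y_sd, spec=spec, unit_levels=unit_levels, driver_medians=medians,
    )


# ---------------------------------------------------------------------------
# the blocked Gibbs sampler

@dataclass
class SamplerConfig:
    n_chains: int = 4
    n_draws: int = 2000
    n_warmup: int = 1000
    seed: int | None = None
    prior_fixed_var: float = 1000.0
    prior_shape: float = 1.0
    prior_rate: float = 5e-5
    fix_resid_sd: float | None = None   # for conjugate-case validation
    loglik_max_draws: int = 1000


def _slice_sample_1d(logp, x0: float, rng: np.random.Generator,
                     w: float = 1.0, max_steps: int = 50) -> float:
    """One slice-sampling update (stepping out + shrinkage) of a 1-D density."""
    y = logp(x0) - rng.exponential()
    u = rng.random()
    lo, hi = x0 - w * u, x0 + w * (1 - u)
    for _ in range(max_steps):
        if logp(lo) <= y:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) <= y:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logp(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _sample_group_precision_collapsed(
    child_means: np.ndarray, child_counts: np.ndarray, child_tau: float,
    hyper_mean: float, tau0: float, shape0: float, rate0: float,
    rng: np.random.Generator,
) -> float:
    """Draw a group-level precision with the group means integrated out.

    ``child_means[b]`` is the average of the m_b child effects in group b,
    each child ~ N(group mean, 1/child_tau), group means ~ N(hyper_mean,
    1/tau).  The marginal ``child_means[b] ~ N(hyper_mean, 1/tau +
    1/(m_b child_tau))`` gives a 1-D conditional for tau, sampled on the
    log scale by slice sampling.  Collapsing avoids the zero-trap the
    conditional-on-group-means update falls into when the group variance
    is small.
    """
    dev2 = (child_means - hyper_mean) ** 2

    def logp(log_tau: float) -> float:
        tau = np.exp(log_tau)
        v = 1.0 / tau + 1.0 / (child_counts * child_tau)
        return (
            shape0 * log_tau - rate0 * tau
            - 0.5 * np.sum(np.log(v)) - 0.5 * np.sum(dev2 / v)
        )

    return float(np.exp(_slice_sample_1d(logp, np.log(tau0), rng)))


def _gibbs_chain(
    rng: np.random.Generator, design: Design, cfg: SamplerConfig
) -> dict[str, np.ndarray]:
    """One chain of the blocked Gibbs sampler.

    Uses the hierarchically centred parameterization — site effects are
    drawn around basin means and basin means around the fixed intercept /
    slope — which leaves the posterior unchanged but avoids the slow
    mixing (zero-trap) of the additive parameterization.  Draws are
    stored in the additive form (fixed alpha_0 / mu plus zero-mean
    deviations a_n, a_{i|n}, b_n, b_{i|n}).
    """
    X_full, y, t = design.X, design.y, design.time
    n = len(y)
    basin, site = design.basin_idx, design.site_idx
    site_basin = design.site_basin
    B = len(design.basin_ids)
    S = len(design.site_ids)
    spec = design.spec
    use_basin = B > 1
    ri = spec.random_intercepts
    rs = spec.random_slopes

    prior_prec = 1.0 / cfg.prior_fixed_var
    shape0, rate0 = cfg.prior_shape, cfg.prior_rate

    # columns absorbed into the random-effect hierarchies
    i_int = design.names.index("intercept") if (ri and "intercept" in design.names) else None
    i_time = design.names.index("Time") if (rs and "Time" in design.names) else None
    absorbed = [i for i in (i_int, i_time) if i is not None]
    keep = [j for j in range(X_full.shape[1]) if j not in absorbed]
    X = X_full[:, keep]
    p = X.shape[1]
    XtX = X.T @ X

    n_site = np.bincount(site, minlength=S).astype(float)
    t_site = np.bincount(site, weights=t, minlength=S)
    t2_site = np.bincount(site, weights=t ** 2, minlength=S)
    m_bas = np.bincount(site_basin, minlength=B).astype(float)  # sites per basin

    beta = np.zeros(p)
    alpha0 = float(y.mean()) if ri else 0.0
    mu = 0.0
    h_bas = np.full(B, alpha0)     # basin-level intercept means
    eta_site = np.full(S, alpha0)  # site-level intercepts
    m_slope = np.zeros(B)          # basin-level slope means
    v_site = np.zeros(S)           # site-level slopes
    tau = {"a_basin": 1.0, "a_site": 1.0, "b_basin": 1.0, "b_site": 1.0}
    tau_eps = (
        1.0 / cfg.fix_resid_sd ** 2 if cfg.fix_resid_sd is not None else 1.0
    )

    total = cfg.n_warmup + cfg.n_draws
    out = {
        "beta": np.empty((cfg.n_draws, X_full.shape[1])),
        "a_basin": np.empty((cfg.n_draws, B)),
        "a_site": np.empty((cfg.n_draws, S)),
        "b_basin": np.empty((cfg.n_draws, B)),
        "b_site": np.empty((cfg.n_draws, S)),
        "sigma_a_basin": np.empty(cfg.n_draws),
        "sigma_a_site": np.empty(cfg.n_draws),
        "sigma_b_basin": np.empty(cfg.n_draws),
        "sigma_b_site": np.empty(cfg.n_draws),
        "sigma_eps": np.empty(cfg.n_draws),
    }

    def hier_contrib() -> np.ndarray:
        c = np.zeros(n)
        if ri:
            c += eta_site[site]
        if rs:
            c += v_site[site] * t
        return c

    for it in range(total):
        # --- residual fixed effects (everything outside the hierarchies)
        if p:
            r = y - hier_contrib()
            A = tau_eps * XtX + prior_prec * np.eye(p)
            L = np.linalg.cholesky(A)
            bmean = cho_solve((L, True), tau_eps * (X.T @ r))
            z = rng.standard_normal(p)
            # x = mean + L^-T z  has covariance A^-1
            beta = bmean + solve_triangular(L, z, lower=True, trans="T")
        fixed = X @ beta if p else np.zeros(n)

        # --- site-level effects: joint (intercept, slope) draw per site.
        # Time is not centred, so a site's intercept and slope are strongly
        # correlated given the data; a joint 2x2 block keeps mixing fast.
        if ri and rs:
            r = y - fixed
            prior_int = h_bas[site_basin] if use_basin else alpha0
            prior_slo = m_slope[site_basin] if use_basin else mu
            s11 = tau_eps * n_site + tau["a_site"]
            s12 = tau_eps * t_site
            s22 = tau_eps * t2_site + tau["b_site"]
            b1 = tau_eps * np.bincount(site, weights=r, minlength=S) \
                + tau["a_site"] * prior_int
            b2 = tau_eps * np.bincount(site, weights=r * t, minlength=S) \
                + tau["b_site"] * prior_slo
            det = s11 * s22 - s12 ** 2
            m1 = (s22 * b1 - s12 * b2) / det
            m2 = (s11 * b2 - s12 * b1) / det
            # Cholesky of the 2x2 covariance (= precision inverse), vectorized
            c11, c12, c22 = s22 / det, -s12 / det, s11 / det
            l11 = np.sqrt(c11)
            l21 = c12 / l11
            l22 = np.sqrt(c22 - l21 ** 2)
            z1 = rng.standard_normal(S)
            z2 = rng.standard_normal(S)
            eta_site = m1 + l11 * z1
            v_site = m2 + l21 * z1 + l22 * z2

        # --- intercept hierarchy: eta_site -> h_bas -> alpha0
        if ri:
            if not rs:
                r = y - fixed
                s = np.bincount(site, weights=r, minlength=S)
                prior_mean = h_bas[site_basin] if use_basin else alpha0
                prec = tau_eps * n_site + tau["a_site"]
                eta_site = (tau_eps * s + tau["a_site"] * prior_mean) / prec \
                    + rng.standard_normal(S) / np.sqrt(prec)
            if use_basin:
                s = np.bincount(site_basin, weights=eta_site, minlength=B)
                # precision first, with basin means collapsed out
                tau["a_basin"] = _sample_group_precision_collapsed(
                    s / m_bas, m_bas, tau["a_site"], alpha0,
                    tau["a_basin"], shape0, rate0, rng,
                )
                prec = tau["a_site"] * m_bas + tau["a_basin"]
                h_bas = (tau["a_site"] * s + tau["a_basin"] * alpha0) / prec \
                    + rng.standard_normal(B) / np.sqrt(prec)
                prec0 = tau["a_basin"] * B + prior_prec
                alpha0 = tau["a_basin"] * h_bas.sum() / prec0 \
                    + rng.standard_normal() / np.sqrt(prec0)
            else:
                prec0 = tau["a_site"] * S + prior_prec
                alpha0 = tau["a_site"] * eta_site.sum() / prec0 \
                    + rng.standard_normal() / np.sqrt(prec0)

        # --- slope hierarchy: v_site -> m_slope -> mu
        if rs:
            if not ri:
                r = y - fixed
                s = np.bincount(site, weights=r * t, minlength=S)
                prior_mean = m_slope[site_basin] if use_basin else mu
                prec = tau_eps * t2_site + tau["b_site"]
                v_site = (tau_eps * s + tau["b_site"] * prior_mean) / prec \
                    + rng.standard_normal(S) / np.sqrt(prec)
            if use_basin:
                s = np.bincount(site_basin, weights=v_site, minlength=B)
                tau["b_basin"] = _sample_group_precision_collapsed(
                    s / m_bas, m_bas, tau["b_site"], mu,
                    tau["b_basin"], shape0, rate0, rng,
                )
                prec = tau["b_site"] * m_bas + tau["b_basin"]
                m_slope = (tau["b_site"] * s + tau["b_basin"] * mu) / prec \
                    + rng.standard_normal(B) / np.sqrt(prec)
                prec0 = tau["b_basin"] * B + prior_prec
                mu = tau["b_basin"] * m_slope.sum() / prec0 \
                    + rng.standard_normal() / np.sqrt(prec0)
            else:
                prec0 = tau["b_site"] * S + prior_prec
                mu = tau["b_site"] * v_site.sum() / prec0 \
                    + rng.standard_normal() / np.sqrt(prec0)

        # --- remaining precisions (basin levels updated collapsed, above)
        if ri:
            dev = eta_site - (h_bas[site_basin] if use_basin else alpha0)
            tau["a_site"] = rng.gamma(shape0 + S / 2, 1.0 / (rate0 + 0.5 * dev @ dev))
        if rs:
            dev = v_site - (m_slope[site_basin] if use_basin else mu)
            tau["b_site"] = rng.gamma(shape0 + S / 2, 1.0 / (rate0 + 0.5 * dev @ dev))
        resid = y - fixed - hier_contrib()
        if cfg.fix_resid_sd is None:
            tau_eps = rng.gamma(shape0 + n / 2, 1.0 / (rate0 + 0.5 * resid @ resid))

        k = it - cfg.n_warmup
        if k >= 0:
            full_beta = np.zeros(X_full.shape[1])
            full_beta[keep] = beta
            if i_int is not None:
                full_beta[i_int] = alpha0
            if i_time is not None:
                full_beta[i_time] = mu
            out["beta"][k] = full_beta
            if ri and use_basin:
                out["a_basin"][k] = h_bas - alpha0
                out["a_site"][k] = eta_site - h_bas[site_basin]
            else:
                out["a_basin"][k] = 0.0
                out["a_site"][k] = eta_site - alpha0 if ri else 0.0
            if rs and use_basin:
                out["b_basin"][k] = m_slope - mu
                out["b_site"][k] = v_site - m_slope[site_basin]
            else:
                out["b_basin"][k] = 0.0
                out["b_site"][k] = v_site - mu if rs else 0.0
            out["sigma_a_basin"][k] = 1.0 / np.sqrt(tau["a_basin"])
            out["sigma_a_site"][k] = 1.0 / np.sqrt(tau["a_site"])
            out["sigma_b_basin"][k] = 1.0 / np.sqrt(tau["b_basin"])
            out["sigma_b_site"][k] = 1.0 / np.sqrt(tau["b_site"])
            out["sigma_eps"][k] = 1.0 / np.sqrt(tau_eps)
    return out


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat convergence diagnostic for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half
    before computing the between/within variance ratio.
    """
    halves = []
    for ch in chains:
        m = len(ch) // 2
        halves.extend([ch[:m], ch[m:2 * m]])
    arr = np.asarray(halves, dtype=float)
    m, n = arr.shape
    if n < 2:
        return np.nan
    means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# posterior summaries

def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding ``mass`` of the draws.

    Ties on width resolve to the first (lowest) such window.
    """
    if not (0 < mass < 1):
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 + np.arange(n - m + 1)] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def classify_evidence(draws: np.ndarray) -> str:
    """Evidence tier from nested HPD intervals excluding zero.

    strong if the 95% HPD excludes 0, else moderate (90%), else weak
    (80%), else none.
    """
    for mass, tier in ((0.95, "strong"), (0.90, "moderate"), (0.80, "weak")):
        lo, hi = hpd_interval(draws, mass)
        if lo > 0 or hi < 0:
            return tier
    return "none"


def percent_per_decade(slope: np.ndarray | float) -> np.ndarray | float:
    """Percent change per decade implied by a slope on the
    log-response / log(year+1)-time scale: (e^(slope * ln 11) - 1) * 100."""
    return (np.exp(np.asarray(slope, dtype=float) * LOG_DECADE) - 1.0) * 100.0


def units_per_decade(slope: np.ndarray | float) -> np.ndarray | float:
    """Change per decade for identity-scale responses: slope * ln 11."""
    return np.asarray(slope, dtype=float) * LOG_DECADE


def waic_from_loglik(loglik: np.ndarray) -> float:
    """WAIC = -2 (lppd - p_waic) from a (draws x observations) pointwise
    log-likelihood matrix, with p_waic the summed posterior variances."""
    from scipy.special import logsumexp

    d = loglik.shape[0]
    lppd = float(np.sum(logsumexp(loglik, axis=0) - np.log(d)))
    p_waic = float(np.sum(loglik.var(axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic)


def vif(X: np.ndarray, names: list[str] | None = None) -> pd.Series:
    """Variance inflation factors, 1 / (1 - R^2_j), one per column.

    Exactly collinear columns report infinity.  Columns are regressed on
    all the others (with an intercept added when absent).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two columns")
    names = names or [f"x{j}" for j in range(p)]
    out = {}
    has_const = np.any(np.all(X == X[0], axis=0))
    for j in range(p):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        if not has_const:
            others = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out[names[j]] = np.inf if has_const else 1.0
            continue
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# the estimator

class HierarchicalTrendModel(BaseEstimator):
    """Bayesian hierarchical trend model for one community metric.

    Parameters
    ----------
    spec : ModelSpec or str
        A full specification, or a response name (resolved through
        :func:`response_spec`).
    with_drivers : bool
        When ``spec`` is a name: include the driver covariates and their
        time interactions.
    n_chains, n_draws, n_warmup : int
        Sampler schedule; ``n_draws`` are kept per chain after warm-up.
    seed : int or None
        Seed for the sampler's random number generator.

    After ``fit`` the posterior is in ``draws_`` (a dict of arrays over
    all chains), convergence diagnostics in ``rhat_``, and the summaries
    are exposed by :meth:`coefficient_table`, :meth:`site_trends`,
    :meth:`global_trend`, :meth:`r2`, :meth:`waic` and
    :meth:`predict_baseline`.
    """

    def __init__(
        self,
        spec: ModelSpec | str = "total_abundance",
        with_drivers: bool = False,
        n_chains: int = 4,
        n_draws: int = 2000,
        n_warmup: int = 1000,
        seed: int | None = None,
        prior_fixed_var: float = 1000.0,
        prior_shape: float = 1.0,
        prior_rate: float = 5e-5,
        fix_resid_sd: float | None = None,
        loglik_max_draws: int = 1000,
    ):
        self.spec = spec
        self.with_drivers = with_drivers
        self.n_chains = n_chains
        self.n_draws = n_draws
        self.n_warmup = n_warmup
        self.seed = seed
        self.prior_fixed_var = prior_fixed_var
        self.prior_shape = prior_shape
        self.prior_rate = prior_rate
        self.fix_resid_sd = fix_resid_sd
        self.loglik_max_draws = loglik_max_draws

    # -- fitting ----------------------------------------------------------

    def _resolve_spec(self) -> ModelSpec:
        if isinstance(self.spec, ModelSpec):
            return self.spec
        return response_spec(self.spec, with_drivers=self.with_drivers)

    def fit(self, data: pd.DataFrame, y=None) -> "HierarchicalTrendModel":
        spec = self._resolve_spec()
        design = build_design(data, spec)
        if design.X.shape[0] <= design.X.shape[1]:
            raise ValueError("more fixed effects than observations")
        if len(design.basin_ids) == 1 and (spec.random_intercepts or spec.random_slopes):
            warnings.warn(
                "single basin: basin-level random effects dropped, site-only model",
                UserWarning,
            )
        cfg = SamplerConfig(
            n_chains=self.n_chains, n_draws=self.n_draws, n_warmup=self.n_warmup,
            seed=self.seed, prior_fixed_var=self.prior_fixed_var,
            prior_shape=self.prior_shape, prior_rate=self.prior_rate,
            fix_resid_sd=self.fix_resid_sd, loglik_max_draws=self.loglik_max_draws,
        )
        ss = np.random.SeedSequence(self.seed)
        chains = [
            _gibbs_chain(np.random.default_rng(child), design, cfg)
            for child in ss.spawn(cfg.n_chains)
        ]
        self.design_ = design
        self.draws_ = {
            k: np.concatenate([c[k] for c in chains], axis=0) for k in chains[0]
        }
        p = design.X.shape[1]
        self.rhat_ = pd.Series(
            {
                design.names[j]: split_rhat(
                    np.stack([c["beta"][:, j] for c in chains])
                )
                for j in range(p)
            },
            name="rhat",
        )
        if np.any(self.rhat_.to_numpy() > 1.05):
            warnings.warn(
                f"split-Rhat above 1.05 for: "
                f"{self.rhat_[self.rhat_ > 1.05].index.tolist()}",
                UserWarning,
            )
        self._compute_loglik(cfg)
        return self

    def _linear_predictor(self, idx: np.ndarray) -> np.ndarray:
        """Full (fixed + random) predictor for a subset of draws."""
        d = self.design_
        dr = self.draws_
        eta = dr["beta"][idx] @ d.X.T
        use_basin = len(d.basin_ids) > 1
        if d.spec.random_intercepts:
            if use_basin:
                eta += dr["a_basin"][idx][:, d.basin_idx]
            eta += dr["a_site"][idx][:, d.site_idx]
        if d.spec.random_slopes:
            slope = dr["b_site"][idx][:, d.site_idx]
            if use_basin:
                slope = slope + dr["b_basin"][idx][:, d.basin_idx]
            eta += slope * d.time[None, :]
        return eta

    def _compute_loglik(self, cfg: SamplerConfig) -> None:
        d = self.design_
        total = self.draws_["beta"].shape[0]
        keep = min(cfg.loglik_max_draws, total)
        idx = np.linspace(0, total - 1, keep).astype(int)
        eta = self._linear_predictor(idx)
        sd = self.draws_["sigma_eps"][idx][:, None]
        resid = d.y[None, :] - eta
        self.loglik_ = (
            -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * (resid / sd) ** 2
        )
        self._loglik_idx_ = idx

    # -- summaries --------------------------------------------------------

    @property
    def coef_names_(self) -> list[str]:
        return self.design_.names

    def coefficient_table(self) -> pd.DataFrame:
        """Posterior mean, 80/90/95% HPD bounds and evidence tier for every
        fixed effect (on the standardized model scale)."""
        rows = []
        for j, name in enumerate(self.design_.names):
            dr = self.draws_["beta"][:, j]
            row = {"term": name, "mean": float(dr.mean())}
            for mass in (0.80, 0.90, 0.95):
                lo, hi = hpd_interval(dr, mass)
                pct = int(mass * 100)
                row[f"hpd{pct}_lo"], row[f"hpd{pct}_hi"] = lo, hi
            row["evidence"] = classify_evidence(dr)
            rows.append(row)
        return pd.DataFrame(rows)

    def variance_components(self) -> pd.DataFrame:
        """Posterior summaries of the random-effect and residual SDs."""
        rows = []
        for key in ("sigma_a_basin", "sigma_a_site", "sigma_b_basin",
                    "sigma_b_site", "sigma_eps"):
            dr = self.draws_[key]
            lo, hi = hpd_interval(dr, 0.95)
            rows.append({"component": key, "mean": float(dr.mean()),
                         "hpd95_lo": lo, "hpd95_hi": hi})
        return pd.DataFrame(rows)

    def _slope_draws_natural(self) -> np.ndarray:
        """Global time-slope draws on the natural (unscaled) response scale."""
        j = self.design_.names.index("Time")
        return self.draws_["beta"][:, j] * self.design_.y_sd

    def global_trend(self) -> dict:
        """Average temporal trend with HPD bounds, evidence tier and the
        per-decade back-transform appropriate for the response scale."""
        d = self.design_
        slope = self._slope_draws_natural()
        decade = (
            percent_per_decade(slope) if d.spec.log_response else units_per_decade(slope)
        )
        out = {
            "response": d.spec.response,
            "slope_mean": float(slope.mean()),
            "trend_per_decade": float(np.mean(decade)),
            "evidence": classify_evidence(slope),
            "unit": "percent" if d.spec.log_response else "natural",
        }
        for mass in (0.80, 0.90, 0.95):
            lo, hi = hpd_interval(decade, mass)
            pct = int(mass * 100)
            out[f"hpd{pct}_lo"], out[f"hpd{pct}_hi"] = lo, hi
        return out

    def site_trends(self) -> pd.DataFrame:
        """Per-site posterior-mean temporal trend (mu + b_n + b_{i|n}).

        Returns natural-scale slopes and the per-decade trend (percent for
        log responses, response units otherwise), one row per site.
        """
        d = self.design_
        j = d.names.index("Time")
        mu = self.draws_["beta"][:, j][:, None]
        slopes = mu + self.draws_["b_site"]
        if len(d.basin_ids) > 1:
            slopes = slopes + self.draws_["b_basin"][:, d.site_basin]
        slopes = slopes * d.y_sd
        mean_slope = slopes.mean(axis=0)
        decade = (
            percent_per_decade(mean_slope)
            if d.spec.log_response else units_per_decade(mean_slope)
        )
        return pd.DataFrame(
            {
                "site_id": d.site_ids,
                "basin_id": [d.basin_ids[b] for b in d.site_basin],
                "slope": mean_slope,
                "trend_per_decade": decade,
            }
        )

    def r2(self) -> dict:
        """Marginal and conditional R^2 (posterior mean and 95% HPD).

        Per draw: Var_fit is the variance of the fixed-effect predictions;
        only the intercept random-effect variances enter the conditional
        numerator; the denominator adds the residual variance of that draw.
        """
        d = self.design_
        n_draw = self.draws_["beta"].shape[0]
        idx = np.linspace(0, n_draw - 1, min(1000, n_draw)).astype(int)
        yhat = self.draws_["beta"][idx] @ d.X.T
        var_fit = yhat.var(axis=1, ddof=1)
        eta = self._linear_predictor(idx)
        var_res = (d.y[None, :] - eta).var(axis=1, ddof=1)
        var_a = np.zeros(len(idx))
        if d.spec.random_intercepts:
            var_a = self.draws_["sigma_a_site"][idx] ** 2
            if len(d.basin_ids) > 1:
                var_a = var_a + self.draws_["sigma_a_basin"][idx] ** 2
        denom = var_fit + var_a + var_res
        r2m = var_fit / denom
        r2c = (var_fit + var_a) / denom
        out = {"r2_marginal": float(r2m.mean()), "r2_conditional": float(r2c.mean())}
        out["r2_marginal_hpd95"] = hpd_interval(r2m, 0.95)
        out["r2_conditional_hpd95"] = hpd_interval(r2c, 0.95)
        return out

    def waic(self) -> float:
        return waic_from_loglik(self.loglik_)

    def vif(self) -> pd.Series:
        d = self.design_
        if d.X.shape[1] < 2:
            raise ValueError("VIF needs at least two fixed-effect columns")
        return vif(d.X, d.names)

    # -- baseline predictions ---------------------------------------------

    def _baseline_row(self, driver_values: dict | None) -> np.ndarray:
        """Fixed-effect row at t = 0, reference unit, given driver values
        (medians where unspecified)."""
        d = self.design_
        values = dict(d.driver_medians)
        if driver_values:
            values.update(driver_values)
        row = np.zeros(len(d.names))
        for j, name in enumerate(d.names):
            if name == "intercept":
                row[j] = 1.0
            elif name in values:
                row[j] = values[name]
            # Time, Time:* and unit dummies stay 0 at baseline
        return row

    def predict_baseline(self, driver_values: dict | None = None) -> dict:
        """Posterior predictive mean response at t = 0 on the natural scale.

        Non-specified drivers sit at their observed medians; the abundance
        unit is the reference level (raw count).  Warns when a requested
        driver value falls outside the observed range.
        """
        d = self.design_
        if driver_values:
            for k, v in driver_values.items():
                col = d.names.index(k) if k in d.names else None
                if col is not None:
                    lo, hi = d.X[:, col].min(), d.X[:, col].max()
                    if not (lo <= v <= hi):
                        warnings.warn(f"{k}={v} outside observed range [{lo:.3g}, {hi:.3g}]")
        row = self._baseline_row(driver_values)
        eta = self.draws_["beta"] @ row
        natural = eta * d.y_sd
        pred = np.exp(natural) if d.spec.log_response else natural
        lo, hi = hpd_interval(pred, 0.95)
        return {"mean": float(pred.mean()), "hpd95_lo": lo, "hpd95_hi": hi,
                "draws": pred}

    def baseline_contrast(
        self, driver: str, value_a: float, value_b: float
    ) -> dict:
        """Percent difference of baseline predictions at two driver values:
        100 * (pred(a) / pred(b) - 1), with a 95% HPD."""
        pa = self.predict_baseline({driver: value_a})["draws"]
        pb = self.predict_baseline({driver: value_b})["draws"]
        ratio = 100.0 * (pa / pb - 1.0)
        lo, hi = hpd_interval(ratio, 0.95)
        return {"mean": float(ratio.mean()), "hpd95_lo": lo, "hpd95_hi": hi,
                "draws": ratio}


def fit_posterior(
    data: pd.DataFrame,
    spec: ModelSpec | str,
    with_drivers: bool = False,
    **sampler_kwargs,
) -> HierarchicalTrendModel:
    """Functional wrapper: fit the hierarchical model and return it."""
    model = HierarchicalTrendModel(spec=spec, with_drivers=with_drivers, **sampler_kwargs)
    return model.fit(data)


def trend_characteristics_check(
    trend_table: pd.DataFrame, series_summary: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rank correlations of per-site trends against time-series
    characteristics (span, completeness, first year).

    A constant trend column yields undefined correlations, reported NaN.
    """
    merged = trend_table.merge(series_summary, on="site_id")
    rows = []
    trend = merged["trend_per_decade"].to_numpy(dtype=float)
    for char in ("span_years", "completeness", "first_year"):
        x = merged[char].to_numpy(dtype=float)
        if np.all(trend == trend[0]) or np.all(x == x[0]):
            rho = np.nan
        else:
            rho = float(np.corrcoef(rankdata(trend), rankdata(x))[0, 1])
        rows.append({"characteristic": char, "spearman_rho": rho, "n": len(merged)})
    return pd.DataFrame(rows)
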