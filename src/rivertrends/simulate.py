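"""Synthetic data with the statistical structure the analysis assumes.

Three generators, each seeded and returning its ground truth:

* :func:`simulate_from_model` draws Gaussian responses exactly under the
  hierarchical trend model (nested random intercepts/slopes on
  log(year+1) time), for parameter-recovery and calibration experiments;
* :func:`simulate_drivers` builds per-site covariate tables with
  near-independent drivers, footprint values on the 0-50 index with most
  sites above the degradation threshold of 4, and five stream variables
  organized along one latent upstream-downstream gradient;
* :func:`simulate_communities` emits long-format survey records whose
  implied community metrics carry configured trends: lognormal
  abundances with multiplicative drift, species replacement at a set
  rate, non-native introductions concentrated at high-footprint sites,
  mixed abundance units, and missing years.

Default variance components make the site-level slope spread twice the
basin-level spread, the ordering the analysis is expected to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import COVARIATE_COLUMNS

UNIT_MIX = {"count": 0.47, "density_100m2": 0.5181, "cpue": 0.0105, "leslie": 0.0014}


@dataclass
class SimConfig:
    """Conditions for the synthetic generators.

    Variance components default to a site-level slope SD twice the
    basin-level one; the time covariate is log(years since start + 1).
    """

    n_basins: int = 30
    sites_per_basin: int = 8
    n_years: int = 15
    completeness: float = 0.8       # probability a year is sampled (ends kept)
    first_year: int = 1995

    # fixed effects (on the model's response scale)
    alpha0: float = 2.0
    mu: float = 0.3                  # global time slope
    beta_x: dict = field(default_factory=dict)          # driver main effects
    beta_tx: dict = field(default_factory=dict)         # Time x driver
    beta_txx: dict = field(default_factory=dict)        # Time x driver x driver

    # variance components
    sigma_a_basin: float = 0.1
    sigma_a_site: float = 0.2
    sigma_b_basin: float = 0.1
    sigma_b_site: float = 0.2       # 2x the basin-level slope SD
    sigma_eps: float = 0.5

    # community generator
    species_pool: int = 40          # native pool size per basin
    richness_mean: float = 12.0     # expected baseline richness per site
    nonnative_pool: int = 12        # shared non-native pool size
    introduction_rate: float = 0.15  # yearly introduction prob at footprint 50
    replacement_rate: float = 0.03   # yearly species-replacement probability
    abundance_drift: float = 0.05    # site-mean multiplicative drift (log scale)

    seed: int | None = None


@dataclass
class GroundTruth:
    """Everything the generator knew: coefficients and per-site slopes."""

    coefficients: dict
    site_slopes: pd.DataFrame
    cluster_labels: pd.Series | None = None


def _site_frame(cfg: SimConfig) -> pd.DataFrame:
    sites = []
    for b in range(cfg.n_basins):
        for s in range(cfg.sites_per_basin):
            sites.append({"site_id": f"B{b:03d}S{s:03d}", "basin_id": f"B{b:03d}"})
    return pd.DataFrame(sites)


def _sampled_years(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    keep = rng.random(cfg.n_years) < cfg.completeness
    keep[0] = keep[-1] = True  # span is fixed; completeness varies
    return np.flatnonzero(keep)


def simulate_from_model(
    cfg: SimConfig | None = None,
    drivers: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw responses exactly under the hierarchical Gaussian trend model.

    When a driver table is given (with X_past / X_change / X_stream per
    site), main effects and interactions from ``cfg.beta_*`` enter the
    mean.  Returns a long table with columns ``site_id, basin_id, t, y``
    (plus driver columns) and the ground truth.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    sites = _site_frame(cfg)
    n_sites = len(sites)
    basins = sites["basin_id"].unique()

    a_bas = rng.normal(0, cfg.sigma_a_basin, len(basins))
    b_bas = rng.normal(0, cfg.sigma_b_basin, len(basins))
    a_site = rng.normal(0, cfg.sigma_a_site, n_sites)
    b_site = rng.normal(0, cfg.sigma_b_site, n_sites)
    basin_of = {b: i for i, b in enumerate(basins)}

    if drivers is not None:
        drv = drivers.set_index("site_id")
    rows = []
    slopes = []
    for i, site in sites.iterrows():
        bi = basin_of[site["basin_id"]]
        slope = cfg.mu + b_bas[bi] + b_site[i]
        slopes.append(slope)
        x = {}
        if drivers is not None:
            x = {k: float(drv.loc[site["site_id"], k]) for k in ("X_past", "X_change", "X_stream")}
        years = _sampled_years(rng, cfg)
        for t in years:
            time = np.log(t + 1.0)
            mean = cfg.alpha0 + a_bas[bi] + a_site[i] + slope * time
            for k, v in cfg.beta_x.items():
                mean += v * x[k]
            for k, v in cfg.beta_tx.items():
                mean += v * time * x[k]
            for (k, l), v in cfg.beta_txx.items():
                mean += v * time * x[k] * x[l]
            y = mean + rng.normal(0, cfg.sigma_eps)
            row = {"site_id": site["site_id"], "basin_id": site["basin_id"],
                   "t": int(t), "y": y}
            row.update(x)
            rows.append(row)
    data = pd.DataFrame(rows)
    truth = GroundTruth(
        coefficients={
            "alpha0": cfg.alpha0, "mu": cfg.mu,
            "sigma_a_basin": cfg.sigma_a_basin, "sigma_a_site": cfg.sigma_a_site,
            "sigma_b_basin": cfg.sigma_b_basin, "sigma_b_site": cfg.sigma_b_site,
            "sigma_eps": cfg.sigma_eps,
            **{f"beta_{k}": v for k, v in cfg.beta_x.items()},
            **{f"beta_t_{k}": v for k, v in cfg.beta_tx.items()},
            **{f"beta_t_{k}_{l}": v for (k, l), v in cfg.beta_txx.items()},
        },
        site_slopes=pd.DataFrame(
            {"site_id": sites["site_id"], "true_slope": slopes}
        ),
    )
    return data, truth


def simulate_drivers(
    n_sites: int | None = None,
    cfg: SimConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-site covariate table with near-independent drivers.

    The 1993 footprint puts ~92% of sites above the degradation threshold
    of 4; the 2009/1993 ratio averages slightly below 1 (pressures easing
    on average); the five stream variables load on one latent
    upstream-downstream gradient independent of the footprint, so the
    pairwise driver correlations stay near zero.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    if n_sites is None:
        sites = _site_frame(cfg)
    else:
        per = max(1, n_sites // cfg.n_basins)
        sites = _site_frame(
            SimConfig(n_basins=int(np.ceil(n_sites / per)), sites_per_basin=per)
        ).head(n_sites)
    n = len(sites)

    degraded = rng.random(n) < 0.92
    hfi93 = np.where(
        degraded,
        4.0 + 46.0 * rng.beta(1.6, 4.0, n),
        0.2 + 3.8 * rng.random(n),
    )
    log2_ratio = rng.normal(-0.06, 0.35, n)  # mild average easing of pressure
    hfi09 = np.clip(hfi93 * 2.0 ** log2_ratio, 0.0, 50.0)

    g = rng.normal(0, 1, n)  # latent upstream(-)/downstream(+) gradient
    noise = lambda s: rng.normal(0, s, n)
    covs = pd.DataFrame(
        {
            "site_id": sites["site_id"],
            "basin_id": sites["basin_id"],
            "hfi_1993": hfi93,
            "hfi_2009": hfi09,
            "altitude_m": np.exp(5.5 - 0.8 * g + noise(0.4)),
            "slope_deg": np.exp(0.5 - 0.6 * g + noise(0.5)),
            "discharge_m3s": np.exp(1.0 + 1.2 * g + noise(0.4)),
            "dist_source_km": np.exp(3.0 + 1.0 * g + noise(0.4)),
            "strahler": np.clip(np.round(3.5 + 1.4 * g + noise(0.5)), 1, 9),
            "limed": False,
            "realm": rng.choice(
                ["Palearctic", "Nearctic", "Australasia"], size=n, p=[0.75, 0.20, 0.05]
            ),
        }
    )[COVARIATE_COLUMNS]
    covs.attrs["latent_gradient"] = g
    return covs


def simulate_communities(
    cfg: SimConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Long-format survey records with configured community-level trends.

    Returns ``(records, covariates, origin_table, truth)``.  Abundances
    are lognormal with a site-specific multiplicative yearly drift drawn
    from the nested slope hierarchy; species are replaced at
    ``replacement_rate`` per year (driving the dissimilarities); a shared
    non-native pool is introduced with a yearly probability proportional
    to the site's 1993 footprint; units are mixed across sites and years
    are thinned to the configured completeness.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    sites = _site_frame(cfg)
    covs = simulate_drivers(cfg=cfg, seed=int(rng.integers(2 ** 31)))
    covs = covs.iloc[: len(sites)].reset_index(drop=True)
    basins = sites["basin_id"].unique()
    basin_of = {b: i for i, b in enumerate(basins)}

    b_bas = rng.normal(0, cfg.sigma_b_basin, len(basins))
    b_site = rng.normal(0, cfg.sigma_b_site, len(sites))

    # species pools: per-basin natives, one shared non-native pool
    native_pool = {
        b: [f"sp_{b}_{j:03d}" for j in range(cfg.species_pool)] for b in basins
    }
    nn_pool = [f"nn_{j:03d}" for j in range(cfg.nonnative_pool)]

    units = rng.choice(list(UNIT_MIX), size=len(sites), p=list(UNIT_MIX.values()))
    records = []
    slopes = []
    hfi = covs.set_index("site_id")["hfi_1993"]
    for i, site in sites.iterrows():
        sid, bid = site["site_id"], site["basin_id"]
        bi = basin_of[bid]
        drift = cfg.abundance_drift + b_bas[bi] + b_site[i]
        slopes.append(drift)
        pool = list(native_pool[bid])
        s0 = min(len(pool), max(3, rng.poisson(cfg.richness_mean)))
        present = list(rng.choice(pool, size=s0, replace=False))
        absent = [s for s in pool if s not in present]
        base_abund = {
            s: float(np.exp(rng.normal(2.0, 1.0))) for s in present
        }
        p_intro = cfg.introduction_rate * float(hfi[sid]) / 50.0
        unit = units[i]
        scale = 1.0 if unit == "count" else float(np.exp(rng.normal(0, 0.5)))
        years = _sampled_years(rng, cfg)
        sample_doy = int(rng.integers(152, 213))  # June-July sampling window
        for t in range(cfg.n_years):
            # community dynamics advance every year, sampled or not
            if t > 0:
                if absent and rng.random() < cfg.replacement_rate * len(present):
                    lost = present[int(rng.integers(len(present)))]
                    gained = absent[int(rng.integers(len(absent)))]
                    present.remove(lost)
                    absent.append(lost)
                    absent.remove(gained)
                    present.append(gained)
                    base_abund[gained] = float(np.exp(rng.normal(2.0, 1.0)))
                if rng.random() < p_intro:
                    new = [s for s in nn_pool if s not in present]
                    if new:
                        sp = new[int(rng.integers(len(new)))]
                        present.append(sp)
                        base_abund[sp] = float(np.exp(rng.normal(1.0, 1.0)))
            if t not in years:
                continue
            date = pd.Timestamp(cfg.first_year + t, 1, 1) + pd.Timedelta(
                days=sample_doy - 1
            )
            growth = np.exp(drift * np.log(t + 1.0))
            for s in present:
                ab = base_abund[s] * growth * float(np.exp(rng.normal(0, 0.3)))
                if unit == "count":
                    ab = max(1.0, np.round(ab))
                else:
                    ab = max(ab * scale, 1e-3)
                records.append(
                    {
                        "site_id": sid, "basin_id": bid, "date": date,
                        "protocol": "electrofishing", "species_id": s,
                        "abundance": float(ab), "unit": unit,
                    }
                )
    records = pd.DataFrame(records)

    origin_rows = []
    for b in basins:
        for s in native_pool[b]:
            origin_rows.append({"species_id": s, "basin_id": b, "country": "",
                                "origin": "native"})
        for s in nn_pool:
            origin_rows.append({"species_id": s, "basin_id": b, "country": "",
                                "origin": "nonnative"})
    origin = pd.DataFrame(origin_rows)

    truth = GroundTruth(
        coefficients={"abundance_drift": cfg.abundance_drift,
                      "introduction_rate": cfg.introduction_rate,
                      "replacement_rate": cfg.replacement_rate},
        site_slopes=pd.DataFrame({"site_id": sites["site_id"], "true_slope": slopes}),
    )
    return records, covs, origin, truth


def simulate_clustered_trends(
    n_per_cluster: int = 50,
    n_outliers: int | None = None,
    spread: float = 0.35,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Six archetypal trend profiles plus gross outliers, for typology tests.

    Archetypes mirror the trajectory types the clustering is meant to
    find: medium change on all axes, high turnover, strong richness
    increase, abundance decline, richness decline, low change.  Returns
    ``(X, labels)`` with outliers labelled -1.
    """
    rng = np.random.default_rng(seed)
    archetypes = np.array(
        [
            [0.5, 0.5, 0.5, 0.5],     # medium change
            [0.3, 0.3, 0.5, 2.5],     # high turnover
            [0.2, 2.5, 0.2, 0.3],     # richness increase
            [-2.5, 0.0, 0.3, 0.3],    # abundance decline
            [0.1, -2.5, 0.3, 0.3],    # richness decline
            [0.0, 0.0, 0.05, 0.05],   # low change
        ]
    )
    X, labels = [], []
    for j, c in enumerate(archetypes):
        X.append(rng.normal(c, spread, size=(n_per_cluster, 4)))
        labels.extend([j] * n_per_cluster)
    if n_outliers is None:
        n_outliers = int(np.ceil(0.05 * 6 * n_per_cluster / 0.95))
    X.append(rng.uniform(-8, 8, size=(n_outliers, 4)))
    labels.extend([-1] * n_outliers)
    return np.vstack(X), np.asarray(labels)
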