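"""End-to-end orchestration: filter -> metrics -> drivers -> fit -> typology."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import drivers as drv
from . import filtering, io, metrics, model, simulate, typology

log = logging.getLogger("rivertrends")

#: responses fitted in a full run, in reporting order
DEFAULT_RESPONSES = (
    "total_abundance", "richness_cov", "prop_nn_abund", "prop_nn_rich",
    "simpson_dissim", "turnover",
)


@dataclass
class RunConfig:
    """Everything a reproducible run needs; serializable to YAML."""

    survey_path: str | None = None
    covariates_path: str | None = None
    origin_path: str | None = None
    synthetic: bool = True          # generate inputs when paths are absent
    out_dir: str = "rivertrends_out"
    seed: int = 0

    # filtering
    min_years: int = 5
    min_span: int = 9
    window_days: float = 45.0

    # metrics
    target_coverage: float = 0.985

    # model
    responses: tuple[str, ...] = DEFAULT_RESPONSES
    n_chains: int = 2
    n_draws: int = 500
    n_warmup: int = 500
    with_drivers: bool = True

    # typology
    n_clusters: int = 6
    alpha: float = 0.05
    affiliation_threshold: float = 1.5
    n_starts: int = 50

    # synthetic generation
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["responses"] = list(d["responses"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 — re-raised with context
                raise StageError(name, e) from e
        return wrapper
    return deco


@_stage("inputs")
def load_inputs(cfg: RunConfig):
    if cfg.survey_path:
        origin = io.read_origin_table(cfg.origin_path) if cfg.origin_path else None
        records = io.read_survey_table(cfg.survey_path, origin_table=origin)
        covs = io.read_site_covariates(cfg.covariates_path)
        return records, covs
    if not cfg.synthetic:
        raise ValueError("no input paths and synthetic generation disabled")
    sim_cfg = simulate.SimConfig(**cfg.sim) if cfg.sim else simulate.SimConfig()
    records, covs, origin, _truth = simulate.simulate_communities(sim_cfg, seed=cfg.seed)
    records["origin"] = io.lookup_origin(records, origin)
    return records, covs


@_stage("filter")
def run_filter(records, covs, cfg: RunConfig):
    params = filtering.FilterParams(
        min_years=cfg.min_years, min_span=cfg.min_span, window_days=cfg.window_days
    )
    return filtering.filter_series(records, covs, params)


@_stage("metrics")
def run_metrics(records, cfg: RunConfig):
    return metrics.metrics_table(records, target_coverage=cfg.target_coverage)


@_stage("drivers")
def run_drivers(covs, cfg: RunConfig):
    table = drv.build_drivers(covs)
    _, loadings = drv.stream_position_axis(covs)
    return table, loadings


@_stage("fit")
def run_fits(metric_table, driver_table, cfg: RunConfig, with_drivers: bool):
    data = metric_table.merge(
        driver_table[["site_id", "X_past", "X_change", "X_stream"]], on="site_id"
    )
    fits = {}
    for j, resp in enumerate(cfg.responses):
        fits[resp] = model.HierarchicalTrendModel(
            spec=resp, with_drivers=with_drivers,
            n_chains=cfg.n_chains, n_draws=cfg.n_draws, n_warmup=cfg.n_warmup,
            seed=cfg.seed + 101 * (j + 1),
        ).fit(data)
    return fits


@_stage("typology")
def run_typology(fits, covs, cfg: RunConfig):
    trends = {r: f.site_trends() for r, f in fits.items()}
    variables = tuple(
        v for v in typology.TREND_VARIABLES if v in trends
    )
    mat = typology.trend_matrix(trends, variables)
    # standardized units for clustering; per-decade trends are reported
    z = (mat - mat.mean()) / mat.std(ddof=1)
    pca = typology.TrendPCA().fit(mat)
    km = typology.TrimmedKMeans(
        n_clusters=cfg.n_clusters, alpha=cfg.alpha, n_starts=cfg.n_starts,
        random_state=cfg.seed,
    ).fit(z.to_numpy())
    labels = typology.affiliation_filter(km, z.to_numpy(), cfg.affiliation_threshold)
    realms = (
        covs.set_index("site_id")["realm"].reindex(mat.index)
        if "realm" in covs.columns else None
    )
    freq = typology.cluster_frequencies(labels, realms)
    assign = pd.DataFrame({"site_id": mat.index, "cluster": labels})
    return {"matrix": mat, "pca": pca, "kmeans": km, "labels": assign, "freq": freq}


def run_all(cfg: RunConfig) -> dict:
    """Execute the whole pipeline and write every intermediate table.

    Returns a dict with the in-memory results; all tables also land under
    ``cfg.out_dir`` together with the archived config and an audit log.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    records, covs = load_inputs(cfg)
    clean, audit = run_filter(records, covs, cfg)
    io.write_table(audit, out / "filter_audit.csv")
    io.write_table(clean, out / "records_filtered.csv")

    summary = filtering.summarize_series(clean)
    with open(out / "series_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    per_site = filtering.series_summary_per_site(clean)
    io.write_table(per_site, out / "series_per_site.csv")

    metric_table = run_metrics(clean, cfg)
    io.write_table(metric_table, out / "metrics.csv")

    driver_table, loadings = run_drivers(covs, cfg)
    io.write_table(driver_table, out / "drivers.csv")
    io.write_table(loadings.reset_index(names="variable"), out / "stream_axis_loadings.csv")

    # time-only fits drive the trend histograms and the typology
    fits_time = run_fits(metric_table, driver_table, cfg, with_drivers=False)
    trend_rows = [f.global_trend() for f in fits_time.values()]
    io.write_table(pd.DataFrame(trend_rows), out / "global_trends.csv")
    site_trend_tables = []
    for resp, f in fits_time.items():
        t = f.site_trends()
        t.insert(0, "response", resp)
        site_trend_tables.append(t)
    io.write_table(pd.concat(site_trend_tables), out / "site_trends.csv")

    checks = []
    for resp, f in fits_time.items():
        chk = model.trend_characteristics_check(f.site_trends(), per_site)
        chk.insert(0, "response", resp)
        checks.append(chk)
    io.write_table(pd.concat(checks), out / "trend_characteristics_check.csv")

    result = {
        "records": clean, "metrics": metric_table, "drivers": driver_table,
        "summary": summary, "fits_time": fits_time,
    }

    typ = run_typology(fits_time, covs, cfg)
    io.write_table(typ["labels"], out / "cluster_assignments.csv")
    io.write_table(
        pd.DataFrame(typ["kmeans"].cluster_centers_,
                     columns=typ["matrix"].columns), out / "cluster_centers.csv"
    )
    io.write_table(typ["freq"], out / "cluster_frequencies.csv")
    result["typology"] = typ

    if cfg.with_drivers:
        fits_drv = run_fits(metric_table, driver_table, cfg, with_drivers=True)
        coef_tables = []
        for resp, f in fits_drv.items():
            t = f.coefficient_table()
            t.insert(0, "response", resp)
            coef_tables.append(t)
        io.write_table(pd.concat(coef_tables), out / "driver_coefficients.csv")
        fit_rows = []
        for resp, f in fits_drv.items():
            r2 = f.r2()
            fit_rows.append({"response": resp, "waic": f.waic(),
                             "r2_marginal": r2["r2_marginal"],
                             "r2_conditional": r2["r2_conditional"]})
        io.write_table(pd.DataFrame(fit_rows), out / "fit_summary.csv")
        result["fits_drivers"] = fits_drv

    _write_report_plots(result, out)
    log.info("run complete: outputs in %s", out)
    return result


def _write_report_plots(result: dict, out: Path) -> None:
    """Per-metric site-trend histograms (the headline figure's layout)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fits = result["fits_time"]
    n = len(fits)
    fig, axes = plt.subplots((n + 2) // 3, 3, figsize=(11, 3 * ((n + 2) // 3)))
    for ax, (resp, f) in zip(np.ravel(axes), fits.items()):
        trends = f.site_trends()["trend_per_decade"]
        ax.hist(trends, bins=40, color="steelblue")
        ax.axvline(0, ls="--", c="k", lw=0.8)
        ax.set_title(resp, fontsize=9)
    for ax in np.ravel(axes)[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out / "trend_histograms.png", dpi=120)
    plt.close(fig)
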