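"""Time-series selection rules producing one clean annual series per site.

The cascade, applied per site:

1. keep only sampling events using the site's most frequent protocol;
2. keep only events within 45 days (circular day-of-year distance) of the
   centre of the most frequently sampled month;
3. when a year still holds several events, keep the one closest to the
   site's most frequently sampled day-of-year;
4. retain the site only if it has >= 5 sampled years spanning >= 10
   calendar years (inclusive) and has not been limed.

All ties are broken deterministically (lexicographically first protocol,
earlier date) and every removal is recorded in an audit log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAYS_IN_YEAR = 365.25


@dataclass
class FilterParams:
    min_years: int = 5          # minimum sampled years per series
    min_span: int = 9           # minimum last-first year difference (10 y inclusive)
    window_days: float = 45.0   # seasonal half-window around the modal month
    drop_limed: bool = True


@dataclass
class AuditLog:
    """Per-site record of what each selection rule removed."""

    entries: list[dict] = field(default_factory=list)

    def add(self, site_id: str, rule: str, removed: int, detail: str = "") -> None:
        if removed:
            self.entries.append(
                {"site_id": site_id, "rule": rule, "removed": removed, "detail": detail}
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["site_id", "rule", "removed", "detail"])


def _event_table(records: pd.DataFrame) -> pd.DataFrame:
    """One row per (site, date) sampling event."""
    return records[["site_id", "date", "protocol"]].drop_duplicates()


def _circular_doy_distance(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs(a - b)
    return np.minimum(d, DAYS_IN_YEAR - d)


def select_primary_method(records: pd.DataFrame, log: AuditLog | None = None) -> pd.DataFrame:
    """Keep, per site, only events sampled with the modal protocol.

    The mode is counted over sampling events (site-date pairs), not over
    species rows; ties pick the lexicographically first protocol.
    """
    if records.empty:
        return records
    keep = []
    for site, grp in records.groupby("site_id", sort=False):
        events = _event_table(grp)
        counts = events["protocol"].value_counts()
        top = counts[counts == counts.max()].index.min()
        mask = grp["protocol"] == top
        if log is not None:
            log.add(site, "primary_method", int((~mask).sum()), f"kept protocol={top}")
        keep.append(grp[mask])
    return pd.concat(keep) if keep else records.iloc[:0]


def select_seasonal_window(
    records: pd.DataFrame,
    window_days: float = 45.0,
    log: AuditLog | None = None,
) -> pd.DataFrame:
    """Keep events within ``window_days`` of the modal month's centre.

    Distance is circular in day-of-year, so late-December and
    early-January surveys of a winter-sampled site both survive.
    """
    if records.empty:
        return records
    keep = []
    for site, grp in records.groupby("site_id", sort=False):
        events = _event_table(grp)
        months = events["date"].dt.month
        counts = months.value_counts()
        modal_month = counts[counts == counts.max()].index.min()
        # centre of the modal month = day-of-year of its 15th
        centre = pd.Timestamp(2001, modal_month, 15).dayofyear
        doy = grp["date"].dt.dayofyear.to_numpy(dtype=float)
        mask = _circular_doy_distance(doy, centre) <= window_days
        if log is not None:
            log.add(site, "seasonal_window", int((~mask).sum()), f"modal_month={modal_month}")
        keep.append(grp[mask])
    return pd.concat(keep) if keep else records.iloc[:0]


def dedupe_annual(records: pd.DataFrame, log: AuditLog | None = None) -> pd.DataFrame:
    """Keep one sampling event per site-year: the event closest (circular
    day-of-year distance) to the site's most frequently sampled day-of-year;
    equidistant ties keep the earlier date."""
    if records.empty:
        return records
    keep = []
    for site, grp in records.groupby("site_id", sort=False):
        events = _event_table(grp)
        doys = events["date"].dt.dayofyear
        counts = doys.value_counts()
        modal_doy = float(counts[counts == counts.max()].index.min())
        chosen_dates = []
        for _, yr_events in events.groupby(events["date"].dt.year):
            # stable argmin + pre-sorted dates => earlier date wins ties
            yr_events = yr_events.sort_values("date")
            d = _circular_doy_distance(
                yr_events["date"].dt.dayofyear.to_numpy(dtype=float), modal_doy
            )
            chosen_dates.append(yr_events["date"].iloc[int(np.argmin(d))])
        mask = grp["date"].isin(chosen_dates)
        if log is not None:
            log.add(site, "dedupe_annual", int((~mask).sum()), f"modal_doy={modal_doy:.0f}")
        keep.append(grp[mask])
    return pd.concat(keep) if keep else records.iloc[:0]


def series_summary_per_site(records: pd.DataFrame) -> pd.DataFrame:
    """Per-site series characteristics (first year, span, completeness)."""
    rows = []
    for site, grp in records.groupby("site_id", sort=True):
        years = np.sort(grp["date"].dt.year.unique())
        span = int(years[-1] - years[0])
        rows.append(
            {
                "site_id": site,
                "basin_id": grp["basin_id"].iloc[0],
                "unit": grp["unit"].iloc[0],
                "protocol": grp["protocol"].iloc[0],
                "first_year": int(years[0]),
                "n_years": int(len(years)),
                "span_years": span,
                "completeness": len(years) / (span + 1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id", "basin_id", "unit", "protocol", "first_year",
            "n_years", "span_years", "completeness",
        ],
    )


def apply_series_criteria(
    records: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    params: FilterParams | None = None,
    log: AuditLog | None = None,
) -> pd.DataFrame:
    """Retain sites with >= min_years sampled years over an inclusive
    (min_span + 1)-year window, excluding limed sites."""
    params = params or FilterParams()
    if records.empty:
        return records
    limed = set()
    if params.drop_limed and covariates is not None:
        limed = set(covariates.loc[covariates["limed"].astype(bool), "site_id"])
    summary = series_summary_per_site(records)
    ok = summary[
        (summary["n_years"] >= params.min_years)
        & (summary["span_years"] >= params.min_span)
        & (~summary["site_id"].isin(limed))
    ]["site_id"]
    mask = records["site_id"].isin(set(ok))
    if log is not None:
        for site in sorted(set(records["site_id"]) - set(ok)):
            why = "limed" if site in limed else "too short/sparse"
            log.add(site, "series_criteria", int((records["site_id"] == site).sum()), why)
    return records[mask]


def filter_series(
    records: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    params: FilterParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full selection cascade; returns (clean records, audit log)."""
    params = params or FilterParams()
    log = AuditLog()
    out = select_primary_method(records, log)
    out = select_seasonal_window(out, params.window_days, log)
    out = dedupe_annual(out, log)
    out = apply_series_criteria(out, covariates, params, log)
    return out.reset_index(drop=True), log.to_frame()


def summarize_series(records: pd.DataFrame) -> dict:
    """Dataset-level summary of the retained series.

    Medians and quartiles of time span, completeness and first study year,
    plus counts of sites, basins, sampling events, abundance records and
    species.
    """
    if records.empty:
        raise ValueError("cannot summarize an empty record collection")
    per_site = series_summary_per_site(records)

    def q(s: pd.Series) -> tuple[float, float, float]:
        return (float(s.median()), float(s.quantile(0.25)), float(s.quantile(0.75)))

    span_med, span_lo, span_hi = q(per_site["span_years"])
    comp_med, comp_lo, comp_hi = q(per_site["completeness"])
    fy_med, fy_lo, fy_hi = q(per_site["first_year"])
    return {
        "n_sites": int(per_site.shape[0]),
        "n_basins": int(per_site["basin_id"].nunique()),
        "n_events": int(records[["site_id", "date"]].drop_duplicates().shape[0]),
        "n_records": int(records.shape[0]),
        "n_species": int(records["species_id"].nunique()),
        "span_median": span_med, "span_q25": span_lo, "span_q75": span_hi,
        "completeness_median": comp_med,
        "completeness_q25": comp_lo, "completeness_q75": comp_hi,
        "first_year_median": fy_med, "first_year_q25": fy_lo, "first_year_q75": fy_hi,
    }
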