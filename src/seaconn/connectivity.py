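"""Connectivity products derived from simulated larval fluxes.

A :class:`FluxTable` accumulates, per release year and month, the
survival-weighted number of larvae moving between each pair of sites,
together with release bookkeeping (potential releases over the whole
spawning window, actual releases on open spawning days, total survival
weight and weight-free arrival counts).  From it we derive:

* connectivity *effectiveness* — mean over years of the annual ratio
  between successful larvae and larvae released (diagonal = retention);
* connectivity *persistence* — the stabilization coefficient, i.e. the
  reciprocal coefficient of variation of the annual flux;
* a per-site decomposition into release, arrival, survival and success
  rates;
* monthly effectiveness matrices;
* interannual trend tests with the autocorrelation-corrected
  (Hamed-Rao) Mann-Kendall test plus OLS and Sen slopes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Sentinel destination for particles that settled nowhere.
NO_DESTINATION = "-"


@dataclass
class FluxTable:
    """Per-(year, month, origin, destination) larval flux plus release counts.

    ``records`` columns: year, month, origin, destination, weight
    (survival-weighted arrivals) and count (unweighted arrivals);
    ``releases`` columns: year, origin, released_actual, released_potential,
    sum_survival_weight, n_arrived.
    """

    records: pd.DataFrame
    releases: pd.DataFrame
    site_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.releases):
            bad = self.releases["released_actual"] > self.releases["released_potential"]
            if bad.any():
                raise ValueError("released_actual exceeds released_potential")
        if len(self.records) and (self.records["weight"] < 0).any():
            raise ValueError("arrival weights must be >= 0")

    @property
    def years(self) -> list[int]:
        return sorted(self.releases["year"].unique())

    def annual_flux(self) -> pd.DataFrame:
        """(year, origin, destination) -> weight, summed over months."""
        rec = self.records[self.records["destination"] != NO_DESTINATION]
        return (rec.groupby(["year", "origin", "destination"], as_index=False)
                ["weight"].sum())

    def to_csv(self, path) -> None:
        rows = self.records.merge(self.releases, on=["year", "origin"], how="left")
        rows.insert(0, "site_order", "")
        if len(rows):
            rows.loc[rows.index[0], "site_order"] = "|".join(self.site_order)
        rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FluxTable":
        df = pd.read_csv(path, keep_default_na=False,
                         dtype={"destination": str, "origin": str})
        order = [s for s in str(df["site_order"].iloc[0]).split("|") if s] \
            if len(df) else []
        records = df[["year", "month", "origin", "destination", "weight", "count"]].copy()
        releases = (df[["year", "origin", "released_actual", "released_potential",
                        "sum_survival_weight", "n_arrived"]]
                    .drop_duplicates(["year", "origin"]).reset_index(drop=True))
        return cls(records=records, releases=releases, site_order=order)


@dataclass
class ConnectivityMatrix:
    """Origin x destination matrix of mean annual transfer fractions."""

    values: pd.DataFrame
    normalization: str  # "actual" or "potential"
    units: str = "fraction"

    def as_percent(self) -> pd.DataFrame:
        return self.values * 100.0

    def to_csv(self, path, percent: bool = True, decimals: int = 3) -> None:
        out = (self.as_percent() if percent else self.values).round(decimals)
        out.to_csv(path, na_rep="")


def _release_column(normalization: str) -> str:
    if normalization not in ("actual", "potential"):
        raise ValueError("normalization must be 'actual' or 'potential'")
    return f"released_{normalization}"


def effectiveness(flux: FluxTable, normalization: str = "actual",
                  months: list[int] | None = None) -> ConnectivityMatrix:
    """Mean over years of (annual arrival weight / annual release).

    Years in which an origin released nothing are excluded for that origin
    (with a log warning); the diagonal is retention.
    """
    col = _release_column(normalization)
    sites = flux.site_order
    rec = flux.records[flux.records["destination"] != NO_DESTINATION]
    if months is not None:
        rec = rec[rec["month"].isin(months)]
    annual = (rec.groupby(["year", "origin", "destination"], as_index=False)
              ["weight"].sum())
    out = pd.DataFrame(0.0, index=sites, columns=sites)
    for origin in sites:
        rel = flux.releases[flux.releases["origin"] == origin]
        valid = rel[rel[col] > 0]
        if len(valid) < len(rel):
            logger.warning("origin %s: %d year(s) with zero release excluded",
                           origin, len(rel) - len(valid))
        if not len(valid):
            out.loc[origin] = np.nan
            continue
        ratios = []
        for _, row in valid.iterrows():
            year_arr = annual[(annual["year"] == row["year"])
                              & (annual["origin"] == origin)]
            r = pd.Series(0.0, index=sites)
            for _, a in year_arr.iterrows():
                r[a["destination"]] += a["weight"] / row[col]
            ratios.append(r)
        out.loc[origin] = pd.concat(ratios, axis=1).mean(axis=1)
    return ConnectivityMatrix(values=out, normalization=normalization)


def persistence(flux: FluxTable) -> ConnectivityMatrix:
    """Stabilization coefficient mean/sd of the annual flux per site pair.

    Uses the sample (n-1) standard deviation.  All-zero flux -> NaN
    (undefined, rendered as missing); constant nonzero flux -> +inf.
    """
    years = flux.years
    if len(years) < 2:
        raise ValueError("persistence needs at least two years of flux")
    sites = flux.site_order
    annual = flux.annual_flux()
    out = pd.DataFrame(np.nan, index=sites, columns=sites)
    for origin in sites:
        for dest in sites:
            series = np.array([
                annual[(annual["year"] == y) & (annual["origin"] == origin)
                       & (annual["destination"] == dest)]["weight"].sum()
                for y in years])
            if not series.any():
                continue
            sd = series.std(ddof=1)
            out.loc[origin, dest] = np.inf if sd == 0 else series.mean() / sd
    return ConnectivityMatrix(values=out, normalization="flux")


def stabilization_coefficient(series) -> float:
    """1/CV of a series with sample (n-1) sd; NaN if all zero, inf if constant."""
    x = np.asarray(series, dtype=float)
    if not x.any():
        return float("nan")
    sd = x.std(ddof=1)
    return float("inf") if sd == 0 else float(x.mean() / sd)


def rate_decomposition(flux: FluxTable) -> pd.DataFrame:
    """Per-origin release, survival, arrival and success rates.

    release_rate = actual/potential releases; survival_rate = mean final
    survival weight of released larvae; arrival_rate = weight-free fraction
    of released larvae ending inside any settlement buffer; success_rate =
    survival-weighted arrivals / actual release.  Each is the mean over
    years of the annual ratio.
    """
    sites = flux.site_order
    arr = (flux.records[flux.records["destination"] != NO_DESTINATION]
           .groupby(["year", "origin"])["weight"].sum())
    rows = {}
    for origin in sites:
        rel = flux.releases[flux.releases["origin"] == origin]
        rates = {"release_rate": [], "survival_rate": [], "arrival_rate": [],
                 "success_rate": []}
        for _, r in rel.iterrows():
            if r["released_potential"] > 0:
                rates["release_rate"].append(r["released_actual"] / r["released_potential"])
            if r["released_actual"] > 0:
                rates["survival_rate"].append(r["sum_survival_weight"] / r["released_actual"])
                rates["arrival_rate"].append(r["n_arrived"] / r["released_actual"])
                w = arr.get((r["year"], origin), 0.0)
                rates["success_rate"].append(w / r["released_actual"])
            else:
                rates["survival_rate"].append(np.nan)
                rates["arrival_rate"].append(np.nan)
                rates["success_rate"].append(0.0)
        rows[origin] = {k: float(np.nanmean(v)) if len(v) else np.nan
                        for k, v in rates.items()}
    return pd.DataFrame(rows).T


def monthly_matrices(flux: FluxTable, normalization: str = "actual"
                     ) -> dict[int, ConnectivityMatrix]:
    """One effectiveness matrix per release month (April-July).

    Monthly matrices are normalized by the *annual* release so that, by
    construction, they sum month-wise to the annual effectiveness matrix.
    Months with no arrivals and no spawning yield an all-zero matrix
    flagged with a warning.
    """
    out = {}
    months_present = set(flux.records["month"].unique())
    for month in (4, 5, 6, 7):
        if month not in months_present:
            warnings.warn(f"month {month}: no spawning days in flux table")
        out[month] = effectiveness(flux, normalization, months=[month])
    return out


# ----------------------------------------------------------------------
# trend testing
# ----------------------------------------------------------------------

def sen_slope(series: np.ndarray) -> float:
    """Median of pairwise slopes (Theil-Sen)."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    slopes = [(x[j] - x[i]) / (j - i) for i in range(n) for j in range(i + 1, n)]
    return float(np.median(slopes))


def hamed_rao_trend(series, alpha: float = 0.05) -> dict:
    """Mann-Kendall trend test with the Hamed-Rao autocorrelation correction.

    The S statistic uses the tie-corrected variance; the effective-sample
    correction factor is 1 + 2/(n(n-1)(n-2)) * sum_i (n-i)(n-i-1)(n-i-2)
    rho_s(i) over lags whose rank autocorrelation (computed on the
    Sen-detrended series) exceeds the two-sided normal cutoff.  A
    continuity-corrected two-sided normal p-value is returned together
    with the OLS and Sen slopes.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("trend test needs at least 4 observations")

    s = 0
    for i in range(n - 1):
        s += np.sign(x[i + 1:] - x[i]).sum()
    s = float(s)

    _, tie_counts = np.unique(x, return_counts=True)
    var_s = (n * (n - 1) * (2 * n + 5)
             - sum(t * (t - 1) * (2 * t + 5) for t in tie_counts)) / 18.0

    # rank autocorrelation of the Sen-detrended series
    slope = sen_slope(x)
    detrended = x - slope * np.arange(n)
    ranks = stats.rankdata(detrended)
    rc = ranks - ranks.mean()
    denom = (rc**2).sum()
    correction = 1.0
    if denom > 0:
        acc = 0.0
        for lag in range(1, n - 2):
            rho = (rc[:-lag] * rc[lag:]).sum() / denom
            cutoff = stats.norm.ppf(0.975) * np.sqrt(1.0 / (n - lag))
            if abs(rho) > cutoff:
                acc += (n - lag) * (n - lag - 1) * (n - lag - 2) * rho
        correction = 1.0 + 2.0 / (n * (n - 1) * (n - 2)) * acc
    corrected_var = var_s * max(correction, 0.0)

    if s == 0 or corrected_var <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (s - np.sign(s)) / np.sqrt(corrected_var)
        p = 2 * stats.norm.sf(abs(z))

    ols = float(np.polyfit(np.arange(n), x, 1)[0])
    return {
        "S": s, "variance": var_s, "correction_factor": correction,
        "corrected_variance": corrected_var, "z": float(z), "p": float(p),
        "significant": bool(p < alpha), "ols_slope": ols, "sen_slope": slope,
    }


def interannual_trends(flux: FluxTable, alpha: float = 0.05) -> dict[str, dict]:
    """Hamed-Rao trend tests on yearly mean release/survival/success rates."""
    years = flux.years
    rates_by_year = {}
    arr = (flux.records[flux.records["destination"] != NO_DESTINATION]
           .groupby(["year", "origin"])["weight"].sum())
    for y in years:
        rel = flux.releases[flux.releases["year"] == y]
        release = (rel["released_actual"] / rel["released_potential"]).mean()
        act = rel[rel["released_actual"] > 0]
        survival = (act["sum_survival_weight"] / act["released_actual"]).mean()
        succ = np.mean([arr.get((y, o), 0.0) / a for o, a in
                        zip(act["origin"], act["released_actual"])])
        rates_by_year[y] = (release, survival, succ)
    out = {}
    for i, name in enumerate(("release_rate", "survival_rate", "success_rate")):
        series = [rates_by_year[y][i] for y in years]
        out[name] = hamed_rao_trend(series, alpha=alpha)
    return out
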