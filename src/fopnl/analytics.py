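"""Uptake statistics, linear-trend fits and projections, chi-square
comparisons, and stratified uptake reports.

Uptake is reported on two denominators: all counted launches (uptake per
total product) and launches whose panels satisfy their subgroup criteria
(uptake per eligible product). Annual uptake proportions are fitted with the
closed-form least-squares line ``y = a + bX`` (normal equations
``b = (n Σty − Σt Σy) / (n Σt² − (Σt)²)``, ``a = (Σy − b Σt)/n``), where X
counts study years from 1. Projections extrapolate that line; displayed
projections are clamped to [0, 1] while the unclamped value is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .thcl_eligibility import FLAG_ANOMALY


class TrendError(ValueError):
    pass


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(x: float | None, decimals: int = 1) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "N/A"
    return f"{round_half_up(100.0 * x, decimals):.{decimals}f}"


def parse_pct(text: str) -> float | None:
    if text.strip().upper() in {"N/A", "NA", ""}:
        return None
    return float(text.strip().rstrip("%")) / 100.0


def uptake_total(n_labeled: int, n_total: int) -> float | None:
    """Labeled share of all counted launches; ``None`` when undefined."""
    if n_total <= 0:
        return None
    if not 0 <= n_labeled <= n_total:
        raise ValueError("need 0 <= n_labeled <= n_total")
    return n_labeled / n_total


def uptake_eligible(n_labeled: int, n_eligible: int) -> float | None:
    """Labeled share of eligible launches; ``None`` when no product is
    eligible (small strata can have empty denominators)."""
    if n_eligible <= 0:
        return None
    if not 0 <= n_labeled <= n_eligible:
        raise ValueError("need 0 <= n_labeled <= n_eligible")
    return n_labeled / n_eligible


@dataclass
class UptakeSeries:
    """Yearly (labeled, eligible, total) counts for one stratum."""

    years: list[int]
    n_labeled: list[int]
    n_eligible: list[int]
    n_total: list[int]
    scope: str = "overall"

    def __post_init__(self) -> None:
        for y, lab, eli, tot in zip(self.years, self.n_labeled, self.n_eligible, self.n_total):
            if not (0 <= lab <= eli <= tot):
                raise ValueError(
                    f"{self.scope} {y}: need n_labeled <= n_eligible <= n_total "
                    f"(got {lab}, {eli}, {tot}); display anomalies must be "
                    "resolved via the display-consistency tags first"
                )

    def proportions(self, per: Literal["total", "eligible"]) -> list[float | None]:
        if per == "total":
            return [uptake_total(l, t) for l, t in zip(self.n_labeled, self.n_total)]
        return [uptake_eligible(l, e) for l, e in zip(self.n_labeled, self.n_eligible)]

    def pooled(self, per: Literal["total", "eligible"]) -> float | None:
        lab = sum(self.n_labeled)
        den = sum(self.n_total if per == "total" else self.n_eligible)
        return uptake_total(lab, den) if den else None


@dataclass
class TrendFit:
    intercept: float
    slope: float
    r_squared: Optional[float]
    slope_ci_half_width: Optional[float]
    n: int
    x_start: int
    window: tuple[int, int]
    degenerate: bool = False

    def predict(self, year: int) -> float:
        x = year - self.x_start + 1
        return self.intercept + self.slope * x


def fit_linear_trend(
    years: Sequence[int],
    proportions: Sequence[float],
    x_start: int | None = None,
    ci_level: float = 0.95,
) -> TrendFit:
    """Closed-form least-squares fit of uptake on study-year index.

    Years are encoded X = 1, 2, ... from ``x_start`` (default: first fitted
    year). The slope CI uses the OLS slope standard error with a t quantile
    at n-2 df. A constant series fits slope 0 with undefined R² (flagged
    degenerate).
    """
    years = list(years)
    y = np.asarray(proportions, dtype=float)
    if len(years) != len(y):
        raise TrendError("years and proportions must align")
    if len(set(years)) < 2:
        raise TrendError("need at least 2 distinct years")
    x_start = x_start if x_start is not None else min(years)
    t = np.asarray([yr - x_start + 1 for yr in years], dtype=float)

    n = len(t)
    st, sy = t.sum(), y.sum()
    sty, stt = (t * y).sum(), (t * t).sum()
    denom = n * stt - st**2
    if denom == 0:
        raise TrendError("zero variance in the year encoding")
    b = (n * sty - st * sy) / denom
    a = (sy - b * st) / n

    resid = y - (a + b * t)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    # constant series up to floating-point residue: R^2 is undefined
    degenerate = ss_tot <= 1e-18 * max(1.0, float(np.abs(y).max()) ** 2)
    r2 = None if degenerate else 1.0 - ss_res / ss_tot

    ci_half = None
    if n > 2:
        sxx = stt - st**2 / n
        se_b = math.sqrt(ss_res / (n - 2) / sxx)
        ci_half = float(stats.t.ppf(0.5 + ci_level / 2, n - 2) * se_b)

    return TrendFit(
        intercept=float(a),
        slope=float(b),
        r_squared=r2,
        slope_ci_half_width=ci_half,
        n=n,
        x_start=x_start,
        window=(min(years), max(years)),
        degenerate=degenerate,
    )


def project_uptake(fit: TrendFit, horizon_year: int) -> pd.DataFrame:
    """Per-year linear extrapolation beyond the fit window up to the horizon;
    columns carry both the raw prediction and a [0, 1]-clamped display copy."""
    if horizon_year < fit.window[1]:
        raise TrendError("projection horizon precedes the fit window")
    years = list(range(fit.window[1] + 1, horizon_year + 1))
    raw = [fit.predict(y) for y in years]
    return pd.DataFrame(
        {
            "year": years,
            "predicted": raw,
            "predicted_clamped": [min(1.0, max(0.0, v)) for v in raw],
        }
    )


def chi_square_uptake(table: np.ndarray | Sequence[Sequence[int]]) -> dict:
    """Pearson chi-square (no continuity correction) on a 2 x k
    labeled/not-labeled by stratum contingency table; df = k - 1."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("cells must be nonnegative integers")
    col_totals = obs.sum(axis=0)
    if (col_totals == 0).any():
        raise ValueError("every stratum needs a positive total")
    row_totals = obs.sum(axis=1)
    grand = obs.sum()
    expected = np.outer(row_totals, col_totals) / grand
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[1] - 1
    p = float(stats.chi2.sf(statistic, df))
    return {
        "statistic": statistic,
        "p_value": p,
        "df": df,
        "low_expected_warning": bool((expected < 1).any()),
    }


# ---------------------------------------------------------------------------
# series construction and stratified reports


def _counted(frame: pd.DataFrame) -> pd.DataFrame:
    counted = frame[frame["status"] == "assigned_in_window"]
    anomalies = int((counted.get("uptake_flag") == FLAG_ANOMALY).sum())
    if anomalies:
        # keep the labeled<=eligible invariant of the series; anomalies stay
        # visible through the uptake_flag column
        counted = counted[counted["uptake_flag"] != FLAG_ANOMALY]
    return counted


def uptake_series(
    frame: pd.DataFrame,
    scope: str = "overall",
    years: Sequence[int] | None = None,
) -> UptakeSeries:
    """Build the yearly counts series from an annotated product frame
    (restricted to counted = in-scope, in-window records)."""
    counted = _counted(frame)
    if years is None:
        years = sorted(counted["release_year"].unique())
    rows = []
    for year in years:
        sub = counted[counted["release_year"] == year]
        rows.append(
            (
                int((sub["thcl_displayed"]).sum()),
                int(sub["eligible"].sum()),
                int(len(sub)),
            )
        )
    return UptakeSeries(
        years=list(years),
        n_labeled=[r[0] for r in rows],
        n_eligible=[r[1] for r in rows],
        n_total=[r[2] for r in rows],
        scope=scope,
    )


def _trend_cells(series: UptakeSeries, per: Literal["total", "eligible"], x_start: int):
    props = series.proportions(per)
    pairs = [(y, p) for y, p in zip(series.years, props) if p is not None]
    if len(pairs) < 2:
        return None, None
    try:
        fit = fit_linear_trend([p[0] for p in pairs], [p[1] for p in pairs], x_start=x_start)
    except TrendError:
        return None, None
    return fit.slope, fit.r_squared


def build_report(
    frame: pd.DataFrame,
    by: Literal["reporting_group", "hsr", "manufacturer"] = "reporting_group",
    min_labeled: int = 5,
    other_label: str = "All other companies",
    fit_trends: bool = True,
) -> pd.DataFrame:
    """Stratified uptake report (one row per stratum plus a Total row).

    Columns give labeled/total, labeled/eligible and eligible/total as
    ``n/N`` strings with half-up one-decimal percentages, plus the per-
    stratum linear-trend slope (percentage points per annum) and R². In
    manufacturer mode, firms with fewer than ``min_labeled`` labeled products
    fold into a single residual row, and trends are omitted (firm-level
    yearly series are too sparse to fit meaningfully).
    """
    counted = _counted(frame)
    if by == "reporting_group":
        key = counted["reporting_group"]
    elif by == "hsr":
        key = counted["stars"]
    elif by == "manufacturer":
        labeled_per_firm = counted[counted["thcl_displayed"]].groupby("manufacturer").size()
        majors = set(labeled_per_firm[labeled_per_firm >= min_labeled].index)
        key = counted["manufacturer"].where(counted["manufacturer"].isin(majors), other_label)
        fit_trends = False
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(by)

    x_start = int(counted["release_year"].min()) if len(counted) else 0
    rows = []
    strata = sorted(key.dropna().unique(), key=str)
    if by == "manufacturer" and other_label in strata:
        strata = [s for s in strata if s != other_label] + [other_label]
    for stratum in strata:
        sub = counted[key == stratum]
        rows.append(_report_row(str(stratum), sub, fit_trends, x_start))
    rows.append(_report_row("Total", counted, fit_trends, x_start))
    report = pd.DataFrame(rows)
    if by == "manufacturer":
        # firms descend by eligible-uptake; residual and Total rows stay last
        tail = report["stratum"].isin([other_label, "Total"])
        head = report[~tail].sort_values(
            "pct_labeled_per_eligible", ascending=False, kind="stable"
        )
        report = pd.concat([head, report[tail]]).reset_index(drop=True)
    return report


def _report_row(name: str, sub: pd.DataFrame, fit_trends: bool, x_start: int) -> dict:
    n_total = int(len(sub))
    n_eligible = int(sub["eligible"].sum())
    n_labeled = int(sub["thcl_displayed"].sum())
    u_tot = uptake_total(n_labeled, n_total) if n_total else None
    u_eli = uptake_eligible(n_labeled, n_eligible) if n_eligible else None
    e_tot = uptake_total(n_eligible, n_total) if n_total else None
    row = {
        "stratum": name,
        "labeled_per_total": f"{n_labeled}/{n_total}",
        "pct_labeled_per_total": None if u_tot is None else round_half_up(100 * u_tot),
        "labeled_per_eligible": f"{n_labeled}/{n_eligible}",
        "pct_labeled_per_eligible": None if u_eli is None else round_half_up(100 * u_eli),
        "eligible_per_total": f"{n_eligible}/{n_total}",
        "pct_eligible_per_total": None if e_tot is None else round_half_up(100 * e_tot),
        "n_labeled": n_labeled,
        "n_eligible": n_eligible,
        "n_total": n_total,
    }
    if fit_trends:
        series = uptake_series(sub, scope=name)
        for per in ("total", "eligible"):
            slope, r2 = _trend_cells(series, per, x_start)
            row[f"trend_slope_pct_{per}"] = None if slope is None else round_half_up(100 * slope)
            row[f"trend_r2_{per}"] = None if r2 is None else round(r2, 4)
    return row
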