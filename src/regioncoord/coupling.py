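"""Coupling degree, coupling coordination degree (CCD), grading, and the
regional/temporal summary statistics built on them.

C = 3 * [ (U_EC * U_SO * U_HE) / (U_EC + U_SO + U_HE)^3 ]^(1/3) measures how
evenly the three system scores interact (1 iff all equal and positive);
T = alpha*U_EC + beta*U_SO + gamma*U_HE is the overall level; the
coordination degree D = sqrt(C * T) combines both and is graded on a
10-level scale from Extreme disorder to Excellent coordination.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .panel_io import RegionRecord, match_regions

#: 10-level grade scale: half-open [lo, hi) bins, top bin closed at 1.0.
GRADES = [
    (0.0, 0.1, "Extreme disorder"),
    (0.1, 0.2, "Severe disorder"),
    (0.2, 0.3, "Moderate disorder"),
    (0.3, 0.4, "Mild disorder"),
    (0.4, 0.5, "Near disorder"),
    (0.5, 0.6, "Reluctant coordination"),
    (0.6, 0.7, "Primary coordination"),
    (0.7, 0.8, "Intermediate coordination"),
    (0.8, 0.9, "Good coordination"),
    (0.9, 1.0, "Excellent coordination"),
]
GRADE_LABELS = [g[2] for g in GRADES]


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (the convention of the reported tables)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def coupling_degree(u_ec, u_so, u_he):
    """Coupling degree C in [0,1]; 0 whenever any score is 0 (including all)."""
    u = np.asarray([u_ec, u_so, u_he], dtype=float)
    if ((u < 0) | (u > 1)).any():
        raise DomainError(f"system scores must lie in [0,1], got {u.tolist()}")
    if (u == 0).any():
        return 0.0
    # log-space evaluation keeps tiny scores from under/overflowing the cube
    log_ratio = np.log(u).sum() - 3.0 * np.log(u.sum())
    return float(min(3.0 * np.exp(log_ratio / 3.0), 1.0))


def coordination_degree(c, u_ec, u_so, u_he,
                        alpha: float = 1 / 3, beta: float = 1 / 3,
                        gamma: float = 1 / 3):
    """Composite index T and coordination degree D = sqrt(C*T)."""
    if not (0.0 <= c <= 1.0 + 1e-12):
        raise DomainError(f"coupling degree must lie in [0,1], got {c}")
    w = np.asarray([alpha, beta, gamma], dtype=float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError(f"weights must be nonnegative and sum to 1, got {w.tolist()}")
    t = float(alpha * u_ec + beta * u_so + gamma * u_he)
    d = float(np.sqrt(c * t))
    return t, d


def classify(d: float) -> str:
    """Grade label for a coordination degree in [0,1]."""
    if not (0.0 <= d <= 1.0):
        raise DomainError(f"coordination degree must lie in [0,1], got {d}")
    for lo, hi, label in GRADES:
        if lo <= d < hi:
            return label
    return GRADES[-1][2]  # d == 1.0


@dataclass
class CCDRecord:
    county_id: str
    year: int
    C: float
    T: float
    D: float
    grade: str


def ccd_table(scores: pd.DataFrame, alpha: float = 1 / 3, beta: float = 1 / 3,
              gamma: float = 1 / 3) -> pd.DataFrame:
    """Compute C, T, D and grade for every (county, year) row of a scores
    frame with columns U_EC, U_SO, U_HE."""
    rows = []
    for (county, year), r in scores.iterrows():
        c = coupling_degree(r["U_EC"], r["U_SO"], r["U_HE"])
        t, d = coordination_degree(c, r["U_EC"], r["U_SO"], r["U_HE"],
                                   alpha, beta, gamma)
        rows.append((county, int(year), c, t, d, classify(d)))
    return pd.DataFrame(rows, columns=["county", "year", "C", "T", "D", "grade"])


def _summary_stats(vals: np.ndarray, ddof: int = 1) -> dict:
    mean = float(np.mean(vals))
    std = float(np.std(vals, ddof=ddof)) if len(vals) > ddof else 0.0
    return {
        "mean": mean,
        "median": float(np.median(vals)),
        "std": std,
        "cv": std / mean if mean != 0 else float("nan"),
        "n": int(len(vals)),
    }


def regional_summary(ccd: pd.DataFrame, regions: list[RegionRecord] | None = None,
                     ddof: int = 1, ndigits: int | None = 3) -> pd.DataFrame:
    """Per-year, per-group summary statistics of D.

    ``ccd`` is a long frame with columns county, year, D.  Groups are
    mountain_island / other (from ``regions``) plus the pooled "all" group.
    Median is the mean of the two middle order statistics for even n; std is
    the sample (n-1) estimator by default; CV = std/mean.  Values are
    rounded half-away-from-zero at ``ndigits`` (None keeps full precision).
    """
    df = ccd.copy()
    if regions is not None:
        matched = match_regions(sorted(df["county"].unique()), regions)
        gmap = {r.county_name: r.group for r in matched}
        df["group"] = df["county"].map(gmap)
    rows = []
    for year, ydf in df.groupby("year"):
        blocks = [("all", ydf)]
        if regions is not None:
            for g, gdf in ydf.groupby("group"):
                blocks.append((g, gdf))
        for gname, gdf in blocks:
            if len(gdf) == 0:
                raise ValidationError(f"empty group {gname!r} in year {year}")
            stats = _summary_stats(gdf["D"].to_numpy(), ddof=ddof)
            if ndigits is not None:
                stats = {k: (round_half_away(v, ndigits) if k != "n" else v)
                         for k, v in stats.items()}
            rows.append({"year": int(year), "group": gname, **stats})
    return pd.DataFrame(rows)


@dataclass
class TrendSummary:
    grade_counts: pd.DataFrame       # index year, columns grade labels
    n_high: dict                     # year -> count D >= high_cut
    n_low: dict                      # year -> count D < low_cut
    fold_increase_high: float | None  # (N_high(b)-N_high(a))/N_high(a)
    pct_decrease_low: float | None    # (N_low(a)-N_low(b))/N_low(a)*100
    year_a: int
    year_b: int


def trend_summary(ccd: pd.DataFrame, year_a: int, year_b: int,
                  low_cut: float = 0.4, high_cut: float = 0.7) -> TrendSummary:
    """Grade-band trend counts between two years.

    N_high counts counties at or above ``high_cut`` (Intermediate
    coordination or above by default); N_low counts counties strictly below
    ``low_cut`` (Mild disorder or below).  The fold increase of N_high and
    percent decrease of N_low between ``year_a`` and ``year_b`` are the
    headline temporal statistics.
    """
    years = set(ccd["year"].unique())
    for y in (year_a, year_b):
        if y not in years:
            raise ValidationError(f"year {y} not present in CCD table")
    counts = {}
    n_high, n_low = {}, {}
    for year, ydf in ccd.groupby("year"):
        d = ydf["D"].to_numpy()
        labels = [classify(v) for v in d]
        counts[int(year)] = {g: labels.count(g) for g in GRADE_LABELS}
        n_high[int(year)] = int((d >= high_cut).sum())
        n_low[int(year)] = int((d < low_cut).sum())
    grade_counts = pd.DataFrame(counts).T[GRADE_LABELS]
    fold = (None if n_high[year_a] == 0
            else (n_high[year_b] - n_high[year_a]) / n_high[year_a])
    pct = (None if n_low[year_a] == 0
           else (n_low[year_a] - n_low[year_b]) / n_low[year_a] * 100.0)
    return TrendSummary(grade_counts, n_high, n_low, fold, pct, year_a, year_b)
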