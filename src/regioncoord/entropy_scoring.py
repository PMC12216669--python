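"""Entropy-weight scoring of indicator panels.

Pipeline: min-max normalization of each indicator column (per year by
default), characteristic proportions p_ij = x_ij / sum_i x_ij, Shannon
entropy E_j = -(1/ln m) * sum_i p ln p, weights w_j proportional to the
information content 1 - E_j, and finally weighted system scores U_EC, U_SO,
U_HE plus unweighted subsystem condition values (the Z-block means used
downstream as fuzzy-set conditions).

Indicators whose column is constant within a normalization scope carry no
discriminating information: they normalize to 0, receive entropy 1 and
weight 0, and are reported in the result's ``degenerate`` set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, DomainError, ValidationError
from .panel_io import SYSTEMS, IndicatorPanel, IndicatorScheme


@dataclass
class NormalizedPanel:
    """Min-max normalized panel values in [0,1].

    ``values`` shares the (county, year) x indicator layout of the raw
    panel; ``degenerate`` lists (year, indicator) pairs (or (None,
    indicator) when pooling across years) whose column was constant.
    """

    values: pd.DataFrame
    pooling: str  # "per_year" | "pooled"
    scheme: IndicatorScheme
    degenerate: set = field(default_factory=set)


@dataclass
class WeightSet:
    """Per-year entropy values and weights, one row per (year, indicator).

    ``scope`` records whether weights sum to one within each system block
    ("per_system") or over all indicators ("global").
    """

    weights: pd.DataFrame   # index (year, indicator) -> weight
    entropies: pd.DataFrame  # index (year, indicator) -> entropy
    scope: str

    def weight(self, year: int, indicator: str) -> float:
        return float(self.weights.loc[(year, indicator), "weight"])

    def table(self) -> pd.DataFrame:
        out = self.entropies.join(self.weights).reset_index()
        return out[["year", "indicator", "entropy", "weight"]]


@dataclass
class SystemScores:
    """Weighted system scores and unweighted subsystem condition values.

    ``scores`` is indexed by (county, year) with columns U_EC, U_SO, U_HE;
    ``condition_values`` has one column per subsystem Z1..Z8.
    """

    scores: pd.DataFrame
    condition_values: pd.DataFrame

    def table(self) -> pd.DataFrame:
        return self.scores.join(self.condition_values).reset_index()


def normalize(panel: IndicatorPanel, pooling: str = "per_year") -> NormalizedPanel:
    """Min-max normalize each indicator column to [0,1].

    Positive indicators map min->0, max->1; negative indicators are
    reflected (max->0, min->1).  With ``per_year`` pooling the extrema are
    taken within each year; with ``pooled`` over all county-years, which
    puts all years on a common scale for cross-year comparison.
    """
    if pooling not in ("per_year", "pooled"):
        raise ValueError(f"pooling must be per_year or pooled, got {pooling!r}")
    vals = panel.values
    if not np.isfinite(vals.to_numpy()).all():
        raise ValidationError("panel contains non-finite values")
    out = pd.DataFrame(index=vals.index, columns=vals.columns, dtype=float)
    degenerate: set = set()

    def _norm_block(block: pd.DataFrame, tag):
        for ind in block.columns:
            col = block[ind]
            lo, hi = float(col.min()), float(col.max())
            if hi <= lo:
                out.loc[block.index, ind] = 0.0
                degenerate.add((tag, ind))
                continue
            if panel.scheme.direction(ind) == "positive":
                out.loc[block.index, ind] = (col - lo) / (hi - lo)
            else:
                out.loc[block.index, ind] = (hi - col) / (hi - lo)

    if pooling == "per_year":
        for year in panel.years:
            block = vals.xs(year, level="year", drop_level=False)
            _norm_block(block, year)
    else:
        _norm_block(vals, None)

    n_scopes = len(panel.years) if pooling == "per_year" else 1
    if len(degenerate) == n_scopes * len(vals.columns):
        raise DegenerateDataError("every indicator column is constant")
    if degenerate:
        warnings.warn(f"degenerate (constant) indicator columns: {sorted(degenerate, key=str)}",
                      stacklevel=2)
    return NormalizedPanel(out, pooling, panel.scheme, degenerate)


def proportions(norm: NormalizedPanel, year: int) -> pd.DataFrame:
    """Characteristic proportions p_ij = x_ij / sum_i x_ij for one year.

    Columns with zero sum (fully degenerate) yield all-zero proportions.
    """
    block = norm.values.xs(year, level="year")
    sums = block.sum(axis=0)
    p = block.div(sums.where(sums > 0, np.nan), axis=1).fillna(0.0)
    return p


def entropy(p: pd.DataFrame, m: int | None = None) -> pd.Series:
    """Shannon entropy E_j of each proportion column, scaled by 1/ln m.

    Uses the convention 0*ln 0 = 0.  Columns that do not sum to ~1
    (degenerate all-zero columns) get E = 1: no information.
    """
    m = m if m is not None else len(p)
    if m < 2:
        raise DomainError(f"entropy needs at least 2 alternatives, got m={m}")
    arr = p.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(arr > 0, arr * np.log(arr), 0.0)
    e = -plogp.sum(axis=0) / np.log(m)
    colsums = arr.sum(axis=0)
    e = np.where(np.abs(colsums - 1.0) > 1e-9, 1.0, e)
    # clip tiny negative round-off and cap at 1
    e = np.clip(e, 0.0, 1.0)
    return pd.Series(e, index=p.columns, name="entropy")


def weights_from_entropy(entropies: pd.Series, scheme: IndicatorScheme,
                         scope: str = "per_system") -> pd.Series:
    """Weights w_j = (1-E_j) / sum_block (1-E_j) for one year.

    The normalizing sum runs over each system block (``per_system``) or over
    all indicators (``global``).  A block in which every indicator has
    E = 1 carries no information and raises.
    """
    if scope not in ("per_system", "global"):
        raise ValueError(f"scope must be per_system or global, got {scope!r}")
    if ((entropies < -1e-12) | (entropies > 1 + 1e-12)).any():
        raise DomainError("entropies must lie in [0,1]")
    info = (1.0 - entropies).clip(lower=0.0)
    w = pd.Series(0.0, index=entropies.index, name="weight")
    blocks = ([scheme.block(s) for s in SYSTEMS] if scope == "per_system"
              else [list(entropies.index)])
    for block in blocks:
        block = [b for b in block if b in entropies.index]
        if not block:
            continue
        total = info[block].sum()
        if total <= 0:
            raise DegenerateDataError(
                f"no information in indicator block {block}: all entropies are 1"
            )
        w[block] = info[block] / total
    return w


def compute_weights(norm: NormalizedPanel, scope: str = "per_system") -> WeightSet:
    """Per-year entropies and weights over every year in the panel."""
    years = sorted(norm.values.index.get_level_values("year").unique())
    ent_rows, w_rows = [], []
    for year in years:
        p = proportions(norm, year)
        e = entropy(p)
        w = weights_from_entropy(e, norm.scheme, scope)
        for ind in p.columns:
            ent_rows.append((year, ind, float(e[ind])))
            w_rows.append((year, ind, float(w[ind])))
    ent = pd.DataFrame(ent_rows, columns=["year", "indicator", "entropy"])
    wdf = pd.DataFrame(w_rows, columns=["year", "indicator", "weight"])
    return WeightSet(wdf.set_index(["year", "indicator"]),
                     ent.set_index(["year", "indicator"]), scope)


def system_scores(norm: NormalizedPanel, wset: WeightSet) -> SystemScores:
    """Weighted system scores U_EC/U_SO/U_HE and unweighted Z-block means."""
    scheme = norm.scheme
    years = sorted(norm.values.index.get_level_values("year").unique())
    w_years = sorted(wset.weights.index.get_level_values("year").unique())
    if years != w_years:
        raise ValidationError(f"year sets differ: panel {years} vs weights {w_years}")

    score_frames = []
    for year in years:
        block = norm.values.xs(year, level="year", drop_level=False)
        w = wset.weights.xs(year, level="year")["weight"]
        row = {}
        for sys_name, col in zip(SYSTEMS, ("U_EC", "U_SO", "U_HE")):
            inds = scheme.block(sys_name)
            row[col] = block[inds].mul(w[inds], axis=1).sum(axis=1)
        score_frames.append(pd.DataFrame(row))
    scores = pd.concat(score_frames).sort_index()

    cond = pd.DataFrame(index=norm.values.index)
    for z in scheme.subsystems:
        cond[z] = norm.values[scheme.subsystem_block(z)].mean(axis=1)
    return SystemScores(scores, cond.sort_index())


def score_panel(panel: IndicatorPanel, pooling: str = "per_year",
                scope: str = "per_system") -> tuple[NormalizedPanel, WeightSet, SystemScores]:
    """Convenience wrapper: normalize, weight, and score in one call."""
    norm = normalize(panel, pooling)
    wset = compute_weights(norm, scope)
    return norm, wset, system_scores(norm, wset)
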