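"""Synthetic indicator panels and fsQCA case matrices with known ground truth.

The panel generator emulates the structure of the study system — 86
counties observed over 2020-2022 on 20 positive indicators, split into a
lower-mean mountain/island stratum (25 of 86 counties) and a developed
"other" stratum — without attempting to reproduce any real province's
magnitudes.  Indicator values are log-normal: the log-value of county i,
indicator j, year t is

    mu[group, j] + drift * (t - t0) + spread * u_i + noise * eps_ijt

where u_i is a fixed, evenly spaced county effect within each group (so the
generator has a deterministic ordering at noise 0) and eps is standard
normal.  Mountain/island counties receive a negative location offset on the
economy and healthcare blocks, planting the group ordering that the
recovery harness checks.

The QCA case generator draws condition memberships uniformly on
[0.05, 0.95] and sets the outcome to the max-min evaluation of planted
recipes plus truncated-normal noise clipped into [0.001, 0.999], so that at
noise 0 the planted sufficient configurations are exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fsqca
from .coupling import ccd_table
from .entropy_scoring import score_panel
from .errors import SchemaError, ValidationError
from .fsqca import DEFAULT_CONDITIONS, FuzzyCaseMatrix
from .panel_io import IndicatorPanel, IndicatorScheme, RegionRecord, default_scheme


@dataclass
class PanelSpec:
    """Parameters of the synthetic indicator panel."""

    n_counties: int = 86
    share_mountain_island: float = 25 / 86
    years: tuple = (2020, 2021, 2022)
    base_location: float = 3.0       # log-scale location of indicator levels
    group_gap: float = 1.2           # log-scale deficit of the mountain/island
                                     # stratum on economy + healthcare blocks
    society_gap: float = 0.3         # smaller deficit on the society block
    spread: float = 0.6              # within-group deterministic county spread
    drift: float = 0.08              # log-scale year-on-year growth
    noise: float = 0.15              # log-scale cell noise
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.share_mountain_island < 1):
            raise ValidationError(
                f"share_mountain_island must lie in (0,1), got "
                f"{self.share_mountain_island}")
        if self.noise < 0 or self.spread < 0:
            raise ValidationError("noise and spread must be nonnegative")
        if self.n_counties < 2:
            raise ValidationError("need at least 2 counties")


def generate_panel(spec: PanelSpec,
                   scheme: IndicatorScheme | None = None) -> IndicatorPanel:
    """Generate a reproducible two-stratum log-normal indicator panel."""
    scheme = scheme or default_scheme()
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    n_mi = max(1, round(spec.n_counties * spec.share_mountain_island))
    groups = (["mountain_island"] * n_mi
              + ["other"] * (spec.n_counties - n_mi))
    names = [f"{'MI' if g == 'mountain_island' else 'OT'}{i:03d}"
             for i, g in enumerate(groups)]
    records = [RegionRecord(n, n, g) for n, g in zip(names, groups)]

    # deterministic within-group county effects, evenly spaced in [-0.5, 0.5]
    u = np.empty(spec.n_counties)
    for g in ("mountain_island", "other"):
        idx = [i for i, gg in enumerate(groups) if gg == g]
        u[idx] = (np.linspace(-0.5, 0.5, len(idx)) if len(idx) > 1 else 0.0)

    econ_health = set(scheme.block("economy")) | set(scheme.block("healthcare"))
    rows = []
    t0 = spec.years[0]
    for year in spec.years:
        for i, name in enumerate(names):
            for ind in scheme.indicator_ids:
                gap = (spec.group_gap if ind in econ_health else spec.society_gap)
                mu = spec.base_location + spec.drift * (year - t0) + spec.spread * u[i]
                if groups[i] == "mountain_island":
                    mu -= gap
                eps = rng.standard_normal() if spec.noise > 0 else 0.0
                rows.append((name, year, ind, float(np.exp(mu + spec.noise * eps))))
    long = pd.DataFrame(rows, columns=["county", "year", "indicator", "value"])
    wide = long.pivot(index=["county", "year"], columns="indicator",
                      values="value")[scheme.indicator_ids].sort_index()
    recs = sorted(records, key=lambda r: r.county_name)
    return IndicatorPanel(years=list(spec.years), counties=recs,
                          scheme=scheme, values=wide)


@dataclass
class QCAPlant:
    """Planted sufficient configurations for the case-matrix generator.

    ``recipes`` maps each planted implicant as {condition: 1 or 0}; the
    outcome membership is the max over recipes of the min over literals.
    """

    recipes: list[dict] = field(default_factory=lambda: [{"Z6": 1, "Z7": 1}])
    n_cases: int = 25
    noise: float = 0.0
    seed: int = 0
    conditions: tuple = tuple(DEFAULT_CONDITIONS)

    def __post_init__(self):
        for r in self.recipes:
            unknown = set(r) - set(self.conditions)
            if unknown:
                raise SchemaError(f"planted recipe references unknown "
                                  f"conditions: {sorted(unknown)}")
            if any(v not in (0, 1) for v in r.values()):
                raise SchemaError("planted literals must be 0 (absent) or 1 (present)")
        if self.noise < 0:
            raise ValidationError("noise must be nonnegative")


def evaluate_recipes(recipes: list[dict], data: pd.DataFrame) -> np.ndarray:
    """Max-min fuzzy evaluation of a recipe list on condition memberships."""
    members = []
    for r in recipes:
        cols = [data[c].to_numpy() if v == 1 else 1.0 - data[c].to_numpy()
                for c, v in r.items()]
        members.append(np.minimum.reduce(cols) if cols else np.ones(len(data)))
    return np.maximum.reduce(members) if members else np.zeros(len(data))


def generate_qca_cases(plant: QCAPlant, outcome: str = "CCD") -> FuzzyCaseMatrix:
    """Generate a calibrated-looking case matrix with planted recipes."""
    rng = np.random.Generator(np.random.PCG64(plant.seed))
    conds = list(plant.conditions)
    data = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(plant.n_cases, len(conds))),
        columns=conds,
        index=[f"case{i:03d}" for i in range(plant.n_cases)],
    )
    y = evaluate_recipes(plant.recipes, data)
    if plant.noise > 0:
        y = y + plant.noise * rng.standard_normal(plant.n_cases)
    y = np.clip(y, 0.001, 0.999)
    data[outcome] = fsqca.adjust_ties(y)
    for c in conds:
        data[c] = fsqca.adjust_ties(data[c].to_numpy())
    return FuzzyCaseMatrix(data, conds, outcome)


@dataclass
class RecoveryReport:
    group_ordering_ok: bool            # MI mean CCD < other mean CCD each year
    mean_ccd_by_group: pd.DataFrame
    planted_recovered: bool            # solution == plant on observed corners
    solution_labels: list[str]
    contradiction_rows: int
    robustness_all_same: bool


def _corner_truth(recipes: list[dict], conditions: list[str],
                  corner: tuple) -> bool:
    lookup = dict(zip(conditions, corner))
    return any(all(lookup[c] == v for c, v in r.items()) for r in recipes)


def recovery_harness(spec: PanelSpec | None = None,
                     plant: QCAPlant | None = None,
                     cons_threshold: float = 0.80) -> RecoveryReport:
    """End-to-end check that the pipeline recovers the planted ground truth.

    Runs scoring -> CCD on a generated panel and verifies the planted group
    ordering; runs the sufficiency analysis on a generated case matrix and
    verifies that the parsimonious solution is logically equivalent to the
    planted recipes on the observed truth-table corners, and that the
    consistency-threshold scan leaves the solutions unchanged.
    """
    spec = spec or PanelSpec()
    plant = plant or QCAPlant()

    panel = generate_panel(spec)
    _, _, scores = score_panel(panel)
    ccd = ccd_table(scores.scores)
    gmap = {r.county_name: r.group for r in panel.counties}
    ccd["group"] = ccd["county"].map(gmap)
    means = ccd.groupby(["year", "group"])["D"].mean().unstack()
    ordering_ok = bool((means["mountain_island"] < means["other"]).all())

    matrix = generate_qca_cases(plant)
    table, sols = fsqca.analyze(matrix, cons_threshold=cons_threshold)
    observed = table.onset | table.offset
    pars = sols["parsimonious"]
    recovered = all(
        pars.covers_corner(c, table.conditions)
        == _corner_truth(plant.recipes, table.conditions, c)
        for c in observed
    )
    contradictions = sum(
        1 for r in table.observed()
        if r.outcome_code == 0 and r.raw_consistency >= cons_threshold
    )
    scan = fsqca.robustness_scan(matrix, baseline=cons_threshold)
    return RecoveryReport(
        group_ordering_ok=ordering_ok,
        mean_ccd_by_group=means,
        planted_recovered=bool(recovered),
        solution_labels=pars.recipe_labels(),
        contradiction_rows=contradictions,
        robustness_all_same=scan.all_same(),
    )
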