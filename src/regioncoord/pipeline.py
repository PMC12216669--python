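"""End-to-end pipeline: panel -> scores -> CCD -> summaries -> per-year fsQCA.

Also provides :func:`reproduce_fixture_stats`, which recomputes the headline
regional and temporal statistics from the packaged 86-county coordination
matrix (2020-2022): pooled means, the share of counties in the reluctant-to-
primary coordination band, the grade-band trend counts, and the
mountain/island coefficient of variation identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .coupling import ccd_table, regional_summary, round_half_away, trend_summary
from .entropy_scoring import score_panel
from . import fsqca
from .fsqca import DEFAULT_CONDITIONS
from .panel_io import (IndicatorPanel, load_published_ccd, read_panel,
                       read_region_groups)

log = logging.getLogger("regioncoord")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    panel_path: str | None = None
    region_path: str | None = None
    scheme_path: str | None = None
    pooling: str = "per_year"
    weight_scope: str = "per_system"
    ccd_weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    freq_threshold: int = 1
    cons_threshold: float = 0.80
    pri_threshold: float | str = "auto"
    expectations: dict = field(default_factory=lambda: {
        c: "present" for c in DEFAULT_CONDITIONS})
    scan_thresholds: tuple = (0.75, 0.80, 0.85)
    conditions: tuple = tuple(DEFAULT_CONDITIONS)
    outcome: str = "D"
    out_dir: str = "results/run"
    seed: int = 0


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig,
                 panel: IndicatorPanel | None = None) -> dict:
    """Execute scoring, CCD, summaries and per-year fsQCA; write artifacts.

    Returns a manifest dict (also written as ``manifest.json``).  A panel
    may be passed in memory (e.g. synthetic) instead of ``panel_path``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(config).items()},
                "version": __version__, "inputs": {}, "warnings": []}

    if panel is None:
        if config.panel_path is None:
            raise ValueError("either a panel or config.panel_path is required")
        regions = (read_region_groups(config.region_path)
                   if config.region_path else None)
        panel = read_panel(config.panel_path, regions=regions)
        manifest["inputs"]["panel_sha256"] = _checksum(config.panel_path)
        if config.region_path:
            manifest["inputs"]["regions_sha256"] = _checksum(config.region_path)

    log.info("scoring %d counties x %d years", panel.n_counties, len(panel.years))
    norm, wset, scores = score_panel(panel, config.pooling, config.weight_scope)
    wset.table().to_csv(out / "weights.csv", index=False)
    scores.table().to_csv(out / "scores.csv", index=False)

    a, b, g = config.ccd_weights
    ccd = ccd_table(scores.scores, a, b, g)
    ccd.to_csv(out / "ccd.csv", index=False)

    regions = panel.counties
    summary = regional_summary(ccd, regions)
    summary.to_csv(out / "summary.csv", index=False)
    years = sorted(ccd["year"].unique())
    trend = trend_summary(ccd, years[0], years[-1])
    (out / "trend.json").write_text(json.dumps({
        "n_high": trend.n_high, "n_low": trend.n_low,
        "fold_increase_high": trend.fold_increase_high,
        "pct_decrease_low": trend.pct_decrease_low,
        "grade_counts": trend.grade_counts.to_dict()}, indent=2, default=str))

    # per-year fsQCA over the mountain/island cases, outcome = that year's D
    mi = [r.county_name for r in regions if r.group == "mountain_island"]
    qca_cases = mi if len(mi) >= 4 else [r.county_name for r in regions]
    fsqca_summary = {}
    for year in years:
        cond_vals = scores.condition_values.xs(year, level="year")
        d = ccd[ccd["year"] == year].set_index("county")["D"]
        raw = cond_vals.loc[qca_cases, list(config.conditions)].copy()
        raw["D"] = d.loc[qca_cases]
        try:
            matrix = fsqca.calibrate_matrix(raw, list(config.conditions), "D")
        except fsqca.CalibrationError as exc:
            manifest["warnings"].append(f"fsQCA {year}: {exc}")
            continue
        necessity = fsqca.necessity_analysis(matrix)
        necessity.to_csv(out / f"necessity_{year}.csv", index=False)
        table, sols = fsqca.analyze(
            matrix, freq_threshold=config.freq_threshold,
            cons_threshold=config.cons_threshold,
            pri_threshold=config.pri_threshold,
            expectations=config.expectations)
        table.frame().to_csv(out / f"truth_table_{year}.csv", index=False)
        report = {
            kind: {
                "recipes": [{"literals": r.literals, "core": sorted(r.core),
                             "consistency": r.consistency,
                             "raw_coverage": r.raw_coverage,
                             "unique_coverage": r.unique_coverage}
                            for r in sol.recipes],
                "consistency": sol.consistency, "coverage": sol.coverage,
            } for kind, sol in sols.items()
        }
        (out / f"solutions_{year}.json").write_text(
            json.dumps(report, indent=2))
        (out / f"chart_{year}.txt").write_text(
            fsqca.configuration_chart(sols, list(config.conditions)))
        scan = fsqca.robustness_scan(
            matrix, thresholds=config.scan_thresholds,
            baseline=config.cons_threshold,
            freq_threshold=config.freq_threshold,
            pri_threshold=config.pri_threshold,
            expectations=config.expectations)
        scan.entries.to_csv(out / f"robustness_{year}.csv", index=False)
        fsqca_summary[int(year)] = {
            "intermediate": sols["intermediate"].recipe_labels(),
            "robust": scan.all_same()}

    manifest["fsqca"] = fsqca_summary
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def reproduce_fixture_stats() -> dict:
    """Headline statistics recomputed from the packaged CCD matrix.

    Returns values on the scale the published tables use: means at 3
    decimals, shares and changes as percentages, the fold increase as a
    plain ratio rounded to one decimal.
    """
    fixture = load_published_ccd()
    long = fixture.long()
    summ = regional_summary(long, regions=None, ndigits=None)
    mean = {int(r["year"]): r["mean"] for _, r in summ.iterrows()}
    trend = trend_summary(long, 2020, 2022)
    d22 = fixture.table[2022]
    share_mid = float(((d22 >= 0.5) & (d22 < 0.7)).mean() * 100)
    cv_2022_all = float(summ.set_index("year").loc[2022, "cv"])
    return {
        "mean_ccd_2020": round_half_away(mean[2020], 3),
        "mean_ccd_2022": round_half_away(mean[2022], 3),
        "median_ccd_2022": round_half_away(
            float(summ.set_index("year").loc[2022, "median"]), 3),
        "cv_ccd_2022": round_half_away(cv_2022_all, 3),
        "share_2022_reluctant_to_primary_pct": round(share_mid),
        "n_high_2020": trend.n_high[2020],
        "n_high_2022": trend.n_high[2022],
        "fold_increase_high": round(trend.fold_increase_high, 1),
        "n_low_2020": trend.n_low[2020],
        "n_low_2022": trend.n_low[2022],
        "pct_decrease_low": round(trend.pct_decrease_low),
        "table3_mi_cv_2022_from_printed": round_half_away(0.103 / 0.382, 3),
        "n_entries": fixture.n_entries,
    }
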