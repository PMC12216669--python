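"""Data model and file I/O for county-level indicator panels.

The raw input of the analysis is a county x year x indicator panel of 20
positive socio-economic and healthcare indicators grouped into 8 subsystems
(Z1..Z8) and 3 systems (economy, society, healthcare).  This module defines
the validated in-memory containers, the CSV readers/writers (long and wide
layouts), the region-group file reader, and the packaged verification
fixture: the published 86-county x 3-year coupling-coordination matrix.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import IntegrityError, SchemaError, ValidationError

SYSTEMS = ("economy", "society", "healthcare")

#: subsystem -> system membership of the default scheme
SUBSYSTEM_SYSTEM = {
    "Z1": "economy", "Z2": "economy", "Z3": "economy",
    "Z4": "society", "Z5": "society", "Z6": "society",
    "Z7": "healthcare", "Z8": "healthcare",
}

_FIXTURE_SHA256 = "1e216875da10e115b1ba6957d4e41e11e883338605f17f06e258be71ee715349"


def normalize_name(name: str) -> str:
    """Canonical join key for county names: NFKC-normalized, case-folded."""
    return unicodedata.normalize("NFKC", str(name)).strip().casefold()


@dataclass(frozen=True)
class IndicatorDef:
    id: str
    name: str
    unit: str
    direction: str  # "positive" | "negative"
    subsystem: str  # Z1..Z8
    system: str     # economy | society | healthcare

    def __post_init__(self):
        if self.direction not in ("positive", "negative"):
            raise SchemaError(f"indicator {self.id}: bad direction {self.direction!r}")
        if self.system not in SYSTEMS:
            raise SchemaError(f"indicator {self.id}: bad system {self.system!r}")


@dataclass(frozen=True)
class RegionRecord:
    county_id: str
    county_name: str
    group: str  # "mountain_island" | "other"

    def __post_init__(self):
        if self.group not in ("mountain_island", "other"):
            raise SchemaError(
                f"county {self.county_name}: unknown group {self.group!r} "
                "(expected mountain_island or other)"
            )


@dataclass
class IndicatorScheme:
    """Ordered indicator definitions plus display names for subsystems."""

    indicators: list[IndicatorDef]
    subsystem_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [d.id for d in self.indicators]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate indicator ids in scheme")
        sub2sys = {}
        for d in self.indicators:
            if sub2sys.setdefault(d.subsystem, d.system) != d.system:
                raise SchemaError(
                    f"subsystem {d.subsystem} mapped to more than one system"
                )

    @property
    def indicator_ids(self) -> list[str]:
        return [d.id for d in self.indicators]

    @property
    def subsystems(self) -> list[str]:
        seen = []
        for d in self.indicators:
            if d.subsystem not in seen:
                seen.append(d.subsystem)
        return seen

    def block(self, system: str) -> list[str]:
        """Indicator ids belonging to one of the three systems."""
        return [d.id for d in self.indicators if d.system == system]

    def subsystem_block(self, subsystem: str) -> list[str]:
        return [d.id for d in self.indicators if d.subsystem == subsystem]

    def direction(self, indicator_id: str) -> str:
        for d in self.indicators:
            if d.id == indicator_id:
                return d.direction
        raise SchemaError(f"unknown indicator {indicator_id!r}")


def default_scheme() -> IndicatorScheme:
    """The packaged 20-indicator scheme (x1..x20 over Z1..Z8)."""
    ref = importlib.resources.files("regioncoord.data") / "indicator_scheme.yaml"
    return _scheme_from_text(ref.read_text())


def load_scheme(path) -> IndicatorScheme:
    return _scheme_from_text(Path(path).read_text())


def _scheme_from_text(text: str) -> IndicatorScheme:
    raw = yaml.safe_load(text)
    inds = [IndicatorDef(**item) for item in raw["indicators"]]
    return IndicatorScheme(inds, raw.get("subsystem_names", {}))


@dataclass
class IndicatorPanel:
    """Validated county x year x indicator panel.

    ``values`` is a DataFrame indexed by (county, year) with one column per
    indicator id, dense (no missing cells) and finite.
    """

    years: list[int]
    counties: list[RegionRecord]
    scheme: IndicatorScheme
    values: pd.DataFrame

    @property
    def county_names(self) -> list[str]:
        return [c.county_name for c in self.counties]

    @property
    def n_counties(self) -> int:
        return len(self.counties)

    def value(self, county: str, year: int, indicator: str) -> float:
        return float(self.values.loc[(county, year), indicator])


def _validate_panel(df: pd.DataFrame, scheme: IndicatorScheme) -> None:
    """df: long-form columns county, year, indicator, value."""
    unknown = sorted(set(df["indicator"]) - set(scheme.indicator_ids))
    if unknown:
        raise SchemaError(f"unknown indicator codes: {unknown}")
    dup = df.duplicated(subset=["county", "year", "indicator"])
    if dup.any():
        trip = df.loc[dup, ["county", "year", "indicator"]].iloc[0].tolist()
        raise ValidationError(f"duplicate cell (county,year,indicator)={tuple(trip)}")
    counties = sorted(df["county"].unique())
    years = sorted(df["year"].unique())
    expected = {(c, y, i) for c in counties for y in years
                for i in scheme.indicator_ids}
    got = set(map(tuple, df[["county", "year", "indicator"]].itertuples(index=False)))
    missing = sorted(expected - got)
    if missing:
        shown = ", ".join(map(str, missing[:10]))
        raise ValidationError(
            f"{len(missing)} missing cell(s) (county,year,indicator): {shown}"
        )
    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any() or not vals.apply(lambda v: abs(v) != float("inf")).all():
        bad = df.loc[vals.isna(), ["county", "year", "indicator"]]
        raise ValidationError(f"non-finite values at: {bad.values.tolist()[:10]}")


def read_panel(path, scheme: IndicatorScheme | None = None,
               regions: list[RegionRecord] | None = None) -> IndicatorPanel:
    """Read a panel CSV (long ``county,year,indicator,value`` or wide
    ``county,year,x1..x20`` layout, autodetected) and validate it."""
    scheme = scheme or default_scheme()
    df = pd.read_csv(path)
    cols = list(df.columns)
    if {"county", "year", "indicator", "value"} <= set(cols):
        long = df[["county", "year", "indicator", "value"]].copy()
    elif {"county", "year"} <= set(cols):
        ind_cols = [c for c in cols if c not in ("county", "year")]
        unknown = sorted(set(ind_cols) - set(scheme.indicator_ids))
        if unknown:
            raise SchemaError(f"unknown indicator codes: {unknown}")
        long = df.melt(id_vars=["county", "year"], value_vars=ind_cols,
                       var_name="indicator", value_name="value")
    else:
        raise SchemaError(f"unrecognized panel header: {cols}")
    long["year"] = long["year"].astype(int)
    long["county"] = long["county"].astype(str)
    _validate_panel(long, scheme)
    long["value"] = pd.to_numeric(long["value"])
    wide = long.pivot(index=["county", "year"], columns="indicator",
                      values="value")[scheme.indicator_ids]
    wide = wide.sort_index()
    counties = sorted(long["county"].unique())
    years = [int(y) for y in sorted(long["year"].unique())]
    if regions is None:
        recs = [RegionRecord(c, c, "other") for c in counties]
    else:
        recs = match_regions(counties, regions)
    return IndicatorPanel(years=years, counties=recs, scheme=scheme, values=wide)


def write_panel(panel: IndicatorPanel, path, layout: str = "long") -> None:
    if layout == "long":
        long = panel.values.stack().rename("value").reset_index()
        long.columns = ["county", "year", "indicator", "value"]
        long.to_csv(path, index=False)
    elif layout == "wide":
        panel.values.reset_index().to_csv(path, index=False)
    else:
        raise ValueError(f"layout must be long or wide, got {layout!r}")


def read_region_groups(path) -> list[RegionRecord]:
    """Read ``county,group`` CSV; group is mountain_island or other."""
    df = pd.read_csv(path)
    if not {"county", "group"} <= set(df.columns):
        raise SchemaError(f"region file needs county,group columns, got {list(df.columns)}")
    recs = []
    for _, row in df.iterrows():
        recs.append(RegionRecord(str(row["county"]), str(row["county"]),
                                 str(row["group"])))
    return recs


def match_regions(county_names: list[str],
                  regions: list[RegionRecord]) -> list[RegionRecord]:
    """Join panel counties to region records by normalized county name."""
    if not regions and county_names:
        raise ValidationError("region file is empty but panel has counties")
    lookup = {normalize_name(r.county_name): r for r in regions}
    out = []
    missing = []
    for name in county_names:
        rec = lookup.get(normalize_name(name))
        if rec is None:
            missing.append(name)
        else:
            out.append(RegionRecord(name, name, rec.group))
    if missing:
        raise ValidationError(f"counties missing from region file: {missing}")
    return out


@dataclass
class CCDFixture:
    """The published 86-county x 3-year coordination-degree matrix."""

    table: pd.DataFrame  # index county name, columns 2020/2021/2022

    def lookup(self, county: str, year: int) -> float:
        key = normalize_name(county)
        idx = {normalize_name(c): c for c in self.table.index}
        return float(self.table.loc[idx[key], year])

    @property
    def n_entries(self) -> int:
        return int(self.table.size)

    def long(self) -> pd.DataFrame:
        out = self.table.stack().rename("D").reset_index()
        out.columns = ["county", "year", "D"]
        return out


def load_published_ccd() -> CCDFixture:
    """Load the packaged CCD matrix (86 counties, 2020-2022), checksum-verified."""
    ref = importlib.resources.files("regioncoord.data") / "published_ccd_matrix.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise IntegrityError(
            f"published_ccd_matrix.csv checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    df = pd.read_csv(ref)
    df = df.set_index("county")
    df.columns = [int(c.lstrip("y")) for c in df.columns]
    if df.shape != (86, 3):
        raise IntegrityError(f"fixture shape {df.shape} != (86, 3)")
    if ((df < 0) | (df > 1)).any().any():
        raise IntegrityError("fixture D values outside [0,1]")
    return CCDFixture(df)
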