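"""Country-year panel data model and I/O.

The panel is a long-format table with one row per (unit, year).  The outcome
of interest throughout the package is the mortality rate among women of
reproductive age (WRA, ages 15-49), expressed as deaths per 1,000 WRA per
year.  Whenever raw death and population counts are available the rate is
recomputed from them; an explicit ``outcome`` column is used only as a
fallback.

A study design ties the panel to an evaluation: a single treatment year
splitting calendar time into a pre-period and a post-period, a set of
treated units that are analysed as one population-weighted aggregate, a
donor pool, and an ordered list of predictor columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PREDICTOR_NAMES",
    "MANDATORY_COLUMNS",
    "INCOME_CLASSES",
    "CountryYearPanel",
    "StudyDesign",
    "AggregateSeries",
    "PanelError",
    "SchemaError",
    "DataError",
    "compute_outcome",
    "read_panel",
    "write_panel",
    "aggregate_treated",
    "interpolate_predictors",
]

#: Default predictor set: the 12 covariates entering the synthetic-control
#: matching objective (service delivery, financing, human development,
#: population structure and political stability indicators).
PREDICTOR_NAMES = [
    "hiv_prev",      # HIV prevalence, % of population ages 15-49
    "tb_cdr",        # tuberculosis case detection rate
    "cpr_any",       # contraceptive prevalence rate, any method
    "measles_imm",   # measles immunisation coverage
    "nonusg_oda_pc", # net non-USG ODA received per capita, current USD
    "f_schooling",   # mean years of schooling, female
    "pct_urban",     # % urban population
    "tfr",           # total fertility rate
    "log_pop",       # total population, logged
    "f_lfp",         # female labour force participation
    "gdp_pc",        # GDP per capita
    "polity5",       # Polity5 governance score
]

MANDATORY_COLUMNS = ["unit_id", "year"]

INCOME_CLASSES = ("low", "lower-middle", "upper-middle", "high")


class PanelError(Exception):
    """Base class for panel construction/validation failures."""


class SchemaError(PanelError):
    """A mandatory column is missing or mis-typed."""


class DataError(PanelError):
    """Row-level problem: duplicates, non-numeric cells, missing years."""


def compute_outcome(wra_deaths: float, wra_pop: float) -> float:
    """WRA mortality rate: deaths among women 15-49 per 1,000 WRA per year.

    Parameters
    ----------
    wra_deaths
        Annual deaths among women of reproductive age (count, >= 0).
    wra_pop
        Mid-year WRA population (count, > 0).

    Returns
    -------
    float
        ``wra_deaths / wra_pop * 1000``.
    """
    if wra_pop <= 0:
        raise ValueError(f"wra_pop must be positive, got {wra_pop}")
    return wra_deaths / wra_pop * 1000.0


@dataclass
class CountryYearPanel:
    """Long-format country-year panel.

    ``data`` holds one row per (unit_id, year), sorted, with the outcome in
    deaths per 1,000 WRA.  ``predictor_names`` lists the covariate columns
    in the order they enter the matching objective.
    """

    data: pd.DataFrame
    predictor_names: list[str] = field(default_factory=lambda: list(PREDICTOR_NAMES))

    def __post_init__(self) -> None:
        for col in MANDATORY_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"mandatory column missing: {col!r}")
        dup = self.data.duplicated(subset=["unit_id", "year"])
        if dup.any():
            pairs = self.data.loc[dup, ["unit_id", "year"]].values.tolist()
            raise DataError(f"duplicate (unit, year) rows: {pairs[:5]}")
        self.data = self.data.sort_values(["unit_id", "year"]).reset_index(drop=True)

    @property
    def units(self) -> list[str]:
        return sorted(self.data["unit_id"].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    def unit_series(self, unit_id: str, column: str = "outcome") -> pd.Series:
        """One unit's yearly series, indexed by year."""
        sub = self.data[self.data["unit_id"] == unit_id]
        return pd.Series(sub[column].values, index=sub["year"].values, name=column)

    def subset(self, units) -> "CountryYearPanel":
        units = set(units)
        return CountryYearPanel(
            self.data[self.data["unit_id"].isin(units)].copy(),
            predictor_names=list(self.predictor_names),
        )

    def with_outcome(self, values: pd.Series) -> "CountryYearPanel":
        """Return a copy whose outcome column is replaced (index-aligned to rows)."""
        df = self.data.copy()
        df["outcome"] = np.asarray(values)
        return CountryYearPanel(df, predictor_names=list(self.predictor_names))

    def wide(self, column: str = "outcome") -> pd.DataFrame:
        """Pivot to a years x units matrix for one column."""
        return self.data.pivot(index="year", columns="unit_id", values=column)


@dataclass
class StudyDesign:
    """Treatment assignment and timing for a single-adoption evaluation."""

    treatment_year: int = 2005
    start_year: int = 1990
    end_year: int = 2019
    treated_units: tuple[str, ...] = ()
    donor_units: tuple[str, ...] = ()
    predictor_names: list[str] = field(default_factory=lambda: list(PREDICTOR_NAMES))

    def __post_init__(self) -> None:
        overlap = set(self.treated_units) & set(self.donor_units)
        if overlap:
            raise ValueError(f"treated and donor sets overlap: {sorted(overlap)}")
        if not (self.start_year < self.treatment_year <= self.end_year):
            raise ValueError(
                f"treatment year {self.treatment_year} outside "
                f"[{self.start_year + 1}, {self.end_year}]"
            )
        self.treated_units = tuple(self.treated_units)
        self.donor_units = tuple(self.donor_units)

    @property
    def pre_years(self) -> list[int]:
        return list(range(self.start_year, self.treatment_year))

    @property
    def post_years(self) -> list[int]:
        return list(range(self.treatment_year, self.end_year + 1))

    @property
    def all_years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1))

    def replace(self, **kwargs) -> "StudyDesign":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            treatment_year=int(raw.get("treatment_year", 2005)),
            start_year=int(raw.get("start_year", 1990)),
            end_year=int(raw.get("end_year", 2019)),
            treated_units=tuple(raw.get("treated_units", ())),
            donor_units=tuple(raw.get("donor_units", ())),
            predictor_names=list(raw.get("predictor_names", PREDICTOR_NAMES)),
        )

    def to_yaml(self, path) -> None:
        payload = {
            "treatment_year": self.treatment_year,
            "start_year": self.start_year,
            "end_year": self.end_year,
            "treated_units": list(self.treated_units),
            "donor_units": list(self.donor_units),
            "predictor_names": list(self.predictor_names),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class AggregateSeries:
    """A population-weighted aggregate outcome path with the weights used."""

    years: list[int]
    values: np.ndarray
    weights_used: pd.DataFrame  # years x units, rows sum to 1

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.years)


def read_panel(path, schema: dict[str, str] | None = None,
               predictor_names: list[str] | None = None) -> CountryYearPanel:
    """Read a delimited country-year panel.

    Parameters
    ----------
    path
        CSV file with a header row; one row per unit-year.
    schema
        Optional mapping from this package's column names to the names used
        in the file (e.g. ``{"unit_id": "iso3"}``).
    predictor_names
        Predictor columns to carry; defaults to whichever of the standard
        twelve are present.

    The outcome is recomputed from ``wra_deaths`` and ``wra_pop`` wherever
    both are present, overriding any outcome column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column missing: {col!r}")
    numeric_cols = [c for c in df.columns if c not in ("unit_id", "income_class_baseline")]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.values)[0])
            raise DataError(
                f"non-numeric value {df[col].iloc[idx]!r} in column {col!r}, row {idx}"
            )
        df[col] = converted
    df["year"] = df["year"].astype(int)

    if "wra_deaths" in df.columns and "wra_pop" in df.columns:
        have = df["wra_deaths"].notna() & df["wra_pop"].notna()
        if "outcome" not in df.columns:
            df["outcome"] = np.nan
        df.loc[have, "outcome"] = (
            df.loc[have, "wra_deaths"] / df.loc[have, "wra_pop"] * 1000.0
        )
    elif "outcome" not in df.columns:
        raise SchemaError("panel needs either an outcome column or count columns")

    if "total_deaths" in df.columns and "wra_deaths" in df.columns:
        both = df["total_deaths"].notna() & df["wra_deaths"].notna()
        if (df.loc[both, "wra_deaths"] > df.loc[both, "total_deaths"]).any():
            raise DataError("wra_deaths exceeds total_deaths for some rows")

    if predictor_names is None:
        predictor_names = [p for p in PREDICTOR_NAMES if p in df.columns]
    return CountryYearPanel(df, predictor_names=predictor_names)


def write_panel(panel: CountryYearPanel, path) -> None:
    # %.17g guarantees bit-exact float round trips through text
    panel.data.to_csv(path, index=False, float_format="%.17g")


def aggregate_treated(panel: CountryYearPanel, members,
                      years: list[int] | None = None) -> AggregateSeries:
    """Pool member countries into one treated unit, weighting by population.

    The aggregate outcome in a year is total member WRA deaths divided by
    total member WRA population (x 1000) -- identically the population-
    weighted mean of member mortality rates.  The per-year weights (each
    member's WRA population share) are returned for reuse when aggregating
    predictors or effects.
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("empty member set")
    sub = panel.data[panel.data["unit_id"].isin(members)]
    if years is None:
        years = sorted(sub["year"].unique().tolist())
    pops = sub.pivot(index="year", columns="unit_id", values="wra_pop")
    outcomes = sub.pivot(index="year", columns="unit_id", values="outcome")
    missing = []
    for y in years:
        for m in members:
            if y not in pops.index or pd.isna(pops.loc[y].get(m)) or pd.isna(
                outcomes.loc[y].get(m)
            ):
                missing.append((m, y))
    if missing:
        raise DataError(f"members missing outcome/population for: {missing[:8]}")
    pops = pops.loc[years, members]
    outcomes = outcomes.loc[years, members]
    weights = pops.div(pops.sum(axis=1), axis=0)
    values = (outcomes * weights).sum(axis=1).to_numpy()
    return AggregateSeries(years=list(years), values=values, weights_used=weights)


def aggregate_predictor(panel: CountryYearPanel, members, name: str,
                        years: list[int]) -> pd.Series:
    """Population-weighted mean of a predictor across members, per year.

    Logged total population is special-cased as the log of the summed
    population, so that the aggregate behaves as one large country rather
    than as an average of country sizes.
    """
    members = sorted(set(members))
    sub = panel.data[panel.data["unit_id"].isin(members)]
    pops = sub.pivot(index="year", columns="unit_id", values="wra_pop").loc[years, members]
    if name == "log_pop":
        raw = sub.pivot(index="year", columns="unit_id", values=name).loc[years, members]
        total = np.exp(raw).sum(axis=1)
        return np.log(total)
    vals = sub.pivot(index="year", columns="unit_id", values=name).loc[years, members]
    weights = pops.div(pops.sum(axis=1), axis=0)
    return (vals * weights).sum(axis=1)


def interpolate_predictors(panel: CountryYearPanel) -> tuple[CountryYearPanel, pd.DataFrame]:
    """Fill internal gaps in predictor series by within-unit linear interpolation.

    No extrapolation is performed: values missing at the edges of a unit's
    series stay missing and are reported in the returned flag table
    (unit, predictor, years still missing) so that downstream filters can
    exclude the unit explicitly rather than run on silently patched data.
    """
    df = panel.data.copy()
    flags = []
    for unit, grp in df.groupby("unit_id"):
        idx = grp.sort_values("year").index
        for name in panel.predictor_names:
            if name not in df.columns:
                continue
            series = df.loc[idx, name]
            if series.isna().any():
                filled = series.interpolate(method="linear", limit_area="inside")
                df.loc[idx, name] = filled
                still = filled.isna()
                if still.any():
                    years = df.loc[idx[still.values], "year"].tolist()
                    flags.append({"unit_id": unit, "predictor": name, "years": years})
    flag_df = pd.DataFrame(flags, columns=["unit_id", "predictor", "years"])
    return CountryYearPanel(df, predictor_names=list(panel.predictor_names)), flag_df
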