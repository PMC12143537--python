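"""Annual indicator panels: ingestion, validation, transforms, z-scoring.

An indicator panel is a rectangular years x indicators matrix of annual
observations (sea-surface temperature, zooplankton biomass, seabird hatch
dates, ...) on a contiguous calendar-year grid.  Series may start in
different years and contain sporadic gaps; missing values are represented
as NaN and tracked by an explicit observation mask.  All downstream stages
(dynamic factor analysis, state detection, moving-window screening) consume
the standardized form produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_GROUPS = {"climate", "lower_trophic", "mid_trophic", "seabird", "all_biology"}
VALID_REGIONS = {"western", "eastern"}

__all__ = [
    "IndicatorSeries",
    "IndicatorPanel",
    "StandardizedPanel",
    "load_panel",
    "write_panel",
    "log_offset",
    "standardize",
    "unstandardize",
]


@dataclass(frozen=True)
class IndicatorSeries:
    """One annual indicator on a contiguous year grid (NaN = missing).

    Parameters
    ----------
    name : str
        Short identifier, unique within a panel.
    years : ndarray of int
        Strictly increasing with step 1 over the series' span.
    values : ndarray of float
        Same length as ``years``; NaN marks an unobserved year.
    units, group, region : str, optional
        Free-text units and the model-group / sub-region labels used to
        slice panels into the climate / trophic / seabird sub-models.
    transform_applied : {"none", "log_offset"}
        Whether the log(x + offset) transform has already been applied.
    """

    name: str
    years: np.ndarray
    values: np.ndarray
    units: str = ""
    group: str | None = None
    region: str | None = None
    transform_applied: str = "none"

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.shape != years.shape:
            raise ValueError(f"series {self.name!r}: years/values shape mismatch")
        if len(years) and not np.all(np.diff(years) == 1):
            raise ValueError(f"series {self.name!r}: years must be contiguous")
        if np.isinf(values).any():
            raise ValueError(f"series {self.name!r}: infinite values not allowed")
        if np.sum(np.isfinite(values)) < 2:
            raise ValueError(f"series {self.name!r}: needs at least 2 observed values")
        if self.group is not None and self.group not in VALID_GROUPS:
            raise ValueError(f"series {self.name!r}: unknown group {self.group!r}")
        if self.region is not None and self.region not in VALID_REGIONS:
            raise ValueError(f"series {self.name!r}: unknown region {self.region!r}")
        if self.transform_applied not in ("none", "log_offset"):
            raise ValueError(f"series {self.name!r}: unknown transform")

    @property
    def observed(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class IndicatorPanel:
    """A collection of IndicatorSeries aligned to one contiguous year grid."""

    years: np.ndarray
    series: list[IndicatorSeries] = field(default_factory=list)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        if len(self.years) and not np.all(np.diff(self.years) == 1):
            raise ValueError("panel year_index must be contiguous")
        aligned = []
        for s in self.series:
            if not np.array_equal(s.years, self.years):
                s = _align_series(s, self.years)
            aligned.append(s)
        names = [s.name for s in aligned]
        if len(set(names)) != len(names):
            raise ValueError("duplicate series names in panel")
        self.series = aligned

    # -- matrix views -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        """T x n matrix of observations, NaN where missing."""
        if not self.series:
            return np.empty((len(self.years), 0))
        return np.column_stack([s.values for s in self.series])

    @property
    def missing_mask(self) -> np.ndarray:
        """T x n boolean matrix, True where observed."""
        return np.isfinite(self.values)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.series]

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def n_observed(self) -> int:
        """Total count of observed (non-missing) data points."""
        return int(self.missing_mask.sum())

    # -- slicing ------------------------------------------------------
    def filter(self, group: str | None = None, region: str | None = None) -> "IndicatorPanel":
        keep = [
            s
            for s in self.series
            if (group is None or s.group == group) and (region is None or s.region == region)
        ]
        return IndicatorPanel(self.years, keep)

    def window(self, start_year: int | None = None, end_year: int | None = None) -> "IndicatorPanel":
        """Crop to [start_year, end_year]; series left with <2 observations are dropped."""
        lo = self.years[0] if start_year is None else start_year
        hi = self.years[-1] if end_year is None else end_year
        sel = (self.years >= lo) & (self.years <= hi)
        years = self.years[sel]
        kept = []
        for s in self.series:
            vals = s.values[sel]
            if np.sum(np.isfinite(vals)) >= 2:
                kept.append(replace(s, years=years, values=vals))
        return IndicatorPanel(years, kept)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "year", self.years)
        return df


def _align_series(s: IndicatorSeries, years: np.ndarray) -> IndicatorSeries:
    vals = np.full(len(years), np.nan)
    idx = np.searchsorted(years, s.years)
    inside = (s.years >= years[0]) & (s.years <= years[-1])
    if not inside.all():
        raise ValueError(f"series {s.name!r} extends outside the panel year grid")
    vals[idx] = s.values
    return replace(s, years=years.copy(), values=vals)


@dataclass
class StandardizedPanel(IndicatorPanel):
    """Panel whose series are z-scored over their observed entries.

    ``means``/``sds`` store the per-series statistics so the transform can
    be inverted exactly.
    """

    means: np.ndarray = field(default_factory=lambda: np.empty(0))
    sds: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def load_panel(
    path,
    year_column: str = "year",
    group: str | None = None,
    region: str | None = None,
    metadata_path=None,
) -> IndicatorPanel:
    """Read a wide CSV (one year column, one column per indicator).

    The year grid is made contiguous from the minimum to the maximum
    observed year; interior gap years become all-missing rows so that the
    annual state equation advances one year per step.  Empty cells and
    stray non-numeric tokens become missing; a column with no parseable
    numeric value at all is an error.  An optional sidecar metadata CSV
    (columns: name, group, region, units, transform) attaches group/region
    labels, which the ``group``/``region`` arguments then filter on.
    """
    df = pd.read_csv(path)
    if year_column not in df.columns:
        raise ValueError(f"year column {year_column!r} not found in {path}")
    years_raw = pd.to_numeric(df[year_column], errors="raise").astype(int)
    if years_raw.duplicated().any():
        dups = sorted(years_raw[years_raw.duplicated()].unique().tolist())
        raise ValueError(f"duplicate years in {path}: {dups}")
    df = df.set_index(years_raw).drop(columns=[year_column]).sort_index()

    full = np.arange(df.index.min(), df.index.max() + 1)
    df = df.reindex(full)

    meta = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path).fillna("")
        for _, row in mdf.iterrows():
            meta[str(row["name"])] = row

    series = []
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        if not np.isfinite(vals).any():
            raise ValueError(f"indicator column {col!r} contains no numeric data")
        kw = {}
        if col in meta:
            row = meta[col]
            kw = {
                "units": str(row.get("units", "") or ""),
                "group": str(row["group"]) if row.get("group", "") else None,
                "region": str(row["region"]) if row.get("region", "") else None,
                "transform_applied": str(row.get("transform", "") or "none"),
            }
        series.append(IndicatorSeries(name=str(col), years=full, values=vals, **kw))
    panel = IndicatorPanel(full, series)
    if group is not None or region is not None:
        panel = panel.filter(group=group, region=region)
    return panel


def write_panel(panel: IndicatorPanel, path, float_format: str = "%.17g") -> None:
    """Write a panel back to the wide CSV dialect read by :func:`load_panel`."""
    panel.to_frame().to_csv(path, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def log_offset(series: IndicatorSeries, offset: float = 0.01) -> IndicatorSeries:
    """Natural-log transform ln(x + offset) for non-negative abundance series.

    The small offset keeps zero catches (common in trawl CPUE series)
    finite on the log scale.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    obs = series.observed
    if np.any(series.values[obs] < 0):
        raise ValueError(f"series {series.name!r}: negative values cannot be log-transformed")
    vals = series.values.copy()
    vals[obs] = np.log(vals[obs] + offset)
    return replace(series, values=vals, transform_applied="log_offset")


def standardize(panel: IndicatorPanel) -> StandardizedPanel:
    """Z-score each series over its observed entries (sample sd, ddof=1).

    Mixed-unit indicators (degrees C, CPUE, day-of-year, ...) become
    comparable so that factor loadings can be read against each other.
    Missing entries stay missing.
    """
    means = np.empty(panel.n_series)
    sds = np.empty(panel.n_series)
    new_series = []
    for j, s in enumerate(panel.series):
        obs = s.observed
        mu = float(np.mean(s.values[obs]))
        sd = float(np.std(s.values[obs], ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"series {s.name!r} is constant; cannot standardize")
        vals = s.values.copy()
        vals[obs] = (vals[obs] - mu) / sd
        means[j], sds[j] = mu, sd
        new_series.append(replace(s, values=vals))
    return StandardizedPanel(panel.years.copy(), new_series, means=means, sds=sds)


def unstandardize(panel: StandardizedPanel) -> IndicatorPanel:
    """Invert :func:`standardize` exactly using the stored (mean, sd)."""
    new_series = []
    for j, s in enumerate(panel.series):
        vals = s.values.copy()
        obs = s.observed
        vals[obs] = vals[obs] * panel.sds[j] + panel.means[j]
        new_series.append(replace(s, values=vals))
    return IndicatorPanel(panel.years.copy(), new_series)
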