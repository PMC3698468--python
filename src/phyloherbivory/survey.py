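"""Survey data: quadrat records, plot compositions, per-plant herbivory.

The field design this module mirrors: each plot is surveyed with four 1x1 m
quadrats; a species' abundance score in a plot is the number of quadrats it
occurred in (0-4), a deliberately low-resolution measure.  Herbivory is
recorded per individual plant as (damaged leaves, total leaves), and those
counts - not plot means - are the response the mixed model sees.

File formats are plain UTF-8 CSV/TSV with a header row:

* quadrat file: ``plot,quadrat,species`` (one row per species per quadrat)
* composition file: ``plot,species,abundance`` (sparse; abundance 1-4)
* plant file: ``plot,species,damaged,total``
* dates file: ``plot,date`` (integer day offsets)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QuadratRecord",
    "PlotComposition",
    "PlantObservation",
    "PredictorTable",
    "aggregate_quadrats",
    "species_richness",
    "pielou_evenness",
    "build_predictors",
]

N_QUADRATS = 4


class SurveyError(ValueError):
    """Invalid survey input."""


@dataclass(frozen=True)
class QuadratRecord:
    plot: str
    quadrat: int
    species: frozenset

    def __post_init__(self):
        if not 1 <= self.quadrat <= N_QUADRATS:
            raise SurveyError(f"quadrat index {self.quadrat} outside 1..{N_QUADRATS}")
        if any(not s for s in self.species):
            raise SurveyError("empty species name in quadrat record")


@dataclass(frozen=True)
class PlotComposition:
    """Abundance score (0-4) per species in one plot; absent species omitted."""

    plot: str
    abundances: dict
    date: int = 0

    def __post_init__(self):
        for sp, a in self.abundances.items():
            if not (isinstance(a, (int, np.integer)) and 0 <= a <= N_QUADRATS):
                raise SurveyError(f"abundance for {sp!r} must be an integer in 0..4, got {a!r}")
        if not any(a >= 1 for a in self.abundances.values()):
            raise SurveyError(f"plot {self.plot!r} has no species present")


@dataclass(frozen=True)
class PlantObservation:
    """One individual plant: damaged and total leaf counts."""

    plot: str
    species: str
    damaged: int
    total: int

    def __post_init__(self):
        if not (isinstance(self.damaged, (int, np.integer)) and isinstance(self.total, (int, np.integer))):
            raise SurveyError("leaf counts must be integers")
        if self.total < 1:
            raise SurveyError("total leaves must be >= 1")
        if not 0 <= self.damaged <= self.total:
            raise SurveyError("damaged leaves must lie in [0, total]")


def aggregate_quadrats(records) -> list[PlotComposition]:
    """Combine quadrat presence records into per-plot 0-4 abundance scores.

    A species' abundance is the number of quadrats of the plot in which it
    was recorded.  Duplicate (plot, quadrat) pairs and more than four
    quadrats per plot are rejected.
    """
    by_plot: dict[str, dict[int, frozenset]] = {}
    for rec in records:
        quads = by_plot.setdefault(rec.plot, {})
        if rec.quadrat in quads:
            raise SurveyError(f"duplicate quadrat {rec.quadrat} in plot {rec.plot!r}")
        quads[rec.quadrat] = rec.species
        if len(quads) > N_QUADRATS:
            raise SurveyError(f"more than {N_QUADRATS} quadrats in plot {rec.plot!r}")
    comps = []
    for plot in sorted(by_plot):
        counts: dict[str, int] = {}
        for species in by_plot[plot].values():
            for sp in species:
                counts[sp] = counts.get(sp, 0) + 1
        comps.append(PlotComposition(plot=plot, abundances=counts))
    return comps


def species_richness(comp: PlotComposition) -> int:
    """Number of species with abundance >= 1."""
    return sum(1 for a in comp.abundances.values() if a >= 1)


def pielou_evenness(comp: PlotComposition) -> float:
    """Pielou's J (Shannon H / ln SR) on the 0-4 abundance scores.

    Utility only - evenness never enters the herbivory model.  Returns NaN
    for single-species plots, where evenness is undefined.
    """
    m = np.array([a for a in comp.abundances.values() if a > 0], dtype=float)
    if len(m) < 2:
        return math.nan
    p = m / m.sum()
    H = -(p * np.log(p)).sum()
    return float(H / np.log(len(m)))


@dataclass(frozen=True)
class PredictorTable:
    """Plot-level predictors, centered, with stored means for back-prediction.

    ``frame`` has one row per plot with raw columns ``sr, pd, date``,
    centered columns ``sr_c, pd_c, date_c`` and the interaction
    ``sr_pd_c = sr_c * pd_c`` (formed *after* centering the mains and not
    itself re-centered, so main effects read as slopes at the mean of the
    other variables).
    """

    frame: pd.DataFrame
    means: dict = field(default_factory=dict)

    def center(self, sr, pd_value, date=None):
        """Center new raw-scale values with the stored means.

        Returns (sr_c, pd_c, sr_pd_c, date_c); ``date_c`` is 0 when no
        date is given (i.e. prediction at the mean sampling date).
        """
        sr_c = np.asarray(sr, dtype=float) - self.means["sr"]
        pd_c = np.asarray(pd_value, dtype=float) - self.means["pd"]
        date_c = (
            np.zeros_like(sr_c)
            if date is None
            else np.asarray(date, dtype=float) - self.means["date"]
        )
        return sr_c, pd_c, sr_c * pd_c, date_c


def build_predictors(compositions, pse_values, dates=None) -> PredictorTable:
    """Assemble the centered plot-level predictor table.

    Parameters
    ----------
    compositions:
        PlotComposition list (source of SR; their ``date`` attribute is the
        fallback when ``dates`` is not given).
    pse_values:
        Mapping plot -> PSE.
    dates:
        Optional mapping plot -> integer day offset.
    """
    rows = []
    for comp in compositions:
        plot = comp.plot
        if plot not in pse_values:
            raise KeyError(f"no PSE value for plot {plot!r}")
        date = dates[plot] if dates is not None else comp.date
        rows.append((plot, species_richness(comp), float(pse_values[plot]), int(date)))
    if dates is not None:
        missing = sorted(set(dates) - {r[0] for r in rows})
        # extra dates are harmless; missing plots were caught above
    frame = pd.DataFrame(rows, columns=["plot", "sr", "pd", "date"]).set_index("plot")
    means = {k: float(frame[k].mean()) for k in ("sr", "pd", "date")}
    for k in ("sr", "pd", "date"):
        frame[f"{k}_c"] = frame[k] - means[k]
    frame["sr_pd_c"] = frame["sr_c"] * frame["pd_c"]
    return PredictorTable(frame=frame, means=means)


# -- file IO -----------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def _int_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    try:
        values = df[col].astype(int)
    except (ValueError, TypeError) as exc:
        raise SurveyError(f"non-integer value in column {col!r} of {path}") from exc
    if (df[col].astype(float) != values).any():
        raise SurveyError(f"non-integer value in column {col!r} of {path}")
    return values.to_numpy()


def read_quadrats(path) -> list[QuadratRecord]:
    """Read ``plot,quadrat,species`` rows and group them into records."""
    df = _read_table(path)
    for col in ("plot", "quadrat", "species"):
        if col not in df.columns:
            raise SurveyError(f"missing column {col!r} in {path}")
    df["quadrat"] = _int_column(df, "quadrat", path)
    records = []
    for (plot, quad), grp in df.groupby(["plot", "quadrat"], sort=True):
        records.append(QuadratRecord(plot=str(plot), quadrat=int(quad), species=frozenset(grp["species"])))
    return records


def read_composition(path, dates=None) -> list[PlotComposition]:
    """Read a sparse ``plot,species,abundance`` table."""
    df = _read_table(path)
    for col in ("plot", "species", "abundance"):
        if col not in df.columns:
            raise SurveyError(f"missing column {col!r} in {path}")
    df["abundance"] = _int_column(df, "abundance", path)
    comps = []
    for plot, grp in df.groupby("plot", sort=True):
        ab = {str(r.species): int(r.abundance) for r in grp.itertuples()}
        date = int(dates[str(plot)]) if dates is not None else 0
        comps.append(PlotComposition(plot=str(plot), abundances=ab, date=date))
    return comps


def write_composition(compositions, path) -> None:
    rows = [
        (c.plot, sp, a)
        for c in compositions
        for sp, a in sorted(c.abundances.items())
        if a > 0
    ]
    pd.DataFrame(rows, columns=["plot", "species", "abundance"]).to_csv(path, index=False)


def read_plants(path) -> list[PlantObservation]:
    """Read a ``plot,species,damaged,total`` per-plant table."""
    df = _read_table(path)
    for col in ("plot", "species", "damaged", "total"):
        if col not in df.columns:
            raise SurveyError(f"missing column {col!r} in {path}")
    damaged = _int_column(df, "damaged", path)
    total = _int_column(df, "total", path)
    return [
        PlantObservation(plot=str(p), species=str(s), damaged=int(d), total=int(t))
        for p, s, d, t in zip(df["plot"], df["species"], damaged, total)
    ]


def write_plants(plants, path) -> None:
    pd.DataFrame(
        [(p.plot, p.species, p.damaged, p.total) for p in plants],
        columns=["plot", "species", "damaged", "total"],
    ).to_csv(path, index=False)


def read_plot_summary(path) -> pd.DataFrame:
    """Read a deposited plot-level summary table.

    Layout: one row per plot with at least ``plot`` plus any of
    ``richness``/``sr``, ``pse``/``pd`` and ``herbivory`` columns (name
    matching is case-insensitive).  Useful for comparing a pipeline run
    against published plot-level values; these tables carry no per-plant
    records, so they cannot be used to refit the damage model.
    """
    df = _read_table(path)
    rename = {}
    for col in df.columns:
        low = col.strip().lower()
        if low in ("richness", "sr", "species_richness"):
            rename[col] = "sr"
        elif low in ("pse", "pd", "phylogenetic_diversity"):
            rename[col] = "pse"
        elif low in ("herbivory", "damage"):
            rename[col] = "herbivory"
        elif low == "plot":
            rename[col] = "plot"
    df = df.rename(columns=rename)
    if "plot" not in df.columns:
        raise SurveyError(f"missing column 'plot' in {path}")
    for col in df.columns:
        if col != "plot":
            df[col] = df[col].astype(float)
    return df.set_index("plot")


def read_dates(path) -> dict:
    df = _read_table(path)
    for col in ("plot", "date"):
        if col not in df.columns:
            raise SurveyError(f"missing column {col!r} in {path}")
    dates = _int_column(df, "date", path)
    return {str(p): int(d) for p, d in zip(df["plot"], dates)}


def write_dates(dates: dict, path) -> None:
    pd.DataFrame(sorted(dates.items()), columns=["plot", "date"]).to_csv(path, index=False)
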