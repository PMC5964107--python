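"""Cell and virus-like-particle count ratios across compartments.

Alongside sequence-based enrichment ratios, bulk microbial transfer can be
read directly off microscopy/flow-cytometry concentration time series: the
ratio of aerosol to bulk counts measures how efficiently whole communities
(bacterial cells, free virus particles) move across the air-sea interface,
and SSML:bulk ratios measure surface accumulation.

All concentrations are handled on the x10^7 per-mL scale on which they are
reported; converting aerosol concentrations to a per-m^3 air volume basis
(1 m^3 = 10^6 mL) is a reporting transform available on request and never
applied implicitly.  Aerosol sampling adds a 10% relative flow variance,
propagated in quadrature into every ratio whose numerator is an aerosol
series.

The package ships two small reference tables transcribed from a 34-day
wave-channel mesocosm bloom experiment: per-day virus-like-particle counts
in bulk, SSML and aerosol (``load_vlp_counts``), and the per-day aerosol to
bulk count ratios for viruses and bacteria (``load_reference_ratios``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .samples import Compartment

__all__ = [
    "Entity",
    "Convention",
    "CountSeries",
    "RatioResult",
    "FLOW_VARIANCE",
    "day_ratio",
    "average_ratio",
    "read_counts",
    "write_counts",
    "load_vlp_counts",
    "load_reference_ratios",
    "round_half_away",
]

#: Relative aerosol sampling flow variance folded into aerosol-numerator sds.
FLOW_VARIANCE = 0.10


class Entity(str, enum.Enum):
    BACTERIA_CELLS = "bacteria_cells"
    VIRUS_PARTICLES = "virus_particles"


class Convention(str, enum.Enum):
    PER_DAY = "per_day"
    MEAN_OF_RATIOS = "mean_of_ratios"
    RATIO_OF_MEANS = "ratio_of_means"


@dataclass(frozen=True)
class CountSeries:
    """Concentration time series for one entity in one compartment.

    ``observations`` maps day -> (value, sd); values are on the x10^7
    per-mL scale and sds may be None.
    """

    entity: Entity
    compartment: Compartment
    observations: tuple[tuple[int, float, float | None], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entity", Entity(self.entity))
        object.__setattr__(self, "compartment", Compartment(self.compartment))
        days = [d for d, _, _ in self.observations]
        if len(days) != len(set(days)):
            raise ValueError(
                f"duplicate day in {self.entity.value}/{self.compartment.value} series"
            )
        for d, v, sd in self.observations:
            if v < 0 or (sd is not None and sd < 0):
                raise ValueError(f"negative count or sd on day {d}")

    @property
    def days(self) -> list[int]:
        return sorted(d for d, _, _ in self.observations)

    def value(self, day: int) -> float:
        for d, v, _ in self.observations:
            if d == day:
                return v
        raise KeyError(f"no observation on day {day}")

    def sd(self, day: int) -> float | None:
        for d, _, s in self.observations:
            if d == day:
                return s
        raise KeyError(f"no observation on day {day}")


@dataclass(frozen=True)
class RatioResult:
    """A compartment count ratio, per day or averaged."""

    day: int | str  # integer day or "average"
    numerator: Compartment
    denominator: Compartment
    ratio: float
    sd: float | None
    convention: Convention


def _propagated_sd(
    ratio: float,
    num: float, num_sd: float | None,
    den: float, den_sd: float | None,
    flow: float,
) -> float | None:
    """First-order (delta-method) sd of a quotient, plus flow variance.

    Returns None when neither input sds nor flow variance contribute.
    """
    if (num_sd is None or den_sd is None) and flow == 0:
        return None
    terms = 0.0
    if num_sd is not None and den_sd is not None:
        terms += (num_sd / num) ** 2 + (den_sd / den) ** 2
    terms += flow**2
    return abs(ratio) * math.sqrt(terms)


def day_ratio(
    series_num: CountSeries,
    series_den: CountSeries,
    day: int,
    flow_variance: float = FLOW_VARIANCE,
) -> RatioResult:
    """Ratio of two compartment concentrations on one day.

    The aerosol flow variance enters (as an extra relative term in
    quadrature) only when the numerator series is an aerosol series.
    """
    num, den = series_num.value(day), series_den.value(day)
    if den == 0:
        raise ZeroDivisionError(f"denominator count is 0 on day {day}")
    flow = flow_variance if series_num.compartment is Compartment.AEROSOL else 0.0
    r = num / den
    return RatioResult(
        day=day,
        numerator=series_num.compartment,
        denominator=series_den.compartment,
        ratio=r,
        sd=_propagated_sd(r, num, series_num.sd(day), den, series_den.sd(day), flow),
        convention=Convention.PER_DAY,
    )


def average_ratio(
    series_num: CountSeries,
    series_den: CountSeries,
    convention: Convention | str = Convention.MEAN_OF_RATIOS,
    days: str = "all",
    flow_variance: float = FLOW_VARIANCE,
) -> RatioResult:
    """Average compartment ratio under one of two conventions.

    ``mean_of_ratios`` is the arithmetic mean of the per-day ratios over
    days present in both series.  ``ratio_of_means`` divides the two series'
    mean concentrations; its day sets are ``"all"`` (each series averaged
    over every day it has -- the natural reading of "average aerosol count
    over average bulk count") or ``"common"`` (both restricted to shared
    days).
    """
    convention = Convention(convention)
    if convention is Convention.PER_DAY:
        raise ValueError("use day_ratio for the per-day convention")
    if days not in {"all", "common"}:
        raise ValueError(f"days must be 'all' or 'common', got {days!r}")
    common = sorted(set(series_num.days) & set(series_den.days))
    flow = flow_variance if series_num.compartment is Compartment.AEROSOL else 0.0
    if convention is Convention.MEAN_OF_RATIOS:
        if not common:
            raise ValueError("no common day between the two series")
        per_day = [
            day_ratio(series_num, series_den, d, flow_variance) for d in common
        ]
        ratios = [p.ratio for p in per_day]
        r = float(np.mean(ratios))
        sds = [p.sd for p in per_day]
        sd = (
            math.sqrt(sum(s**2 for s in sds)) / len(sds)
            if all(s is not None for s in sds)
            else None
        )
    else:
        num_days = common if days == "common" else series_num.days
        den_days = common if days == "common" else series_den.days
        if not num_days or not den_days:
            raise ValueError("empty series")
        num_mean = float(np.mean([series_num.value(d) for d in num_days]))
        den_mean = float(np.mean([series_den.value(d) for d in den_days]))
        if den_mean == 0:
            raise ZeroDivisionError("denominator mean is 0")
        r = num_mean / den_mean
        num_sds = [series_num.sd(d) for d in num_days]
        den_sds = [series_den.sd(d) for d in den_days]
        if all(s is not None for s in num_sds) and all(s is not None for s in den_sds):
            num_sd = math.sqrt(sum(s**2 for s in num_sds)) / len(num_sds)
            den_sd = math.sqrt(sum(s**2 for s in den_sds)) / len(den_sds)
            sd = _propagated_sd(r, num_mean, num_sd, den_mean, den_sd, flow)
        else:
            sd = _propagated_sd(r, num_mean, None, den_mean, None, flow)
    return RatioResult(
        day="average",
        numerator=series_num.compartment,
        denominator=series_den.compartment,
        ratio=r,
        sd=sd,
        convention=convention,
    )


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# ---------------------------------------------------------------------------
# I/O


def read_counts(path: str | Path) -> list[CountSeries]:
    """Read a counts table (CSV or TSV) into one series per (entity, compartment).

    Expected columns: ``entity, compartment, day, value, sd`` (sd optional /
    blank).  Duplicate (entity, compartment, day) rows are an error.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty and len(df.columns) <= 1:
        return []
    required = {"entity", "compartment", "day", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing column(s): {sorted(missing)}")
    if "sd" not in df.columns:
        df["sd"] = np.nan
    key_cols = ["entity", "compartment", "day"]
    dupes = df[df.duplicated(key_cols)]
    if not dupes.empty:
        first = dupes.iloc[0]
        raise ValueError(
            "duplicate observation: "
            f"{first['entity']}/{first['compartment']}/day {first['day']}"
        )
    out: list[CountSeries] = []
    for (entity, compartment), grp in df.groupby(["entity", "compartment"], sort=False):
        obs = tuple(
            (
                int(row.day),
                float(row.value),
                None if pd.isna(row.sd) else float(row.sd),
            )
            for row in grp.itertuples(index=False)
        )
        out.append(CountSeries(Entity(entity), Compartment(compartment), obs))
    return out


def write_counts(series: Sequence[CountSeries], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "entity": s.entity.value,
            "compartment": s.compartment.value,
            "day": d,
            "value": v,
            "sd": "" if sd is None else sd,
        }
        for s in series
        for d, v, sd in s.observations
    ]
    pd.DataFrame(rows, columns=["entity", "compartment", "day", "value", "sd"]).to_csv(
        path, index=False
    )
    return path


def _data_path(name: str):
    return resources.files("aeroflux.data").joinpath(name)


def load_vlp_counts() -> dict[Compartment, CountSeries]:
    """Packaged virus-like-particle counts (x10^7 vlp/mL) by compartment.

    Epifluorescence-microscopy VLP concentrations from a 34-day wave-channel
    mesocosm bloom: 24 bulk days, 18 SSML days, 13 aerosol days.
    """
    with resources.as_file(_data_path("table1_vlp.csv")) as p:
        series = read_counts(p)
    return {s.compartment: s for s in series}


def load_reference_ratios() -> pd.DataFrame:
    """Packaged per-day aerosol:bulk count ratios (viruses and bacteria).

    Columns ``day`` (integer day or ``"average"``), ``virus_aerosol_bulk``,
    ``bacteria_aerosol_bulk``, as printed in the source tables.  The virus
    per-day entries are recomputable from :func:`load_vlp_counts`; the
    bacterial entries rest on flow-cytometry counts not shipped here.
    """
    with resources.as_file(_data_path("table2_ratios.csv")) as p:
        return pd.read_csv(p)
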