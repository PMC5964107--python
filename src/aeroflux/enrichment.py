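"""Aerosolization and surface-enrichment factors.

The aerosolization factor (AF) of a taxon is the ratio of its relative
abundance in sea spray aerosol (A) to its relative abundance in bulk
seawater (B) or in the sea surface microlayer (S):

    AF = A / B   (written A:B)    or    AF = A / S   (A:S)

and the surface enrichment factor is S:B = S / B.  AF > 1 means the taxon
is over-represented in the aerosol relative to the water it came from;
AF < 1 means it is preferentially left behind.  Because A, B and S are
per-sample fractions, AF is invariant to sequencing depth.

Ratios are plain quotients with no pseudocounts: a zero denominator yields
a flagged undefined value that summaries simply skip.  Rare-taxon noise is
handled upstream by the abundance filter, not by smoothing.

Each taxon lands in one quadrant of the (A:B, A:S) plane per day:
aerosol-enriched (both > 1), waterborne (both < 1), or enriched relative
to one compartment only.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .samples import (
    AbundanceMatrix,
    AbundanceTableError,
    Compartment,
    Domain,
    Mode,
    SizeFraction,
)

__all__ = [
    "Ratio",
    "EnrichmentRecord",
    "Quadrant",
    "compute_enrichment",
    "classify_quadrant",
    "enrichment_summary",
    "EnrichmentSummary",
    "records_to_frame",
    "write_enrichment_table",
]


@dataclass(frozen=True)
class Ratio:
    """A compartment ratio that may be undefined.

    ``flag`` is None for a defined value, ``"zero_denominator"`` when the
    denominator fraction is 0 but the numerator is positive, ``"absent"``
    when both are 0, and ``"missing_sample"`` when a compartment was not
    sampled in that (day, size fraction) group.
    """

    value: float | None
    flag: str | None = None

    @property
    def defined(self) -> bool:
        return self.flag is None

    @staticmethod
    def of(numerator: float, denominator: float) -> "Ratio":
        if denominator > 0:
            return Ratio(numerator / denominator)
        if numerator > 0:
            return Ratio(None, "zero_denominator")
        return Ratio(None, "absent")


#: Sentinel for a ratio whose compartment was not sampled in the group.
Ratio.MISSING = Ratio(None, "missing_sample")


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-taxon, per-day enrichment ratios in one size fraction.

    ``af_bulk`` is A:B, ``af_ssml`` is A:S, ``sb`` is S:B.  Whenever all
    three are defined the chain identity A:B = (A:S) x (S:B) holds to
    floating precision.
    """

    taxon_id: str
    day: int
    size_fraction: SizeFraction
    A: float | None
    B: float | None
    S: float | None
    af_bulk: Ratio
    af_ssml: Ratio
    sb: Ratio


class Quadrant(str, enum.Enum):
    AEROSOL_ENRICHED = "aerosol_enriched"      # A:B > 1 and A:S > 1
    WATERBORNE = "waterborne"                  # A:B < 1 and A:S < 1
    BULK_ONLY_ENRICHED = "bulk_only_enriched"  # A:B > 1, A:S < 1
    SSML_ONLY_ENRICHED = "ssml_only_enriched"  # A:B < 1, A:S > 1
    NEUTRAL = "neutral"
    UNDEFINED = "undefined"


def compute_enrichment(matrix: AbundanceMatrix) -> list[EnrichmentRecord]:
    """Compute A:B, A:S and S:B for every taxon in every (day, size fraction).

    The matrix must be in fractions mode (typically post-filter).  Within a
    (day, size fraction) group at most one sample per compartment may be
    present; groups with fewer than two compartments yield no records.
    """
    if matrix.mode is not Mode.FRACTIONS:
        raise AbundanceTableError("enrichment requires fractions mode")
    groups: dict[tuple[int, SizeFraction], dict[Compartment, str]] = {}
    for s in matrix.samples:
        key = s.group_key
        comp = groups.setdefault(key, {})
        if s.compartment in comp:
            raise AbundanceTableError(
                f"duplicate compartment {s.compartment.value} in group {key}"
            )
        comp[s.compartment] = s.sample_id
    records: list[EnrichmentRecord] = []
    vals = matrix.values
    for (day, sf), comp in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        if len(comp) < 2:
            continue
        a_col = comp.get(Compartment.AEROSOL)
        b_col = comp.get(Compartment.BULK)
        s_col = comp.get(Compartment.SSML)
        for taxon in vals.index:
            A = float(vals.at[taxon, a_col]) if a_col else None
            B = float(vals.at[taxon, b_col]) if b_col else None
            S = float(vals.at[taxon, s_col]) if s_col else None
            af_bulk = Ratio.of(A, B) if A is not None and B is not None else Ratio.MISSING
            af_ssml = Ratio.of(A, S) if A is not None and S is not None else Ratio.MISSING
            sb = Ratio.of(S, B) if S is not None and B is not None else Ratio.MISSING
            records.append(
                EnrichmentRecord(
                    taxon_id=taxon, day=day, size_fraction=sf,
                    A=A, B=B, S=S,
                    af_bulk=af_bulk, af_ssml=af_ssml, sb=sb,
                )
            )
    return records


def classify_quadrant(record: EnrichmentRecord, tie_epsilon: float = 0.0) -> Quadrant:
    """Place a record in the (A:B, A:S) quadrant scheme.

    With ``tie_epsilon`` = 0 the comparisons are exact and only AF values
    equal to 1 are neutral; a positive epsilon widens the neutral band to
    [1 - eps, 1 + eps] on either ratio.
    """
    if not (record.af_bulk.defined and record.af_ssml.defined):
        return Quadrant.UNDEFINED
    ab, as_ = record.af_bulk.value, record.af_ssml.value
    hi, lo = 1.0 + tie_epsilon, 1.0 - tie_epsilon
    if ab > hi and as_ > hi:
        return Quadrant.AEROSOL_ENRICHED
    if ab < lo and as_ < lo:
        return Quadrant.WATERBORNE
    if ab > hi and as_ < lo:
        return Quadrant.BULK_ONLY_ENRICHED
    if ab < lo and as_ > hi:
        return Quadrant.SSML_ONLY_ENRICHED
    return Quadrant.NEUTRAL


@dataclass(frozen=True)
class EnrichmentSummary:
    """Distribution summary of a set of defined AF values."""

    n: int
    mean: float
    sd: float
    skewness: float
    normality_p: float
    normality_test: str
    fraction_below_1: float
    mean_taxon_max: float
    mean_taxon_min: float
    amplitude_ratio: float


def _af_values(
    records: Iterable[EnrichmentRecord],
    ratios: str,
) -> tuple[list[float], dict[str, list[float]]]:
    pooled: list[float] = []
    per_taxon: dict[str, list[float]] = {}
    for r in records:
        chosen: list[Ratio] = []
        if ratios in ("pooled", "bulk"):
            chosen.append(r.af_bulk)
        if ratios in ("pooled", "ssml"):
            chosen.append(r.af_ssml)
        for ratio in chosen:
            if ratio.defined:
                pooled.append(ratio.value)
                per_taxon.setdefault(r.taxon_id, []).append(ratio.value)
    return pooled, per_taxon


def enrichment_summary(
    records: Sequence[EnrichmentRecord],
    domain_filter: Domain | None = None,
    taxa: dict[str, Domain] | None = None,
    ratios: str = "pooled",
    normality_test: str = "shapiro",
) -> EnrichmentSummary:
    """Summarize the distribution of defined AF values.

    ``ratios`` selects which ratios enter: ``"pooled"`` (A:B and A:S, the
    default), ``"bulk"`` (A:B only) or ``"ssml"`` (A:S only).  Skewness is
    the adjusted Fisher-Pearson standardized moment; the normality test is
    Shapiro-Wilk by default (``"normaltest"`` selects the D'Agostino-Pearson
    omnibus test instead), and the choice is recorded in the output.

    The amplitude ratio compares how far taxa typically rise above 1 at
    their maximum versus how far they fall below 1 at their minimum:
    mean over taxa of |max AF - 1| divided by mean of |1 - min AF|.
    """
    if ratios not in {"pooled", "bulk", "ssml"}:
        raise ValueError(f"unknown ratio selection {ratios!r}")
    if domain_filter is not None:
        if taxa is None:
            raise ValueError("domain_filter requires a taxa -> domain mapping")
        records = [
            r for r in records if taxa.get(r.taxon_id) == Domain(domain_filter)
        ]
    pooled, per_taxon = _af_values(records, ratios)
    if not pooled:
        raise ValueError("no defined AF values to summarize")
    arr = np.asarray(pooled, dtype=float)
    if arr.size < 3:
        skew = float("nan")
    elif np.ptp(arr) == 0:
        skew = 0.0  # constant data: no asymmetry, and the moment ratio is 0/0
    else:
        skew = float(stats.skew(arr, bias=False))
    if arr.size >= 8 and np.ptp(arr) > 0:
        if normality_test == "shapiro":
            p = float(stats.shapiro(arr).pvalue)
        elif normality_test == "normaltest":
            p = float(stats.normaltest(arr).pvalue)
        else:
            raise ValueError(f"unknown normality test {normality_test!r}")
    else:
        p = float("nan")
    maxima = np.array([max(v) for v in per_taxon.values()])
    minima = np.array([min(v) for v in per_taxon.values()])
    denom = float(np.mean(np.abs(1.0 - minima)))
    amp = float(np.mean(np.abs(maxima - 1.0))) / denom if denom > 0 else float("inf")
    return EnrichmentSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        skewness=skew,
        normality_p=p,
        normality_test=normality_test,
        fraction_below_1=float((arr < 1.0).mean()),
        mean_taxon_max=float(maxima.mean()),
        mean_taxon_min=float(minima.mean()),
        amplitude_ratio=amp,
    )


# ---------------------------------------------------------------------------
# Tabular export


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Flatten records to the standard TSV layout."""
    rows = []
    for r in records:
        flags = ";".join(
            f"{name}:{ratio.flag}"
            for name, ratio in (("af_bulk", r.af_bulk), ("af_ssml", r.af_ssml), ("sb", r.sb))
            if ratio.flag is not None
        )
        rows.append(
            {
                "taxon_id": r.taxon_id,
                "day": r.day,
                "size_fraction": r.size_fraction.value,
                "A": r.A, "B": r.B, "S": r.S,
                "af_bulk": r.af_bulk.value if r.af_bulk.defined else np.nan,
                "af_ssml": r.af_ssml.value if r.af_ssml.defined else np.nan,
                "sb": r.sb.value if r.sb.defined else np.nan,
                "quadrant": classify_quadrant(r).value,
                "flags": flags,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["taxon_id", "day", "size_fraction", "A", "B", "S",
                 "af_bulk", "af_ssml", "sb", "quadrant", "flags"],
    )


def write_enrichment_table(records: Sequence[EnrichmentRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, sep="\t", index=False)
    return path
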