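"""Temporal classification and group-level aggregation of enrichment ratios.

A taxon whose observed aerosolization factors sit on one side of 1 in at
least 80% of observations is a *constitutive* aerosolizer (enriched or
depleted); one that swings across 1 is *intermittent*.  Constitutive
behaviour suggests a fixed surface property (e.g. a hydrophobic envelope),
whereas intermittency points at physiological or environmental modulation.

Aggregation by taxonomic class/order, by viral envelope state, or by domain
exposes whether aerosolization is phylogenetically conserved, and the
bacteria-versus-virus comparison quantifies the overall transfer deficit of
viruses relative to bacteria.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentRecord, EnrichmentSummary, Ratio, enrichment_summary
from .samples import Domain, TaxonInfo

__all__ = [
    "TemporalLabel",
    "TemporalClassification",
    "classify_temporal",
    "classify_all",
    "GroupSummary",
    "group_aggregate",
    "DomainComparison",
    "compare_domains",
    "af_series_by_taxon",
]


class TemporalLabel(str, enum.Enum):
    CONSTITUTIVE_ENRICHED = "constitutive_enriched"
    CONSTITUTIVE_DEPLETED = "constitutive_depleted"
    INTERMITTENT = "intermittent"
    INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class TemporalClassification:
    """Outcome of the 80%-rule on one taxon's defined AF series.

    AF values exactly equal to 1 count toward ``n_observed`` but toward
    neither side, so a taxon pinned at 1 is intermittent, not constitutive.
    """

    taxon_id: str
    n_observed: int
    n_above: int
    n_below: int
    label: TemporalLabel


def classify_temporal(
    taxon_id: str,
    af_values: Sequence[float],
    q: float = 0.8,
    min_obs: int = 3,
) -> TemporalClassification:
    """Classify one AF series as constitutive, intermittent, or insufficient.

    ``af_values`` must contain only defined AF observations (undefined
    ratios are dropped upstream).  The taxon is constitutive-enriched when
    at least a fraction ``q`` (inclusive) of observations exceed 1,
    constitutive-depleted symmetrically, and intermittent otherwise;
    series shorter than ``min_obs`` are labelled insufficient.
    """
    if not (0.5 <= q <= 1.0):
        raise ValueError(f"q must be in [0.5, 1], got {q}")
    vals = [float(v) for v in af_values]
    n = len(vals)
    n_above = sum(v > 1.0 for v in vals)
    n_below = sum(v < 1.0 for v in vals)
    if n < min_obs:
        label = TemporalLabel.INSUFFICIENT
    elif n_above / n >= q:
        label = TemporalLabel.CONSTITUTIVE_ENRICHED
    elif n_below / n >= q:
        label = TemporalLabel.CONSTITUTIVE_DEPLETED
    else:
        label = TemporalLabel.INTERMITTENT
    return TemporalClassification(taxon_id, n, n_above, n_below, label)


def af_series_by_taxon(
    records: Iterable[EnrichmentRecord],
    ratios: str = "pooled",
) -> dict[str, list[float]]:
    """Collect each taxon's defined AF observations.

    By default both A:B and A:S contribute to the series (``"pooled"``);
    ``"bulk"`` or ``"ssml"`` restrict to a single ratio.
    """
    if ratios not in {"pooled", "bulk", "ssml"}:
        raise ValueError(f"unknown ratio selection {ratios!r}")
    series: dict[str, list[float]] = {}
    for r in records:
        chosen: list[Ratio] = []
        if ratios in ("pooled", "bulk"):
            chosen.append(r.af_bulk)
        if ratios in ("pooled", "ssml"):
            chosen.append(r.af_ssml)
        for ratio in chosen:
            if ratio.defined:
                series.setdefault(r.taxon_id, []).append(ratio.value)
    return series


def classify_all(
    records: Iterable[EnrichmentRecord],
    q: float = 0.8,
    min_obs: int = 3,
    ratios: str = "pooled",
) -> dict[str, TemporalClassification]:
    """Run the temporal classifier over every taxon with defined AF values."""
    return {
        taxon: classify_temporal(taxon, vals, q=q, min_obs=min_obs)
        for taxon, vals in af_series_by_taxon(records, ratios).items()
    }


# ---------------------------------------------------------------------------
# Group aggregation


@dataclass(frozen=True)
class GroupSummary:
    """Mean enrichment behaviour of one taxonomic / trait group."""

    group_by: str
    group: str
    n_taxa: int
    mean_af: float
    mean_sb: float
    fraction_constitutive: float


_GROUP_KEYS = {"class", "order", "family", "envelope", "domain"}


def _group_of(info: TaxonInfo, group_by: str) -> str | None:
    if group_by == "domain":
        return info.domain.value
    if group_by == "envelope":
        if info.domain is not Domain.VIRUS or info.enveloped is None:
            return None
        return "enveloped" if info.enveloped else "non_enveloped"
    return info.rank(group_by)


def group_aggregate(
    records: Sequence[EnrichmentRecord],
    lineage: Mapping[str, TaxonInfo],
    group_by: str,
    classifications: Mapping[str, TemporalClassification] | None = None,
    exclude_days: Sequence[int] = (),
    ratios: str = "pooled",
    pooled_observations: bool = False,
) -> list[GroupSummary]:
    """Average AF and S:B within lineage or trait groups.

    Group means are taken over per-taxon means (each taxon weighs equally
    regardless of how often it was observed); set ``pooled_observations``
    to average raw observations instead.  Taxa lacking the grouping
    annotation are collected under ``"unannotated"``.  ``exclude_days``
    drops whole days before averaging -- e.g. days on which a global
    surface-enrichment event would dominate the S:B mean.
    """
    if group_by not in _GROUP_KEYS:
        raise ValueError(f"unknown group_by {group_by!r}; choose from {sorted(_GROUP_KEYS)}")
    excluded = set(exclude_days)
    recs = [r for r in records if r.day not in excluded]
    af_series = af_series_by_taxon(recs, ratios)
    sb_series: dict[str, list[float]] = {}
    for r in recs:
        if r.sb.defined:
            sb_series.setdefault(r.taxon_id, []).append(r.sb.value)
    taxa = sorted(set(af_series) | set(sb_series))
    groups: dict[str, list[str]] = {}
    for t in taxa:
        info = lineage.get(t, TaxonInfo(taxon_id=t))
        g = _group_of(info, group_by) or "unannotated"
        groups.setdefault(g, []).append(t)
    out: list[GroupSummary] = []
    for g in sorted(groups):
        members = groups[g]
        if pooled_observations:
            af_pool = [v for t in members for v in af_series.get(t, [])]
            sb_pool = [v for t in members for v in sb_series.get(t, [])]
        else:
            af_pool = [float(np.mean(af_series[t])) for t in members if t in af_series]
            sb_pool = [float(np.mean(sb_series[t])) for t in members if t in sb_series]
        if classifications:
            labelled = [t for t in members if t in classifications]
            const = [
                t for t in labelled
                if classifications[t].label in (
                    TemporalLabel.CONSTITUTIVE_ENRICHED,
                    TemporalLabel.CONSTITUTIVE_DEPLETED,
                )
            ]
            frac_const = len(const) / len(labelled) if labelled else float("nan")
        else:
            frac_const = float("nan")
        out.append(
            GroupSummary(
                group_by=group_by,
                group=g,
                n_taxa=len(members),
                mean_af=float(np.mean(af_pool)) if af_pool else float("nan"),
                mean_sb=float(np.mean(sb_pool)) if sb_pool else float("nan"),
                fraction_constitutive=frac_const,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Bacteria vs virus comparison


@dataclass(frozen=True)
class DomainComparison:
    """Bacterial versus viral AF distribution comparison.

    ``pvalue`` is from the two-sided Mann-Whitney U (rank) test on the
    pooled defined AF observations; ``per_day_mean`` exposes day-resolved
    means to reveal temporal clustering (e.g. viral AFs moving together on
    a given day).
    """

    bacteria: EnrichmentSummary
    viruses: EnrichmentSummary
    mean_difference: float  # viral mean minus bacterial mean
    pvalue: float
    per_day_mean: pd.DataFrame  # columns: day, bacteria, viruses


def compare_domains(
    bacterial_records: Sequence[EnrichmentRecord],
    viral_records: Sequence[EnrichmentRecord],
    ratios: str = "pooled",
) -> DomainComparison:
    """Compare AF distributions between bacteria and viruses."""
    if not bacterial_records or not viral_records:
        raise ValueError("both record sets must be non-empty")
    b_sum = enrichment_summary(bacterial_records, ratios=ratios)
    v_sum = enrichment_summary(viral_records, ratios=ratios)

    def _pool(records: Sequence[EnrichmentRecord]) -> np.ndarray:
        series = af_series_by_taxon(records, ratios)
        return np.array([v for vals in series.values() for v in vals])

    b_vals, v_vals = _pool(bacterial_records), _pool(viral_records)
    if np.array_equal(np.sort(b_vals), np.sort(v_vals)):
        p = 1.0  # identical multisets: no evidence of a shift
    else:
        p = float(stats.mannwhitneyu(b_vals, v_vals, alternative="two-sided").pvalue)

    def _by_day(records: Sequence[EnrichmentRecord]) -> dict[int, float]:
        acc: dict[int, list[float]] = {}
        for r in records:
            for ratio in (r.af_bulk, r.af_ssml) if ratios == "pooled" else (
                (r.af_bulk,) if ratios == "bulk" else (r.af_ssml,)
            ):
                if ratio.defined:
                    acc.setdefault(r.day, []).append(ratio.value)
        return {d: float(np.mean(v)) for d, v in acc.items()}

    b_day, v_day = _by_day(bacterial_records), _by_day(viral_records)
    days = sorted(set(b_day) | set(v_day))
    per_day = pd.DataFrame(
        {
            "day": days,
            "bacteria": [b_day.get(d, np.nan) for d in days],
            "viruses": [v_day.get(d, np.nan) for d in days],
        }
    )
    return DomainComparison(
        bacteria=b_sum,
        viruses=v_sum,
        mean_difference=v_sum.mean - b_sum.mean,
        pvalue=p,
        per_day_mean=per_day,
    )


def classifications_to_frame(
    classifications: Mapping[str, TemporalClassification]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_id": c.taxon_id,
                "n_observed": c.n_observed,
                "n_above": c.n_above,
                "n_below": c.n_below,
                "label": c.label.value,
            }
            for c in classifications.values()
        ],
        columns=["taxon_id", "n_observed", "n_above", "n_below", "label"],
    )


def write_classification_table(
    classifications: Mapping[str, TemporalClassification], path: str | Path
) -> Path:
    path = Path(path)
    classifications_to_frame(classifications).to_csv(path, sep="\t", index=False)
    return path


def write_group_table(groups: Sequence[GroupSummary], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "group_by": g.group_by,
                "group": g.group,
                "n_taxa": g.n_taxa,
                "mean_af": g.mean_af,
                "mean_sb": g.mean_sb,
                "fraction_constitutive": g.fraction_constitutive,
            }
            for g in groups
        ]
    ).to_csv(path, sep="\t", index=False)
    return path
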