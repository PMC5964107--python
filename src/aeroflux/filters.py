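"""Abundance-threshold and genome spatial-coverage exclusion filters.

Read-based taxonomic profiles of environmental metagenomes carry two kinds
of unreliable assignments: genuinely rare taxa whose fractions are dominated
by classifier noise, and spurious species calls driven by a handful of reads
mapping to ubiquitous elements (transposons, rRNA) of an otherwise absent
reference genome.  The two filters here address them separately:

* the abundance filter removes a taxon when its relative abundance dips
  below a hard floor in any sample, or sits below a soft floor in too many
  samples;
* the coverage filter removes a taxon when the mapped reads cover less than
  a threshold fraction (default 0.1%) of its reference genome's positions
  ("spatial coverage", i.e. breadth of coverage).

Both rules are per-taxon and independent of each other, so their composition
is order-independent.  Filtered matrices are never renormalized: surviving
fractions keep their original denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .samples import AbundanceMatrix, AbundanceTableError, Mode

__all__ = [
    "AbundanceFilterConfig",
    "CoverageProfile",
    "FilterReport",
    "apply_abundance_filter",
    "coverage_fraction",
    "apply_coverage_filter",
    "read_bedgraph",
    "read_genome_lengths",
]

#: Default spatial-coverage retention threshold (fraction of genome positions).
DEFAULT_COVERAGE_THRESHOLD = 0.001


@dataclass(frozen=True)
class AbundanceFilterConfig:
    """Thresholds for the two-clause abundance exclusion rule.

    A taxon is removed iff

    * its fraction is below ``min_fraction_any_sample`` in at least one
      sample ("any-sample" clause), or
    * at least ``max_low_samples`` samples have its fraction below
      ``low_fraction`` ("low-samples" clause).

    Two published variants exist.  The procedural ("methods") variant uses
    1e-5 / 1e-4 with a 10-of-18-samples count; the narrative ("results")
    variant uses 1e-4 / 1e-3 with "more than half of samples".  Fractions are
    on [0, 1]; percent thresholds are converted once at construction time,
    never inside the filter.
    """

    min_fraction_any_sample: float = 1e-5
    low_fraction: float = 1e-4
    max_low_samples: int | None = None
    variant: str = "methods"

    def __post_init__(self) -> None:
        if not (0 <= self.min_fraction_any_sample <= self.low_fraction <= 1):
            raise ValueError(
                "need 0 <= min_fraction_any_sample <= low_fraction <= 1, got "
                f"{self.min_fraction_any_sample} / {self.low_fraction}"
            )
        if self.variant not in {"methods", "results"}:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.max_low_samples is not None and self.max_low_samples < 0:
            raise ValueError("max_low_samples must be >= 0")

    @classmethod
    def methods_variant(cls, max_low_samples: int | None = None) -> "AbundanceFilterConfig":
        """The procedural rule: <0.001% anywhere, or >=10 of 18 samples <0.01%."""
        return cls(1e-5, 1e-4, max_low_samples, "methods")

    @classmethod
    def results_variant(cls, max_low_samples: int | None = None) -> "AbundanceFilterConfig":
        """The narrative rule: <0.01% anywhere, or more than half of samples <0.1%."""
        return cls(1e-4, 1e-3, max_low_samples, "results")

    def low_sample_count(self, n_samples: int) -> int:
        """Resolve the low-samples clause count for an ``n_samples`` design.

        When ``max_low_samples`` is unset, the methods variant scales the
        10-of-18 count as ceil(10 * N / 18); the results variant means
        "more than half", i.e. floor(N/2) + 1.
        """
        if self.max_low_samples is not None:
            return self.max_low_samples
        if self.variant == "methods":
            return math.ceil(10 * n_samples / 18)
        return n_samples // 2 + 1


@dataclass
class FilterReport:
    """Per-taxon record of which exclusion rule fired (or why none did)."""

    removed: dict[str, str] = field(default_factory=dict)  # taxon_id -> rule
    retained: list[str] = field(default_factory=list)
    notes: dict[str, str] = field(default_factory=dict)  # e.g. "no reference"
    statistics: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon_id": t, "rule": rule, "statistic": self.statistics.get(t, float("nan"))}
            for t, rule in self.removed.items()
        ]
        rows += [
            {"taxon_id": t, "rule": self.notes.get(t, "retained"),
             "statistic": self.statistics.get(t, float("nan"))}
            for t in self.retained
        ]
        return pd.DataFrame(rows, columns=["taxon_id", "rule", "statistic"])


def apply_abundance_filter(
    matrix: AbundanceMatrix, config: AbundanceFilterConfig | None = None
) -> tuple[AbundanceMatrix, FilterReport]:
    """Apply the two-clause abundance rule to a fractions-mode matrix.

    Returns the retained matrix (original denominators preserved -- no
    renormalization) and a report naming, for each removed taxon, the first
    clause that fired ("any-sample" before "low-samples").
    """
    if matrix.mode is not Mode.FRACTIONS:
        raise AbundanceTableError("abundance filter requires fractions mode")
    config = config or AbundanceFilterConfig()
    n = len(matrix.sample_ids)
    low_count = config.low_sample_count(n)
    report = FilterReport()
    vals = matrix.values
    for taxon in vals.index:
        row = vals.loc[taxon]
        fmin = float(row.min())
        n_low = int((row < config.low_fraction).sum())
        if fmin < config.min_fraction_any_sample:
            report.removed[taxon] = "any-sample"
            report.statistics[taxon] = fmin
        elif n_low >= low_count:
            report.removed[taxon] = "low-samples"
            report.statistics[taxon] = n_low
        else:
            report.retained.append(taxon)
    return matrix.subset_taxa(report.retained), report


# ---------------------------------------------------------------------------
# Spatial coverage


@dataclass(frozen=True)
class CoverageProfile:
    """Covered positions of one (concatenated) reference genome.

    Intervals are 0-based half-open [start, end) on the concatenated genome
    and are canonicalized on construction: sorted, merged, non-overlapping.
    """

    taxon_id: str
    genome_length: int
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError(f"genome_length must be > 0, got {self.genome_length}")
        merged = merge_intervals(self.intervals)
        for start, end in merged:
            if start < 0 or end > self.genome_length:
                raise ValueError(
                    f"interval [{start}, {end}) outside genome of length "
                    f"{self.genome_length} for {self.taxon_id}"
                )
        object.__setattr__(self, "intervals", merged)

    @property
    def covered_positions(self) -> int:
        return sum(e - s for s, e in self.intervals)


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    """Canonicalize half-open intervals: sort, merge touching/overlapping."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def coverage_fraction(profile: CoverageProfile) -> float:
    """Breadth of coverage: covered positions / genome length, in [0, 1]."""
    return profile.covered_positions / profile.genome_length


def apply_coverage_filter(
    matrix: AbundanceMatrix,
    profiles: Mapping[str, CoverageProfile],
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> tuple[AbundanceMatrix, FilterReport]:
    """Remove taxa whose spatial coverage is strictly below ``threshold``.

    Taxa with no profile (no usable reference genome) cannot be tested and
    are retained, flagged ``"no reference"`` in the report.  A taxon at
    exactly the threshold is retained.
    """
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    report = FilterReport()
    for taxon in matrix.taxon_ids:
        prof = profiles.get(taxon)
        if prof is None:
            report.retained.append(taxon)
            report.notes[taxon] = "no reference"
            continue
        frac = coverage_fraction(prof)
        report.statistics[taxon] = frac
        if frac < threshold:
            report.removed[taxon] = "low-coverage"
        else:
            report.retained.append(taxon)
    return matrix.subset_taxa(report.retained), report


def read_bedgraph(
    path: str | Path,
    genome_length: int,
    taxon_id: str | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> CoverageProfile:
    """Build a coverage profile from a 4-column bedgraph.

    Multiple chromosomes/contigs are concatenated in file order with
    cumulative offsets (coordinates restart per contig in the file; the
    profile lives on the concatenated genome).  Only presence matters:
    intervals with value > 0 are covered, the depth itself is discarded.
    ``genome_length`` is the total concatenated length and caps the final
    coordinate.

    When ``chrom_lengths`` is given it fixes each contig's extent exactly;
    otherwise the extent is the maximum end coordinate observed for the
    contig, which is exact for bedgraphs that report zero-coverage runs
    (``bedtools genomecov -bga`` output) and a lower bound otherwise.
    """
    path = Path(path)
    intervals: list[tuple[int, int]] = []
    offset = 0
    current_chrom: str | None = None
    chrom_extent = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start {start} >= end {end}")
            if chrom != current_chrom:
                if current_chrom is not None:
                    offset += chrom_extent
                current_chrom = chrom
                chrom_extent = 0
            if chrom_lengths is not None:
                if chrom not in chrom_lengths:
                    raise ValueError(f"{path}:{ln}: unknown contig {chrom!r}")
                if end > chrom_lengths[chrom]:
                    raise ValueError(
                        f"{path}:{ln}: end {end} beyond contig length "
                        f"{chrom_lengths[chrom]}"
                    )
                chrom_extent = chrom_lengths[chrom]
            else:
                chrom_extent = max(chrom_extent, end)
            if offset + end > genome_length:
                raise ValueError(
                    f"{path}:{ln}: position {offset + end} exceeds genome "
                    f"length {genome_length}"
                )
            if value > 0:
                intervals.append((offset + start, offset + end))
    return CoverageProfile(
        taxon_id=taxon_id or path.stem,
        genome_length=genome_length,
        intervals=tuple(intervals),
    )


def read_genome_lengths(path: str | Path) -> dict[str, int]:
    """Read a TSV ``taxon_id, genome_length`` into a dict."""
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str, "genome_length": int})
    if not {"taxon_id", "genome_length"} <= set(df.columns):
        raise ValueError("genome length table needs taxon_id and genome_length columns")
    return dict(zip(df["taxon_id"], df["genome_length"]))
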