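"""Sample, taxon, and abundance-table data model.

The study design this package targets samples three compartments of an
enclosed ocean-atmosphere mesocosm -- bulk seawater, the sea surface
microlayer (SSML), and sea spray aerosol (SSA) -- on a series of days,
with each sample split by serial filtration into two size fractions
(0.2-3 um, which captures free bacteria, and 0.025-0.2 um, which captures
free viruses).  Shotgun reads from each filter are taxonomically profiled,
giving a taxon x sample count table.  Everything downstream (filtering,
aerosolization factors, temporal classification) operates on per-sample
relative abundances, so the central invariant here is that normalization
is per-column and depth-invariant.

The canonical on-disk formats are plain TSV:

* abundance table -- first column ``taxon_id``, remaining columns sample ids;
* sample metadata -- columns ``sample_id, day, compartment, size_fraction``;
* lineage table   -- columns ``taxon_id, name, domain, class, order, family,
  enveloped`` (``enveloped`` meaningful for viruses only).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Compartment",
    "SizeFraction",
    "Domain",
    "SampleDescriptor",
    "TaxonInfo",
    "AbundanceMatrix",
    "AbundanceTableError",
    "read_abundance_table",
    "write_abundance_table",
    "read_lineage_table",
    "write_lineage_table",
    "normalize",
]


class AbundanceTableError(ValueError):
    """Raised for malformed abundance, metadata, or lineage inputs."""


class Compartment(str, enum.Enum):
    """Mesocosm compartment a sample was drawn from."""

    BULK = "bulk"
    SSML = "ssml"
    AEROSOL = "aerosol"


class SizeFraction(str, enum.Enum):
    """Serial-filtration size window.

    ``F3000_200`` is the 0.2-3 um window (free bacteria); ``F200_25`` is the
    0.025-0.2 um window (free viruses).  Names encode the bounds in nm.
    """

    F3000_200 = "f3000_200"
    F200_25 = "f200_25"


class Domain(str, enum.Enum):
    BACTERIA = "bacteria"
    VIRUS = "virus"
    OTHER = "other"


@dataclass(frozen=True)
class SampleDescriptor:
    """Identity of one metagenomic sample."""

    sample_id: str
    day: int
    compartment: Compartment
    size_fraction: SizeFraction

    def __post_init__(self) -> None:
        if self.day < 0:
            raise AbundanceTableError(f"day must be >= 0, got {self.day}")
        object.__setattr__(self, "compartment", Compartment(self.compartment))
        object.__setattr__(self, "size_fraction", SizeFraction(self.size_fraction))

    @property
    def group_key(self) -> tuple[int, SizeFraction]:
        """(day, size_fraction) -- the unit within which compartments are compared."""
        return (self.day, self.size_fraction)


@dataclass(frozen=True)
class TaxonInfo:
    """Taxonomic annotation for one genome/species.

    ``lineage`` is an ordered (rank, name) tuple covering at least class and
    order where known.  ``enveloped`` is meaningful only for viruses (lipid
    envelope present / absent) and must be None otherwise.
    """

    taxon_id: str
    name: str = ""
    domain: Domain = Domain.OTHER
    lineage: tuple[tuple[str, str], ...] = ()
    enveloped: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain", Domain(self.domain))
        ranks = [r for r, _ in self.lineage]
        if len(ranks) != len(set(ranks)):
            raise AbundanceTableError(
                f"duplicate rank in lineage of {self.taxon_id}: {ranks}"
            )
        if self.enveloped is not None and self.domain is not Domain.VIRUS:
            raise AbundanceTableError(
                f"enveloped flag set on non-virus taxon {self.taxon_id}"
            )

    def rank(self, rank_name: str) -> str | None:
        for r, n in self.lineage:
            if r == rank_name:
                return n
        return None


class Mode(str, enum.Enum):
    COUNTS = "counts"
    FRACTIONS = "fractions"


@dataclass
class AbundanceMatrix:
    """Taxon x sample abundance table.

    ``values`` is a DataFrame indexed by taxon_id with one column per
    sample_id; ``mode`` records whether entries are raw read counts or
    per-sample fractions.  In fractions mode every non-flagged column sums
    to 1 within 1e-9; columns that were all-zero at normalization time stay
    zero and are listed in ``zero_samples``.
    """

    values: pd.DataFrame
    samples: tuple[SampleDescriptor, ...]
    taxa: tuple[TaxonInfo, ...] = ()
    mode: Mode = Mode.COUNTS
    zero_samples: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        if (self.values.to_numpy() < 0).any():
            raise AbundanceTableError("negative abundance value")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise AbundanceTableError(f"duplicate taxon_id(s): {dupes}")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise AbundanceTableError("duplicate sample_id in metadata")
        keys = [(s.day, s.compartment, s.size_fraction) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise AbundanceTableError(
                "duplicate (day, compartment, size_fraction) in metadata"
            )
        missing = [c for c in self.values.columns if c not in set(sample_ids)]
        if missing:
            raise AbundanceTableError(
                f"sample column(s) without metadata: {missing}"
            )
        # keep only descriptors for columns actually present, in column order
        by_id = {s.sample_id: s for s in self.samples}
        self.samples = tuple(by_id[c] for c in self.values.columns)
        if not self.taxa:
            self.taxa = tuple(TaxonInfo(taxon_id=t) for t in self.values.index)
        else:
            by_taxon = {t.taxon_id: t for t in self.taxa}
            unknown = [t for t in self.values.index if t not in by_taxon]
            if unknown:
                self.taxa = tuple(
                    by_taxon.get(t, TaxonInfo(taxon_id=t)) for t in self.values.index
                )
            else:
                self.taxa = tuple(by_taxon[t] for t in self.values.index)
        if self.mode is Mode.FRACTIONS:
            sums = self.values.sum(axis=0)
            for sid, s in sums.items():
                if sid in self.zero_samples:
                    if s != 0:
                        raise AbundanceTableError(
                            f"flagged all-zero sample {sid} has nonzero mass"
                        )
                elif abs(s - 1.0) > 1e-9:
                    raise AbundanceTableError(
                        f"fractions column {sid} sums to {s!r}, not 1"
                    )

    # -- convenience -------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def taxon_info(self, taxon_id: str) -> TaxonInfo:
        for t in self.taxa:
            if t.taxon_id == taxon_id:
                return t
        raise KeyError(taxon_id)

    def subset_size_fraction(self, size_fraction: SizeFraction | str) -> "AbundanceMatrix":
        """Restrict to the columns of one size fraction.

        Enrichment and filtering are defined within a size fraction (the
        0.2-3 um window for bacteria, 0.025-0.2 um for free viruses), so a
        two-fraction study is analyzed as two single-fraction matrices.
        Fractions are untouched; taxa absent from every retained column
        (e.g. viruses in the bacterial fraction) remain as all-zero rows and
        fall to the abundance filter.
        """
        sf = SizeFraction(size_fraction)
        keep = [s.sample_id for s in self.samples if s.size_fraction is sf]
        m = AbundanceMatrix.__new__(AbundanceMatrix)
        m.values = self.values[keep]
        m.samples = tuple(s for s in self.samples if s.sample_id in set(keep))
        m.taxa = self.taxa
        m.mode = self.mode
        m.zero_samples = frozenset(z for z in self.zero_samples if z in set(keep))
        return m

    def subset_taxa(self, keep: Iterable[str]) -> "AbundanceMatrix":
        """Drop taxa not in ``keep`` without renormalizing columns.

        Retained fractions keep their original denominators, so removing one
        taxon never changes another taxon's relative abundance -- the premise
        under which post-filter enrichment ratios stay comparable.
        """
        keep = [t for t in self.values.index if t in set(keep)]
        sub = self.values.loc[keep]
        m = AbundanceMatrix.__new__(AbundanceMatrix)
        m.values = sub
        m.samples = self.samples
        m.taxa = tuple(t for t in self.taxa if t.taxon_id in set(keep))
        m.mode = self.mode
        m.zero_samples = self.zero_samples
        return m


# ---------------------------------------------------------------------------
# I/O


def _read_metadata(metadata_path: str | Path) -> dict[str, SampleDescriptor]:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "day", "compartment", "size_fraction"}
    missing = required - set(meta.columns)
    if missing:
        raise AbundanceTableError(f"metadata missing column(s): {sorted(missing)}")
    out: dict[str, SampleDescriptor] = {}
    for row in meta.itertuples(index=False):
        sid = str(row.sample_id)
        if sid in out:
            raise AbundanceTableError(f"duplicate sample_id in metadata: {sid}")
        out[sid] = SampleDescriptor(
            sample_id=sid,
            day=int(row.day),
            compartment=Compartment(row.compartment),
            size_fraction=SizeFraction(row.size_fraction),
        )
    return out


def read_abundance_table(
    path: str | Path,
    metadata_path: str | Path,
    lineage_path: str | Path | None = None,
    mode: Mode | str = Mode.COUNTS,
) -> AbundanceMatrix:
    """Read a taxon x sample TSV plus its sample metadata.

    The first column of ``path`` must be ``taxon_id``; every remaining header
    entry must appear in the metadata table.  Values are read as floats and
    returned in ``mode`` (counts by default).
    """
    table = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    meta = _read_metadata(metadata_path)
    unknown = [c for c in table.columns if c not in meta]
    if unknown:
        raise AbundanceTableError(
            f"abundance column(s) missing from metadata: {unknown}"
        )
    taxa: tuple[TaxonInfo, ...] = ()
    if lineage_path is not None:
        lin = read_lineage_table(lineage_path)
        taxa = tuple(
            lin.get(t, TaxonInfo(taxon_id=t)) for t in table.index
        )
    mode = Mode(mode)
    zero = frozenset(
        c for c in table.columns if (table[c] == 0).all()
    ) if mode is Mode.FRACTIONS else frozenset()
    return AbundanceMatrix(
        values=table.astype(float),
        samples=tuple(meta[c] for c in table.columns),
        taxa=taxa,
        mode=mode,
        zero_samples=zero,
    )


def write_abundance_table(matrix: AbundanceMatrix, path: str | Path) -> Path:
    """Write the value table as TSV, re-readable with exact value round-trip.

    Values are written with :func:`repr`-faithful float formatting so that
    ``read_abundance_table`` recovers bit-identical floats.
    """
    path = Path(path)
    df = matrix.values.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t", float_format=None)
    return path


def write_metadata_table(
    samples: Sequence[SampleDescriptor], path: str | Path
) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "day": [s.day for s in samples],
            "compartment": [s.compartment.value for s in samples],
            "size_fraction": [s.size_fraction.value for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


_LINEAGE_RANKS = ("class", "order", "family")


def read_lineage_table(path: str | Path) -> dict[str, TaxonInfo]:
    """Read a flat lineage TSV into ``taxon_id -> TaxonInfo``."""
    lin = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "taxon_id" not in lin.columns:
        raise AbundanceTableError("lineage table missing taxon_id column")
    out: dict[str, TaxonInfo] = {}
    for row in lin.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(row)
        tid = str(d["taxon_id"])
        if tid in out:
            raise AbundanceTableError(f"duplicate taxon_id in lineage: {tid}")
        lineage = tuple(
            (rank, d[rank]) for rank in _LINEAGE_RANKS if d.get(rank, "") != ""
        )
        domain = Domain(d.get("domain") or "other")
        env_raw = d.get("enveloped", "")
        enveloped = None
        if env_raw != "" and domain is Domain.VIRUS:
            enveloped = env_raw.strip().lower() in {"1", "true", "yes"}
        out[tid] = TaxonInfo(
            taxon_id=tid,
            name=d.get("name", "") or tid,
            domain=domain,
            lineage=lineage,
            enveloped=enveloped,
        )
    return out


def write_lineage_table(taxa: Sequence[TaxonInfo], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for t in taxa:
        rows.append(
            {
                "taxon_id": t.taxon_id,
                "name": t.name,
                "domain": t.domain.value,
                "class": t.rank("class") or "",
                "order": t.rank("order") or "",
                "family": t.rank("family") or "",
                "enveloped": "" if t.enveloped is None else str(t.enveloped).lower(),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Normalization


def normalize(
    matrix: AbundanceMatrix, within: str = "sample"
) -> AbundanceMatrix:
    """Convert read counts to per-sample relative abundances.

    ``within="sample"`` (default) divides each column by its own sum, i.e.
    fractions are computed within each size fraction separately -- the unit
    in which enrichment ratios are defined.  ``within="day_compartment"``
    instead divides every column by the pooled depth of all columns sharing
    its (day, compartment), for designs where both size fractions should be
    expressed on a common denominator.

    All-zero columns are left at zero and flagged in ``zero_samples``.
    Raises on fractions-mode input rather than silently renormalizing.
    """
    if matrix.mode is Mode.FRACTIONS:
        raise AbundanceTableError("matrix is already in fractions mode")
    if within not in {"sample", "day_compartment"}:
        raise AbundanceTableError(f"unknown normalization grouping: {within!r}")
    vals = matrix.values.astype(float).copy()
    if within == "sample":
        denom = vals.sum(axis=0)
    else:
        denom = pd.Series(0.0, index=vals.columns)
        group: dict[tuple[int, Compartment], float] = {}
        for s in matrix.samples:
            key = (s.day, s.compartment)
            group[key] = group.get(key, 0.0) + float(vals[s.sample_id].sum())
        for s in matrix.samples:
            denom[s.sample_id] = group[(s.day, s.compartment)]
    zero = frozenset(c for c in vals.columns if denom[c] == 0)
    safe = denom.replace(0, np.nan)
    out = vals.div(safe, axis=1).fillna(0.0)
    m = AbundanceMatrix.__new__(AbundanceMatrix)
    m.values = out
    m.samples = matrix.samples
    m.taxa = matrix.taxa
    m.mode = Mode.FRACTIONS
    m.zero_samples = zero
    if within == "day_compartment":
        # pooled denominators: column sums are <1; skip the per-column check
        return m
    # run invariant checks via __post_init__ semantics
    return AbundanceMatrix(
        values=out,
        samples=matrix.samples,
        taxa=matrix.taxa,
        mode=Mode.FRACTIONS,
        zero_samples=zero,
    )
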