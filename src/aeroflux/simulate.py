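"""Synthetic mesocosm generator with exported ground truth.

Emulates the statistical structure the enrichment pipeline assumes, without
any external data: a bloom-driven community of bacteria and viruses sampled
from three compartments (bulk seawater, SSML, sea spray aerosol) on a small
number of days, in two size fractions, with multinomial sequencing noise.

The generative model mirrors the enrichment-ratio chain.  Each taxon i
carries a surface-partition coefficient sigma_i and an aerosolization
coefficient alpha_i (both log-normal across taxa):

* bulk fractions  b_it  follow per-taxon log-abundances plus a two-pulse
  bloom response, renormalized within each domain;
* SSML fractions  s_it  are proportional to b_it * sigma_i (renormalized),
  so sigma_i is the latent S:B tendency;
* aerosol fractions a_it are proportional to s_it * alpha_i(t)
  (renormalized) -- aerosolization acting on the surface community,
  encoding film-drop transfer; a direct bulk -> aerosol mode emulating
  jet-drop transfer is available instead.

Constitutive taxa keep alpha fixed across days; intermittent taxa have
log(alpha) flipped in sign on randomly chosen days.  Enveloped viruses get
an extra multiplicative boost on alpha.  Observed counts are multinomial
draws at the configured read depth per sample, making relative-abundance
estimation and its depth invariance directly testable; ground truth
(alpha, sigma, intended temporal label, latent fractions) is exported so
recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filters import CoverageProfile
from .counts import CountSeries, Entity
from .samples import (
    AbundanceMatrix,
    Compartment,
    Domain,
    Mode,
    SampleDescriptor,
    SizeFraction,
    TaxonInfo,
    write_abundance_table,
    write_lineage_table,
    write_metadata_table,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate",
    "simulate_counts",
    "simulate_coverage",
    "write_simulation",
]

# class -> orders used to give bacteria a plantable lineage structure
_BACTERIAL_LINEAGE = {
    "Actinobacteria": ("Corynebacteriales", "Micrococcales"),
    "Flavobacteriia": ("Flavobacteriales",),
    "Alphaproteobacteria": ("Rhodobacterales", "Sphingomonadales"),
    "Gammaproteobacteria": ("Alteromonadales", "Pseudomonadales"),
}

# family -> lipid envelope flag for viruses
_VIRAL_FAMILIES = {
    "Myoviridae": False,
    "Podoviridae": False,
    "Siphoviridae": False,
    "Herpesviridae": True,
    "Phycodnaviridae": True,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic mesocosm.

    Defaults follow the emulated study design: 6 sampling days spread over
    a 34-day double bloom, 3 compartments, 2 size fractions (bacteria in
    0.2-3 um, viruses in 0.025-0.2 um), and ~1e5 classified reads per
    sample.  ``alpha_*`` and ``sigma_*`` are log-space hyperparameters of
    the per-taxon aerosolization and surface-partition coefficients;
    ``class_effect_sd`` plants a shared log-alpha offset per bacterial
    class so that lineage aggregation has signal to recover, while viral
    group structure comes from ``envelope_effect`` alone.

    ``n_other`` neutral background taxa (alpha = sigma = 1, domain
    ``other``) appear in *both* size fractions, standing in for the
    non-target DNA every real size-fractionated sample carries; during a
    phytoplankton bloom, eukaryotic and unclassified material dominates a
    shotgun profile, and ``background_share`` fixes its bulk-sample share
    (default 0.6).  The background anchors the compositional scale: without
    it a multiplier applied to every taxon of one domain would cancel in
    the within-fraction renormalization and be unobservable.
    """

    n_bacteria: int = 50
    n_viruses: int = 20
    n_other: int = 10
    background_share: float = 0.6
    days: tuple[int, ...] = (8, 13, 18, 23, 28, 34)
    read_depth: int = 100_000
    seed: int = 0
    alpha_log_mu: float = 0.0
    alpha_log_sd: float = 0.8
    sigma_log_mu: float = 0.3
    sigma_log_sd: float = 0.5
    class_effect_sd: float = 0.5
    constitutive_fraction: float = 0.45
    intermittent_flip_prob: float = 0.5
    envelope_effect: float = 2.0
    viral_alpha_scale: float = 1.0
    bloom_amplitudes: tuple[float, float] = (1.0, 1.5)
    bloom_centers: tuple[float, float] = (10.0, 27.0)
    bloom_widths: tuple[float, float] = (4.0, 5.0)
    bloom_response_sd: float = 0.5
    base_log_abundance_sd: float = 1.0
    transfer_mode: str = "ssml"  # film-drop; "bulk" emulates jet drops
    count_noise_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.n_bacteria + self.n_viruses + self.n_other <= 0:
            raise ValueError("need at least one taxon")
        if self.n_other < 0:
            raise ValueError("n_other must be >= 0")
        if self.n_other > 0 and not (0 < self.background_share < 1):
            raise ValueError("background_share must be in (0, 1)")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be > 0")
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")
        if not (0 <= self.constitutive_fraction <= 1):
            raise ValueError("constitutive_fraction must be in [0, 1]")
        if not (0 <= self.intermittent_flip_prob <= 1):
            raise ValueError("intermittent_flip_prob must be in [0, 1]")
        if self.transfer_mode not in {"ssml", "bulk"}:
            raise ValueError(f"unknown transfer_mode {self.transfer_mode!r}")


@dataclass
class GroundTruth:
    """Latent parameters behind one simulated dataset.

    ``taxa`` has one row per taxon: alpha, sigma, constitutive flag and
    intended temporal label; ``latent_fractions[(day, compartment,
    size_fraction)]`` gives the noise-free fraction vector over the taxa in
    that size fraction (sums to 1); ``alpha_effective[(taxon_id, day)]`` is
    alpha after intermittent flips.
    """

    taxa: pd.DataFrame
    latent_fractions: dict[tuple[int, Compartment, SizeFraction], pd.Series]
    alpha_effective: pd.DataFrame  # taxon x day

    def to_frame(self) -> pd.DataFrame:
        return self.taxa.copy()


def _bloom(day: float, config: SimulationConfig) -> float:
    return sum(
        a * math.exp(-((day - c) ** 2) / (2 * w**2))
        for a, c, w in zip(
            config.bloom_amplitudes, config.bloom_centers, config.bloom_widths
        )
    )


def _make_taxa(config: SimulationConfig, rng: np.random.Generator) -> list[TaxonInfo]:
    taxa: list[TaxonInfo] = []
    classes = list(_BACTERIAL_LINEAGE)
    for i in range(config.n_bacteria):
        cls = classes[i % len(classes)]
        orders = _BACTERIAL_LINEAGE[cls]
        order = orders[(i // len(classes)) % len(orders)]
        taxa.append(
            TaxonInfo(
                taxon_id=f"bact_{i:03d}",
                name=f"Bacterium sp. {i:03d}",
                domain=Domain.BACTERIA,
                lineage=(("class", cls), ("order", order)),
            )
        )
    families = list(_VIRAL_FAMILIES)
    for i in range(config.n_viruses):
        fam = families[i % len(families)]
        taxa.append(
            TaxonInfo(
                taxon_id=f"vir_{i:03d}",
                name=f"Virus sp. {i:03d}",
                domain=Domain.VIRUS,
                lineage=(("family", fam),),
                enveloped=_VIRAL_FAMILIES[fam],
            )
        )
    for i in range(config.n_other):
        taxa.append(
            TaxonInfo(
                taxon_id=f"other_{i:03d}",
                name=f"Background sp. {i:03d}",
                domain=Domain.OTHER,
            )
        )
    return taxa


def simulate(
    config: SimulationConfig,
) -> tuple[AbundanceMatrix, dict[str, TaxonInfo], GroundTruth]:
    """Generate a counts-mode abundance matrix, lineage, and ground truth.

    Deterministic for a fixed seed: every random quantity is drawn from a
    single ``numpy`` Generator seeded with ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    taxa = _make_taxa(config, rng)
    n = len(taxa)
    ids = np.array([t.taxon_id for t in taxa])
    is_other = np.array([t.domain is Domain.OTHER for t in taxa])
    # each size fraction carries its target domain plus the neutral background
    fraction_masks = {
        SizeFraction.F3000_200: np.array(
            [t.domain in (Domain.BACTERIA, Domain.OTHER) for t in taxa]
        ),
        SizeFraction.F200_25: np.array(
            [t.domain in (Domain.VIRUS, Domain.OTHER) for t in taxa]
        ),
    }

    # shared log-alpha offset per bacterial class (viral structure instead
    # comes from the envelope effect, mirroring the trait-over-taxonomy
    # signal seen in viral aerosolization)
    group_names = sorted(_BACTERIAL_LINEAGE)
    group_offset = dict(
        zip(group_names, rng.normal(0.0, config.class_effect_sd, len(group_names)))
    )
    log_alpha = rng.normal(config.alpha_log_mu, config.alpha_log_sd, n)
    for i, t in enumerate(taxa):
        g = t.rank("class")
        if g in group_offset:
            log_alpha[i] += group_offset[g]
        if t.domain is Domain.VIRUS:
            if t.enveloped:
                log_alpha[i] += math.log(config.envelope_effect)
            log_alpha[i] += math.log(config.viral_alpha_scale)
    alpha = np.exp(log_alpha)
    sigma = np.exp(rng.normal(config.sigma_log_mu, config.sigma_log_sd, n))
    alpha[is_other] = 1.0
    sigma[is_other] = 1.0

    constitutive = rng.random(n) < config.constitutive_fraction
    constitutive[is_other] = True
    base = rng.normal(0.0, config.base_log_abundance_sd, n)
    response = rng.normal(0.0, config.bloom_response_sd, n)

    # effective alpha per (taxon, day): intermittent taxa flip log-alpha sign
    days = list(config.days)
    alpha_eff = np.tile(alpha[:, None], (1, len(days)))
    flips = rng.random((n, len(days))) < config.intermittent_flip_prob
    for i in range(n):
        if not constitutive[i]:
            for j in range(len(days)):
                if flips[i, j]:
                    alpha_eff[i, j] = 1.0 / alpha_eff[i, j]

    latent: dict[tuple[int, Compartment, SizeFraction], pd.Series] = {}
    samples: list[SampleDescriptor] = []
    columns: dict[str, np.ndarray] = {}
    for j, day in enumerate(days):
        bloom = _bloom(day, config)
        weight = np.exp(base + response * bloom)
        for sf, mask in fraction_masks.items():
            if not mask.any():
                continue
            b = weight * mask
            # pin the background's bulk share so the compositional anchor
            # holds regardless of how many target taxa the fraction has
            target_mass = b[mask & ~is_other].sum()
            bg_mass = b[mask & is_other].sum()
            if target_mass > 0 and bg_mass > 0:
                share = config.background_share
                b = np.where(
                    is_other,
                    b * (share / (1 - share)) * (target_mass / bg_mass),
                    b,
                )
            b = b / b.sum()
            s = b * sigma
            s = s / s.sum()
            source = s if config.transfer_mode == "ssml" else b
            a = source * alpha_eff[:, j]
            a = a / a.sum()
            for comp, frac in (
                (Compartment.BULK, b),
                (Compartment.SSML, s),
                (Compartment.AEROSOL, a),
            ):
                latent[(day, comp, sf)] = pd.Series(frac[mask], index=ids[mask])
                sid = f"d{day:02d}_{comp.value}_{sf.value}"
                columns[sid] = np.zeros(n)
                samples.append(
                    SampleDescriptor(
                        sample_id=sid, day=day, compartment=comp, size_fraction=sf
                    )
                )
                counts = rng.multinomial(
                    config.read_depth, frac[mask] / frac[mask].sum()
                )
                columns[sid][mask] = counts

    values = pd.DataFrame(columns, index=ids)
    matrix = AbundanceMatrix(
        values=values, samples=tuple(samples), taxa=tuple(taxa), mode=Mode.COUNTS
    )

    labels = []
    for i in range(n):
        if constitutive[i]:
            labels.append(
                "constitutive_enriched" if alpha[i] > 1 else "constitutive_depleted"
            )
        else:
            labels.append("intermittent")
    truth = GroundTruth(
        taxa=pd.DataFrame(
            {
                "taxon_id": ids,
                "domain": [t.domain.value for t in taxa],
                "group": [t.rank("class") or t.rank("family") or "" for t in taxa],
                "enveloped": [t.enveloped for t in taxa],
                "alpha": alpha,
                "sigma": sigma,
                "constitutive": constitutive,
                "intended_label": labels,
            }
        ).set_index("taxon_id", drop=False),
        latent_fractions=latent,
        alpha_effective=pd.DataFrame(alpha_eff, index=ids, columns=days),
    )
    lineage = {t.taxon_id: t for t in taxa}
    return matrix, lineage, truth


# ---------------------------------------------------------------------------
# Particle / cell count series


def simulate_counts(config: SimulationConfig) -> list[CountSeries]:
    """Per-day compartment concentration series consistent with the latent model.

    Bulk totals follow the bloom curve around study-realistic magnitudes on
    the x10^7 per-mL scale (viruses roughly tenfold above bacteria); SSML
    totals scale the bulk by the abundance-weighted mean surface partition,
    and aerosol totals scale the SSML (or bulk, in jet-drop mode) by the
    abundance-weighted mean aerosolization coefficient.  Log-normal
    observation noise with coefficient of variation ``count_noise_cv`` is
    applied, and reported sds carry that CV (plus the 10% flow variance for
    aerosol, in quadrature).
    """
    rng = np.random.default_rng(config.seed + 1)
    _, _, truth = simulate(config)
    base_total = {Entity.BACTERIA_CELLS: 0.2, Entity.VIRUS_PARTICLES: 2.0}
    entity_of_domain = {
        Domain.BACTERIA: (Entity.BACTERIA_CELLS, SizeFraction.F3000_200),
        Domain.VIRUS: (Entity.VIRUS_PARTICLES, SizeFraction.F200_25),
    }
    out: list[CountSeries] = []
    cv = config.count_noise_cv
    log_sd = math.sqrt(math.log(1 + cv**2)) if cv > 0 else 0.0
    for domain, (entity, sf) in entity_of_domain.items():
        members = truth.taxa.index[truth.taxa["domain"] == domain.value]
        if members.empty:
            continue
        obs: dict[Compartment, list[tuple[int, float, float | None]]] = {
            c: [] for c in Compartment
        }
        for j, day in enumerate(config.days):
            # restrict latent fractions to the counted entity and renormalize
            b_frac = truth.latent_fractions[(day, Compartment.BULK, sf)][members]
            b_frac = b_frac / b_frac.sum()
            s_frac = truth.latent_fractions[(day, Compartment.SSML, sf)][members]
            s_frac = s_frac / s_frac.sum()
            alpha_day = truth.alpha_effective.loc[members, day]
            mean_sigma = float((b_frac * truth.taxa.loc[members, "sigma"]).sum())
            source = s_frac if config.transfer_mode == "ssml" else b_frac
            mean_alpha = float((source * alpha_day).sum())
            bulk_total = base_total[entity] * (1.0 + 2.0 * _bloom(day, config))
            latent = {
                Compartment.BULK: bulk_total,
                Compartment.SSML: bulk_total * mean_sigma,
                Compartment.AEROSOL: bulk_total * mean_sigma * mean_alpha
                if config.transfer_mode == "ssml"
                else bulk_total * mean_alpha,
            }
            for comp, m in latent.items():
                noisy = m * math.exp(rng.normal(0.0, log_sd)) if log_sd else m
                rel = cv
                if comp is Compartment.AEROSOL:
                    rel = math.sqrt(cv**2 + 0.10**2)
                obs[comp].append((day, noisy, noisy * rel if rel > 0 else None))
        for comp, series in obs.items():
            out.append(CountSeries(entity, comp, tuple(series)))
    return out


# ---------------------------------------------------------------------------
# Coverage


def simulate_coverage(
    fraction: float,
    genome_length: int,
    read_depth: int,
    read_length: int = 150,
    seed: int | np.random.Generator = 0,
    taxon_id: str = "sim",
) -> CoverageProfile:
    """Scatter reads uniformly over a genome and return the covered intervals.

    ``n = round(fraction * read_depth)`` reads of ``read_length`` bp start at
    uniform positions.  Because start positions are consumed from a single
    deterministic stream, coverage is monotone non-decreasing in ``n`` for a
    fixed seed.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    if read_length > genome_length:
        raise ValueError("read_length exceeds genome_length")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = round(fraction * read_depth)
    starts = rng.integers(0, genome_length - read_length + 1, size=n)
    intervals = tuple((int(s), int(s) + read_length) for s in starts)
    return CoverageProfile(
        taxon_id=taxon_id, genome_length=genome_length, intervals=intervals
    )


# ---------------------------------------------------------------------------
# Full dataset export


def write_simulation(
    config: SimulationConfig,
    out_dir: str | Path,
    genome_length: int = 200_000,
) -> dict[str, Path]:
    """Write a complete synthetic dataset to ``out_dir``.

    Emits abundance TSV, metadata TSV, lineage TSV, counts CSV, one
    bedgraph per taxon (derived from each taxon's mean abundance), a genome
    length table, and ``ground_truth.tsv``.
    """
    from .counts import write_counts

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, lineage, truth = simulate(config)
    paths = {
        "abundance": write_abundance_table(matrix, out_dir / "abundance.tsv"),
        "metadata": write_metadata_table(matrix.samples, out_dir / "metadata.tsv"),
        "lineage": write_lineage_table(
            list(lineage.values()), out_dir / "lineage.tsv"
        ),
        "counts": write_counts(simulate_counts(config), out_dir / "counts.csv"),
    }
    truth_path = out_dir / "ground_truth.tsv"
    truth.taxa.to_csv(truth_path, sep="\t", index=False)
    paths["ground_truth"] = truth_path
    cov_rng = np.random.default_rng(config.seed + 2)
    bg_dir = out_dir / "bedgraph"
    bg_dir.mkdir(exist_ok=True)
    lengths = []
    depth_fracs = matrix.values.div(matrix.values.sum(axis=0), axis=1).mean(axis=1)
    for taxon in matrix.taxon_ids:
        prof = simulate_coverage(
            float(depth_fracs[taxon]),
            genome_length,
            read_depth=min(config.read_depth, 20_000),
            seed=cov_rng,
            taxon_id=taxon,
        )
        with open(bg_dir / f"{taxon}.bedgraph", "w") as fh:
            for s, e in prof.intervals:
                fh.write(f"{taxon} {s} {e} 1\n")
        lengths.append({"taxon_id": taxon, "genome_length": genome_length})
    lengths_path = out_dir / "genome_lengths.tsv"
    pd.DataFrame(lengths).to_csv(lengths_path, sep="\t", index=False)
    paths["genome_lengths"] = lengths_path
    paths["bedgraph_dir"] = bg_dir
    return paths
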