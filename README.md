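# aeroflux

Taxon-specific aerosolization statistics for air–sea interface
metagenomics.

When bubbles burst at the ocean surface they eject sea spray aerosol (SSA)
whose microbial cargo is not a random draw from the water: some bacteria
and viruses transfer into the air far more efficiently than others.
`aeroflux` quantifies this from size-fractionated, taxon × sample
metagenomic abundance tables collected across three compartments — bulk
seawater, the sea surface microlayer (SSML, the top ~1–1000 µm), and SSA —
as sampled, for example, in an enclosed wave-channel mesocosm over a
phytoplankton bloom.

It is written for microbial ecologists and aerosol scientists who have
taxonomic profiles (e.g. Kraken-style read counts) per compartment and
day and want defensible per-taxon enrichment statistics.

## The statistics

For a taxon with relative abundance A in aerosol, B in bulk water, and S
in the SSML (fractions within one sample and size fraction), the
**aerosolization factor** is

```
AF = A / B   (A:B)      or      AF = A / S   (A:S)
```

and the **surface enrichment factor** is `S:B = S / B`.  AF > 1 means
preferential transfer into the aerosol; AF < 1 means the taxon stays in
the water.  Because the inputs are per-sample fractions, AF is invariant
to sequencing depth, and `A:B = (A:S) × (S:B)` exactly.

Around this core the package provides:

* **Exclusion filters** — the two-clause relative-abundance rule (drop a
  taxon below a hard floor in any sample, or below a soft floor in too
  many samples) and a genome spatial-coverage filter (drop taxa whose
  mapped reads cover < 0.1% of the reference genome, from bedgraph input);
* **Quadrant classification** of the (A:B, A:S) plane — aerosol-enriched,
  waterborne, or enriched against one compartment only;
* **Temporal classification** — a taxon is a *constitutive* aerosolizer
  when ≥ 80% of its observed AF values fall on one side of 1, otherwise
  *intermittent*;
* **Group aggregation** by taxonomic class/order, viral envelope state, or
  domain, plus a bacteria-versus-virus distribution comparison;
* **Count-ratio analysis** of cell / virus-like-particle concentration
  time series across compartments, with first-order error propagation and
  a 10% aerosol flow-variance term (packaged VLP reference tables
  included);
* **A synthetic mesocosm generator** with per-taxon ground-truth
  aerosolization (α) and surface-partition (σ) coefficients, bloom
  dynamics, intermittency, and multinomial sequencing noise, so the whole
  pipeline is testable end to end without any external data.

## Worked example

Count-based enrichment from the packaged virus-like-particle tables:

```python
from aeroflux import *

vlp = load_vlp_counts()
r = day_ratio(vlp[Compartment.AEROSOL], vlp[Compartment.BULK], 4)
print(f"day 4 virus aerosol:bulk = {r.ratio:.2f} +/- {r.sd:.2f}")
r = average_ratio(vlp[Compartment.SSML], vlp[Compartment.BULK], "mean_of_ratios")
print(f"virus SSML:bulk (mean of ratios) = {r.ratio:.2f}")
```

```
day 4 virus aerosol:bulk = 0.54 +/- 0.14
virus SSML:bulk (mean of ratios) = 1.02
```

On day 4 free viruses were roughly half as concentrated in aerosol as in
bulk water (the ±0.14 folds in the counting s.d.s and the 10% aerosol
flow variance), while on average the SSML held essentially the same viral
concentration as the bulk (1.02).

Sequence-based enrichment on a synthetic mesocosm (3 compartments ×
6 days × 2 size fractions, 50 bacteria + 20 viruses + background):

```python
from aeroflux import *
from aeroflux.temporal import classify_all

cfg = SimulationConfig(seed=0)
matrix, lineage, truth = simulate(cfg)          # counts + ground truth
records, reports = enrichment_by_domain(matrix, lineage)

bact = records[Domain.BACTERIA]
s = enrichment_summary(bact)
print(f"bacterial AF: n={s.n} mean={s.mean:.2f} sd={s.sd:.2f} "
      f"skew={s.skewness:.2f} fraction<1={s.fraction_below_1:.2f}")

cls = classify_all(bact)
n_const = sum(c.label.value.startswith("constitutive") for c in cls.values())
print(f"constitutive bacteria: {n_const}/{len(cls)}")

for g in group_aggregate(records[Domain.VIRUS], lineage, "envelope"):
    print(f"{g.group}: n={g.n_taxa} mean AF={g.mean_af:.2f} mean S:B={g.mean_sb:.2f}")
```

```
bacterial AF: n=600 mean=1.23 sd=1.13 skew=1.79 fraction<1=0.60
constitutive bacteria: 24/50
enveloped: n=8 mean AF=1.58 mean S:B=1.01
non_enveloped: n=12 mean AF=1.15 mean S:B=1.36
```

The pooled bacterial AF distribution is positively skewed with most
values below 1 — a few strong aerosolizers against a mostly waterborne
majority — about half the community is constitutive, and enveloped
viruses (simulated with an envelope boost on α) out-aerosolize
non-enveloped ones.

The same pipeline runs from the shell:

```bash
aeroflux simulate --seed 0 --out-dir sim/
aeroflux validate sim/abundance.tsv sim/metadata.tsv
aeroflux enrich sim/abundance.tsv sim/metadata.tsv --lineage sim/lineage.tsv --out enrichment.tsv
aeroflux dynamics sim/abundance.tsv sim/metadata.tsv --lineage sim/lineage.tsv \
    --group-by class,envelope --out-prefix dyn
aeroflux counts --convention mean_of_ratios --num ssml --den bulk
```

## Layout

| Module | Contents |
| --- | --- |
| `aeroflux.samples` | sample/taxon/abundance data model, TSV I/O, normalization |
| `aeroflux.filters` | abundance-threshold and spatial-coverage filters, bedgraph reader |
| `aeroflux.enrichment` | AF and S:B computation, quadrants, distribution summaries |
| `aeroflux.temporal` | constitutive/intermittent classification, group aggregation, domain comparison |
| `aeroflux.counts` | compartment count-ratio analysis, packaged VLP tables |
| `aeroflux.simulate` | synthetic mesocosm generator with ground truth |
| `aeroflux.pipeline` | counts → filtered per-domain enrichment convenience |
| `aeroflux.cli` | `aeroflux` command-line interface |

See `docs/methods.md` for the model, parameter and design notes.
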