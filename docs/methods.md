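# Methods

## Enrichment model

All statistics operate on per-sample relative abundances.  A study
consists of samples indexed by (day, compartment, size fraction) with
compartments bulk seawater, sea surface microlayer (SSML), and sea spray
aerosol.  Counts are normalized per column (i.e. within each size
fraction), making every downstream ratio invariant to sequencing depth;
a pooled per-(day, compartment) normalization is available for designs
where both size fractions should share a denominator.

For taxon fractions A (aerosol), B (bulk), S (SSML) within one
(day, size fraction) group, the aerosolization factors are A:B and A:S
and the surface enrichment factor is S:B.  Ratios are plain quotients —
no pseudocounts.  A zero denominator yields an undefined value flagged
`zero_denominator` (or `absent` when the numerator is also zero, or
`missing_sample` when the compartment was not sampled); summaries and
classifications simply skip undefined values.  Rare-taxon noise is
handled where it belongs, in the exclusion filters, rather than by
smoothing, which would bias ratios near the detection limit.  Whenever
all three ratios are defined, A:B = (A:S) × (S:B) holds to floating
precision, which the tests enforce at 1e-12 relative.

Bacteria are read out of the 0.2–3 µm size fraction and free viruses out
of the 0.025–0.2 µm fraction; both are overridable.

## Exclusion filters

Two independent per-taxon rules:

* **Abundance.** Remove a taxon if its fraction falls below
  `min_fraction_any_sample` in at least one sample, or below
  `low_fraction` in at least `max_low_samples` samples.  Two published
  variants of the thresholds exist and both are provided; the default is
  the procedural variant (1e-5 / 1e-4 with a 10-of-18 sample count).  For
  sample counts N ≠ 18 the count scales as ceil(10·N/18) (methods
  variant) or "more than half", floor(N/2)+1 (results variant), unless
  overridden.  Comparisons are strict `<`.
* **Spatial coverage.** Remove a taxon whose reference-genome breadth of
  coverage (covered positions / genome length, from merged bedgraph
  intervals) is strictly below 0.1%.  A taxon at exactly the threshold is
  retained.  Taxa without a reference profile cannot be tested and are
  retained, flagged "no reference".

Filtered matrices are never renormalized: surviving fractions keep their
original denominators, so removing one taxon never changes another's
ratios.  Because both rules are per-taxon, the filters commute.

Bedgraph input is 0-based half-open; depth values are reduced to
covered/uncovered since only breadth matters.  Multiple contigs are
concatenated in file order; without an explicit contig-length table the
extent of a contig is its maximum end coordinate, exact for bedgraphs
that include zero-coverage runs (`bedtools genomecov -bga`).

## Temporal classification

A taxon's defined AF observations (both A:B and A:S by default; either
alone on request) are classified with threshold q = 0.8 (inclusive ≥, so
4 of 5 one-sided observations qualifies) and a minimum of
`min_obs = 3` observations.  Values exactly 1 count toward the
observation total but toward neither side — the one-sided wording leaves
them unassigned, and treating them as support for either direction would
manufacture constitutive calls from flat series.  `min_obs` guards taxa
seen once or twice from being labelled constitutive; it is configurable
and the published analyses state no minimum.

Group summaries average per-taxon means rather than pooled observations,
so frequently-observed taxa do not dominate their class (a pooled mode
exists).  A day-exclusion list allows removing days with global events
(e.g. community-wide surface enrichment) before averaging.  The
bacteria-versus-virus comparison reports per-domain summaries, the
difference of means, a two-sided Mann–Whitney U p-value on the pooled
defined AF values, and day-resolved mean series to expose temporal
clustering.

Distribution summaries report adjusted Fisher–Pearson skewness and a
Shapiro–Wilk normality p-value (D'Agostino–Pearson selectable); the test
choice is recorded in the output.  The amplitude ratio — mean |max AF − 1|
over mean |1 − min AF| across taxa — expresses how much farther taxa rise
above neutrality at their peak than they fall below it at their trough.

## Count-ratio analysis

Concentration time series (cells or virus-like particles, per
compartment) are compared on the ×10⁷ mL⁻¹ scale on which they are
reported; converting aerosol concentrations to a per-m³ air basis
(1 m³ = 10⁶ mL) is an explicit reporting transform, never implicit.  Per
day, ratio = numerator/denominator with first-order (delta-method) s.d.
propagation; an extra 10% relative term enters in quadrature when the
numerator is an aerosol series (sampler flow variance).  Averages follow
two conventions that agree only in special cases: *mean of ratios* (over
common days) and *ratio of means* (each series averaged over its own
days, or common days on request).  Comparisons against printed
two-decimal values use round-half-away-from-zero, which matches every
checkable entry.

The packaged VLP tables (24 bulk, 18 SSML, 13 aerosol days) reproduce
all seven printed per-day virus aerosol:bulk ratios at two decimals and
the 1.02 SSML:bulk mean over the 12 shared days.  The printed *average*
row of the ratio table (virus 0.68) is not reproducible from the printed
per-day entries under either convention (mean of ratios ≈ 0.57) and
likely rests on unprinted raw data; it ships as reference data but is
not a computed target.

## Synthetic mesocosm

The generator mirrors the enrichment chain.  Each taxon carries a
surface-partition coefficient σ and an aerosolization coefficient α,
log-normal across taxa; bacterial classes share a planted log-α offset
(`class_effect_sd`), and enveloped viruses get a multiplicative α boost
(`envelope_effect`, default 2).  Per day, bulk fractions follow
per-taxon log-abundances (s.d. 1) plus a bloom response — two Gaussian
pulses on log-abundance centred near days 10 and 27, echoing a two-bloom
experiment; the exact pulse shape is a simulator choice.  SSML fractions
are ∝ bulk × σ (renormalized); aerosol fractions are ∝ SSML × α
(renormalized), encoding film-drop transfer from the surface community;
a bulk → aerosol mode emulates jet-drop transfer instead.  Constitutive
taxa (probability `constitutive_fraction`, default 0.45) keep α fixed;
intermittent taxa flip log α in sign on random days
(`intermittent_flip_prob` = 0.5).  Observed counts are one multinomial
draw per sample at `read_depth` (default 1e5), with bacteria emitted in
the large size fraction and viruses in the small one.

Both size fractions also contain neutral background taxa
(α = σ = 1, domain `other`) holding a pinned share of each bulk sample
(`background_share`, default 0.6) — the eukaryotic and unclassified DNA
that dominates bloom metagenomes.  The background is what makes
domain-level effects observable at all: relative abundances are
compositional, so a multiplier applied to every taxon of one domain
would otherwise cancel exactly in the within-fraction renormalization.
Even with the anchor, part of any domain-wide multiplier is absorbed by
the denominator; recovery of *relative* (per-taxon) effects is
essentially exact, while domain-level contrasts are attenuated — a
faithful reflection of what compositional data can and cannot show.

Recovery experiments that correlate estimated AF with the planted α use
`constitutive_fraction = 1`: sign-flipping intermittency zeroes the mean
log α of affected taxa by construction, so a fixed per-taxon coefficient
is only estimable for constitutive taxa.  The domain-contrast experiment
(0.6× viral α) additionally sets `class_effect_sd = 0` and
`envelope_effect = 1` so no planted lineage or trait effect confounds
the domain difference.  With those settings, rank recovery of log α from
mean log A:S exceeds 0.9 (Spearman) at depth 1e5 with 70 taxa, strong
constitutive labels (α ≥ 2 or ≤ 0.5) are recovered at ≥ 90%, and the
planted viral deficit is detected at p < 0.05 on most seeds; the
bundled acceptance test pins the fixture seed for determinism.

`simulate_counts` produces compartment concentration series consistent
with the latent model: bulk totals follow the bloom around study-scale
magnitudes (×10⁷ mL⁻¹ scale, viruses roughly tenfold above bacteria),
SSML totals scale bulk by the abundance-weighted mean σ, aerosol totals
scale SSML by the abundance-weighted mean α, with log-normal observation
noise (CV 0.10) and the 10% aerosol flow variance in reported s.d.s.
`simulate_coverage` scatters fixed-length reads uniformly over a genome;
its expected breadth follows the occupancy form 1 − (1 − L_read/L)^n,
which the tests verify by Monte Carlo.

What the simulator does **not** emulate: taxon interactions (predation,
lysis), classifier misassignment between taxa, within-day replicate
structure, and compositional correlation between size fractions.  A
passing recovery test therefore demonstrates the statistical machinery
is correct under the stated generative assumptions, not that any given
field data set satisfies them.

## Numerical and design choices

* Fractions live on [0, 1]; percent thresholds are converted once at
  configuration time (0.01% → 1e-4) to preclude 100× unit errors.
* Quadrant and temporal comparisons at AF = 1 are exact by default; a
  `tie_epsilon` widens the neutral band symmetrically if wanted.
* The 18-sample (3 compartments × 6 days) design is a convention, not a
  constraint: any set of (day, compartment, size fraction) is accepted
  and groups are matched on shared days.
* All simulator randomness flows through one `numpy` Generator seeded
  from the configuration, so a fixed seed gives bit-identical output.
* Abundance-table round trips are exact: values are written as full-
  precision decimal text and re-read with round-trip float parsing.
* Test problem sizes (70–80 taxa, depth 1e5, 200-table filter sweeps)
  keep the full suite in the tens of seconds while leaving each check
  comfortably powered.

## Known limitations

* The two published abundance-filter variants differ by a factor of ten;
  results can differ materially between them, which is why the variant
  is an explicit, recorded configuration choice.
* Pooling A:B and A:S in summaries and temporal series doubles the
  weight of days where both are defined; single-ratio modes are provided
  and the pooling choice should be reported alongside results.
* Domain-level mean-AF contrasts are attenuated by compositional closure
  (see above) and should be read as qualitative direction plus
  significance, not as unbiased effect sizes.
* Coverage filtering treats every mapped position equally; it cannot
  distinguish genuine low-abundance presence from conserved-element
  artifacts below the threshold — that is the point of the filter, but
  the 0.1% threshold itself is a convention.
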