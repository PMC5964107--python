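"""Aerosolization-factor computation, quadrants, and distribution summaries."""

import numpy as np
import pandas as pd
import pytest

from aeroflux import (
    AbundanceTableError,
    Compartment,
    Mode,
    Quadrant,
    SampleDescriptor,
    SizeFraction,
    classify_quadrant,
    compute_enrichment,
    enrichment_summary,
    normalize,
)
from aeroflux.enrichment import EnrichmentRecord, Ratio

from conftest import make_matrix, make_samples


def record(ab=None, as_=None, sb=None, taxon="t", day=1):
    wrap = lambda v: Ratio(v) if v is not None else Ratio(None, "zero_denominator")
    return EnrichmentRecord(
        taxon_id=taxon, day=day, size_fraction=SizeFraction.F3000_200,
        A=None, B=None, S=None,
        af_bulk=wrap(ab), af_ssml=wrap(as_), sb=wrap(sb),
    )


def matrix_from_fractions(day_fracs):
    """day_fracs: {day: {compartment: fraction-list}} -> fractions matrix."""
    cols, samples = {}, []
    for day, comps in day_fracs.items():
        for comp, vec in comps.items():
            sid = f"d{day}_{comp}"
            cols[sid] = vec
            samples.append(SampleDescriptor(sid, day, Compartment(comp),
                                            SizeFraction.F3000_200))
    df = pd.DataFrame(cols, index=[f"t{i}" for i in range(len(next(iter(cols.values()))))])
    return make_matrix(df, samples=samples, mode=Mode.FRACTIONS)


class TestComputeEnrichment:
    def test_direct_ratio(self):
        m = matrix_from_fractions({1: {
            "aerosol": [0.02, 0.98], "bulk": [0.01, 0.99], "ssml": [0.05, 0.95],
        }})
        recs = {r.taxon_id: r for r in compute_enrichment(m)}
        assert recs["t0"].af_bulk.value == pytest.approx(2.0)
        assert recs["t0"].af_ssml.value == pytest.approx(0.02 / 0.05)
        assert recs["t0"].sb.value == pytest.approx(5.0)

    def test_identity_when_equal(self):
        m = matrix_from_fractions({1: {
            "aerosol": [0.05, 0.95], "bulk": [0.05, 0.95], "ssml": [0.05, 0.95],
        }})
        r = {x.taxon_id: x for x in compute_enrichment(m)}["t0"]
        assert r.af_bulk.value == r.af_ssml.value == r.sb.value == 1.0

    def test_zero_denominator_flagged(self):
        m = matrix_from_fractions({1: {"aerosol": [0.01, 0.99], "bulk": [0.0, 1.0]}})
        r = {x.taxon_id: x for x in compute_enrichment(m)}["t0"]
        assert not r.af_bulk.defined
        assert r.af_bulk.flag == "zero_denominator"

    def test_both_zero_flagged_absent(self):
        m = matrix_from_fractions({1: {"aerosol": [0.0, 1.0], "bulk": [0.0, 1.0]}})
        r = {x.taxon_id: x for x in compute_enrichment(m)}["t0"]
        assert r.af_bulk.flag == "absent"

    def test_single_compartment_group_skipped(self):
        m = matrix_from_fractions({1: {"bulk": [0.5, 0.5]}})
        assert compute_enrichment(m) == []

    def test_chain_identity_on_random_triples(self, rng):
        """A:B = (A:S) x (S:B) whenever all three fractions are positive."""
        for _ in range(1000):
            a, b, s = rng.uniform(1e-6, 1.0, 3)
            ab, as_, sb = a / b, a / s, s / b
            assert ab == pytest.approx(as_ * sb, rel=1e-12)

    def test_chain_identity_through_pipeline(self, rng):
        frac = rng.dirichlet(np.ones(4), size=3)  # 3 compartments x 4 taxa
        m = matrix_from_fractions({1: {
            "aerosol": frac[0], "bulk": frac[1], "ssml": frac[2],
        }})
        for r in compute_enrichment(m):
            assert r.af_bulk.value == pytest.approx(
                r.af_ssml.value * r.sb.value, rel=1e-12
            )

    def test_depth_invariance(self, rng):
        counts = rng.integers(10, 1000, size=(5, 6)).astype(float)
        samples = make_samples(days=(1, 2))
        df = pd.DataFrame(counts, index=[f"t{i}" for i in range(5)],
                          columns=[s.sample_id for s in samples])
        r1 = compute_enrichment(normalize(make_matrix(df, samples=samples)))
        df2 = df.copy()
        df2.iloc[:, 2] *= 1000.0  # sequence one sample much deeper
        r2 = compute_enrichment(normalize(make_matrix(df2, samples=samples)))
        for x, y in zip(r1, r2):
            assert x.af_bulk.value == pytest.approx(y.af_bulk.value, rel=1e-12)
            assert x.af_ssml.value == pytest.approx(y.af_ssml.value, rel=1e-12)

    def test_filtering_leaves_other_taxa_unchanged(self, rng):
        frac = rng.dirichlet(np.ones(5), size=3)
        m = matrix_from_fractions({1: {
            "aerosol": frac[0], "bulk": frac[1], "ssml": frac[2],
        }})
        before = {r.taxon_id: r.af_bulk.value for r in compute_enrichment(m)}
        sub = m.subset_taxa([t for t in m.taxon_ids if t != "t2"])
        after = {r.taxon_id: r.af_bulk.value for r in compute_enrichment(sub)}
        for t, v in after.items():
            assert v == pytest.approx(before[t], rel=1e-12)

    def test_duplicate_compartment_rejected(self):
        samples = [
            SampleDescriptor("x", 1, Compartment.BULK, SizeFraction.F3000_200),
            SampleDescriptor("y", 2, Compartment.BULK, SizeFraction.F3000_200),
        ]
        df = pd.DataFrame({"x": [1.0], "y": [1.0]}, index=["t0"])
        m = make_matrix(df, samples=samples, mode=Mode.FRACTIONS)
        # same day/fraction duplicated compartment is impossible by matrix
        # invariant; exercise the error by forging the descriptor list
        m.samples = (
            samples[0],
            SampleDescriptor("y", 1, Compartment.BULK, SizeFraction.F3000_200),
        )
        with pytest.raises(AbundanceTableError, match="duplicate compartment"):
            compute_enrichment(m)


class TestQuadrants:
    @pytest.mark.parametrize("ab,as_,expected", [
        (2.0, 1.5, Quadrant.AEROSOL_ENRICHED),
        (0.5, 0.5, Quadrant.WATERBORNE),
        (2.0, 0.5, Quadrant.BULK_ONLY_ENRICHED),
        (0.5, 2.0, Quadrant.SSML_ONLY_ENRICHED),
        (1.0, 1.0, Quadrant.NEUTRAL),
        (1.0, 2.0, Quadrant.NEUTRAL),
    ])
    def test_classification(self, ab, as_, expected):
        assert classify_quadrant(record(ab, as_)) is expected

    def test_undefined_ratio_gives_undefined(self):
        assert classify_quadrant(record(None, 2.0)) is Quadrant.UNDEFINED

    def test_epsilon_band(self):
        assert classify_quadrant(record(1.05, 1.05), tie_epsilon=0.1) is Quadrant.NEUTRAL
        assert classify_quadrant(record(1.2, 1.2), tie_epsilon=0.1) is Quadrant.AEROSOL_ENRICHED


class TestSummary:
    def test_all_ones(self):
        recs = [record(1.0, 1.0, taxon=f"t{i}", day=d)
                for i in range(4) for d in range(3)]
        s = enrichment_summary(recs)
        assert s.mean == 1.0
        assert s.skewness == pytest.approx(0.0, abs=1e-12) or np.isnan(s.skewness)
        assert s.fraction_below_1 == 0.0

    def test_arithmetic_mean(self):
        recs = [record(v, None, taxon=f"t{i}") for i, v in enumerate([0.5, 1.0, 4.5])]
        s = enrichment_summary(recs, ratios="bulk")
        assert s.mean == pytest.approx(2.0)
        assert s.n == 3

    def test_lognormal_positively_skewed_non_normal(self, rng):
        vals = rng.lognormal(0.0, 1.0, 500)
        recs = [record(float(v), None, taxon=f"t{i}") for i, v in enumerate(vals)]
        s = enrichment_summary(recs, ratios="bulk")
        assert s.skewness > 0
        assert s.normality_p < 0.01

    def test_amplitude_ratio(self):
        # taxon A: max 3 (|3-1|=2), min 0.5 (|1-0.5|=0.5)
        recs = [record(3.0, None, taxon="A", day=1), record(0.5, None, taxon="A", day=2)]
        s = enrichment_summary(recs, ratios="bulk")
        assert s.amplitude_ratio == pytest.approx(2.0 / 0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no defined"):
            enrichment_summary([record(None, None)])
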