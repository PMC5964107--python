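"""Abundance-threshold and spatial-coverage exclusion rules."""

import numpy as np
import pandas as pd
import pytest

from aeroflux import (
    AbundanceFilterConfig,
    AbundanceTableError,
    CoverageProfile,
    Mode,
    apply_abundance_filter,
    apply_coverage_filter,
    coverage_fraction,
    normalize,
    read_bedgraph,
)
from aeroflux.filters import merge_intervals

from conftest import make_matrix


def fractions_matrix(rows: dict[str, list[float]]):
    """Build a fractions-mode matrix from per-taxon rows by padding a filler
    taxon so each column sums to 1."""
    df = pd.DataFrame(rows).T
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    filler = 1.0 - df.sum(axis=0)
    assert (filler >= 0).all()
    df.loc["_filler"] = filler
    return make_matrix(df, mode=Mode.FRACTIONS)


METHODS = AbundanceFilterConfig(1e-5, 1e-4, 10, "methods")


class TestAbundanceFilter:
    def test_any_sample_rule(self):
        rows = {"low": [5e-6] + [1e-3] * 17}
        m = fractions_matrix(rows)
        kept, report = apply_abundance_filter(m, METHODS)
        assert report.removed["low"] == "any-sample"
        assert "low" not in kept.taxon_ids

    def test_low_samples_rule(self):
        rows = {"patchy": [5e-5] * 10 + [1e-3] * 8}
        m = fractions_matrix(rows)
        kept, report = apply_abundance_filter(m, METHODS)
        assert report.removed["patchy"] == "low-samples"

    def test_nine_low_samples_retained(self):
        rows = {"ok": [5e-5] * 9 + [1e-4] * 9}
        m = fractions_matrix(rows)
        kept, report = apply_abundance_filter(m, METHODS)
        assert "ok" in kept.taxon_ids

    def test_counts_mode_rejected(self):
        m = make_matrix({"s0": [1, 2]})
        with pytest.raises(AbundanceTableError, match="fractions"):
            apply_abundance_filter(m, METHODS)

    def test_no_renormalization_after_removal(self):
        rows = {"gone": [5e-6] * 18, "stays": [0.25] * 18}
        m = fractions_matrix(rows)
        kept, _ = apply_abundance_filter(m, METHODS)
        assert (kept.values.loc["stays"] == 0.25).all()

    def test_zero_thresholds_retain_everything(self, rng):
        df = pd.DataFrame(rng.dirichlet(np.ones(8), size=5).T,
                          index=[f"t{i}" for i in range(8)])
        df.columns = [f"s{j}" for j in range(5)]
        m = make_matrix(df, mode=Mode.FRACTIONS)
        kept, _ = apply_abundance_filter(m, AbundanceFilterConfig(0, 0, None, "methods"))
        assert kept.taxon_ids == m.taxon_ids

    @pytest.mark.parametrize("variant,n,expected", [
        ("methods", 18, 10),   # the published 10-of-18 count
        ("methods", 9, 5),     # ceil(10*9/18)
        ("results", 18, 10),   # more than half
        ("results", 17, 9),
    ])
    def test_low_sample_count_scaling(self, variant, n, expected):
        cfg = (AbundanceFilterConfig.methods_variant() if variant == "methods"
               else AbundanceFilterConfig.results_variant())
        assert cfg.low_sample_count(n) == expected

    @pytest.mark.parametrize("variant", ["methods", "results"])
    def test_matches_brute_force_oracle(self, rng, variant):
        """Both clauses, checked per taxon against a direct re-statement."""
        cfg = (AbundanceFilterConfig.methods_variant() if variant == "methods"
               else AbundanceFilterConfig.results_variant())
        for _ in range(20):
            # columns are Dirichlet fractions with occasional tiny entries
            raw = rng.dirichlet(np.full(12, 0.05), size=18).T
            df = pd.DataFrame(raw, index=[f"t{i}" for i in range(12)],
                              columns=[f"s{j}" for j in range(18)])
            m = make_matrix(df, mode=Mode.FRACTIONS)
            kept, report = apply_abundance_filter(m, cfg)
            low_count = cfg.low_sample_count(18)
            for taxon in df.index:
                row = df.loc[taxon].to_numpy()
                clause_any = row.min() < cfg.min_fraction_any_sample
                clause_low = int((row < cfg.low_fraction).sum()) >= low_count
                assert (taxon in report.removed) == (clause_any or clause_low)


class TestCoverage:
    def test_simple_fraction(self):
        p = CoverageProfile("t", 1000, ((0, 100),))
        assert coverage_fraction(p) == pytest.approx(0.10)

    def test_overlapping_intervals_merged(self):
        p = CoverageProfile("t", 100, ((0, 50), (25, 75)))
        assert p.intervals == ((0, 75),)
        assert coverage_fraction(p) == pytest.approx(0.75)

    def test_tiny_coverage(self):
        p = CoverageProfile("t", 200_000, ((500, 600),))
        assert coverage_fraction(p) == pytest.approx(0.0005)

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError, match="outside genome"):
            CoverageProfile("t", 100, ((50, 150),))

    def test_invariant_under_splitting(self, rng):
        genome = 5000
        base = ((100, 900), (2000, 2500), (4000, 4999))
        frac0 = coverage_fraction(CoverageProfile("t", genome, base))
        # split every interval at random interior points and shuffle
        pieces = []
        for s, e in base:
            cut = int(rng.integers(s + 1, e))
            pieces += [(s, cut), (cut, e)]
        rng.shuffle(pieces)
        assert coverage_fraction(
            CoverageProfile("t", genome, tuple(pieces))
        ) == pytest.approx(frac0)

    def test_merge_against_per_position_oracle(self, rng):
        for _ in range(30):
            genome = int(rng.integers(50, 300))
            n_iv = int(rng.integers(1, 10))
            ivs = []
            for _ in range(n_iv):
                s = int(rng.integers(0, genome - 1))
                e = int(rng.integers(s + 1, genome + 1))
                ivs.append((s, e))
            covered = np.zeros(genome, dtype=bool)
            for s, e in ivs:
                covered[s:e] = True
            p = CoverageProfile("t", genome, tuple(ivs))
            assert coverage_fraction(p) == pytest.approx(covered.mean())

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="empty or inverted"):
            merge_intervals([(5, 5)])


class TestCoverageFilter:
    def test_below_threshold_removed_exact_retained(self):
        df = pd.DataFrame({"s0": [0.5, 0.5]}, index=["low", "exact"])
        m = make_matrix(df, mode=Mode.FRACTIONS)
        profiles = {
            "low": CoverageProfile("low", 10_000, ((0, 5),)),      # 0.0005
            "exact": CoverageProfile("exact", 10_000, ((0, 10),)),  # exactly 0.001
        }
        kept, report = apply_coverage_filter(m, profiles, 0.001)
        assert "low" in report.removed
        assert "exact" in kept.taxon_ids  # strict < at the threshold

    def test_no_reference_retained_and_flagged(self):
        df = pd.DataFrame({"s0": [1.0]}, index=["orphan"])
        m = make_matrix(df, mode=Mode.FRACTIONS)
        kept, report = apply_coverage_filter(m, {}, 0.001)
        assert "orphan" in kept.taxon_ids
        assert report.notes["orphan"] == "no reference"

    def test_order_independence_with_abundance_filter(self, rng):
        raw = rng.dirichlet(np.full(10, 0.05), size=18).T
        df = pd.DataFrame(raw, index=[f"t{i}" for i in range(10)],
                          columns=[f"s{j}" for j in range(18)])
        m = make_matrix(df, mode=Mode.FRACTIONS)
        profiles = {}
        for i in range(10):
            end = int(rng.integers(1, 50))
            profiles[f"t{i}"] = CoverageProfile(f"t{i}", 10_000, ((0, end),))
        a1, _ = apply_abundance_filter(m, METHODS)
        ab, _ = apply_coverage_filter(a1, profiles, 0.001)
        c1, _ = apply_coverage_filter(m, profiles, 0.001)
        ca, _ = apply_abundance_filter(c1, METHODS)
        assert ab.taxon_ids == ca.taxon_ids


class TestBedgraph:
    def test_single_line(self, tmp_path):
        p = tmp_path / "g.bedgraph"
        p.write_text("g1 0 100 5\n")
        prof = read_bedgraph(p, 1000)
        assert prof.intervals == ((0, 100),)

    def test_zero_value_intervals_excluded(self, tmp_path):
        p = tmp_path / "g.bedgraph"
        p.write_text("g1 0 50 1\ng1 50 80 0\ng1 80 90 2\n")
        prof = read_bedgraph(p, 1000)
        assert prof.intervals == ((0, 50), (80, 90))

    def test_multi_chrom_offsets_match_oracle(self, tmp_path):
        p = tmp_path / "g.bedgraph"
        # chrom a: length 100 (covered 10..40); chrom b: length 200 (covered 50..60)
        p.write_text("a 0 10 0\na 10 40 3\na 40 100 0\nb 0 50 0\nb 50 60 1\nb 60 200 0\n")
        prof = read_bedgraph(p, 300)
        # brute-force per-position oracle on the concatenated genome
        covered = np.zeros(300, dtype=bool)
        covered[10:40] = True
        covered[100 + 50:100 + 60] = True
        assert coverage_fraction(prof) == pytest.approx(covered.mean())
        assert prof.intervals == ((10, 40), (150, 160))

    def test_chrom_lengths_enforced(self, tmp_path):
        p = tmp_path / "g.bedgraph"
        p.write_text("a 0 150 1\n")
        with pytest.raises(ValueError, match="beyond contig length"):
            read_bedgraph(p, 300, chrom_lengths={"a": 100})

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "g.bedgraph"
        p.write_text("a 10 10 1\n")
        with pytest.raises(ValueError, match="start"):
            read_bedgraph(p, 100)

    def test_exceeding_genome_length_rejected(self, tmp_path):
        p = tmp_path / "g.bedgraph"
        p.write_text("a 0 150 1\n")
        with pytest.raises(ValueError, match="exceeds genome"):
            read_bedgraph(p, 100)
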