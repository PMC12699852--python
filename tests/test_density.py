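"""Interval merging, densities, two-stage averaging, composition."""

import numpy as np
import pandas as pd
import pytest

from strscape.density import (
    at_content_by_period,
    compartment_density,
    composition_by_period,
    density_size_correlation,
    gc_threshold_curve,
    genome_density,
    motif_prevalence,
    rank_average_density,
    species_density,
)
from strscape.intervals import IntervalSet, merge_intervals
from strscape.repeats import StrRecord
from strscape.simulate import generate_taxonomy


def rec(start, end, unit, seq_id="seq"):
    return StrRecord(seq_id, start, end, unit)


def coverage_oracle(intervals, length):
    """Boolean-array per-base coverage count, independent of IntervalSet."""
    cov = np.zeros(length, dtype=bool)
    for s, e in intervals:
        cov[s:e] = True
    return int(cov.sum())


class TestMergeIntervals:
    def test_overlapping_merge(self):
        ivs = merge_intervals([rec(0, 10, "A"), rec(5, 15, "A")])
        assert ivs.to_records() == [("seq", 0, 15)]
        assert ivs.total_bp == 15

    def test_disjoint_unchanged(self):
        ivs = merge_intervals([rec(0, 10, "A"), rec(20, 30, "A")])
        assert ivs.total_bp == 20

    def test_random_against_boolean_oracle(self, rng):
        for _ in range(20):
            raw = []
            for _ in range(1000):
                s = int(rng.integers(0, 9900))
                raw.append((s, s + int(rng.integers(1, 100))))
            ivs = IntervalSet({"c": raw})
            assert ivs.total_bp == coverage_oracle(raw, 10_000)
            arr = ivs["c"]
            assert (arr[1:, 0] > arr[:-1, 1]).all()  # disjoint and sorted

    def test_intersect_against_oracle(self, rng):
        a = [(int(s), int(s) + int(rng.integers(1, 50))) for s in rng.integers(0, 950, 200)]
        b = [(int(s), int(s) + int(rng.integers(1, 50))) for s in rng.integers(0, 950, 200)]
        ia, ib = IntervalSet({"c": a}), IntervalSet({"c": b})
        cov_a = np.zeros(1000, dtype=bool)
        cov_b = np.zeros(1000, dtype=bool)
        for s, e in a:
            cov_a[s:e] = True
        for s, e in b:
            cov_b[s:e] = True
        assert ia.intersect(ib).total_bp == int((cov_a & cov_b).sum())


class TestDensities:
    def test_arithmetic(self):
        ivs = IntervalSet({"c": [(0, 109)]})
        assert genome_density(ivs, 1000) == pytest.approx(109.0)

    def test_empty_zero(self):
        assert genome_density(IntervalSet(), 1000) == 0.0

    def test_zero_genome_size(self):
        with pytest.raises(ValueError):
            genome_density(IntervalSet(), 0)

    def test_compartment_whole_genome_equals_genome_density(self, rng):
        raw = [(int(s), int(s) + 10) for s in rng.integers(0, 990, 50)]
        strs = IntervalSet({"c": raw})
        whole = IntervalSet({"c": [(0, 1000)]})
        assert compartment_density(strs, whole) == pytest.approx(
            genome_density(strs, 1000)
        )

    def test_compartment_empty_skipped(self):
        assert compartment_density(IntervalSet({"c": [(0, 5)]}), IntervalSet()) is None

    def test_intergenic_strs_zero_genic_density(self):
        strs = IntervalSet({"c": [(500, 600)]})
        genic = IntervalSet({"c": [(0, 100)]})
        assert compartment_density(strs, genic) == 0.0

    def test_split_record_invariance(self, rng):
        """Splitting one sequence in two at a non-STR point leaves the
        genome density unchanged."""
        raw = [(10, 30), (200, 260), (700, 720)]
        one = genome_density(IntervalSet({"c": raw}), 1000)
        two = genome_density(
            IntervalSet({"c1": [(10, 30), (200, 260)], "c2": [(200, 220)]}), 1000
        )
        split_at = 500
        left = [(s, e) for s, e in raw if e <= split_at]
        right = [(s - split_at, e - split_at) for s, e in raw if s >= split_at]
        two = genome_density(IntervalSet({"c1": left, "c2": right}), 1000)
        assert two == pytest.approx(one)


class TestTwoStageAveraging:
    def test_nested_mean(self):
        tax = generate_taxonomy({"Bacteria": [2]})
        # species sp0 and sp1 in one phylum
        sp = {"Bacteria_phylum0_sp0": 2.0, "Bacteria_phylum0_sp1": 4.0}
        out = rank_average_density(sp, tax, "phylum")
        assert out == {"Bacteria_phylum0": pytest.approx(3.0)}

    def test_species_mean_over_assemblies(self):
        tax = generate_taxonomy({"Bacteria": [1]}, assemblies_per_species=3)
        asm = dict(zip(tax["assembly_id"], [1.0, 3.0, 5.0]))
        assert species_density(asm, tax) == {
            "Bacteria_phylum0_sp0": pytest.approx(3.0)
        }

    def test_assembly_duplication_invariance(self):
        """Duplicating every assembly of one species leaves F(R) unchanged."""
        tax1 = generate_taxonomy({"Euk": [3, 1]}, assemblies_per_species=1)
        rng = np.random.default_rng(2)
        asm1 = dict(zip(tax1["assembly_id"], rng.uniform(0, 10, len(tax1))))
        sp1 = species_density(asm1, tax1)
        r1 = rank_average_density(sp1, tax1, "phylum")
        # duplicate all assemblies of the first species with identical density
        first_sp = tax1["species"].iloc[0]
        dup_rows = tax1[tax1["species"] == first_sp].copy()
        dup_rows["assembly_id"] = dup_rows["assembly_id"] + "_dup"
        tax2 = pd.concat([tax1, dup_rows], ignore_index=True)
        asm2 = dict(asm1)
        for old, new in zip(
            tax1[tax1["species"] == first_sp]["assembly_id"], dup_rows["assembly_id"]
        ):
            asm2[new] = asm1[old]
        r2 = rank_average_density(species_density(asm2, tax2), tax2, "phylum")
        for k in r1:
            assert r2[k] == pytest.approx(r1[k])

    def test_unbalanced_taxonomy_oracle(self):
        """Phylum means ignore assembly counts; equals the nested mean."""
        tax = generate_taxonomy(
            {"D": [2, 1]},
            assemblies_per_species={
                "D_phylum0_sp0": 100,
                "D_phylum0_sp1": 1,
                "D_phylum1_sp0": 1,
            },
        )
        asm = {a: (5.0 if sp == "D_phylum0_sp0" else 1.0)
               for a, sp in zip(tax["assembly_id"], tax["species"])}
        out = rank_average_density(species_density(asm, tax), tax, "phylum")
        assert out["D_phylum0"] == pytest.approx((5.0 + 1.0) / 2)
        assert out["D_phylum1"] == pytest.approx(1.0)

    def test_missing_species_excluded(self):
        tax = generate_taxonomy({"D": [1]})
        out = rank_average_density({"ghost_species": 9.0}, tax, "phylum")
        assert out == {}


class TestMotifPrevalence:
    def test_single_class_full(self):
        recs = [rec(0, 20, "AT"), rec(30, 50, "TA")]
        out = motif_prevalence({"sp": recs}, period=2)
        assert out == {"AT": pytest.approx(1.0)}

    def test_equal_split(self):
        recs = [rec(0, 20, "AT"), rec(30, 50, "CG")]
        out = motif_prevalence({"sp": recs}, period=2)
        assert out["AT"] == pytest.approx(0.5)
        assert out["CG"] == pytest.approx(0.5)

    def test_species_averaging(self):
        sp1 = [rec(0, 20, "AC"), rec(30, 110, "AT")]  # AC prop 0.2
        sp2 = [rec(0, 60, "AC"), rec(70, 110, "AT")]  # AC prop 0.6
        out = motif_prevalence({"s1": sp1, "s2": sp2}, period=2)
        assert out["AC"] == pytest.approx(0.4)

    def test_zero_str_species_excluded(self):
        out = motif_prevalence({"s1": [rec(0, 20, "AT")], "s2": []}, period=2)
        assert out == {"AT": pytest.approx(1.0)}

    def test_proportions_sum_to_one_within_species(self, rng):
        recs = [rec(i * 50, i * 50 + int(rng.integers(10, 40)), u)
                for i, u in enumerate(["AC", "AG", "AT", "CG"] * 3)]
        out = motif_prevalence({"sp": recs}, period=2)
        assert sum(out.values()) == pytest.approx(1.0)


class TestComposition:
    def test_only_polya(self):
        df = composition_by_period([rec(0, 12, "A"), rec(20, 35, "A")])
        assert df["occurrence_proportion"].tolist() == [1.0]
        assert at_content_by_period([rec(0, 12, "A")]) == {1: 1.0}

    def test_mixed_periods(self):
        df = composition_by_period([rec(0, 12, "ACG"), rec(20, 30, "A")])
        row3 = df[df["period"] == 3].iloc[0]
        assert row3["occurrence_proportion"] == pytest.approx(0.5)
        assert row3["bp_proportion"] == pytest.approx(12 / 22)

    def test_proportions_sum_to_one(self, rng):
        recs = [rec(i * 40, i * 40 + 10 + int(rng.integers(0, 20)), "ACGT"[: 1 + i % 3] or "A")
                for i in range(20)]
        recs = [rec(i * 40, i * 40 + 12, ["A", "AC", "ACG"][i % 3]) for i in range(20)]
        df = composition_by_period(recs)
        assert df["occurrence_proportion"].sum() == pytest.approx(1.0)
        assert df["bp_proportion"].sum() == pytest.approx(1.0)


class TestGcCurveAndCorrelation:
    def test_polya_dropped_at_low_threshold(self):
        recs = [rec(0, 12, "A"), rec(20, 32, "A")]
        out = gc_threshold_curve(recs, [0.0, 0.1])
        assert out[0.0] == 2 and out[0.1] == 0

    def test_monotone_and_matches_filter(self, rng):
        units = ["A", "AT", "AC", "CG", "G", "ACG", "GGC"]
        recs = [rec(i * 30, i * 30 + 12, units[i % len(units)]) for i in range(50)]
        ts = [0.0, 0.1, 0.4, 0.6, 1.0]
        out = gc_threshold_curve(recs, ts)
        vals = [out[t] for t in ts]
        assert vals == sorted(vals, reverse=True)
        from strscape.repeats import motif_gc
        for t in ts:
            assert out[t] == sum(motif_gc(r.unit) >= t for r in recs)

    def test_perfect_monotone_rho(self):
        sizes = [1e6, 2e6, 3e6, 4e6]
        dens = [1.0, 2.0, 5.0, 9.0]
        rho, _ = density_size_correlation(sizes, dens)
        assert rho == pytest.approx(1.0)
        # invariant under monotone transform of size
        rho2, _ = density_size_correlation(np.log(sizes), dens)
        assert rho2 == pytest.approx(rho)

    def test_independent_null(self):
        rng = np.random.default_rng(3)
        small = sum(
            abs(density_size_correlation(rng.normal(size=200), rng.normal(size=200))[0]) < 0.2
            for _ in range(40)
        )
        assert small >= 38

    def test_constant_flagged(self):
        rho, p = density_size_correlation([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho)
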