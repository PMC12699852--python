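"""Positional profiles, relative enrichment, bootstrap bands, PWM."""

import numpy as np
import pytest

from strscape.repeats import StrRecord, reverse_complement
from strscape.simulate import generate_taxonomy
from strscape.topography import (
    PositionalProfile,
    Window,
    bootstrap_bands,
    landmark_windows,
    nucleotide_counts,
    positional_profile,
    pwm_estimate,
    relative_enrichment,
)


class TestLandmarkWindows:
    def test_plus_strand_tss(self):
        wins = landmark_windows([("c", 1000, 2000, "+")], {"c": 5000}, "TSS", 500)
        assert wins == [Window("c", 1000, +1)]

    def test_minus_strand_tss_mirrors(self):
        wins = landmark_windows([("c", 1000, 2000, "-")], {"c": 5000}, "TSS", 500)
        assert wins == [Window("c", 1999, -1)]

    def test_tes_landmarks(self):
        assert landmark_windows([("c", 1000, 2000, "+")], {"c": 5000}, "TES") == [
            Window("c", 1999, +1)
        ]
        assert landmark_windows([("c", 1000, 2000, "-")], {"c": 5000}, "TES") == [
            Window("c", 1000, -1)
        ]

    def test_strandless_skipped(self):
        assert landmark_windows([("c", 0, 10, ".")], {"c": 100}) == []

    def test_bad_landmark(self):
        with pytest.raises(ValueError):
            landmark_windows([], {}, "middle")


class TestPositionalProfile:
    def test_profile_length_is_1001(self):
        prof = positional_profile([], [Window("c", 2000, 1)], {"c": 5000}, flank=500)
        assert len(prof.counts) == 1001

    def test_single_str_in_window(self):
        strs = [StrRecord("c", 2100, 2110, "A")]
        prof = positional_profile(strs, [Window("c", 2000, 1)], {"c": 5000})
        assert prof.counts.sum() == 10
        assert (prof.counts[np.arange(600, 610)] == 1).all()

    def test_no_strs_zero_vector(self):
        prof = positional_profile([], [Window("c", 2000, 1)], {"c": 5000})
        assert prof.counts.sum() == 0

    def test_edge_truncation_masked(self):
        prof = positional_profile([], [Window("c", 100, 1)], {"c": 5000})
        assert (prof.n_valid[:400] == 0).all()
        assert (prof.n_valid[400:] == 1).all()

    def test_brute_force_overlap_oracle(self, rng):
        strs = []
        for s in rng.integers(0, 4900, size=40):
            strs.append(StrRecord("c", int(s), int(s) + int(rng.integers(10, 60)), "AC"))
        wins = [Window("c", int(c), int(st)) for c, st in
                zip(rng.integers(0, 5000, 10), rng.choice([-1, 1], 10))]
        prof = positional_profile(strs, wins, {"c": 5000})
        cov = np.zeros(5000, dtype=bool)
        for r in strs:
            cov[r.start : min(5000, r.end)] = True
        expected = np.zeros(1001, dtype=int)
        for w in wins:
            for k, off in enumerate(range(-500, 501)):
                pos = w.center + w.strand * off
                if 0 <= pos < 5000 and cov[pos]:
                    expected[k] += 1
        assert (prof.counts == expected).all()

    def test_strand_flip_consistency(self, rng):
        """Profiles on the reverse-complemented genome with mirrored genes
        reproduce the forward profiles."""
        from strscape.repeats import find_strs

        from conftest import random_sequence

        seq = random_sequence(rng, 3000, gc=0.25)
        L = len(seq)
        strs = find_strs(seq, "c")
        genes = [("c", 1000, 1600, "+"), ("c", 2000, 2500, "-")]
        wins = landmark_windows(genes, {"c": L}, "TSS", 200)
        prof = positional_profile(strs, wins, {"c": L}, flank=200)

        rc = reverse_complement(seq)
        strs_rc = find_strs(rc, "c")
        genes_rc = [("c", L - e, L - s, "-" if st == "+" else "+") for _, s, e, st in genes]
        wins_rc = landmark_windows(genes_rc, {"c": L}, "TSS", 200)
        prof_rc = positional_profile(strs_rc, wins_rc, {"c": L}, flank=200)
        assert (prof.counts == prof_rc.counts).all()


class TestRelativeEnrichment:
    def test_uniform_is_all_ones(self):
        prof = PositionalProfile(np.full(1001, 7), np.ones(1001, dtype=int))
        assert relative_enrichment(prof) == pytest.approx(np.ones(1001))

    def test_single_spike(self):
        counts = np.zeros(1001)
        counts[500] = 3
        out = relative_enrichment(counts)
        assert out[500] == pytest.approx(1001.0)
        assert out[0] == 0.0

    def test_mean_is_one(self, rng):
        counts = rng.integers(1, 50, size=1001)
        out = relative_enrichment(counts.astype(float))
        assert out.mean() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_flagged(self):
        with pytest.raises(ValueError):
            relative_enrichment(np.zeros(1001))

    def test_masked_offsets_excluded_from_mean(self):
        counts = np.array([0, 2, 2, 2, 0], dtype=float)
        prof = PositionalProfile(counts, np.array([0, 1, 1, 1, 0]))
        out = relative_enrichment(prof)
        assert out[1] == pytest.approx(1.0)
        assert np.isnan(out[0])


class TestBootstrapBands:
    def test_identical_profiles_zero_width(self):
        profs = {f"s{i}": np.ones(11) for i in range(5)}
        mean, lo, hi = bootstrap_bands(profs, n_rep=100, seed=1)
        assert (lo == hi).all() and (mean == 1.0).all()

    def test_deterministic_given_seed(self, rng):
        profs = {f"s{i}": rng.normal(1, 0.2, 21) for i in range(8)}
        b1 = bootstrap_bands(profs, n_rep=200, seed=5)
        b2 = bootstrap_bands(profs, n_rep=200, seed=5)
        for a, b in zip(b1, b2):
            assert (a == b).all()

    def test_coverage_of_true_mean(self):
        """Species-level band covers the true mean at >= 93% of offsets."""
        rng = np.random.default_rng(7)
        width = 101
        profs = {f"s{i}": 1.0 + rng.normal(0, 0.3, width) for i in range(100)}
        _, lo, hi = bootstrap_bands(profs, n_rep=1000, seed=3)
        covered = ((lo <= 1.0) & (1.0 <= hi)).mean()
        assert covered >= 0.93

    def test_family_band_wider_with_family_effects(self):
        rng = np.random.default_rng(9)
        tax_rows = []
        profs = {}
        for f in range(6):
            fam_effect = rng.normal(0, 0.5)
            for s in range(4):
                sp = f"fam{f}_sp{s}"
                tax_rows.append({"assembly_id": sp, "species": sp,
                                 "family": f"fam{f}", "phylum": "p",
                                 "kingdom": "k", "domain": "d"})
                profs[sp] = 1.0 + fam_effect + rng.normal(0, 0.05, 51)
        import pandas as pd

        tax = pd.DataFrame(tax_rows)
        _, lo_s, hi_s = bootstrap_bands(profs, tax, "species", n_rep=400, seed=2)
        _, lo_f, hi_f = bootstrap_bands(profs, tax, "family", n_rep=400, seed=2)
        assert (hi_f - lo_f).mean() > (hi_s - lo_s).mean()

    def test_band_shrinks_with_more_units(self):
        rng = np.random.default_rng(13)
        make = lambda n: {f"s{i}": rng.normal(0, 1, 31) for i in range(n)}
        _, lo1, hi1 = bootstrap_bands(make(10), n_rep=400, seed=1)
        _, lo2, hi2 = bootstrap_bands(make(160), n_rep=400, seed=1)
        assert (hi2 - lo2).mean() < 0.5 * (hi1 - lo1).mean()

    def test_single_unit_degenerate(self):
        profs = {"only": np.arange(5.0)}
        mean, lo, hi = bootstrap_bands(profs, n_rep=10, seed=0)
        assert (lo == mean).all() and (hi == mean).all()


class TestPwm:
    def test_uniform_prior_all_zero_counts(self):
        prof = pwm_estimate(np.zeros((4, 1001)), 1.0)
        assert prof.probabilities == pytest.approx(np.full((4, 1001), 0.25))

    def test_laplace_column(self):
        counts = np.zeros((4, 1))
        counts[:, 0] = [3, 1, 0, 0]
        prof = pwm_estimate(counts, 1.0)
        assert prof.probabilities[:, 0] == pytest.approx([0.5, 0.25, 0.125, 0.125])

    def test_columns_sum_to_one(self, rng):
        counts = rng.integers(0, 100, size=(4, 50))
        prof = pwm_estimate(counts, [0.5, 1.0, 1.5, 2.0])
        assert prof.probabilities.sum(axis=0) == pytest.approx(np.ones(50))

    def test_zero_alpha_zero_column_rejected(self):
        with pytest.raises(ValueError):
            pwm_estimate(np.zeros((4, 3)), 0.0)

    def test_nucleotide_counts_strand_translation(self):
        """Minus-strand windows count the complement of the genomic base."""
        seq = {"c": "A" * 100}
        strs = [StrRecord("c", 40, 60, "A")]
        win_plus = [Window("c", 50, +1)]
        win_minus = [Window("c", 50, -1)]
        cp = nucleotide_counts(seq, strs, win_plus, flank=5)
        cm = nucleotide_counts(seq, strs, win_minus, flank=5)
        assert cp[0].sum() == 11 and cp[1:].sum() == 0  # A on + strand
        assert cm[3].sum() == 11 and cm[:3].sum() == 0  # T on - strand
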