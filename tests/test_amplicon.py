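"""Demultiplexing, rare-sequence filtering, and frequency estimation."""

import itertools

import numpy as np
import pytest

from btrefuge.amplicon import (
    AlleleCounts,
    SiteSample,
    annual_mean_bootstrap,
    count_alleles,
    demultiplex_and_merge,
    merge_pair,
    site_frequency,
    SiteFrequency,
    TagScheme,
)
from btrefuge.stats import GenotypeTally
from btrefuge.synth import PoolSpec, simulate_pooled_reads


def make_reads(scheme, reference, site_counts, error_rate=0.0, seed=0):
    """Error-controlled read pairs for given per-site (r_copies, s_copies)."""
    r1_all, r2_all = [], []
    for site_id, (n_r, n_s) in site_counts.items():
        pool = scheme[site_id]
        tally = GenotypeTally(ss=n_s, rs=0, rr=n_r)  # 2 copies per moth
        spec = PoolSpec(
            site_id=site_id,
            year=pool.year,
            n_legs=pool.n_legs,
            true_p=n_r / (n_r + n_s),
            depth=2 * (n_r + n_s),
            error_rate=error_rate,
            seed=seed,
            allocation="proportional",
        )
        r1, r2 = simulate_pooled_reads(tally, spec, scheme, reference)
        r1_all.extend(r1)
        r2_all.extend(r2)
    return r1_all, r2_all


class TestMergePair:
    def test_reconstructs_amplicon(self):
        amplicon = "ACGT" * 54  # 216 nt
        from Bio.Seq import Seq

        r1 = amplicon[:150]
        r2 = str(Seq(amplicon).reverse_complement())[:150]
        assert merge_pair(r1, r2) == amplicon

    def test_overlap_disagreement_rejected(self):
        amplicon = "ACGT" * 54
        from Bio.Seq import Seq

        r1 = amplicon[:150]
        last150 = amplicon[66:]
        mutated = ("A" if last150[0] != "A" else "C") + last150[1:]
        r2 = str(Seq(mutated).reverse_complement())
        assert merge_pair(r1, r2) is None


class TestDemultiplex:
    def test_error_free_counts_exact(self, three_site_scheme, reference):
        counts = {"siteA": (0, 50), "siteB": (100, 0), "siteC": (75, 75)}
        r1, r2 = make_reads(three_site_scheme, reference, counts)
        samples, rejected = demultiplex_and_merge(r1, r2, three_site_scheme)
        assert rejected == 0
        assert len(samples["siteA"].sequences) == 100
        assert len(samples["siteB"].sequences) == 200
        assert len(samples["siteC"].sequences) == 300
        assert all(
            len(s) == 204 for s in samples["siteC"].sequences
        )

    def test_unknown_tags_rejected_and_conserved(self, three_site_scheme, reference):
        from btrefuge.synth import make_tag_scheme

        other = make_tag_scheme([("ghost", 10, 2016)], seed=99)
        r1, r2 = make_reads(other, reference, {"ghost": (5, 5)})
        samples, rejected = demultiplex_and_merge(r1, r2, three_site_scheme)
        assigned = sum(len(s.sequences) for s in samples.values())
        assert (assigned, rejected) == (0, 20)

    def test_conservation_with_errors(self, three_site_scheme, reference):
        counts = {"siteA": (100, 100), "siteB": (50, 450)}
        r1, r2 = make_reads(three_site_scheme, reference, counts, error_rate=0.01)
        samples, rejected = demultiplex_and_merge(r1, r2, three_site_scheme)
        assigned = sum(len(s.sequences) for s in samples.values())
        assert assigned + rejected == 1400

    def test_unpaired_input_reported(self, three_site_scheme, reference):
        r1, r2 = make_reads(three_site_scheme, reference, {"siteA": (1, 1)})
        with pytest.raises(ValueError, match="record index"):
            demultiplex_and_merge(r1, r2[:-1], three_site_scheme)


def sample_from(seqs, n_legs=1, site_id="s", year=2016):
    return SiteSample(site_id=site_id, year=year, n_legs=n_legs, sequences=list(seqs))


class TestCountAlleles:
    def test_single_moth_pool_majority_only(self, reference):
        ref = reference.sequence
        alt = reference.resistant_sequence
        sample = sample_from([ref] * 6 + [alt] * 4, n_legs=1)
        counts = count_alleles(
            sample, ref, reference.variant_offset, reference.resistant_base
        )
        # threshold 1/(2*1) = 0.5 removes the 0.4-frequency variant
        assert (counts.s_count, counts.r_count) == (6, 0)
        assert counts.n_reads_removed == 4

    def test_error_variant_below_threshold_removed(self, reference):
        ref = reference.sequence
        err = "A" + ref[1:] if ref[0] != "A" else "C" + ref[1:]
        sample = sample_from([ref] * 997 + [err] * 3, n_legs=100)
        counts = count_alleles(
            sample, ref, reference.variant_offset, reference.resistant_base
        )
        # 3/1000 = 0.003 < 1/(2*100) = 0.005
        assert counts.n_reads_removed == 3
        assert counts.n_distinct_surviving == 1

    def test_threshold_is_theoretical_minimum_allele_frequency(self):
        assert 1.0 / (2 * 996) == pytest.approx(0.000502, abs=1e-6)

    def test_filter_idempotent(self, reference):
        ref = reference.sequence
        alt = reference.resistant_sequence
        err = ref[:50] + ("A" if ref[50] != "A" else "G") + ref[51:]
        sample = sample_from([ref] * 180 + [alt] * 17 + [err] * 3, n_legs=10)
        once = count_alleles(
            sample, ref, reference.variant_offset, reference.resistant_base
        )
        survivors = [ref] * once.s_count + [alt] * once.r_count
        twice = count_alleles(
            sample_from(survivors, n_legs=10),
            ref,
            reference.variant_offset,
            reference.resistant_base,
        )
        assert (twice.r_count, twice.s_count, twice.other_count) == (
            once.r_count,
            once.s_count,
            once.other_count,
        )
        assert twice.n_reads_removed == 0

    def test_offset_out_of_range(self, reference):
        sample = sample_from([reference.sequence], n_legs=1)
        with pytest.raises(ValueError, match="variant_offset"):
            count_alleles(sample, reference.sequence, 204, "C")

    def test_length_mismatch_reported(self, reference):
        sample = sample_from(["ACGT"], n_legs=1)
        with pytest.raises(ValueError, match="length"):
            count_alleles(sample, reference.sequence, 10, "C")


def counts_of(r, s, other=0, n_legs=100):
    return AlleleCounts(
        site_id="s", year=2016, n_legs=n_legs, r_count=r, s_count=s,
        other_count=other, n_distinct_surviving=2, n_reads_input=r + s + other,
        n_reads_removed=0,
    )


class TestSiteFrequency:
    @pytest.mark.parametrize(
        "r,s,other,expected",
        [(0, 1000, 0, 0.0), (500, 500, 0, 0.5), (100, 880, 20, 0.1)],
    )
    def test_ratio(self, r, s, other, expected):
        assert site_frequency(counts_of(r, s, other)).frequency == expected

    def test_no_surviving_reads(self):
        with pytest.raises(ValueError, match="no reads"):
            site_frequency(counts_of(0, 0, 0))


def freqs(values, year=2016):
    return [
        SiteFrequency(site_id=f"s{i}", year=year, frequency=v, n_legs=100)
        for i, v in enumerate(values)
    ]


class TestAnnualMeanBootstrap:
    def test_single_site_interval_collapses(self):
        mean, ci = annual_mean_bootstrap(freqs([0.07]), reps=200, seed=1)
        assert mean == ci.lower == ci.upper == 0.07

    def test_identical_sites_interval_collapses(self):
        mean, ci = annual_mean_bootstrap(freqs([0.1, 0.1, 0.1]), reps=200, seed=1)
        assert (mean, ci.lower, ci.upper) == pytest.approx((0.1, 0.1, 0.1))

    def test_deterministic_under_seed(self):
        values = freqs([0.02, 0.08, 0.11, 0.05, 0.09])
        a = annual_mean_bootstrap(values, reps=500, seed=123)
        b = annual_mean_bootstrap(values, reps=500, seed=123)
        assert a == b

    def test_interval_covers_truth_for_scattered_sites(self, rng):
        values = freqs(np.clip(rng.normal(0.10, 0.02, size=8), 0, 1))
        mean, ci = annual_mean_bootstrap(values, reps=1000, seed=7)
        assert ci.lower <= 0.10 <= ci.upper

    @pytest.mark.parametrize("site_values", [[0.0, 0.1, 0.3], [0.05, 0.2, 0.4, 0.9]])
    def test_matches_exhaustive_resampling_oracle(self, site_values):
        """Percentile bounds agree with full enumeration of all resamples."""
        n = len(site_values)
        arr = np.array(site_values)
        exhaustive = np.sort(
            [np.mean(arr[list(idx)]) for idx in itertools.product(range(n), repeat=n)]
        )
        lo_ex, hi_ex = np.quantile(exhaustive, [0.025, 0.975])
        step = np.max(np.diff(np.unique(exhaustive)))
        _, ci = annual_mean_bootstrap(freqs(site_values), reps=4000, seed=3)
        assert abs(ci.lower - lo_ex) <= step
        assert abs(ci.upper - hi_ex) <= step

    def test_sqrt_legs_weighting_close_to_unweighted(self):
        values = [
            SiteFrequency(site_id=f"s{i}", year=2016, frequency=v, n_legs=n)
            for i, (v, n) in enumerate(
                [(0.08, 50), (0.12, 80), (0.10, 120), (0.09, 100)]
            )
        ]
        unweighted, _ = annual_mean_bootstrap(values, reps=200, seed=1)
        weighted, _ = annual_mean_bootstrap(
            values, reps=200, seed=1, weight_by_sqrt_legs=True
        )
        assert weighted == pytest.approx(unweighted, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            annual_mean_bootstrap([])


class TestEndToEndRecovery:
    @pytest.mark.parametrize("true_p", [0.01, 0.1, 0.5])
    def test_exact_recovery_without_errors(
        self, three_site_scheme, reference, true_p
    ):
        from btrefuge.synth import simulate_moth_pool

        n_legs = 100
        tally = simulate_moth_pool(true_p, n_legs, seed=8)
        spec = PoolSpec(
            site_id="siteC", year=2016, n_legs=n_legs, true_p=true_p,
            depth=2000, error_rate=0.0, seed=9, allocation="proportional",
        )
        r1, r2 = simulate_pooled_reads(tally, spec, three_site_scheme, reference)
        samples, rejected = demultiplex_and_merge(r1, r2, three_site_scheme)
        counts = count_alleles(
            samples["siteC"], reference.sequence, reference.variant_offset,
            reference.resistant_base,
        )
        pool_freq = tally.r_copies / (2 * n_legs)
        assert rejected == 0
        assert site_frequency(counts).frequency == pytest.approx(pool_freq, abs=0)
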