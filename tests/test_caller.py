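"""Site likelihood, MAF estimation, LLR, and the filter battery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from segreg.alignment_io import PileupSite, encode_sequence, phred_to_error
from segreg.caller import (CallThresholds, SiteEvidence, call_minor_alleles,
                           estimate_maf, llr, pos_rank_sum, signal_score,
                           site_likelihood, strand_bias, titv_ratio)

from oracles import direct_product_likelihood, grid_mle_llr


def ev(minor, major, **kw):
    return SiteEvidence(np.asarray(minor, float), np.asarray(major, float), **kw)


class TestSiteLikelihood:
    def test_two_reads_at_half_frequency(self):
        # one minor + one major read, eps = 0.01 each, f = 0.5:
        # both factors are exactly 0.5
        assert site_likelihood(0.5, ev([0.01], [0.01])) == pytest.approx(0.25)

    def test_null_with_no_minor_reads(self):
        e = ev([], [0.01, 0.02, 0.05])
        assert site_likelihood(0.0, e) == pytest.approx(0.99 * 0.98 * 0.95)

    def test_minor_read_at_null_contributes_its_error_rate(self):
        assert site_likelihood(0.0, ev([0.01], [])) == pytest.approx(0.01)

    def test_invalid_error_rates_rejected(self):
        with pytest.raises(ValueError):
            ev([0.0], [])
        with pytest.raises(ValueError):
            ev([], [1.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-4, 0.6), max_size=10),
           st.lists(st.floats(1e-4, 0.6), min_size=1, max_size=10),
           st.floats(0, 0.5))
    def test_log_space_matches_direct_product(self, minor, major, f):
        got = site_likelihood(f, ev(minor, major))
        want = direct_product_likelihood(f, minor, major)
        assert got == pytest.approx(want, rel=1e-12)


class TestMafAndLlr:
    def test_no_minor_reads_estimates_zero(self):
        e = ev([], [0.001] * 50)
        assert estimate_maf(e) == 0.0
        assert llr(e) == 0.0

    def test_ten_of_a_thousand_matches_grid(self):
        e = ev([0.001] * 10, [0.001] * 990)
        f_grid, llr_grid = grid_mle_llr(e.minor_errors, e.major_errors)
        assert estimate_maf(e) == pytest.approx(f_grid, abs=1e-4)
        assert estimate_maf(e) == pytest.approx(0.01, abs=1e-3)
        assert llr(e) == pytest.approx(llr_grid, abs=1e-3)

    def test_all_minor_reads_hit_upper_bound(self):
        assert estimate_maf(ev([1e-4] * 30, [])) == pytest.approx(0.5, abs=1e-5)

    def test_extra_minor_read_never_decreases_llr(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            minor = list(10.0 ** -rng.uniform(1, 4, rng.integers(0, 6)))
            major = list(10.0 ** -rng.uniform(1, 4, rng.integers(5, 60)))
            base = llr(ev(minor, major))
            grown = llr(ev(minor + [0.01], major))
            assert grown >= base - 1e-9


class TestStrandBias:
    def test_proportional_table_passes(self):
        assert strand_bias(10, 10, 100, 100) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association_filtered(self):
        score = strand_bias(50, 0, 0, 50)
        assert score > 1.0
        # agrees with the exact hypergeometric tail
        _, p = sps.fisher_exact([[50, 0], [0, 50]])
        assert score == pytest.approx(-math.log10(p) / 2)

    def test_threshold_matches_p_001(self):
        # sb < 1 must be exactly equivalent to Fisher p > 0.01
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(0, 30, size=4)
            if t.sum() == 0:
                continue
            sb = strand_bias(*t)
            _, p = sps.fisher_exact(t.reshape(2, 2))
            assert (sb < 1.0) == (p > 0.01)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            strand_bias(0, 0, 0, 0)


class TestPosRankSum:
    def test_identical_distributions_near_zero(self):
        z = pos_rank_sum(list(range(1, 101)), list(range(1, 101)))
        assert abs(z) < 0.1

    def test_end_clustered_minor_filtered(self):
        z = pos_rank_sum([96, 97, 98, 99, 100], list(range(1, 101)))
        assert z < -3

    def test_start_clustered_minor_positive(self):
        z = pos_rank_sum([1, 2, 3, 4, 5], list(range(1, 101)))
        assert z > 3

    def test_empty_stratum_indeterminate(self):
        assert pos_rank_sum([], [1, 2, 3]) is None


class TestSignalScore:
    def test_single_read(self):
        assert signal_score([20]) == pytest.approx(100.0)

    def test_histogram_sum(self):
        assert signal_score({20: 2, 30: 1}) == pytest.approx(1200.0)

    def test_empty(self):
        assert signal_score([]) == 0.0


def _make_site(position, ref_base, minor_n=20, major_n=1980, minor="G",
               major="A", quality=30, balanced=True, minor_positions=None):
    n = minor_n + major_n
    allele = np.array([encode_sequence(minor)[0]] * minor_n
                      + [encode_sequence(major)[0]] * major_n, dtype=np.uint8)
    rev = np.zeros(n, bool)
    rev[::2] = True if balanced else False
    qual = np.full(n, quality, dtype=np.int16)
    rng = np.random.default_rng(position)
    rpos = rng.integers(1, 101, size=n).astype(np.int32)
    if minor_positions is not None:
        rpos[:minor_n] = minor_positions
    return PileupSite(position=position, ref_base=ref_base, allele=allele,
                      is_reverse=rev, qual=qual, read_pos=rpos)


class TestCallMinorAlleles:
    def test_strong_site_passes_all_filters(self):
        calls = call_minor_alleles([_make_site(1000, "A")])
        assert len(calls) == 1
        c = calls[0]
        assert c.passed and all(
            c.flags[k] for k in ("min_strand_reads", "min_maf", "min_llr",
                                 "strand_bias", "pos_rank_sum",
                                 "masked_region"))
        assert (c.major_allele, c.minor_allele) == ("A", "G")
        assert c.minor_count == 20 and c.depth == 2000
        assert c.ml_maf == pytest.approx(0.01, abs=2e-3)

    def test_masked_region_site_fails_only_that_flag(self):
        c = call_minor_alleles([_make_site(310, "A")])[0]
        assert not c.passed and not c.flags["masked_region"]
        assert c.flags["min_llr"] and c.flags["strand_bias"]

    def test_no_minor_reads_no_call(self):
        site = _make_site(50, "A", minor_n=0, major_n=100)
        assert call_minor_alleles([site]) == []

    def test_low_quality_bases_not_counted(self):
        site = _make_site(50, "A", quality=15)
        assert call_minor_alleles([site]) == []

    def test_single_strand_minor_fails_strand_filters(self):
        site = _make_site(50, "A", minor_n=10, major_n=990)
        site.is_reverse[:10] = False        # all minor reads forward
        site.is_reverse[10:] = np.arange(990) % 2 == 0
        c = call_minor_alleles([site])[0]
        assert not c.flags["min_strand_reads"]
        assert not c.passed

    def test_end_clustered_minor_fails_rank_sum(self):
        site = _make_site(50, "A", minor_n=10, major_n=990,
                          minor_positions=np.arange(91, 101))
        c = call_minor_alleles([site])[0]
        assert not c.flags["pos_rank_sum"]

    def test_maf_below_cutoff_fails(self):
        site = _make_site(50, "A", minor_n=4, major_n=4996)
        c = call_minor_alleles([site])[0]
        assert c.ml_maf < 0.001
        assert not c.flags["min_maf"]

    def test_scoring_mode_skips_filter_statistics(self):
        full = call_minor_alleles([_make_site(70, "A")])[0]
        fast = call_minor_alleles([_make_site(70, "A")],
                                  filter_statistics=False)[0]
        assert fast.llr == pytest.approx(full.llr)
        assert math.isnan(fast.strand_bias)
        assert fast.flags["strand_bias"] and fast.flags["pos_rank_sum"]


class TestTiTv:
    def _call(self, major, minor):
        return call_minor_alleles(
            [_make_site(60, major, major=major, minor=minor)])[0]

    def test_ratio(self):
        calls = [self._call("A", "G"), self._call("C", "T"),
                 self._call("A", "C")]
        res = titv_ratio(calls)
        assert (res.transitions, res.transversions) == (2, 1)
        assert res.ratio == pytest.approx(2.0)

    def test_only_transitions_undefined(self):
        res = titv_ratio([self._call("A", "G")])
        assert not res.defined and math.isnan(res.ratio)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            titv_ratio([])


def test_llr_scan_matches_caller():
    """The histogram scanner and the per-site caller agree exactly."""
    from segreg.pipeline import llr_scan
    from segreg.simulate import ErrorProfile, simulate_reads
    from segreg.alignment_io import Pileup

    template = "".join("ACGT"[c] for c in
                       np.random.default_rng(8).integers(0, 4, 1500))
    reads = simulate_reads(template, ErrorProfile.uniform(0.01, 30),
                           coverage=150, read_length=50, paired=True, seed=5)
    batch = reads.observation_batch(template)
    pile = Pileup.from_batch(batch, template, min_quality=0)
    calls = {c.position: c for c in
             call_minor_alleles(pile, masked_regions=(),
                                filter_statistics=False)}
    scan = llr_scan(batch, template)
    assert set(scan.position) == set(calls)
    for _, row in scan.iterrows():
        c = calls[row.position]
        assert (row.minor, row.major) == (c.minor_allele, c.major_allele)
        assert row.minor_count == c.minor_count
        assert row.llr == pytest.approx(c.llr, abs=1e-9)
        assert row.ml_maf == pytest.approx(c.ml_maf, abs=1e-9)
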