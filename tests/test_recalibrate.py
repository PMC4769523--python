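"""Segmented-regression training, the trained model, and its application."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from segreg.alignment_io import BaseObservation, ObservationBatch
from segreg.recalibrate import (FALLBACK, FITTED, GroupKey, QualityBin,
                                RecalibrationModel, SegmentedFit,
                                apply_to_alignments, assign_group,
                                combine_error_rates, empirical_phred,
                                enumerate_groups, fit_segmented,
                                recalibrate_quality, tabulate_bins,
                                train_model)
from segreg.simulate import ErrorProfile, simulate_reads

from oracles import brute_force_segmented


def _bins(rows, group=GroupKey(1, 1, "A", "START")):
    return [QualityBin.build(group, q, n, e, min_bin_count=1)
            for q, n, e in rows]


class TestEmpiricalPhred:
    def test_formula_values(self):
        assert empirical_phred(10, 1000) == pytest.approx(19.7903, abs=1e-3)
        assert empirical_phred(1, 10) == pytest.approx(8.4510, abs=1e-3)

    def test_zero_errors_finite(self):
        assert np.isfinite(empirical_phred(0, 1000))
        assert empirical_phred(0, 1000) > 30

    def test_all_errors_clamped_at_zero(self):
        assert empirical_phred(50, 50) == 0.0

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            empirical_phred(0, 0)


class TestCombineErrorRates:
    def test_background_correction_values(self):
        assert round(combine_error_rates(40, 1e-3), 2) == 29.59
        assert round(combine_error_rates(10, 1e-3), 2) == 9.96

    def test_zero_background_is_identity(self):
        q = np.arange(2, 61)
        assert np.allclose(combine_error_rates(q, 0.0), q)

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            combine_error_rates(30, 1.5)


class TestGrouping:
    def test_paired_end_length_100_has_3200_context_groups(self):
        assert len(enumerate_groups(100, paired=True)) == 2 * 100 * 4 * 4

    def test_single_end_length_50(self):
        assert len(enumerate_groups(50, paired=False)) == 1 * 50 * 4 * 4

    def test_start_context_keys_counted_separately(self):
        with_start = enumerate_groups(100, include_start_context=True)
        assert len(with_start) == 3200 + 2 * 4

    def test_cycle_one_uses_start_sentinel(self):
        obs = BaseObservation(1, 1, "A", "START", 30, "forward", 1, 5, False)
        assert assign_group(obs) == GroupKey(1, 1, "A", "START")

    def test_n_base_ineligible(self):
        obs = BaseObservation(1, 3, "N", "A", 30, "forward", 3, 5, False)
        with pytest.raises(ValueError):
            assign_group(obs)


class TestTabulateBins:
    def _obs(self, n, quality=30, mismatches=0, position=5):
        return [BaseObservation(1, 2, "C", "A", quality, "forward", 2,
                                position, i < mismatches) for i in range(n)]

    def test_counts_and_errors(self):
        bins = tabulate_bins(self._obs(1000, mismatches=10), min_bin_count=100)
        (key, blist), = bins.items()
        assert key == GroupKey(1, 2, "C", "A")
        b = blist[0]
        assert (b.base_count, b.error_count, b.masked) == (1000, 10, False)
        assert b.empirical_quality == pytest.approx(
            empirical_phred(10, 1000))

    def test_small_bins_masked(self):
        bins = tabulate_bins(self._obs(99), min_bin_count=100)
        b = next(iter(bins.values()))[0]
        assert b.masked and b.empirical_quality is None

    def test_known_variant_positions_excluded(self):
        bins = tabulate_bins(self._obs(50, position=7),
                             known_variant_positions={7})
        assert bins == {}

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            tabulate_bins([])


class TestFitSegmented:
    def test_identity_line_zero_residual(self):
        # y = x exactly: both segments recover the identity with zero SSE,
        # and on the all-tied SSE the smallest valid breakpoint is chosen
        # (>= 2 bins per side, so the first candidate is between bins 2 and 3)
        bins = _bins([(q, 1000, 0) for q in (10, 20, 30, 40, 50)])
        for b in bins:
            b.empirical_quality = float(b.raw_quality)
        fit = fit_segmented(bins, min_bin_count=1)
        assert fit.status == FITTED
        assert fit.sse == pytest.approx(0, abs=1e-9)
        for a, b_ in ((fit.a0, fit.b0), (fit.a1, fit.b1)):
            assert a == pytest.approx(1) and b_ == pytest.approx(0, abs=1e-9)
        assert fit.bk == 25.0

    def test_v_shape_recovers_breakpoint_and_slopes(self):
        bins = _bins([(x, 100, 0) for x in (5, 10, 15, 20, 25, 30, 35, 40)])
        for b in bins:
            x = b.raw_quality
            b.empirical_quality = float(30 - x if x <= 20 else x - 10)
        fit = fit_segmented(bins, min_bin_count=1)
        # the vertex (20, 10) lies on both arms, so every split that keeps it
        # adjacent to the hinge is SSE-0-optimal; the smallest-bk tie rule
        # admits 17.5 as well as 22.5
        assert 15 < fit.bk < 25
        assert fit.a0 == pytest.approx(-1) and fit.a1 == pytest.approx(1)
        assert fit.sse == pytest.approx(0, abs=1e-9)
        assert fit.predict(5) == pytest.approx(25)
        assert fit.predict(40) == pytest.approx(30)

    def test_three_usable_bins_fall_back(self):
        fit = fit_segmented(_bins([(10, 500, 5), (20, 500, 5), (30, 500, 5)]),
                            min_bin_count=100)
        assert fit.status == FALLBACK
        assert fit.predict(17) == 17      # pass-through

    def test_masked_bins_do_not_count_toward_minimum(self):
        rows = [(10, 500, 5), (20, 500, 5), (30, 500, 5), (40, 99, 1)]
        assert fit_segmented(_bins(rows), min_bin_count=100).status == FALLBACK

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            n = int(rng.integers(4, 41))
            x = np.sort(rng.choice(np.arange(2, 61), size=n, replace=False))
            y = rng.normal(x, 4.0)
            w = rng.integers(100, 5000, size=n).astype(float)
            bins = _bins([(int(xi), int(wi), 0) for xi, wi in zip(x, w)])
            for b, yi in zip(bins, y):
                b.empirical_quality = float(yi)
            fit = fit_segmented(bins, min_bin_count=1)
            sse, bk, a0, b0, a1, b1 = brute_force_segmented(x, y, w)
            assert fit.sse == pytest.approx(sse, rel=1e-6, abs=1e-6)
            assert fit.bk == pytest.approx(bk)
            assert fit.a0 == pytest.approx(a0, rel=1e-5, abs=1e-6)
            assert fit.a1 == pytest.approx(a1, rel=1e-5, abs=1e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 60), st.integers(100, 10_000)),
                    min_size=4, max_size=20, unique_by=lambda t: round(t[0])))
    def test_fitted_sse_never_beats_oracle(self, rows):
        rows = sorted((round(q), n) for q, n in rows)
        if len({q for q, _ in rows}) < 4:
            return
        bins = _bins([(q, n, 0) for q, n in rows])
        rng = np.random.default_rng(1)
        for b in bins:
            b.empirical_quality = float(rng.normal(b.raw_quality, 3))
        fit = fit_segmented(bins, min_bin_count=1)
        x = np.array([b.raw_quality for b in bins], float)
        y = np.array([b.empirical_quality for b in bins])
        w = np.array([b.base_count for b in bins], float)
        sse, *_ = brute_force_segmented(x, y, w)
        assert fit.sse <= sse + 1e-6 * max(1.0, sse)


class TestModel:
    def _model(self):
        fits = {GroupKey(1, 1, "A", "START"):
                SegmentedFit(0.5, 5.0, 1.0, 0.0, 20.0, 1.25, FITTED),
                GroupKey(1, 2, "C", "A"): SegmentedFit()}
        return RecalibrationModel(fits, metadata={"training_file": "x"})

    def test_piecewise_evaluation_and_rounding(self):
        m = self._model()
        g = GroupKey(1, 1, "A", "START")
        assert recalibrate_quality(g, 10, m) == 10      # 0.5*10+5
        assert recalibrate_quality(g, 30, m) == 30      # upper segment y=x
        assert recalibrate_quality(g, 19, m) == 15      # round(14.5) -> 15

    def test_clamped_to_output_range(self):
        m = RecalibrationModel({GroupKey(1, 1, "A", "START"):
                                SegmentedFit(3.0, 0.0, 3.0, 0.0, 0.0, 0.0,
                                             FITTED)})
        assert m.recalibrate(GroupKey(1, 1, "A", "START"), 40) == 60

    def test_fallback_and_unknown_groups_return_raw(self):
        m = self._model()
        assert m.recalibrate(GroupKey(1, 2, "C", "A"), 37) == 37
        assert m.recalibrate(GroupKey(2, 9, "T", "G"), 11) == 11
        assert m.fallback_events == 2

    def test_serialisation_round_trip_lossless(self, tmp_path):
        reads = simulate_reads("ACGT" * 300, ErrorProfile(), coverage=120,
                               read_length=40, paired=True, seed=7)
        model = train_model(reads.observation_batch("ACGT" * 300),
                            "ACGT" * 300, min_bin_count=20)
        path = tmp_path / "model.tsv"
        model.save(path)
        loaded = RecalibrationModel.load(path)
        assert set(loaded.fits) == set(model.fits)
        for key, fit in model.fits.items():
            got = loaded.fits[key]
            assert got.status == fit.status
            for f in ("a0", "b0", "a1", "b1", "bk", "sse"):
                a, b = getattr(got, f), getattr(fit, f)
                assert a == b or (np.isnan(a) and np.isnan(b)), (key, f)
        assert loaded.min_bin_count == model.min_bin_count
        assert loaded.clamp == model.clamp

    def test_monotone_within_segment_for_nonnegative_slope(self):
        m = self._model()
        g = GroupKey(1, 1, "A", "START")
        lower = [m.recalibrate(g, q) for q in range(2, 20)]
        assert all(b >= a for a, b in zip(lower, lower[1:]))


class TestTraining:
    def test_calibrated_input_trains_near_identity(self):
        template = "".join("ACGT"[c] for c in
                           np.random.default_rng(0).integers(0, 4, 2000))
        profile = ErrorProfile.calibrated(
            quality_levels=(12, 17, 22, 27), level_weights=(.25, .25, .25, .25),
            cycle_downgrade=0.0)
        reads = simulate_reads(template, profile, coverage=3000,
                               read_length=10, paired=False, seed=13)
        batch = reads.observation_batch(template)
        model = train_model(batch, template)
        recal = model.recalibrate_batch(batch)
        # emitted scores already equal true scores: recalibration ~ no-op
        # up to per-bin estimation noise
        diff = np.abs(recal - batch.qual)
        assert diff.mean() < 0.7
        assert np.mean(diff <= 2) > 0.99

    def test_known_variant_exclusion_changes_bins(self):
        template = "A" * 200
        reads = simulate_reads(template, ErrorProfile.uniform(0.05),
                               coverage=100, read_length=20, paired=False,
                               seed=3)
        batch = reads.observation_batch(template)
        all_bins = tabulate_bins(batch, min_bin_count=1)
        masked_bins = tabulate_bins(batch, known_variant_positions=set(range(1, 101)),
                                    min_bin_count=1)
        n_all = sum(b.base_count for bl in all_bins.values() for b in bl)
        n_masked = sum(b.base_count for bl in masked_bins.values() for b in bl)
        assert 0 < n_masked < n_all

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            train_model(ObservationBatch.from_observations([]), "ACGT")


class TestApplyToAlignments:
    def test_identity_model_preserves_qualities(self, sam_factory, tmp_path):
        rows = [{"name": "r1", "pos": 0, "seq": "ACGTACGT",
                 "quals": [2, 12, 22, 32, 33, 34, 35, 36]},
                {"name": "r2", "pos": 2, "seq": "GTACGTAC", "flag": 16,
                 "quals": [30] * 8}]
        src = sam_factory(rows, 20)
        model = RecalibrationModel({})      # everything falls back to raw
        out = str(tmp_path / "recal.sam")
        # a model with no fitted groups has no cycles; give it one identity fit
        model.fits[GroupKey(1, 1, "A", "START")] = SegmentedFit(
            1.0, 0.0, 1.0, 0.0, 0.0, 0.0, FITTED)
        stats = apply_to_alignments(src, out, model)
        assert stats == {"reads": 2, "bases": 16}
        got = list(pysam.AlignmentFile(out).fetch(until_eof=True))
        for r, row in zip(got, rows):
            assert list(r.query_qualities) == row["quals"]
            assert r.get_tag("OQ") is not None

    def test_planted_shift_corrected_on_alignments(self, tmp_path):
        template = "".join("ACGT"[c] for c in
                           np.random.default_rng(2).integers(0, 4, 1500))
        profile = ErrorProfile(quality_levels=(20, 25, 30, 35),
                               level_weights=(.25, .25, .25, .25),
                               cycle_downgrade=0.0, background_error=3e-3,
                               cycle_ramp=0.0,
                               context_factors=np.ones((5, 4)))
        reads = simulate_reads(template, profile, coverage=2500,
                               read_length=10, paired=False, seed=21)
        model = train_model(reads.observation_batch(template), template,
                            min_bin_count=100)
        sam = tmp_path / "in.sam"
        reads.to_sam(sam)
        out = str(tmp_path / "out.sam")
        apply_to_alignments(str(sam), out, model)
        recal = np.concatenate(
            [r.query_qualities for r in
             pysam.AlignmentFile(out).fetch(until_eof=True)])
        # raw 35 claims eps 3.2e-4 but truth is ~3.3e-3 (q ~ 24.8)
        raw = np.concatenate(
            [r.query_qualities for r in
             pysam.AlignmentFile(str(sam)).fetch(until_eof=True)])
        corrected = recal[raw == 35]
        assert np.abs(corrected.mean() - combine_error_rates(35, 3e-3)) < 1.0

    def test_empty_input_empty_output(self, sam_factory, tmp_path):
        src = sam_factory([], 50)
        out = str(tmp_path / "o.sam")
        stats = apply_to_alignments(src, out, RecalibrationModel({}))
        assert stats["reads"] == 0
        assert list(pysam.AlignmentFile(out, check_sq=False)
                    .fetch(until_eof=True)) == []
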