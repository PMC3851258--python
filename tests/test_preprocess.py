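import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dntox.errors import ConfigurationError, ParameterError, ValidationError
from dntox.preprocess import (ExpressionMatrix, NoiseModel, align_baseline,
                              apply_noise_floor, normalize_by_od,
                              preprocess_pipeline, smooth_moving_average,
                              subtract_promoterless_background)

from conftest import LABELS, TIMES, make_experiment, make_well


class TestOdNormalization:
    def test_divides_by_od(self, toy_experiment):
        out = normalize_by_od(toy_experiment)
        w1 = next(w for w in out.wells if w.well_id == "w1")
        orig = next(w for w in toy_experiment.wells if w.well_id == "w1")
        np.testing.assert_allclose(w1.series["0"], orig.series["0"] / 2.0)

    def test_od_one_is_identity(self):
        series = {lab: np.arange(18.0) for lab in LABELS}
        wells = [make_well("w1", "promoter", gene="g", od=1.0, series=series),
                 make_well("w2", "promoterless"), make_well("w3", "empty")]
        out = normalize_by_od(make_experiment(wells))
        np.testing.assert_allclose(out.wells[0].series["0"], np.arange(18.0))

    def test_replicate_wells_use_their_own_od(self):
        base = np.full(18, 100.0)
        wells = [
            make_well("w1", "promoter", gene="g", od=2.0,
                      series={lab: base.copy() for lab in LABELS}),
            make_well("w2", "promoter", gene="g", od=4.0,
                      series={lab: base.copy() for lab in LABELS}),
            make_well("w3", "promoterless"), make_well("w4", "empty"),
        ]
        out = normalize_by_od(make_experiment(wells))
        np.testing.assert_allclose(out.wells[0].series["0"], 50.0)
        np.testing.assert_allclose(out.wells[1].series["0"], 25.0)

    def test_missing_od_on_promoter_rejected(self):
        with pytest.raises(ValidationError):
            make_well("w1", "promoter", gene="g", od=None)

    def test_empty_wells_pass_through(self, toy_experiment):
        out = normalize_by_od(toy_experiment)
        w4 = next(w for w in out.wells if w.role == "empty")
        orig = next(w for w in toy_experiment.wells if w.role == "empty")
        np.testing.assert_allclose(w4.series["0"], orig.series["0"])

    def test_scale_equivariance(self, toy_experiment):
        """Scaling a well's raw series and od by the same c leaves output unchanged."""
        import copy
        scaled = copy.deepcopy(toy_experiment)
        w = scaled.wells[0]
        w.od *= 3.7
        for lab in w.series:
            w.series[lab] = w.series[lab] * 3.7
        a = normalize_by_od(toy_experiment).wells[0]
        b = normalize_by_od(scaled).wells[0]
        for lab in LABELS:
            np.testing.assert_allclose(a.series[lab], b.series[lab])


class TestSmoothing:
    def test_constant_preserved(self):
        np.testing.assert_allclose(smooth_moving_average(np.full(4, 5.0)), 5.0)

    def test_endpoint_shrinking_window(self):
        np.testing.assert_allclose(smooth_moving_average(np.array([0.0, 3.0, 6.0])),
                                   [1.5, 3.0, 4.5])

    def test_linear_ramp_interior_unchanged(self):
        ramp = np.arange(5.0)
        out = smooth_moving_average(ramp)
        np.testing.assert_allclose(out[1:-1], ramp[1:-1])

    @pytest.mark.parametrize("window", [2, 21])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ParameterError):
            smooth_moving_average(np.zeros(18), window=window)


class TestBackgroundSubtraction:
    def test_constant_background_shifts_genes(self):
        wells = [
            make_well("w1", "promoter", gene="g",
                      series={lab: np.full(18, 10.0) for lab in LABELS}),
            make_well("w2", "promoterless",
                      series={lab: np.full(18, 4.0) for lab in LABELS}),
            make_well("w3", "empty"),
        ]
        out, noise = subtract_promoterless_background(make_experiment(wells))
        np.testing.assert_allclose(out.wells[0].series["0"], 6.0)
        assert noise.promoterless_sd == 0.0

    def test_gene_equal_to_background_becomes_zero(self):
        wells = [
            make_well("w1", "promoter", gene="g",
                      series={lab: np.full(18, 4.0) for lab in LABELS}),
            make_well("w2", "promoterless",
                      series={lab: np.full(18, 4.0) for lab in LABELS}),
            make_well("w3", "empty"),
        ]
        out, _ = subtract_promoterless_background(make_experiment(wells))
        np.testing.assert_allclose(out.wells[0].series["0"], 0.0)

    def test_pooled_mean_over_wells_and_treatments(self):
        """Per-time mean over (2 promoterless wells) x (4 treatments)."""
        rng = np.random.default_rng(0)
        pl1 = {lab: rng.uniform(0, 10, 18) for lab in LABELS}
        pl2 = {lab: rng.uniform(0, 10, 18) for lab in LABELS}
        wells = [
            make_well("w1", "promoter", gene="g",
                      series={lab: np.zeros(18) for lab in LABELS}),
            make_well("w2", "promoterless", series=pl1),
            make_well("w3", "promoterless", series=pl2),
            make_well("w4", "empty"),
        ]
        out, noise = subtract_promoterless_background(make_experiment(wells))
        expected = np.mean([pl1[lab] for lab in LABELS] + [pl2[lab] for lab in LABELS], axis=0)
        np.testing.assert_allclose(noise.promoterless_mean, expected)
        np.testing.assert_allclose(out.wells[0].series["10"], -expected)

    def test_no_promoterless_is_rejected(self):
        wells = [make_well("w1", "promoter", gene="g"), make_well("w2", "empty")]
        with pytest.raises((ConfigurationError, ValidationError)):
            subtract_promoterless_background(make_experiment(wells))


class TestBaselineAlignment:
    def test_four_treatment_offsets(self):
        per = {lab: np.full(18, v) for lab, v in zip(LABELS, [1.0, 2.0, 3.0, 4.0])}
        out = align_baseline(per)
        for lab in LABELS:
            assert out[lab][0] == pytest.approx(2.5)
        # offsets shift entire series
        np.testing.assert_allclose(out["0"], 2.5)

    def test_identical_series_unchanged(self):
        s = np.sin(np.arange(18.0))
        out = align_baseline({lab: s.copy() for lab in LABELS})
        for lab in LABELS:
            np.testing.assert_allclose(out[lab], s)

    def test_single_treatment_identity(self):
        s = np.arange(18.0) + 3
        out = align_baseline({"0": s.copy()})
        np.testing.assert_allclose(out["0"], s)


class TestNoiseFloor:
    def matrix(self, values):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        return ExpressionMatrix(genes=[f"g{i}" for i in range(values.shape[0])],
                                times=np.arange(values.shape[1], dtype=float),
                                values=values)

    def test_strict_threshold(self):
        noise = NoiseModel(promoterless_mean=np.zeros(4), promoterless_sd=1.0)
        out = apply_noise_floor(self.matrix([0.5, 1.9, 2.0, 3.0]), noise)
        np.testing.assert_allclose(out.values[0], [0.0, 0.0, 2.0, 3.0])

    def test_zero_sd_zeroes_only_negatives(self):
        noise = NoiseModel(promoterless_mean=np.zeros(4), promoterless_sd=0.0)
        out = apply_noise_floor(self.matrix([-1.0, 0.0, 0.5, 2.0]), noise)
        np.testing.assert_allclose(out.values[0], [0.0, 0.0, 0.5, 2.0])

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=18),
           st.floats(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_never_grows(self, values, sd):
        noise = NoiseModel(promoterless_mean=np.zeros(len(values)), promoterless_sd=sd)
        m = self.matrix(values)
        once = apply_noise_floor(m, noise)
        twice = apply_noise_floor(once, noise)
        np.testing.assert_array_equal(once.values, twice.values)
        assert np.all(np.abs(once.values) <= np.abs(m.values) + 1e-15)


class TestPipeline:
    def test_deterministic(self, toy_experiment):
        a = preprocess_pipeline(toy_experiment)
        b = preprocess_pipeline(toy_experiment)
        for lab in LABELS:
            np.testing.assert_array_equal(a.gene_matrices[lab].values,
                                          b.gene_matrices[lab].values)

    def test_t1_aligned_across_treatments(self, toy_experiment):
        pre = preprocess_pipeline(toy_experiment, floor_multiplier=0.0)
        first = {lab: pre.gene_matrices[lab].values[:, 0] for lab in LABELS}
        for lab in LABELS[1:]:
            np.testing.assert_allclose(first[lab], first["0"], atol=1e-12)

    def test_invertible_fixture_recovers_activity(self):
        """Zero noise, constant background, od=1: output = activity minus
        baseline shift (activity chosen smooth so smoothing is identity)."""
        activity = 5.0 + 0.25 * np.arange(18.0)      # linear: MA-invariant inside
        wells = [
            make_well("w1", "promoter", gene="g",
                      series={lab: activity + 2.0 for lab in LABELS}),
            make_well("w2", "promoterless",
                      series={lab: np.full(18, 2.0) for lab in LABELS}),
            make_well("w3", "empty"),
        ]
        pre = preprocess_pipeline(make_experiment(wells))
        out = pre.gene_matrices["0"].values[0]
        np.testing.assert_allclose(out[1:-1], activity[1:-1], atol=1e-10)

    def test_single_promoter_well_gives_1xT(self, toy_experiment):
        wells = [w for w in toy_experiment.wells if w.well_id != "w2"]
        pre = preprocess_pipeline(make_experiment(wells))
        assert pre.gene_matrices["0"].values.shape == (1, 18)

    def test_no_promoterless_fails(self):
        wells = [make_well("w1", "promoter", gene="g"), make_well("w2", "empty")]
        with pytest.raises((ConfigurationError, ValidationError)):
            preprocess_pipeline(make_experiment(wells))
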