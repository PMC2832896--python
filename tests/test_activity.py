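"""TF-activity inference: codec, objective, confidence band, determinism."""

import numpy as np
import pytest

from nlhvdm import (
    ActivityCodec,
    ExpressionDataset,
    GASettings,
    TFActivityEstimator,
    activity_confidence_band,
    relative_fit_error,
    training_objective,
)
from nlhvdm.errors import (
    InvalidConfigError,
    MissingProbeError,
    UndefinedNormalizationError,
)

TINY_GA = GASettings(population_size=16, generations=10)


class TestActivityCodec:
    def test_canonical_parameter_count(self):
        # 5 genes x 4 rates + 6 free activity knots = 26
        codec = ActivityCodec(5, np.arange(0.0, 13.0, 2.0))
        assert codec.n_parameters == 26

    def test_encode_decode_roundtrip(self):
        codec = ActivityCodec(3, np.arange(0.0, 13.0, 2.0))
        rng = np.random.default_rng(0)
        lb, ub = codec.bounds()
        v = rng.uniform(lb, ub)
        kin, knots = codec.decode(v)
        assert np.array_equal(codec.encode(kin, knots), v)

    def test_bounds_shapes(self):
        codec = ActivityCodec(5, np.arange(0.0, 13.0, 2.0))
        lb, ub = codec.bounds()
        assert lb.size == ub.size == 26
        assert np.all(ub > lb)


class TestTrainingObjective:
    def test_zero_at_truth(self, training_truth):
        codec = ActivityCodec(5, training_truth.dataset.times)
        kin = np.array([k.as_array() for k in training_truth.panel])
        v = codec.encode(kin, training_truth.profile.knot_values[1:])
        assert training_objective(v, training_truth.dataset) < 1e-6

    def test_hand_computed_relative_error(self):
        # c=k=d=0 freezes the simulation at x0=1, so u=(1,1) against x=(1,2):
        # eps = (0 + 1) / (1 + 4) = 0.2
        ds = ExpressionDataset(["g1"], [0.0, 1.0, 2.0], np.array([[1.0, 1.0, 2.0]]))
        codec = ActivityCodec(1, ds.times)
        v = np.zeros(codec.n_parameters)
        v[2] = 1.0  # K
        assert training_objective(v, ds) == pytest.approx(0.2, abs=1e-12)

    def test_out_of_bounds_clamped_with_warning(self, training_truth):
        codec = ActivityCodec(5, training_truth.dataset.times)
        v = np.full(codec.n_parameters, 99.0)
        with pytest.warns(UserWarning):
            val = training_objective(v, training_truth.dataset)
        assert np.isfinite(val)


class TestConfidenceBand:
    def test_identical_runs_collapse(self):
        runs = np.tile(np.linspace(0, 1, 7), (30, 1))
        mean, lo, hi = activity_confidence_band(runs)
        assert np.allclose(hi - lo, 0.0)

    def test_mean_of_spread_runs(self):
        runs = np.linspace(0.1, 1.0, 10)[:, None]
        mean, lo, hi = activity_confidence_band(runs)
        assert mean[0] == pytest.approx(0.55)
        assert lo[0] <= np.median(runs) <= hi[0]

    def test_single_run_warns(self):
        with pytest.warns(UserWarning):
            mean, lo, hi = activity_confidence_band(np.array([[0.2, 0.4]]))
        assert np.array_equal(mean, lo)


class TestRelativeFitError:
    def test_exact_match(self):
        p = np.array([0.1, 0.5, 1.0])
        assert relative_fit_error(p, p) == 0.0

    def test_doubled_estimate(self):
        p = np.array([0.2, 0.4, 0.8])
        assert relative_fit_error(2 * p, p) == pytest.approx(1.0)

    def test_hand_value(self):
        assert relative_fit_error(np.array([1.0, 0.0]), np.array([1.0, 1.0])) == pytest.approx(0.5)

    def test_zero_reference_rejected(self):
        with pytest.raises(UndefinedNormalizationError):
            relative_fit_error(np.array([1.0]), np.array([0.0]))


class TestEstimator:
    def test_determinism(self, training_truth):
        kw = dict(restarts=2, random_state=7, ga=TINY_GA)
        a = TFActivityEstimator(**kw).fit(training_truth.dataset)
        b = TFActivityEstimator(**kw).fit(training_truth.dataset)
        assert a.objective_ == b.objective_
        assert np.array_equal(a.profile_.knot_values, b.profile_.knot_values)
        assert np.array_equal(a.run_objectives_, b.run_objectives_)

    def test_best_run_selection_and_bounds(self, training_truth):
        est = TFActivityEstimator(restarts=3, random_state=1, ga=TINY_GA).fit(training_truth.dataset)
        assert est.objective_ == est.run_objectives_.min()
        assert len(est.run_objectives_) == 3
        for kin in est.kinetics_:
            c, k, K, d = kin.as_array()
            assert 0 <= c <= 5 and 0 <= k <= 5 and 0 < K <= 5 and 0 <= d <= 2
        assert np.all(est.profile_.knot_values >= 0)
        assert np.all(est.profile_.knot_values <= 1)

    def test_ga_history_non_increasing(self, training_truth):
        est = TFActivityEstimator(restarts=1, random_state=1, ga=TINY_GA).fit(training_truth.dataset)
        hist = est.ga_results_[0].history
        assert np.all(np.diff(hist) <= 0)

    def test_per_replicate_mode_run_count(self, pulse_profile):
        from nlhvdm import simulate_panel

        truth = simulate_panel(pulse_profile, 2, noise_sd=0.05, delay_choices=(0.0,),
                               well_conditioned=True, seed=5)
        est = TFActivityEstimator(restarts=2, random_state=1, ga=TINY_GA,
                                  mode="per-replicate").fit(truth.dataset)
        assert len(est.run_objectives_) == 2 * truth.dataset.n_replicates

    def test_missing_training_id(self, training_truth):
        with pytest.raises(MissingProbeError):
            TFActivityEstimator(restarts=1, ga=TINY_GA).fit(
                training_truth.dataset, training_ids=["NOPE"])

    def test_invalid_restarts(self, training_truth):
        with pytest.raises(InvalidConfigError):
            TFActivityEstimator(restarts=0).fit(training_truth.dataset)

    def test_sklearn_params_clone(self):
        from sklearn.base import clone

        est = TFActivityEstimator(restarts=3, random_state=9)
        cloned = clone(est)
        assert cloned.get_params()["restarts"] == 3
        assert cloned.get_params()["random_state"] == 9
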