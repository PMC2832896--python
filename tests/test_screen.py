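"""Per-gene screening: sign calling, consensus, probe collapsing, filters."""

import numpy as np
import pytest

from nlhvdm import (
    FitResult,
    GASettings,
    GeneKinetics,
    TFActivityProfile,
    apply_filters,
    collapse_probes,
    consensus_states,
    correlation_sign,
    fit_gene,
    simulate_panel,
    top_fraction,
)
from nlhvdm.errors import InvalidConfigError, InvalidInputError

SMALL_GA = GASettings(population_size=24, generations=30)


def _result(pid, error, sign_model=+1, sign_corr=+1, k=1.0):
    kin = GeneKinetics(c=1.0, k=k, K=1.0, d=1.0, delta=1 if sign_model > 0 else 0)
    return FitResult(probe_id=pid, kinetics=kin, error=error, used_delay=False,
                     run_errors=np.array([error]), sign_model=sign_model,
                     sign_correlation=sign_corr)


class TestCorrelationSign:
    def test_perfectly_correlated(self, pulse_profile):
        act = pulse_profile.value(pulse_profile.knot_times)
        assert correlation_sign(act, pulse_profile, pulse_profile.knot_times) == +1

    def test_anticorrelated(self, pulse_profile):
        act = pulse_profile.value(pulse_profile.knot_times)
        assert correlation_sign(1.0 - act, pulse_profile, pulse_profile.knot_times) == -1

    def test_hand_computed_negative_half(self):
        # activity (0.3, 0.1, 0.2) against probe (1, 2, 3): r = -0.5 -> -1
        prof = TFActivityProfile([0.0, 2.0, 4.0], [0.3, 0.1, 0.2], baseline_value=0.3)
        assert correlation_sign(np.array([1.0, 2.0, 3.0]), prof, np.array([0.0, 2.0, 4.0])) == -1

    def test_zero_variance_returns_zero(self, pulse_profile):
        with pytest.warns(UserWarning):
            s = correlation_sign(np.ones(7), pulse_profile, pulse_profile.knot_times)
        assert s == 0

    def test_too_few_points(self, pulse_profile):
        with pytest.raises(InvalidInputError):
            correlation_sign(np.array([1.0, 2.0]), pulse_profile, np.array([0.0, 2.0]))


class TestConsensus:
    def test_all_agree(self):
        results = [_result(f"p{i}", 0.1 * i) for i in range(4)]
        counts = consensus_states(results)
        assert counts == {"agree": 4, "disagree": 0, "undetermined": 0}
        assert all(r.consensus == "agree" for r in results)

    def test_disagree_and_undetermined(self):
        results = [_result("a", 0.1, +1, -1), _result("b", 0.2, +1, 0)]
        counts = consensus_states(results)
        assert counts["disagree"] == 1
        assert counts["undetermined"] == 1


class TestCollapseProbes:
    def test_smallest_error_kept(self):
        results = [_result("201476_S_AT", 0.2046), _result("201477_S_AT", 0.31)]
        mapping = {"201476_S_AT": "RRM1", "201477_S_AT": "RRM1"}
        kept = collapse_probes(results, mapping)
        assert len(kept) == 1 and kept[0].probe_id == "201476_S_AT"

    def test_single_probe_untouched(self):
        results = [_result("x", 0.5)]
        assert collapse_probes(results, {"x": "GENE"}) == results

    def test_tie_breaks_on_probe_id(self):
        results = [_result("b_probe", 0.3), _result("a_probe", 0.3)]
        kept = collapse_probes(results, {"a_probe": "G", "b_probe": "G"})
        assert kept[0].probe_id == "a_probe"

    def test_unmapped_pass_through(self):
        results = [_result("u1", 0.9)]
        assert collapse_probes(results, {})[0].probe_id == "u1"


class TestFiltersAndRanking:
    def test_small_k_filtered(self):
        results = [_result("weak", 0.1, k=0.0), _result("strong", 0.2, k=2.0)]
        report = apply_filters(results, k_min=0.05)
        assert [r.probe_id for r in report.ranked] == ["strong"]
        assert report.removed[0][1] == "small-k"

    def test_no_motif_filtered(self):
        results = [_result("m0", 0.1), _result("m2", 0.2)]
        report = apply_filters(results, k_min=0.0, require_motif=True,
                               motif_counts={"m0": 0, "m2": 2})
        assert [r.probe_id for r in report.ranked] == ["m2"]
        assert report.removed[0][1] == "no-motif"

    def test_identity_without_filters(self):
        results = [_result("a", 0.2), _result("b", 0.1)]
        report = apply_filters(results, k_min=0.0)
        assert [r.probe_id for r in report.ranked] == ["b", "a"]
        assert report.removed == []

    @pytest.mark.parametrize("n, fraction, expected", [(1312, 0.5, 656), (1312, 0.25, 328), (10, 1.0, 10)])
    def test_top_fraction_counts(self, n, fraction, expected):
        results = [_result(f"p{i:05d}", i / n) for i in range(n)]
        assert len(top_fraction(results, fraction)) == expected

    def test_top_fraction_permutation_invariant(self):
        rng = np.random.default_rng(1)
        results = [_result(f"p{i}", e) for i, e in enumerate(rng.uniform(size=20))]
        shuffled = list(results)
        rng.shuffle(shuffled)
        ids_a = [r.probe_id for r in top_fraction(results, 0.3)]
        ids_b = [r.probe_id for r in top_fraction(shuffled, 0.3)]
        assert ids_a == ids_b

    def test_bad_fraction(self):
        with pytest.raises(InvalidConfigError):
            top_fraction([], 0.0)


class TestFitGene:
    def test_inhibited_delayed_gene_recovery(self, pulse_profile):
        kin_true = GeneKinetics(c=2.0, k=3.0, K=0.4, d=0.8, tau=1.0, delta=0)
        from nlhvdm import simulate_gene

        times = np.arange(0.0, 13.0, 2.0)
        x0 = (kin_true.c + kin_true.k) / kin_true.d  # inhibited pre-stimulus steady state
        values = simulate_gene(kin_true, pulse_profile, x0, times).values
        res = fit_gene(values, times, pulse_profile, config=SMALL_GA,
                       restarts=4, seed=11, probe_id="inh")
        assert res.kinetics.delta == 0
        assert res.sign_model == -1
        assert abs(res.kinetics.tau - 1.0) <= 0.5
        assert res.used_delay

    def test_error_is_min_of_run_errors(self, pulse_profile):
        truth = simulate_panel(pulse_profile, 1, noise_sd=0.05, delay_choices=(0.0,),
                               well_conditioned=True, seed=2)
        res = fit_gene(truth.dataset.replicate_mean()[0], truth.dataset.times,
                       pulse_profile, config=SMALL_GA, restarts=3, seed=5)
        assert res.error == res.run_errors.min()
        assert len(res.run_errors) == 2 * 3  # two variants per restart

    def test_constant_probe_warns(self, pulse_profile):
        times = np.arange(0.0, 13.0, 2.0)
        with pytest.warns(UserWarning):
            res = fit_gene(np.ones(7), times, pulse_profile,
                           config=GASettings(population_size=8, generations=3),
                           restarts=1, seed=0)
        assert res.degenerate
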