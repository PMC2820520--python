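"""Open-loop gain, overshoot, response times, learning, induction range."""

import math

import numpy as np
import pytest

from tcsfeedback import (
    SPECIES,
    Trajectory,
    WILD_TYPE,
    count_sign_switches,
    feedback_response_ratio,
    flux_fraction,
    gain_scan,
    induction_range,
    learning_experiment,
    make_topology,
    open_loop_gain,
    overshoot,
    response_time,
    solve_steady_state,
)
from tcsfeedback.simulation import activation_run

from oracles import sensitivity_gain


class TestOpenLoopGain:
    def test_zero_without_regulated_transcription(self, neg_params):
        """With k_txn = 0 the exogenous regulator has nothing to act on."""
        g = open_loop_gain(neg_params.replace(k_txn=0.0))
        assert g.success
        assert g.sign == "zero-within-tolerance"
        assert abs(g.value) < 1e-4

    def test_printed_sets_have_published_signs(self, neg_params, pos_params):
        gn = open_loop_gain(neg_params)
        gp = open_loop_gain(pos_params)
        assert gn.success and gp.success
        assert gn.sign == "negative" and gn.value < 0
        assert gp.sign == "positive" and gp.value > 0

    @pytest.mark.parametrize("which", ["neg_params", "pos_params"])
    def test_central_difference_agrees_with_implicit_sensitivity(self, which, request):
        """Finite-difference gain vs linearized steady-state sensitivity."""
        p = request.getfixturevalue(which)
        rest = solve_steady_state(p, k_ph=10.0)
        closed = solve_steady_state(p, k_ph=0.1, initial_state=rest.state)
        g = open_loop_gain(p, closed_state=closed.state)
        oracle = sensitivity_gain(p, closed.state, k_ph=0.1)
        assert g.value == pytest.approx(oracle, rel=1e-3)


class TestFluxFraction:
    def test_zero_without_exogenous_phosphorylation(self, pos_params):
        fd = flux_fraction(pos_params.replace(k_exp=0.0))
        assert fd is not None
        assert fd.J_E == 0.0
        assert fd.fraction == 0.0

    def test_negative_example_dominated_by_exogenous_flux(self, neg_params):
        fd = flux_fraction(neg_params)
        assert fd.J_E > 0 and fd.J_S > 0
        assert fd.fraction > 1e-3

    def test_fraction_bounded(self, neg_params, pos_params):
        for p in (neg_params, pos_params):
            fd = flux_fraction(p)
            assert 0.0 <= fd.fraction <= 1.0


def _synthetic_trajectory(times, rrp2, mrna_ds):
    states = np.zeros((len(times), len(SPECIES)))
    states[:, SPECIES.index("RRP2")] = rrp2
    states[:, SPECIES.index("mRNA_ds")] = mrna_ds
    return Trajectory(times=np.asarray(times, float), states=states)


class TestOvershoot:
    times = np.linspace(0.0, 100.0, 201)

    def test_monotone_trajectory_has_no_overshoot(self):
        y = 1.0 - np.exp(-self.times / 10.0)
        traj = _synthetic_trajectory(self.times, y, y)
        ss = traj.states[-1]
        res = overshoot(traj, ss)
        assert not res.flag and res.magnitude <= 0.0 and res.valid

    def test_injected_peak_in_dimer_and_mrna(self):
        peak = 1.0 + 0.6 * np.exp(-((self.times - 20.0) / 5.0) ** 2)
        traj = _synthetic_trajectory(self.times, peak, peak)
        ss = traj.states[-1].copy()
        ss[SPECIES.index("RRP2")] = 1.0
        ss[SPECIES.index("mRNA_ds")] = 1.0
        res = overshoot(traj, ss)
        assert res.flag and res.valid
        assert res.magnitude == pytest.approx(0.60, abs=1e-6)
        assert res.peak_time == pytest.approx(20.0, abs=0.5)

    def test_dimer_peak_without_mrna_peak_is_excluded(self):
        """An RRP2-only overshoot is not a transcriptional-feedback
        signature and must not be flagged when mRNA confirmation is on."""
        peak = 1.0 + 0.6 * np.exp(-((self.times - 20.0) / 5.0) ** 2)
        mono = 1.0 - np.exp(-self.times / 10.0)
        traj = _synthetic_trajectory(self.times, peak, mono)
        ss = traj.states[-1].copy()
        ss[SPECIES.index("RRP2")] = 1.0
        res = overshoot(traj, ss)
        assert not res.flag
        assert overshoot(traj, ss, require_mrna_overshoot=False).flag

    def test_unsettled_trajectory_flagged_invalid(self):
        y = np.linspace(0.0, 0.5, len(self.times))  # still climbing
        traj = _synthetic_trajectory(self.times, y, y)
        ss = np.zeros(len(SPECIES))
        ss[SPECIES.index("RRP2")] = 1.0
        assert not overshoot(traj, ss).valid


class TestResponseTime:
    def test_zero_when_already_at_level(self):
        traj = _synthetic_trajectory([0.0, 1.0, 2.0], [0.7, 0.8, 1.0], [0, 0, 0])
        assert response_time(traj, "RRP2", 0.5, target=1.0) == 0.0

    def test_birth_death_half_rise_matches_closed_form(self):
        """x' = a - k x from 0 crosses half of a/k at ln2/k."""
        a, k = 3.0, 0.013
        t = np.linspace(0.0, 600.0, 4001)
        x = a / k * (1.0 - np.exp(-k * t))
        traj = _synthetic_trajectory(t, x, x)
        tau = response_time(traj, "RRP2", 0.5, target=a / k)
        assert tau == pytest.approx(math.log(2.0) / k, rel=1e-3)

    def test_unreachable_level_reported_unbounded(self):
        traj = _synthetic_trajectory([0.0, 1.0], [0.1, 0.2], [0, 0])
        assert response_time(traj, "RRP2", 0.95, target=1.0) == math.inf

    def test_negative_feedback_set_responds_faster(self, neg_params, pos_params):
        """tau95 of downstream protein elevation: the negative-feedback
        example beats the positive one under matched activation."""
        taus = {}
        for name, p in (("neg", neg_params), ("pos", pos_params)):
            traj, rest, act, settled = activation_run(p)
            assert settled
            i = SPECIES.index("DS")
            taus[name] = response_time(traj, "DS", 0.95,
                                       target=float(act[i]),
                                       baseline=float(rest[i]))
        assert 0.0 < taus["neg"] < taus["pos"]


class TestLearning:
    def test_full_relaxation_erases_memory(self, pos_params):
        res = learning_experiment(pos_params, interregnum=100.0 / pos_params.k_dil)
        assert res.ratio == pytest.approx(1.0, rel=0.01)
        assert abs(res.delta_shk_pct) < 1.0

    def test_positive_example_learns_after_45_min_interruption(self, pos_params):
        res = learning_experiment(pos_params, interregnum=2700.0)
        assert res.delta_shk_pct > 0.0     # protein memory persists
        assert res.delta_rr_pct > 0.0
        assert res.ratio > 1.0             # second response is faster

    def test_zero_interregnum_reports_unbounded_ratio(self, pos_params):
        res = learning_experiment(pos_params, interregnum=0.0)
        assert res.tau_second == 0.0
        assert res.ratio == math.inf


class TestInductionRange:
    def test_control_normalizes_to_one(self, neg_params):
        control = make_topology("no_feedback", neg_params)
        val = induction_range(neg_params, topology=control, control=control)
        assert val == pytest.approx(1.0)

    def test_wild_type_matches_direct_recomputation(self, neg_params):
        from tcsfeedback.feedback_metrics import _induction_difference

        control = make_topology("no_feedback", neg_params)
        val = induction_range(neg_params, control=control)
        direct = (_induction_difference(neg_params, WILD_TYPE)
                  / _induction_difference(neg_params, control))
        assert val == pytest.approx(direct, rel=1e-12)
        assert math.isfinite(val) and val > 0


class TestGainScan:
    def test_cells_match_pointwise_gain_calls(self, neg_params):
        grid = [0.05, 0.5]
        scan = gain_scan(neg_params, grid)
        for kph, val in zip(scan.k_ph, scan.gain):
            direct = open_loop_gain(neg_params, k_ph=kph)
            assert val == pytest.approx(direct.value, rel=1e-9)

    def test_negative_example_sign_reverses_in_signal_space(self, neg_params):
        """The effective feedback sign depends on the signal: scanning
        kinase activity alongside phosphatase activity uncovers both
        negative- and positive-gain regions for the same parameter set."""
        scan = gain_scan(neg_params, np.geomspace(1e-3, 10.0, 4),
                         k_ap_grid=np.geomspace(neg_params.k_ap, 100 * neg_params.k_ap, 4))
        ok = scan[scan.success]
        signs = set(ok.sign)
        assert "negative" in signs and "positive" in signs

    def test_no_negative_cells_without_exogenous_flux(self, pos_params):
        """Exogenous RR phosphorylation is the mechanism of effectively
        negative feedback; without it no grid cell is negative."""
        p = pos_params.replace(k_exp=0.0)
        scan = gain_scan(p, np.geomspace(1e-3, 10.0, 8))
        ok = scan[scan.success]
        assert len(ok) > 0
        assert not (ok.sign == "negative").any()


class TestFeedbackResponseRatio:
    def test_negative_set_speeds_positive_set_slows(self, neg_params, pos_params):
        """Relative to a matched no-feedback control, the negative
        example responds faster and the positive example slower."""
        rn = feedback_response_ratio(neg_params, baseline_from_rest=True)
        rp = feedback_response_ratio(pos_params, baseline_from_rest=True)
        assert rn < 1.0 < rp
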