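"""Feedback-sign and response-dynamics statistics.

The effective sign of the transcriptional feedback is measured by the
open-loop gain: the log-log sensitivity of steady-state RRP2 to an
exogenous regulator R0 that replaces RRP2 in the TCS-operon
transcription law, evaluated at R0 equal to the closed-loop steady-state
RRP2.  A negative gain means the autoregulatory loop effectively
attenuates activated-regulator levels (negative feedback) even though
the transcriptional interaction itself is activating.

The other statistics quantify the dynamical signatures associated with
the feedback sign: overshoot of RRP2 past its activated steady state,
response times (tau50/tau95), the "learning" speed-up of a second
response after a transient signal interruption, and the induction range
of the steady-state dose response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .reaction_network import (
    SPECIES,
    WILD_TYPE,
    CircuitTopology,
    KineticParameters,
    extended_fluxes,
    make_topology,
    rr_total,
    rrp_total,
    shk_total,
)
from .simulation import (
    ACTIVATED_K_PH,
    RESTING_K_PH,
    SignalProtocol,
    Trajectory,
    activation_run,
    integrate,
    solve_steady_state,
)

__all__ = [
    "GainResult",
    "FluxDecomposition",
    "OvershootResult",
    "LearningResult",
    "open_loop_gain",
    "flux_fraction",
    "overshoot",
    "response_time",
    "learning_experiment",
    "induction_range",
    "feedback_response_ratio",
    "gain_scan",
]

#: |gain| below this is classified as zero-within-tolerance
SIGN_TOLERANCE = 1e-4


@dataclass(frozen=True)
class GainResult:
    value: float
    k_ph: float
    k_ap: Optional[float]
    rel_step: float
    success: bool
    message: str = ""

    @property
    def sign(self) -> str:
        if not self.success:
            return "undefined"
        if abs(self.value) < SIGN_TOLERANCE:
            return "zero-within-tolerance"
        return "negative" if self.value < 0 else "positive"


@dataclass(frozen=True)
class FluxDecomposition:
    """Exogenous (J_E, reaction 19) vs SHK-mediated (J_S, reaction 16)
    phosphorylation flux at a named steady state."""

    J_E: float
    J_S: float
    condition: str = "activated"

    @property
    def fraction(self) -> float:
        total = self.J_E + self.J_S
        return self.J_E / total if total > 0 else 0.0


@dataclass(frozen=True)
class OvershootResult:
    flag: bool
    magnitude: float      # (peak - steady state) / steady state
    peak_time: float
    valid: bool = True    # False when the trajectory had not settled
    mrna_overshoot: bool = False


@dataclass(frozen=True)
class LearningResult:
    tau_first: float
    tau_second: float
    delta_shk_pct: float
    delta_rr_pct: float
    tau_first_ds: float = math.nan
    tau_second_ds: float = math.nan

    @property
    def ratio(self) -> float:
        """tau_first / tau_second; > 1 means the second response is faster.

        Unbounded (inf) when the second response starts at or above the
        threshold, e.g. for a vanishing interregnum.
        """
        if self.tau_second == 0.0:
            return math.inf
        return self.tau_first / self.tau_second


def _closed_loop_activated(params: KineticParameters, k_ph: float,
                           k_ap: Optional[float],
                           rest_state: Optional[np.ndarray] = None):
    """Resting steady state, then the activated one reached from it."""
    if rest_state is None:
        rest = solve_steady_state(params, WILD_TYPE, k_ph=RESTING_K_PH, k_ap=k_ap)
        if not rest.success:
            return None, None
        rest_state = rest.state
    act = solve_steady_state(params, WILD_TYPE, k_ph=k_ph, k_ap=k_ap,
                             initial_state=rest_state)
    if not act.success:
        return rest_state, None
    return rest_state, act.state


def open_loop_gain(params: KineticParameters,
                   k_ph: float = ACTIVATED_K_PH,
                   k_ap: Optional[float] = None,
                   rel_step: float = 0.01,
                   closed_state: Optional[np.ndarray] = None,
                   rest_state: Optional[np.ndarray] = None) -> GainResult:
    """Open-loop gain d ln(RRP2) / d ln(R0) at R0 = closed-loop RRP2.

    Computed by a central difference in log space: the open-loop steady
    state is solved at ``R0* exp(+-rel_step)``, starting each root find
    from the closed-loop fixed point.
    """
    if closed_state is None:
        _, closed_state = _closed_loop_activated(params, k_ph, k_ap, rest_state)
        if closed_state is None:
            return GainResult(math.nan, k_ph, k_ap, rel_step, False,
                              "closed-loop steady state not found")
    R0 = float(closed_state[SPECIES.index("RRP2")])
    if R0 <= 0.0:
        return GainResult(math.nan, k_ph, k_ap, rel_step, False,
                          "closed-loop RRP2 is zero; gain undefined")
    logs = []
    for s in (+1.0, -1.0):
        topo = CircuitTopology("open_loop", R0=R0 * math.exp(s * rel_step))
        ss = solve_steady_state(params, topo, k_ph=k_ph, k_ap=k_ap,
                                initial_state=closed_state, near=True)
        if not ss.success or ss.state[SPECIES.index("RRP2")] <= 0.0:
            return GainResult(math.nan, k_ph, k_ap, rel_step, False,
                              f"open-loop steady state failed at R0*exp({s:+.0f}h)")
        logs.append(math.log(ss.state[SPECIES.index("RRP2")]))
    return GainResult((logs[0] - logs[1]) / (2.0 * rel_step), k_ph, k_ap,
                      rel_step, True)


def flux_fraction(params: KineticParameters,
                  k_ph: float = ACTIVATED_K_PH,
                  k_ap: Optional[float] = None,
                  state: Optional[np.ndarray] = None,
                  rest_state: Optional[np.ndarray] = None) -> Optional[FluxDecomposition]:
    """J_E/(J_E+J_S) at the closed-loop activated steady state.

    Returns ``None`` if the steady state cannot be solved.
    """
    if state is None:
        _, state = _closed_loop_activated(params, k_ph, k_ap, rest_state)
        if state is None:
            return None
    v = extended_fluxes(state, params.with_signal(k_ph=k_ph, k_ap=k_ap), WILD_TYPE)
    return FluxDecomposition(J_E=float(v[26]), J_S=float(v[23]))


def response_time(trajectory: Trajectory,
                  observable: str,
                  level: float,
                  target: Optional[float] = None,
                  baseline: float = 0.0) -> float:
    """First time the observable crosses the ``level`` threshold (upward).

    The threshold is ``baseline + level * (target - baseline)``:
    ``level`` of the activated steady state for the default zero
    baseline (the survey convention, sensible when induction exceeds
    2-fold), or ``level`` of the resting-to-activated elevation when the
    resting value is passed as baseline (robust for weakly induced
    systems).  ``target`` defaults to the final value of the observable.
    Linear interpolation between grid points; ``inf`` when the level is
    never reached.
    """
    y = trajectory.observable(observable)
    thr = baseline + level * ((y[-1] if target is None else target) - baseline)
    if y[0] >= thr:
        return 0.0
    above = np.nonzero(y >= thr)[0]
    if above.size == 0:
        return math.inf
    i = int(above[0])
    t0, t1 = trajectory.times[i - 1], trajectory.times[i]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (thr - y0) * (t1 - t0) / (y1 - y0))


def overshoot(trajectory: Trajectory,
              activated_state: np.ndarray,
              threshold: float = 0.5,
              require_mrna_overshoot: bool = True,
              settle_rtol: float = 0.01,
              mrna_margin: float = 1e-3) -> OvershootResult:
    """Transient RRP2 peak more than ``threshold`` above the steady state.

    A peak counts only if (when required) the downstream mRNA also peaks
    above its steady state — an RRP2-only overshoot can arise from
    post-translational kinetics alone and is not a feedback signature.
    The result is flagged invalid unless the trajectory has settled to
    within ``settle_rtol`` of the activated steady state.
    """
    i_rrp2 = SPECIES.index("RRP2")
    i_mrna = SPECIES.index("mRNA_ds")
    ss = float(activated_state[i_rrp2])
    y = trajectory.observable("RRP2")
    if ss <= 0.0:
        return OvershootResult(False, math.nan, math.nan, valid=False)
    valid = abs(y[-1] - ss) <= settle_rtol * ss
    k = int(np.argmax(y))
    magnitude = (float(y[k]) - ss) / ss
    peak_time = float(trajectory.times[k])
    m = trajectory.observable("mRNA_ds")
    m_ss = float(activated_state[i_mrna])
    mrna_over = bool(np.max(m) > (1.0 + mrna_margin) * m_ss) if m_ss > 0 else False
    flag = magnitude > threshold and (mrna_over or not require_mrna_overshoot)
    return OvershootResult(flag=bool(flag), magnitude=magnitude,
                           peak_time=peak_time, valid=bool(valid),
                           mrna_overshoot=mrna_over)


def learning_experiment(params: KineticParameters,
                        topology: CircuitTopology = WILD_TYPE,
                        interregnum: float = 2700.0,
                        act_k_ph: float = ACTIVATED_K_PH,
                        rest_k_ph: float = RESTING_K_PH,
                        level: float = 0.5,
                        rest_state: Optional[np.ndarray] = None,
                        act_state: Optional[np.ndarray] = None,
                        first_trajectory: Optional[Trajectory] = None) -> LearningResult:
    """Signal-interruption ("learning") experiment.

    Activate from rest, run to the activated steady state, hold the
    resting signal for ``interregnum`` seconds, re-activate; tau50 of
    total phosphorylated RR (RRP_tot) is measured for both activations
    against the same activated-steady-state target.  Percent changes in
    total SHK and total RR over the episode quantify the accumulated
    protein that drives the speed-up.
    """
    if first_trajectory is None or rest_state is None or act_state is None:
        first_trajectory, rest_state, act_state, _ = activation_run(
            params, topology, act_k_ph=act_k_ph, rest_k_ph=rest_k_ph,
            rest_state=rest_state, act_state=act_state)
    target_rrp = float(rrp_total(act_state))
    target_ds = float(act_state[SPECIES.index("DS")])
    tau1 = response_time(first_trajectory, "RRP_tot", level, target=target_rrp)
    tau1_ds = response_time(first_trajectory, "DS", level, target=target_ds)

    if interregnum > 0.0:
        proto = SignalProtocol(((0.0, rest_k_ph, None),), initial_condition="given_state")
        inter = integrate(params, topology, proto, duration=interregnum,
                          initial_state=act_state, points_per_segment=120)
        start = inter.final_state
    else:
        start = act_state
    proto2 = SignalProtocol(((0.0, act_k_ph, None),), initial_condition="given_state")
    horizon = max(first_trajectory.times[-1], 20.0 / params.k_dil)
    second = integrate(params, topology, proto2, duration=horizon, initial_state=start)
    tau2 = response_time(second, "RRP_tot", level, target=target_rrp)
    tau2_ds = response_time(second, "DS", level, target=target_ds)

    shk0, shk1 = float(shk_total(rest_state)), float(shk_total(start))
    rr0, rr1 = float(rr_total(rest_state)), float(rr_total(start))
    return LearningResult(
        tau_first=tau1, tau_second=tau2,
        delta_shk_pct=100.0 * (shk1 - shk0) / shk0 if shk0 > 0 else math.nan,
        delta_rr_pct=100.0 * (rr1 - rr0) / rr0 if rr0 > 0 else math.nan,
        tau_first_ds=tau1_ds, tau_second_ds=tau2_ds)


def _induction_difference(params: KineticParameters, topology: CircuitTopology) -> Optional[float]:
    """RRP2 difference between the saturated (k_ph = 0) and basal
    (k_ph = 10) signal limits."""
    rest = solve_steady_state(params, topology, k_ph=RESTING_K_PH)
    if not rest.success:
        return None
    sat = solve_steady_state(params, topology, k_ph=0.0, initial_state=rest.state)
    if not sat.success:
        return None
    i = SPECIES.index("RRP2")
    return float(sat.state[i] - rest.state[i])


def induction_range(params: KineticParameters,
                    variant: str = "wild_type",
                    topology: Optional[CircuitTopology] = None,
                    control: Optional[CircuitTopology] = None) -> float:
    """Steady-state induction range, normalized to the no-feedback control.

    The range is RRP2 at the saturated signal limit (k_ph = 0) minus
    RRP2 at the basal limit (k_ph = 10), computed for the requested
    variant and divided by the same difference for a no-feedback control
    whose constitutive transcription is calibrated to the wild-type
    activated production rate.  Returns NaN when either limit fails to
    solve or the control range is zero.
    """
    if topology is None:
        topology = make_topology(variant, params)
    if control is None:
        control = make_topology("no_feedback", params)
    num = _induction_difference(params, topology)
    den = _induction_difference(params, control)
    if num is None or den is None or den == 0.0:
        return math.nan
    return num / den


def feedback_response_ratio(params: KineticParameters,
                            level: float = 0.95,
                            observable: str = "DS",
                            variant: str = "wild_type",
                            control: Optional[CircuitTopology] = None,
                            baseline_from_rest: bool = False,
                            **run_kwargs) -> float:
    """tau(feedback variant) / tau(no-feedback control) for downstream
    protein accumulation under matched activation.

    The control's constitutive TCS transcription equals the wild-type
    activated production rate, so both systems approach the same
    activated steady state; values < 1 mean the feedback speeds the
    response.  ``baseline_from_rest`` switches the crossing threshold
    from a fraction of the activated level to a fraction of the
    resting-to-activated elevation (each run against its own resting
    state).  NaN when either response time is undefined.
    """
    topology = make_topology(variant, params)
    if control is None:
        control = make_topology("no_feedback", params)
    taus = []
    for topo in (topology, control):
        traj, rest, act, settled = activation_run(params, topo, **run_kwargs)
        if not settled:
            return math.nan
        i = SPECIES.index(observable)
        base = float(rest[i]) if baseline_from_rest else 0.0
        taus.append(response_time(traj, observable, level,
                                  target=float(act[i]), baseline=base))
    if not all(math.isfinite(t) for t in taus) or taus[1] == 0.0:
        return math.nan
    return taus[0] / taus[1]


def gain_scan(params: KineticParameters,
              k_ph_grid: Sequence[float],
              k_ap_grid: Optional[Sequence[float]] = None,
              rel_step: float = 0.01) -> pd.DataFrame:
    """Open-loop gain over a signal grid (long-format table).

    Columns: k_ap, k_ph, gain, sign, success.  Per-point failures are
    recorded, not raised.  Resting and closed-loop steady states are
    re-used along the k_ph axis for speed; every cell equals an
    independent :func:`open_loop_gain` call at that condition.
    """
    k_ap_values = [None] if k_ap_grid is None else list(k_ap_grid)
    rows = []
    for kap in k_ap_values:
        rest = solve_steady_state(params, WILD_TYPE, k_ph=RESTING_K_PH, k_ap=kap)
        rest_state = rest.state if rest.success else None
        for kph in k_ph_grid:
            g = open_loop_gain(params, k_ph=float(kph), k_ap=kap,
                               rel_step=rel_step, rest_state=rest_state)
            rows.append({"k_ap": params.k_ap if kap is None else kap,
                         "k_ph": float(kph), "gain": g.value,
                         "sign": g.sign, "success": g.success})
    return pd.DataFrame(rows)


def count_sign_switches(scan: pd.DataFrame) -> int:
    """Number of feedback-sign reversals along the k_ph axis.

    For a multi-k_ap scan the maximum count over k_ap rows is returned.
    Zero-within-tolerance and failed cells are ignored.
    """
    best = 0
    for _, grp in scan.groupby("k_ap"):
        signs = [s for s in grp.sort_values("k_ph")["sign"]
                 if s in ("negative", "positive")]
        best = max(best, sum(a != b for a, b in zip(signs, signs[1:])))
    return best
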