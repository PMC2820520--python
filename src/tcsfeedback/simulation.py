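"""Steady states and signal-protocol time courses.

Signals enter the model through the SHK phosphatase rate ``k_ph``
(optionally also the kinase rate ``k_ap``).  The resting condition is a
high phosphatase activity (k_ph = 10/s); activation lowers it
(k_ph = 0.1/s).  Protocols are piecewise-constant schedules of these two
parameters.

Steady states are found by integrating toward equilibrium with a stiff
solver and polishing the endpoint with a damped Newton root find; a
candidate root is accepted only if its residual is tiny, it is
nonnegative (up to solver tolerance) and linearly stable.  This keeps
the result on the branch reachable from the supplied initial condition,
which matters for the few parameter sets where positive feedback could
support multiple equilibria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import ODEintWarning, odeint, solve_ivp
from scipy.optimize import root

from .reaction_network import (
    SPECIES,
    WILD_TYPE,
    CircuitTopology,
    KineticParameters,
    make_rhs,
    rr_total,
    rrp_total,
    shk_total,
)

__all__ = [
    "SteadyStateResult",
    "SignalProtocol",
    "Trajectory",
    "solve_steady_state",
    "integrate",
    "activation_protocol",
    "interruption_protocol",
    "settle_time",
]

RESTING_K_PH = 10.0
ACTIVATED_K_PH = 0.1


@dataclass(frozen=True)
class SteadyStateResult:
    state: np.ndarray
    residual: float
    success: bool
    message: str = ""

    def __iter__(self):  # allows ``state, residual = result``
        yield self.state
        yield self.residual


def _scaled_residual(f, y: np.ndarray) -> float:
    return float(np.linalg.norm(f(0.0, y)))


def _is_stable(jac, y: np.ndarray) -> bool:
    lam = np.linalg.eigvals(jac(0.0, y))
    radius = float(np.max(np.abs(lam))) if lam.size else 0.0
    return bool(np.max(lam.real) < 1e-12 + 1e-9 * radius)


def _try_polish(f, jac, y0: np.ndarray, tol_abs: float):
    sol = root(lambda y: f(0.0, y), y0, jac=lambda y: jac(0.0, y), method="hybr")
    y = sol.x
    scale = max(1.0, float(np.linalg.norm(y)))
    res = _scaled_residual(f, y)
    if res >= tol_abs * scale:
        return None
    if np.min(y) < -1e-9 * scale:
        return None
    if not _is_stable(jac, y):
        return None
    return np.where((y < 0) & (y > -1e-9 * scale), 0.0, y), res


def solve_steady_state(params: KineticParameters,
                       topology: CircuitTopology = WILD_TYPE,
                       k_ph: Optional[float] = None,
                       k_ap: Optional[float] = None,
                       initial_state: Optional[np.ndarray] = None,
                       near: bool = False,
                       tol: float = 1e-10,
                       max_chunks: int = 30) -> SteadyStateResult:
    """Stable steady state reached from ``initial_state`` (default: empty cell).

    ``near=True`` declares the initial state to be already close to the
    sought steady state (e.g. after a small parameter perturbation); the
    Newton polish is then attempted before any integration.
    The residual norm of the accepted state is below
    ``tol * max(1, ||state||)``.
    """
    if params.k_dil <= 0.0:
        raise ValueError("steady-state solving requires k_dil > 0")
    f, jac = make_rhs(params, topology, k_ph=k_ph, k_ap=k_ap)
    y = np.zeros(len(SPECIES)) if initial_state is None else np.asarray(initial_state, dtype=float).copy()

    if near and initial_state is not None:
        polished = _try_polish(f, jac, y, tol)
        if polished is not None:
            ref = max(1.0, float(np.linalg.norm(y)))
            if np.linalg.norm(polished[0] - y) <= 0.5 * ref:
                return SteadyStateResult(polished[0], polished[1], True, "polished from guess")

    T = 20.0 / params.k_dil
    prev = y.copy()
    for chunk in range(max_chunks):
        try:
            # coarse tolerance suffices here: the Newton polish below
            # restores full accuracy once the basin is reached; "excess
            # work" truncations are retried with a longer horizon
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ODEintWarning)
                ys = odeint(f, y, np.array([0.0, T]), Dfun=jac, tfirst=True,
                            rtol=1e-6, atol=1e-12, mxstep=100000)
        except Exception as exc:  # pragma: no cover - integrator blow-up
            return SteadyStateResult(y, np.inf, False, f"integration failed: {exc}")
        y = ys[-1]
        settled = np.allclose(y, prev, rtol=1e-7, atol=1e-13)
        polished = _try_polish(f, jac, y, tol)
        if polished is not None:
            ref = float(np.linalg.norm(y)) + 1e-12
            if settled or np.linalg.norm(polished[0] - y) <= 0.05 * ref + 1e-10:
                return SteadyStateResult(polished[0], polished[1], True, "integrated then polished")
        prev = y.copy()
        T *= 3.0
    res = _scaled_residual(f, y)
    ok = res < tol * max(1.0, float(np.linalg.norm(y)))
    return SteadyStateResult(y, res, ok, "integration only" if ok else "no convergence")


# ---------------------------------------------------------------------------
# protocols

@dataclass(frozen=True)
class SignalProtocol:
    """Piecewise-constant schedule of the signal parameters.

    ``segments`` is an ordered tuple of ``(start_time, k_ph, k_ap)``
    triples (``k_ap = None`` keeps the parameter-set value).  The first
    segment must start at time 0.  ``initial_condition`` selects whether
    integration starts from the resting steady state (computed at
    ``rest_k_ph``) or from a caller-supplied state.
    """

    segments: tuple
    initial_condition: str = "resting_steady_state"
    rest_k_ph: float = RESTING_K_PH

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        segs = tuple((float(t), float(kph), None if kap is None else float(kap))
                     for t, kph, kap in self.segments)
        object.__setattr__(self, "segments", segs)
        times = [s[0] for s in segs]
        if times[0] != 0.0:
            raise ValueError("first segment must start at t = 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if self.initial_condition not in ("resting_steady_state", "given_state"):
            raise ValueError(f"unknown initial condition {self.initial_condition!r}")


def activation_protocol(act_k_ph: float = ACTIVATED_K_PH,
                        rest_k_ph: float = RESTING_K_PH,
                        k_ap: Optional[float] = None) -> SignalProtocol:
    """Step the signal from rest to the activated level at t = 0."""
    return SignalProtocol(((0.0, act_k_ph, k_ap),), rest_k_ph=rest_k_ph)


@dataclass(frozen=True)
class Trajectory:
    """Time course on an output grid, one row of ``states`` per time."""

    times: np.ndarray
    states: np.ndarray
    protocol: Optional[SignalProtocol] = None
    parameter_set_id: Optional[str] = None

    _DERIVED = {"SHK_tot": shk_total, "RR_tot": rr_total, "RRP_tot": rrp_total}

    def observable(self, name: str) -> np.ndarray:
        """Series of a species or a derived total (SHK_tot/RR_tot/RRP_tot)."""
        if name in SPECIES:
            return self.states[:, SPECIES.index(name)]
        if name in self._DERIVED:
            return self._DERIVED[name](self.states)
        raise KeyError(f"unknown observable {name!r}")

    def to_frame(self):
        """Tidy table: a time column plus one column per species."""
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time", self.times)
        return df

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def _segment_grid(t0: float, t1: float, n: int) -> np.ndarray:
    span = t1 - t0
    dt0 = min(1.0, span * 1e-6)
    return np.concatenate(([t0], t0 + np.geomspace(dt0, span, n - 1)))


def integrate(params: KineticParameters,
              topology: CircuitTopology = WILD_TYPE,
              protocol: SignalProtocol = None,
              duration: float = None,
              initial_state: Optional[np.ndarray] = None,
              points_per_segment: int = 400,
              t_eval: Optional[Sequence[float]] = None,
              rtol: float = 1e-8,
              atol: float = 1e-12) -> Trajectory:
    """Integrate a signal protocol with a stiff solver (LSODA).

    Integration restarts at every segment boundary.  The default output
    grid is geometric within each segment, dense enough for
    interpolation-based response times; pass ``t_eval`` for an explicit
    grid.  Raises ``RuntimeError`` on integrator failure.
    """
    if protocol is None:
        protocol = activation_protocol()
    if duration is None:
        if params.k_dil <= 0.0:
            raise ValueError("give an explicit duration when k_dil = 0")
        duration = 20.0 / params.k_dil
    starts = [s[0] for s in protocol.segments]
    if duration <= starts[-1]:
        raise ValueError("duration must extend past the last segment start")

    if protocol.initial_condition == "resting_steady_state":
        ss = solve_steady_state(params, topology, k_ph=protocol.rest_k_ph)
        if not ss.success:
            raise RuntimeError("resting steady state not found for protocol start")
        y0 = ss.state
    else:
        if initial_state is None:
            raise ValueError("protocol demands a given initial state")
        y0 = np.asarray(initial_state, dtype=float)

    bounds = starts + [float(duration)]
    all_t, all_y = [], []
    y = y0
    for k, (_, kph, kap) in enumerate(protocol.segments):
        t0, t1 = bounds[k], bounds[k + 1]
        if t_eval is not None:
            te = np.asarray([t for t in t_eval if t0 <= t <= t1], dtype=float)
            grid = np.unique(np.concatenate(([t0], te, [t1])))
        else:
            grid = _segment_grid(t0, t1, points_per_segment)
        f, jac = make_rhs(params, topology, k_ph=kph, k_ap=kap)
        sol = solve_ivp(f, (t0, t1), y, method="LSODA", jac=jac,
                        t_eval=grid, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed in segment {k}: {sol.message}")
        y = sol.y[:, -1]
        all_t.append(sol.t)
        all_y.append(sol.y.T)
    times = np.concatenate(all_t)
    states = np.concatenate(all_y, axis=0)
    if t_eval is not None:
        keep = np.isin(times, np.asarray(t_eval, dtype=float))
        # segment boundaries are integrated either way; report the grid asked for
        times, states = times[keep], states[keep]
    scale = max(1.0, float(np.max(states)))
    if float(np.min(states)) < -1e-6 * scale:
        raise RuntimeError("integration produced negative concentrations "
                           "beyond tolerance")
    return Trajectory(times=times, states=np.maximum(states, 0.0), protocol=protocol)


def activation_run(params: KineticParameters,
                   topology: CircuitTopology = WILD_TYPE,
                   act_k_ph: float = ACTIVATED_K_PH,
                   rest_k_ph: float = RESTING_K_PH,
                   k_ap: Optional[float] = None,
                   settle_rtol: float = 0.01,
                   points_per_segment: int = 400,
                   rest_state: Optional[np.ndarray] = None,
                   act_state: Optional[np.ndarray] = None):
    """Simulate a step from the resting to the activated signal.

    Returns ``(trajectory, rest_state, act_state, settled)`` where the
    trajectory starts at the resting steady state, the signal switches at
    t = 0, and the horizon is extended until the trajectory ends within
    ``settle_rtol`` of the activated steady state (or a 320/k_dil cap is
    hit, reported via ``settled=False``).  Precomputed steady states may
    be passed in to avoid re-solving.
    """
    if rest_state is None:
        rest = solve_steady_state(params, topology, k_ph=rest_k_ph, k_ap=k_ap)
        if not rest.success:
            raise RuntimeError("resting steady state not found")
        rest_state = rest.state
    if act_state is None:
        act = solve_steady_state(params, topology, k_ph=act_k_ph, k_ap=k_ap,
                                 initial_state=rest_state)
        if not act.success:
            raise RuntimeError("activated steady state not found")
        act_state = act.state
    proto = SignalProtocol(((0.0, act_k_ph, k_ap),), initial_condition="given_state",
                           rest_k_ph=rest_k_ph)
    scale = float(np.max(np.abs(act_state))) + 1e-30
    horizon = 20.0 / params.k_dil
    settled = False
    while True:
        traj = integrate(params, topology, proto, duration=horizon,
                         initial_state=rest_state,
                         points_per_segment=points_per_segment)
        if np.max(np.abs(traj.final_state - act_state)) / scale < settle_rtol:
            settled = True
            break
        if horizon >= 320.0 / params.k_dil:
            break
        horizon *= 4.0
    return traj, rest_state, act_state, settled


def settle_time(params: KineticParameters,
                topology: CircuitTopology,
                k_ph: float,
                from_state: np.ndarray,
                target: Optional[np.ndarray] = None,
                rel_tol: float = 1e-3,
                max_horizon_dil: float = 200.0) -> float:
    """First time the trajectory comes within ``rel_tol`` of the steady state.

    Used to decide how long the first stimulus of the interruption
    protocol must last for the activated steady state to be attained.
    """
    if target is None:
        ss = solve_steady_state(params, topology, k_ph=k_ph, initial_state=from_state)
        if not ss.success:
            raise RuntimeError("steady state for settle detection not found")
        target = ss.state
    scale = float(np.max(np.abs(target))) + 1e-30
    horizon = 20.0 / params.k_dil
    while horizon <= max_horizon_dil / params.k_dil:
        traj = integrate(params, topology,
                         SignalProtocol(((0.0, k_ph, None),), initial_condition="given_state"),
                         duration=horizon, initial_state=from_state)
        dev = np.max(np.abs(traj.states - target), axis=1) / scale
        hit = np.nonzero(dev < rel_tol)[0]
        if hit.size:
            return float(traj.times[hit[0]])
        horizon *= 4.0
    raise RuntimeError("system did not settle within the allowed horizon")


def interruption_protocol(params: KineticParameters,
                          topology: CircuitTopology = WILD_TYPE,
                          interregnum: float = 2700.0,
                          act_k_ph: float = ACTIVATED_K_PH,
                          rest_k_ph: float = RESTING_K_PH) -> SignalProtocol:
    """Activate, hold until the activated steady state is attained, rest
    for ``interregnum`` seconds, then re-activate.

    The first-stimulus duration is found by settle detection rather than
    a fixed time, so the second response is measured against a genuine
    steady-state prior.  ``interregnum = 0`` degenerates to a plain
    activation protocol (the learning ratio is then unbounded and is
    reported as such by the metric layer).
    """
    rest = solve_steady_state(params, topology, k_ph=rest_k_ph)
    if not rest.success:
        raise RuntimeError("resting steady state not found")
    t_on = settle_time(params, topology, act_k_ph, rest.state)
    if interregnum <= 0.0:
        return SignalProtocol(((0.0, act_k_ph, None),), rest_k_ph=rest_k_ph)
    return SignalProtocol(
        ((0.0, act_k_ph, None),
         (t_on, rest_k_ph, None),
         (t_on + interregnum, act_k_ph, None)),
        rest_k_ph=rest_k_ph,
    )
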