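"""Monte Carlo parameter surveys and genetic-algorithm selection.

The sampler draws each kinetic parameter independently from a
log-uniform distribution.  Published sampling intervals for the model
are not available, so the default interval for each parameter spans
from a tenth of the smaller to ten times the larger of the two bundled
example values — guaranteeing that both published regimes (negative and
positive effective feedback) are interior points of the sampled space.

Sampled sets pass through a feasibility filter encoding physical
realizability and known characteristics of two-component systems:

1. mRNA below 100 copies/cell at every tested steady state;
2. mRNA degradation faster than protein dilution (k_mRNAdeg > k_dil);
3. basal transcription below the regulated maximum (k_txnbasal < k_txn);
4. sufficient induction of active regulator:
   [RRP2](k_ph=1e-3) - [RRP2](k_ph=10) > 1 molecule/cell;
5. low activity without signal: [RRP2](k_ph=10) <= 1 molecule/cell, with
   and without regulated transcription (k_txn = 0);
6. feedback-independent basal downstream expression: [DS](k_ph=10)
   differs < 10% with vs without regulated transcription;
7. [DS], [RRP2] and [RR_tot] each change more than 2-fold between
   k_ph = 10 and k_ph = 0.1.

Sets whose steady states cannot be solved are marked ``unsolvable``,
distinct from ``infeasible``; surveys log them rather than dropping
them silently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .feedback_metrics import (
    flux_fraction,
    induction_range,
    learning_experiment,
    open_loop_gain,
    overshoot,
    response_time,
)
from .interface_io import load_fixture
from .reaction_network import (
    SAMPLED_PARAMETERS,
    SPECIES,
    WILD_TYPE,
    KineticParameters,
    make_topology,
    rr_total,
)
from .simulation import activation_run, solve_steady_state

__all__ = [
    "SamplingIntervals",
    "default_intervals",
    "sample_parameter_set",
    "FeasibilityReport",
    "feasibility_filter",
    "run_survey",
    "SURVEY_METRICS",
    "FitnessCriteria",
    "ga_fitness",
    "ga_evolve",
    "GAResult",
]


@dataclass(frozen=True)
class SamplingIntervals:
    """Per-parameter (low, high) bounds for log-uniform sampling."""

    bounds: dict

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if name not in SAMPLED_PARAMETERS:
                raise KeyError(f"{name!r} is not a sampled parameter")
            if not (0.0 < lo <= hi):
                raise ValueError(f"interval for {name} must satisfy 0 < low <= high, "
                                 f"got ({lo}, {hi})")

    def sample(self, rng: np.random.Generator) -> dict:
        out = {}
        for name, (lo, hi) in self.bounds.items():
            u = rng.uniform(math.log(lo), math.log(hi))
            out[name] = math.exp(u)
        return out


def default_intervals(spread: float = 10.0) -> SamplingIntervals:
    """Intervals spanning ``spread``-fold beyond the two example sets."""
    neg = load_fixture("negative_example")
    pos = load_fixture("positive_example")
    bounds = {}
    for name in SAMPLED_PARAMETERS:
        a, b = getattr(neg, name), getattr(pos, name)
        bounds[name] = (min(a, b) / spread, max(a, b) * spread)
    return SamplingIntervals(bounds)


def sample_parameter_set(intervals: SamplingIntervals,
                         rng: np.random.Generator,
                         base: Optional[KineticParameters] = None) -> KineticParameters:
    """Draw one parameter set; unsampled constants come from ``base``."""
    if base is None:
        base = load_fixture("negative_example")
    return base.replace(**intervals.sample(rng))


# ---------------------------------------------------------------------------
# feasibility

_CRITERIA = tuple(f"crit{i}" for i in range(1, 8))


@dataclass
class FeasibilityReport:
    status: str                      # feasible | infeasible | unsolvable
    criteria: dict                   # crit1..crit7 -> True/False/None
    states: dict = field(default_factory=dict)   # cached steady states
    note: str = ""

    @property
    def feasible(self) -> bool:
        return self.status == "feasible"


def feasibility_filter(params: KineticParameters,
                       evaluate_all: bool = False) -> FeasibilityReport:
    """Apply the seven feasibility criteria (see module docstring).

    With ``evaluate_all=False`` (the survey default) evaluation stops at
    the first failed criterion and the remaining entries stay ``None``.
    Solved steady states are cached on the report for re-use:
    ``rest`` (k_ph=10), ``act`` (k_ph=0.1), ``low`` (k_ph=1e-3) and
    ``rest_unregulated`` (k_ph=10, k_txn=0).
    """
    crit = {c: None for c in _CRITERIA}
    states: dict = {}
    one_mc = 1.0 / params.molecules_per_conc_unit
    mrna_cap = 100.0 / params.molecules_per_conc_unit
    i_rrp2, i_ds = SPECIES.index("RRP2"), SPECIES.index("DS")

    def finish(status, note=""):
        return FeasibilityReport(status=status, criteria=crit, states=states, note=note)

    crit["crit3"] = bool(params.k_txnbasal < params.k_txn)
    if not crit["crit3"] and not evaluate_all:
        return finish("infeasible", "basal transcription not below regulated maximum")
    crit["crit2"] = bool(params.k_mRNAdeg > params.k_dil)
    if not crit["crit2"] and not evaluate_all:
        return finish("infeasible", "mRNA decay not faster than dilution")

    def solve(key, p, k_ph, init):
        ss = solve_steady_state(p, WILD_TYPE, k_ph=k_ph, initial_state=init)
        if not ss.success:
            return None
        states[key] = ss.state
        return ss.state

    rest = solve("rest", params, 10.0, None)
    if rest is None:
        return finish("unsolvable", "resting steady state failed")

    crit5a = bool(rest[i_rrp2] <= one_mc)
    if not crit5a and not evaluate_all:
        crit["crit5"] = False
        return finish("infeasible", "resting RRP2 above 1 molecule/cell")

    act = solve("act", params, 0.1, rest)
    if act is None:
        return finish("unsolvable", "activated steady state failed")

    def fold(a, b):
        if b == 0.0:
            return math.inf if a > 0 else 0.0
        return a / b

    folds = (fold(act[i_ds], rest[i_ds]),
             fold(act[i_rrp2], rest[i_rrp2]),
             fold(rr_total(act), rr_total(rest)))
    crit["crit7"] = bool(all(f > 2.0 for f in folds))
    if not crit["crit7"] and not evaluate_all:
        return finish("infeasible", "less than 2-fold induction of DS/RRP2/RR_tot")

    rest_un = solve("rest_unregulated", params.replace(k_txn=0.0), 10.0, None)
    if rest_un is None:
        return finish("unsolvable", "unregulated resting steady state failed")

    crit["crit5"] = bool(crit5a and rest_un[i_rrp2] <= one_mc)
    if not crit["crit5"] and not evaluate_all:
        return finish("infeasible", "resting RRP2 above 1 molecule/cell")
    ref = max(rest[i_ds], rest_un[i_ds])
    crit["crit6"] = bool((ref == 0.0) or (abs(rest[i_ds] - rest_un[i_ds]) / ref < 0.10))
    if not crit["crit6"] and not evaluate_all:
        return finish("infeasible", "basal downstream expression feedback-dependent")

    low = solve("low", params, 1e-3, act)
    if low is None:
        return finish("unsolvable", "saturating-signal steady state failed")
    crit["crit4"] = bool((low[i_rrp2] - rest[i_rrp2]) > one_mc)
    if not crit["crit4"] and not evaluate_all:
        return finish("infeasible", "induction below 1 molecule/cell")

    crit["crit1"] = bool(all(max(s[0], s[1]) < mrna_cap for s in states.values()))
    if not crit["crit1"] and not evaluate_all:
        return finish("infeasible", "mRNA above 100 copies/cell")

    ok = all(bool(v) for v in crit.values())
    return finish("feasible" if ok else "infeasible")


# ---------------------------------------------------------------------------
# surveys

SURVEY_METRICS = ("gain", "flux_fraction", "overshoot", "response_times",
                  "learning", "induction_range", "circuits")


def _metric_columns(metrics) -> list:
    cols = []
    if "gain" in metrics:
        cols += ["gain", "gain_sign"]
    if "flux_fraction" in metrics:
        cols += ["J_E", "J_S", "flux_fraction"]
    if "overshoot" in metrics:
        cols += ["overshoot_flag", "overshoot_magnitude", "overshoot_peak_time",
                 "overshoot_valid", "mrna_overshoot"]
    if "response_times" in metrics:
        cols += ["tau50_ds", "tau95_ds", "tau95_ratio"]
    if "learning" in metrics:
        cols += ["learning_tau_first", "learning_tau_second", "learning_ratio",
                 "learning_tau_first_ds", "learning_tau_second_ds",
                 "learning_ratio_ds", "delta_shk_pct", "delta_rr_pct"]
    if "induction_range" in metrics:
        cols += ["induction_range_wt"]
    if "circuits" in metrics:
        cols += ["circuit_I_tau95_ratio", "circuit_II_induction_range"]
    return cols


def _analyze(params: KineticParameters, report: FeasibilityReport, metrics) -> dict:
    """Metrics for one feasible set, re-using the filter's steady states.

    Every value equals what the corresponding public metric function
    returns when called directly on ``params``; the cached states only
    skip redundant root finds.
    """
    out: dict = {}
    rest, act = report.states.get("rest"), report.states.get("act")
    traj = None

    if "gain" in metrics:
        g = open_loop_gain(params, closed_state=act, rest_state=rest)
        out["gain"], out["gain_sign"] = g.value, g.sign
    if "flux_fraction" in metrics:
        fd = flux_fraction(params, state=act)
        if fd is not None:
            out["J_E"], out["J_S"], out["flux_fraction"] = fd.J_E, fd.J_S, fd.fraction
    needs_traj = {"overshoot", "learning"} & set(metrics)
    if needs_traj:
        traj, rest, act, settled = activation_run(params, rest_state=rest, act_state=act)
    if "overshoot" in metrics:
        ov = overshoot(traj, act)
        out.update(overshoot_flag=ov.flag, overshoot_magnitude=ov.magnitude,
                   overshoot_peak_time=ov.peak_time, overshoot_valid=ov.valid,
                   mrna_overshoot=ov.mrna_overshoot)
    needs_control = {"response_times", "circuits"} & set(metrics)
    if needs_control:
        if traj is None:
            traj, rest, act, _ = activation_run(params, rest_state=rest, act_state=act)
        control = make_topology("no_feedback", params, rest_state=rest,
                                calibration_state=act)

        def tau95(topology):
            tr, _, ta, settled = activation_run(params, topology)
            if not settled:
                return math.nan
            return response_time(tr, "DS", 0.95, target=float(ta[SPECIES.index("DS")]))

        tau95_nf = tau95(control)
    if "response_times" in metrics:
        target = float(act[SPECIES.index("DS")])
        out["tau50_ds"] = response_time(traj, "DS", 0.50, target=target)
        out["tau95_ds"] = response_time(traj, "DS", 0.95, target=target)
        tau95_wt = out["tau95_ds"]
        out["tau95_ratio"] = (tau95_wt / tau95_nf
                              if math.isfinite(tau95_nf) and tau95_nf > 0
                              and math.isfinite(tau95_wt) else math.nan)
    if "learning" in metrics:
        lr = learning_experiment(params, rest_state=rest, act_state=act,
                                 first_trajectory=traj)
        ratio_ds = (math.inf if lr.tau_second_ds == 0.0
                    else lr.tau_first_ds / lr.tau_second_ds)
        out.update(learning_tau_first=lr.tau_first, learning_tau_second=lr.tau_second,
                   learning_ratio=lr.ratio,
                   learning_tau_first_ds=lr.tau_first_ds,
                   learning_tau_second_ds=lr.tau_second_ds,
                   learning_ratio_ds=ratio_ds,
                   delta_shk_pct=lr.delta_shk_pct, delta_rr_pct=lr.delta_rr_pct)
    if "induction_range" in metrics:
        ctrl = (control if needs_control else
                make_topology("no_feedback", params, rest_state=rest,
                              calibration_state=act))
        out["induction_range_wt"] = induction_range(params, control=ctrl)
    if "circuits" in metrics:
        ci = make_topology("circuit_I", params, rest_state=rest,
                           calibration_state=act)
        cii = make_topology("circuit_II", params, rest_state=rest,
                            calibration_state=act)
        tau95_ci = tau95(ci)
        out["circuit_I_tau95_ratio"] = (tau95_ci / tau95_nf
                                        if math.isfinite(tau95_nf) and tau95_nf > 0
                                        and math.isfinite(tau95_ci) else math.nan)
        out["circuit_II_induction_range"] = induction_range(
            params, variant="circuit_II", topology=cii, control=control)
    return out


def run_survey(n_sets: int,
               intervals: Optional[SamplingIntervals] = None,
               seed: int = 0,
               metrics: Sequence[str] = ("gain", "flux_fraction", "overshoot"),
               base: Optional[KineticParameters] = None,
               max_attempts: Optional[int] = None,
               keep_rejected: bool = True,
               progress: Optional[Callable[[int, int], None]] = None) -> pd.DataFrame:
    """Sample until ``n_sets`` feasible parameter sets are analyzed.

    Returns one row per *attempt* (``keep_rejected=False`` keeps only
    feasible rows): the sampled parameters, the feasibility verdict with
    per-criterion outcomes, and the requested metrics for feasible sets.
    Fully reproducible from ``seed``.
    """
    unknown = set(metrics) - set(SURVEY_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}; pick from {SURVEY_METRICS}")
    if intervals is None:
        intervals = default_intervals()
    if base is None:
        base = load_fixture("negative_example")
    if max_attempts is None:
        max_attempts = max(2000, 500 * n_sets)
    rng = np.random.default_rng(seed)

    rows = []
    n_feasible = 0
    attempt = 0
    while n_feasible < n_sets and attempt < max_attempts:
        params = sample_parameter_set(intervals, rng, base=base)
        attempt += 1
        row = {"set_id": f"mc{attempt:06d}", "attempt": attempt}
        row.update({k: getattr(params, k) for k in SAMPLED_PARAMETERS})
        report = feasibility_filter(params)
        row["status"] = report.status
        row["note"] = report.note
        row.update(report.criteria)
        if report.feasible:
            try:
                row.update(_analyze(params, report, metrics))
            except RuntimeError as exc:
                row["status"] = "unsolvable"
                row["note"] = f"metric computation failed: {exc}"
            else:
                n_feasible += 1
                if progress is not None:
                    progress(n_feasible, n_sets)
        if keep_rejected or row["status"] == "feasible":
            rows.append(row)
    if n_feasible < n_sets:
        warnings.warn(f"attempt cap {max_attempts} reached with only "
                      f"{n_feasible}/{n_sets} feasible sets; returning partial table")
    columns = (["set_id", "attempt"] + list(SAMPLED_PARAMETERS)
               + ["status", "note"] + list(_CRITERIA) + _metric_columns(metrics))
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# genetic algorithm

@dataclass(frozen=True)
class FitnessCriteria:
    """Fold-change targets for PhoPQ-like behavior after activation.

    f1: RRP2 induction (activated / resting steady state);
    f2: total-RR induction; f3: peak RRP2 over the activated steady
    state (overshoot).  Each contributes ``min(fold / threshold, 1)``
    and the fitness is their product, saturating at 1 when all targets
    are met.
    """

    f1_threshold: float = 2.0
    f2_threshold: float = 2.0
    f3_threshold: float = 2.0

    def __post_init__(self) -> None:
        for name in ("f1_threshold", "f2_threshold", "f3_threshold"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be > 1")


def ga_fitness(params: KineticParameters,
               criteria: FitnessCriteria = FitnessCriteria(),
               check_feasibility: bool = True) -> float:
    """Saturating-product fitness for the three induction criteria.

    Infeasible (when ``check_feasibility``) or unsolvable sets score 0.
    """
    if check_feasibility:
        report = feasibility_filter(params)
        if not report.feasible:
            return 0.0
        rest, act = report.states["rest"], report.states["act"]
    else:
        rest = act = None
    try:
        traj, rest, act, _ = activation_run(params, rest_state=rest, act_state=act)
    except RuntimeError:
        return 0.0
    i = SPECIES.index("RRP2")
    if rest[i] <= 0.0 or act[i] <= 0.0 or rr_total(rest) <= 0.0:
        return 0.0
    f1 = act[i] / rest[i]
    f2 = rr_total(act) / rr_total(rest)
    f3 = float(np.max(traj.observable("RRP2"))) / act[i]
    score = 1.0
    for fold, thr in ((f1, criteria.f1_threshold),
                      (f2, criteria.f2_threshold),
                      (f3, criteria.f3_threshold)):
        score *= min(fold / thr, 1.0)
    return float(score)


@dataclass
class GAResult:
    best_params: KineticParameters
    best_fitness: float
    history: list           # per-generation best fitness
    population: list        # final population


def _perturb(params: KineticParameters, sigma: float,
             rng: np.random.Generator) -> KineticParameters:
    vec = params.sampled_vector()
    return params.with_sampled_vector(vec * np.exp(rng.normal(0.0, sigma, vec.size)))


def ga_evolve(seed_population: Sequence[KineticParameters],
              generations: int = 50,
              fitness_fn: Optional[Callable[[KineticParameters], float]] = None,
              sigma: float = 0.2,
              select_frac: float = 0.2,
              n_elite: int = 1,
              pop_size: Optional[int] = None,
              seed: int = 0,
              rng: Optional[np.random.Generator] = None) -> GAResult:
    """Evolve parameter sets by multiplicative log-normal mutation and
    truncation selection with elitism.

    Each generation mutates every sampled parameter by a factor
    ``exp(N(0, sigma))``, keeps the ``n_elite`` best unchanged, and
    refills the population from the top ``select_frac`` fraction.  With
    elitism and a deterministic fitness the best-so-far fitness is
    non-decreasing.  A generation in which every candidate scores
    exactly 0 is re-seeded from the initial population with a doubled
    mutation scale.
    """
    if not seed_population:
        raise ValueError("seed population must be non-empty")
    if fitness_fn is None:
        fitness_fn = ga_fitness
    if rng is None:
        rng = np.random.default_rng(seed)
    if pop_size is None:
        pop_size = max(len(seed_population), 50)

    seeds = list(seed_population)
    pop = list(seeds)
    while len(pop) < pop_size:
        pop.append(_perturb(seeds[len(pop) % len(seeds)], sigma, rng))
    pop = pop[:pop_size]

    cache: dict = {}

    def fit(p: KineticParameters) -> float:
        key = tuple(p.sampled_vector())
        if key not in cache:
            cache[key] = fitness_fn(p)
        return cache[key]

    history = []
    scored = sorted(pop, key=fit, reverse=True)
    best, best_f = scored[0], fit(scored[0])
    for _ in range(generations):
        if all(fit(p) == 0.0 for p in pop):
            pop = [_perturb(seeds[rng.integers(len(seeds))], 2.0 * sigma, rng)
                   for _ in range(pop_size)]
            history.append(best_f)
            continue
        scored = sorted(pop, key=fit, reverse=True)
        if fit(scored[0]) > best_f:
            best, best_f = scored[0], fit(scored[0])
        n_parents = max(1, int(math.ceil(select_frac * pop_size)))
        parents = scored[:n_parents]
        next_pop = list(scored[:n_elite])
        while len(next_pop) < pop_size:
            next_pop.append(_perturb(parents[rng.integers(len(parents))], sigma, rng))
        pop = next_pop
        history.append(best_f)
    scored = sorted(pop, key=fit, reverse=True)
    if fit(scored[0]) > best_f:
        best, best_f = scored[0], fit(scored[0])
    return GAResult(best_params=best, best_fitness=best_f, history=history,
                    population=pop)
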