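# Methods

## The model

`tcsfeedback` implements a deterministic mass-action model of a
bacterial two-component signaling system (TCS) whose sensor histidine
kinase (SHK) and response regulator (RR) are expressed from a single
operon activated by the phosphorylated-RR dimer (RRP2) — the common
autoregulated TCS architecture (PhoPQ, PhoBR, CpxRA, ...).  Ten species
(two transcripts, SHK/SHKP, RR/RRP, the two enzyme–substrate complexes,
the dimer, and a downstream reporter protein DS) interact through 22
reactions: regulated and basal transcription of the TCS and downstream
operons, translation, first-order mRNA decay, growth dilution of all
proteins, SHK autophosphorylation/autodephosphorylation, reversible
binding of SHKP to RR and of SHK to RRP, phosphotransfer within the
bound complex, phosphatase catalysis on the SHK·RRP complex, an
SHK-independent (exogenous) Michaelis–Menten
phosphorylation/dephosphorylation route for free RR/RRP, and
dimerization of RRP.

The signal is the SHK phosphatase rate `k_ph` (high = resting, low =
activated; 10/s and 0.1/s by convention), optionally combined with the
kinase rate `k_ap`.  Regulated transcription follows a saturating
activation law `k_txn·[A]/(K + [A])` with Hill coefficient 1, because
the dimerization step already supplies the cooperativity; the activator
A is RRP2, or an exogenous regulator R0 in the open-loop variant.  Both
operons share `k_txn` and `k_txnbasal`; the downstream operon has its
own Michaelis constant `K_mDS`.  RR is translated `tsn_mult`-fold faster
than SHK from the shared transcript.  Auto(de)phosphorylation acts on
free SHK/SHKP only, and mRNA loss is lumped into `k_mRNAdeg` with no
separate mRNA dilution term.

The binding/dissociation constants are indexed by pathway: the unprimed
pair (`k_b`, `k_d`) forms and dissolves the kinase-pathway complex
SHKP·RR, the primed pair (`k_b1`, `k_d1`) the phosphatase-pathway
complex SHK·RRP.  This assignment is the one under which the two bundled
example parameter sets reproduce their documented feedback signs; the
opposite pairing makes both sets weakly positive.

Units are µM and seconds throughout; `molecules_per_conc_unit`
(default 1000 molecules/cell per µM, a ~1.7 fL cell) is used only to
express molecule-per-cell feasibility thresholds as concentrations.

## Feedback sign and the open-loop gain

The wiring diagram suggests pure positive autoregulation, but the
*effective* sign of the loop depends on post-translational kinetics: the
bifunctional SHK both creates and destroys RRP.  The package measures
the sign as the open-loop gain — the log-log derivative
`d ln(RRP2)/d ln(R0)` of the open-loop system (R0 replacing RRP2 in the
TCS-operon transcription law only), evaluated at R0 equal to the
closed-loop steady-state RRP2, where the open-loop fixed point coincides
with the closed-loop state.  It is computed by a central difference with
a 1% multiplicative step; |gain| < 1e-4 is reported as
zero-within-tolerance.  A negative gain requires an SHK-independent
phosphorylation flux (J_E, the exogenous route): without it, SHK-paired
kinase and phosphatase capacities scale together and the loop cannot
attenuate.  Tests cross-check the central difference against an
implicit-differentiation sensitivity oracle built on a finite-difference
Jacobian.

## Steady states and integration

Steady states are found by stiff integration (LSODA, analytic Jacobian)
toward equilibrium followed by a Newton polish, accepted only when the
residual is below `1e-10·max(1, ‖x‖)`, the state is nonnegative up to
solver tolerance, and the Jacobian eigenvalues indicate linear
stability.  Integration-first keeps the result on the branch reachable
from the supplied initial condition, which matters in principle for
positive-feedback parameter sets.  When a caller declares its initial
guess near the target (small parameter perturbations, calibrations), the
polish runs first and falls back to integration.  Time courses use
LSODA with `rtol 1e-8`, `atol 1e-12`, restart at every
signal-protocol segment boundary, and a geometric output grid dense
enough for interpolation-based response times; a refinement test checks
checkpoints against a 10× tighter tolerance.

## Response metrics

* **Response time** τ_50/τ_95: first upward crossing, linearly
  interpolated, of 50%/95% of the activated steady state of the chosen
  observable.  For surveys this absolute convention is well posed
  because feasibility demands >2-fold induction; for weakly induced
  systems (including the bundled examples under the package's dilution
  constant) an elevation convention is available in which the threshold
  is a fraction of the resting→activated rise.
* **Overshoot**: a transient RRP2 peak more than 50% above the activated
  steady state, counted only when the downstream mRNA also peaks above
  its steady state (an RRP2-only overshoot can arise post-translationally
  and is not a feedback signature), and only when the trajectory has
  settled to within 1% of the steady state.
* **Learning**: activate from rest until the activated steady state is
  attained (settle detection rather than a fixed stimulus length, so the
  second response is measured against a true steady-state prior), hold
  the resting signal for 45 min, re-activate.  τ_50 of total
  phosphorylated RR (RRP_tot = RRP + SHK·RRP + 2·RRP2) is measured for
  both activations against the same target; the ratio τ_first/τ_second
  (>1 = faster second response) is related to the percent change of
  total SHK over the episode.  Downstream-protein response times are
  also recorded, but DS decays so slowly that it rarely re-crosses its
  threshold — RRP_tot is the informative observable.
* **Induction range**: steady-state RRP2 at the saturated signal limit
  (k_ph = 0 exactly, phosphatase off) minus RRP2 at the basal limit
  (k_ph = 10), normalized by the same difference in a no-feedback
  control.
* **Circuit variants**: `open_loop` (R0 replaces RRP2), `no_feedback`
  (constitutive TCS transcription), `circuit_I` (SHK constitutive,
  feedback to RR alone) and `circuit_II` (RR constitutive, feedback to
  SHK alone).  Constitutive rates are calibrated to the wild-type
  production fluxes at the activated steady state (k_ph = 0.1/s), which
  makes the no-feedback control's activated state coincide with the
  wild-type one (verified as a fixed-point test).

## The synthetic population

No deposited data exist for this model; the study population is
generated by the package itself.  Each of the 21 kinetic parameters is
drawn log-uniformly; because the original sampling intervals are not
published, the default interval per parameter spans from a tenth of the
smaller to ten times the larger of the two bundled example values, so
both documented regimes are interior points.  Sampled sets must pass
seven feasibility criteria (mRNA < 100 copies/cell; mRNA decay faster
than dilution; basal below regulated transcription; > 1 molecule/cell of
RRP2 induction; ≤ 1 molecule/cell resting RRP2 with and without
regulated transcription; < 10% feedback dependence of basal downstream
expression; > 2-fold induction of DS, RRP2 and RR_tot).  About 1% of
draws pass; surveys record every attempt with per-criterion verdicts,
and unsolvable sets are flagged distinctly rather than dropped.

The population emulates the diversity of realizable TCS kinetics, not
any one organism: passing tests show that the *mechanistic* claims
(overshoot only under negative gain, negative gain only with exogenous
flux, protein-accumulation-driven learning) hold across a broad
parameter space, but absolute population fractions (e.g. the share of
negative-feedback sets, ~5% here) depend on the interval choice and
should not be read as biological frequencies.

## The dilution constant

The growth-dilution rate is not among the published constants.  The
package default is `k_dil = 1e-3 s^-1`, chosen so that the 45-minute
signal interruption of the learning experiment erases most of the
protein memory (`k_dil·2700 ≈ 2.7`): with substantially slower dilution
the interregnum leaves more than half the protein excess in place, every
induced set re-crosses its τ_50 threshold by phospho-equilibration alone
within seconds, and the documented correlation between protein
accumulation and response speed-up cannot exist for any parameter set.
The value also respects the feasibility requirement that both example
sets' mRNA decay outpaces dilution (the negative example's
`k_mRNAdeg = 1.383e-3` sits just above it).  The trade-off is that at
this dilution rate the two example sets' downstream induction is
compressed, which is why example-level response-time comparisons use the
elevation convention.  `k_dil` is configurable everywhere.

## Genetic algorithm

`ga_evolve` mutates every sampled parameter multiplicatively
(log-normal, σ = 0.2 by default), applies truncation selection (top 20%)
with one elite, and re-seeds with doubled mutation scale if a generation
scores uniformly zero.  The default fitness targets PhoPQ-like behavior
as a saturating product `Π min(fold_i/2, 1)` over three folds: RRP2
induction, total-RR induction, and peak-over-steady-state RRP2
(overshoot).  The saturating-product form and the GA hyperparameters are
package choices; the selection thresholds (2-fold each) are the
documented criteria.  With elitism and deterministic fitness the
best-so-far fitness is provably non-decreasing, and the GA recovers the
optimum of a smooth surrogate within 10% in the test suite.

## Problem sizes and numerical choices

Population-level checks use 500 feasible sets (overshoot/gain/flux/
learning) and 200 feasible sets (circuit-variant comparisons), sampled
with fixed seeds; the acceptance script re-runs the 500-set learning
survey from scratch.  Solver tolerances: steady-state residual
`1e-10·max(1,‖x‖)`; trajectory `rtol 1e-8`; gain step 1%; sign tolerance
1e-4; overshoot settling 1%.  Degenerate inputs are handled explicitly:
zero activator/substrate concentrations short-circuit the Michaelis
terms, τ of an already-crossed threshold is 0, a vanishing interregnum
yields an unbounded learning ratio (reported as `inf`), and a zero
induction range in the control makes the normalized range undefined
(`NaN`), never silently zero.

## Known limitations

* Deterministic ODEs only; no stochastic (CME/SSA) treatment, so noise-
  driven phenomena are out of scope.
* The exogenous flux is modeled in Michaelis–Menten form only (the
  linear variant is not a supported mode).
* The sampling intervals and `k_dil` are reconstructions (see above);
  population *fractions* are therefore indicative, and one documented
  population-level pattern — circuit I responding more slowly than wild
  type for the *majority* of feasible sets — holds here only within the
  negative-feedback subpopulation (and for the negative example set),
  not across the positive-dominated default population.
* Multi-stability is handled by basin-respecting initialization rather
  than exhaustive equilibrium enumeration.
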