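"""Reaction network of an autoregulated bacterial two-component system.

The model describes a sensor histidine kinase (SHK) and a response
regulator (RR) expressed from a single operon whose transcription is
activated by the phosphorylated-RR dimer (RRP2).  The bifunctional SHK
phosphorylates RR by phosphotransfer within a bound complex and, in its
unphosphorylated form, dephosphorylates RR-P.  An exogenous
(SHK-independent) phosphorylation/dephosphorylation flux with
Michaelis-Menten kinetics represents cross-talk or small-molecule
phosphodonors.  A downstream (DS) operon under RRP2 control serves as the
transcriptional readout.

Species (all concentrations, µM by convention):

======== ==============================================
mRNA_tcs transcript of the SHK/RR operon
mRNA_ds  transcript of the downstream operon
SHK      free unphosphorylated sensor kinase
SHKP     free phosphorylated sensor kinase
RR       free unphosphorylated response regulator
RRP      free phosphorylated response regulator
C_t      SHK·RRP complex (phosphatase-competent)
C_p      SHKP·RR complex (phosphotransfer-competent)
RRP2     transcriptionally active phospho-RR dimer
DS       downstream protein
======== ==============================================

The 22 reactions:

1   regulated transcription of the TCS operon (activator RRP2, or the
    exogenous regulator R0 in the open-loop variant)
2   regulated transcription of the DS operon (activator RRP2)
3,4 basal transcription of the two operons
5   first-order decay of both mRNAs (k_mRNAdeg)
6   SHK translation from mRNA_tcs
7   RR translation from mRNA_tcs (tsn_mult-fold relative to SHK)
8   DS translation from mRNA_ds
9   growth dilution of all proteins, complexes and the dimer (k_dil)
10  SHK autophosphorylation (k_ap, kinase signal)
11  SHKP autodephosphorylation (k_ad)
12  SHK + RRP binding (k_b1)
13  SHKP + RR binding (k_b)
14  phosphotransfer SHKP·RR -> SHK·RRP (k_pt)
15  reverse phosphotransfer SHK·RRP -> SHKP·RR (k_tp)
16  dissociation SHK·RRP -> SHK + RRP (k_d1)
17  dissociation SHKP·RR -> SHKP + RR (k_d)

The unprimed binding/dissociation pair (k_b, k_d) belongs to the
kinase-pathway complex SHKP·RR; the primed pair (k_b1, k_d1) to the
phosphatase-pathway complex SHK·RRP.  Release of RRP from SHK·RRP
(reaction 16) is the SHK-mediated phosphorylation output flux J_S;
reaction 19 is the exogenous phosphorylation flux J_E.
18  phosphatase catalysis SHK·RRP -> SHK + RR (k_ph, phosphatase signal)
19  exogenous RR phosphorylation, Michaelis-Menten (k_exp, K_mexp)
20  exogenous RRP dephosphorylation, Michaelis-Menten (k_exd, K_mexd)
21  RRP dimerization (k_RRPdm)
22  RRP2 undimerization (k_RRPmd)

Reactions 5 and 9 are reaction *families* (one instance per decaying or
diluted species).  The flux vector returned by :func:`reaction_fluxes`
lumps each family into its total flux so that index ``i`` corresponds to
reaction ``i+1`` of the table above; :func:`extended_fluxes` and
:func:`stoichiometry_matrix` expand the families so that the mass balance
``dx/dt = S @ v`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

__all__ = [
    "SPECIES",
    "SAMPLED_PARAMETERS",
    "PARAMETER_NAMES",
    "KineticParameters",
    "CircuitTopology",
    "ConfigurationError",
    "reaction_fluxes",
    "extended_fluxes",
    "stoichiometry_matrix",
    "time_derivative",
    "jacobian",
    "make_rhs",
    "make_topology",
    "shk_total",
    "rr_total",
    "rrp_total",
]

SPECIES = (
    "mRNA_tcs",
    "mRNA_ds",
    "SHK",
    "SHKP",
    "RR",
    "RRP",
    "C_t",
    "C_p",
    "RRP2",
    "DS",
)

N_SPECIES = len(SPECIES)
N_REACTIONS = 22

#: parameters drawn by the Monte Carlo sampler (everything except the
#: signal k_ph and the fixed culture/unit constants)
SAMPLED_PARAMETERS = (
    "k_ap",
    "k_ad",
    "k_pt",
    "k_tp",
    "k_b",
    "k_d",
    "k_b1",
    "k_d1",
    "k_RRPdm",
    "k_RRPmd",
    "k_txn",
    "k_SKtsn",
    "tsn_mult",
    "k_txnbasal",
    "K_mDS",
    "K_m",
    "k_mRNAdeg",
    "k_exp",
    "K_mexp",
    "k_exd",
    "K_mexd",
)

PARAMETER_NAMES = SAMPLED_PARAMETERS + ("k_ph", "k_dil", "molecules_per_conc_unit")


class ConfigurationError(ValueError):
    """A circuit variant is missing (or given inconsistent) constants."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the two-component system model.

    Units: first-order rates in 1/s, bimolecular rates in 1/(µM·s),
    transcription rates in µM/s, Michaelis constants in µM.
    ``molecules_per_conc_unit`` (molecules/cell per µM) is used only to
    translate molecule-per-cell feasibility thresholds into
    concentrations.
    """

    k_ap: float        # SHK autophosphorylation (kinase signal)
    k_ad: float        # SHKP autodephosphorylation
    k_pt: float        # phosphotransfer SHKP.RR -> SHK.RRP
    k_tp: float        # reverse phosphotransfer
    k_b: float         # SHKP + RR binding (kinase complex)
    k_d: float         # SHKP.RR dissociation
    k_b1: float        # SHK + RRP binding (phosphatase complex)
    k_d1: float        # SHK.RRP dissociation
    k_RRPdm: float     # RRP dimerization
    k_RRPmd: float     # RRP2 undimerization
    k_txn: float       # maximal regulated transcription rate
    k_SKtsn: float     # SHK translation rate per mRNA
    tsn_mult: float    # RR translation multiplier relative to SHK
    k_txnbasal: float  # basal transcription rate
    K_mDS: float       # activation Michaelis constant, DS operon
    K_m: float         # activation Michaelis constant, TCS operon
    k_mRNAdeg: float   # mRNA decay rate
    k_exp: float       # exogenous RR phosphorylation Vmax
    K_mexp: float      # exogenous phosphorylation Michaelis constant
    k_exd: float       # exogenous RRP dephosphorylation Vmax
    K_mexd: float      # exogenous dephosphorylation Michaelis constant
    k_ph: float = 10.0    # phosphatase catalysis rate (primary signal)
    k_dil: float = 1.0e-3  # growth dilution rate (fast exponential growth)
    molecules_per_conc_unit: float = 1000.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v!r}")
        # k_dil = 0 is allowed for conservation analyses; steady-state
        # routines require k_dil > 0 for a well-defined protein level

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_signal(self, k_ph: Optional[float] = None, k_ap: Optional[float] = None) -> "KineticParameters":
        """Copy with the signal parameters replaced."""
        kw = {}
        if k_ph is not None:
            kw["k_ph"] = k_ph
        if k_ap is not None:
            kw["k_ap"] = k_ap
        return replace(self, **kw) if kw else self

    def replace(self, **kwargs) -> "KineticParameters":
        return replace(self, **kwargs)

    def sampled_vector(self) -> np.ndarray:
        """The 21 Monte-Carlo-sampled parameters, in canonical order."""
        return np.array([getattr(self, n) for n in SAMPLED_PARAMETERS])

    def with_sampled_vector(self, vec: np.ndarray) -> "KineticParameters":
        return replace(self, **dict(zip(SAMPLED_PARAMETERS, (float(v) for v in vec))))


_VARIANTS = ("wild_type", "open_loop", "no_feedback", "circuit_I", "circuit_II")


@dataclass(frozen=True)
class CircuitTopology:
    """Wiring variant of the circuit.

    wild_type
        both SHK and RR expressed from the RRP2-regulated operon.
    open_loop
        TCS-operon transcription driven by a fixed exogenous regulator
        concentration ``R0`` instead of RRP2 (the DS operon stays under
        RRP2 control).
    no_feedback
        TCS-operon transcription fixed at ``const_tcs_txn``.
    circuit_I
        feedback to RR only; SHK produced constitutively at
        ``const_shk_txn`` (protein flux).
    circuit_II
        feedback to SHK only; RR produced constitutively at
        ``const_rr_txn`` (protein flux).
    """

    variant: str = "wild_type"
    R0: Optional[float] = None
    const_tcs_txn: Optional[float] = None
    const_shk_txn: Optional[float] = None
    const_rr_txn: Optional[float] = None

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ConfigurationError(
                f"unknown circuit variant {self.variant!r}; expected one of {_VARIANTS}"
            )
        required = {
            "open_loop": "R0",
            "no_feedback": "const_tcs_txn",
            "circuit_I": "const_shk_txn",
            "circuit_II": "const_rr_txn",
        }.get(self.variant)
        if required is not None and getattr(self, required) is None:
            raise ConfigurationError(
                f"variant {self.variant!r} requires the constant {required!r}"
            )

    def with_R0(self, R0: float) -> "CircuitTopology":
        if self.variant != "open_loop":
            raise ConfigurationError("R0 applies only to the open_loop variant")
        return replace(self, R0=float(R0))


WILD_TYPE = CircuitTopology("wild_type")


# ---------------------------------------------------------------------------
# derived totals

def shk_total(state: np.ndarray) -> np.ndarray:
    """Total sensor kinase: SHK + SHKP + both complexes."""
    s = np.asarray(state)
    return s[..., 2] + s[..., 3] + s[..., 6] + s[..., 7]


def rr_total(state: np.ndarray) -> np.ndarray:
    """Total response regulator: RR + RRP + complexes + 2*RRP2."""
    s = np.asarray(state)
    return s[..., 4] + s[..., 5] + s[..., 6] + s[..., 7] + 2.0 * s[..., 8]


def rrp_total(state: np.ndarray) -> np.ndarray:
    """Total phosphorylated RR: free RRP + RRP in SHK·RRP + 2*RRP2.

    The RR moiety of the SHKP·RR complex is unphosphorylated and is not
    counted.
    """
    s = np.asarray(state)
    return s[..., 5] + s[..., 6] + 2.0 * s[..., 8]


# ---------------------------------------------------------------------------
# flux evaluation

def _check_state(state: np.ndarray) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (N_SPECIES,):
        raise ValueError(f"state must have shape ({N_SPECIES},), got {x.shape}")
    scale = max(1.0, float(np.max(np.abs(x))))
    if np.min(x) < -1e-9 * scale:
        raise ValueError(f"negative concentration in state: min = {np.min(x)}")
    return x


def _tcs_txn_flux(x: np.ndarray, p: KineticParameters, topo: CircuitTopology) -> float:
    """Reaction 1: regulated transcription of the TCS operon."""
    if topo.variant == "open_loop":
        a = topo.R0
    elif topo.variant == "no_feedback":
        return topo.const_tcs_txn
    else:
        a = x[8]
    return p.k_txn * a / (p.K_m + a) if a > 0 else 0.0


def extended_fluxes(state, params: KineticParameters, topology: CircuitTopology = WILD_TYPE) -> np.ndarray:
    """Per-instance fluxes (length 30), reaction families expanded.

    Layout: reactions 1-4, then decay of each mRNA (family 5), reactions
    6-8, then dilution of each of the 8 diluted species (family 9), then
    reactions 10-22.
    """
    x = _check_state(state)
    p = params
    mT, mD, S, Sp, R, Rp, Ct, Cp, D2, DS = x

    v = np.empty(30)
    v[0] = _tcs_txn_flux(x, p, topology)
    v[1] = p.k_txn * D2 / (p.K_mDS + D2) if D2 > 0 else 0.0
    v[2] = 0.0 if topology.variant == "no_feedback" else p.k_txnbasal
    v[3] = p.k_txnbasal
    v[4] = p.k_mRNAdeg * mT
    v[5] = p.k_mRNAdeg * mD
    v[6] = topology.const_shk_txn if topology.variant == "circuit_I" else p.k_SKtsn * mT
    v[7] = topology.const_rr_txn if topology.variant == "circuit_II" else p.tsn_mult * p.k_SKtsn * mT
    v[8] = p.k_SKtsn * mD
    v[9:17] = p.k_dil * np.array([S, Sp, R, Rp, Ct, Cp, D2, DS])
    v[17] = p.k_ap * S
    v[18] = p.k_ad * Sp
    v[19] = p.k_b1 * S * Rp
    v[20] = p.k_b * Sp * R
    v[21] = p.k_pt * Cp
    v[22] = p.k_tp * Ct
    v[23] = p.k_d1 * Ct
    v[24] = p.k_d * Cp
    v[25] = p.k_ph * Ct
    v[26] = p.k_exp * R / (p.K_mexp + R) if R > 0 else 0.0
    v[27] = p.k_exd * Rp / (p.K_mexd + Rp) if Rp > 0 else 0.0
    v[28] = p.k_RRPdm * Rp * Rp
    v[29] = p.k_RRPmd * D2
    return v


def reaction_fluxes(state, params: KineticParameters, topology: CircuitTopology = WILD_TYPE) -> np.ndarray:
    """The 22 per-reaction fluxes; families 5 and 9 reported as totals."""
    ve = extended_fluxes(state, params, topology)
    v = np.empty(N_REACTIONS)
    v[0:4] = ve[0:4]
    v[4] = ve[4] + ve[5]
    v[5:8] = ve[6:9]
    v[8] = ve[9:17].sum()
    v[9:22] = ve[17:30]
    return v


def stoichiometry_matrix() -> np.ndarray:
    """10 x 30 stoichiometry matrix matching :func:`extended_fluxes`."""
    S = np.zeros((N_SPECIES, 30))
    i = {name: k for k, name in enumerate(SPECIES)}

    S[i["mRNA_tcs"], 0] = 1   # reaction 1
    S[i["mRNA_ds"], 1] = 1    # reaction 2
    S[i["mRNA_tcs"], 2] = 1   # reaction 3
    S[i["mRNA_ds"], 3] = 1    # reaction 4
    S[i["mRNA_tcs"], 4] = -1  # reaction 5 (mRNA_tcs decay)
    S[i["mRNA_ds"], 5] = -1   # reaction 5 (mRNA_ds decay)
    S[i["SHK"], 6] = 1        # reaction 6
    S[i["RR"], 7] = 1         # reaction 7
    S[i["DS"], 8] = 1         # reaction 8
    for k, sp in enumerate(("SHK", "SHKP", "RR", "RRP", "C_t", "C_p", "RRP2", "DS")):
        S[i[sp], 9 + k] = -1  # reaction 9 (dilution)
    S[i["SHK"], 17], S[i["SHKP"], 17] = -1, 1    # reaction 10
    S[i["SHKP"], 18], S[i["SHK"], 18] = -1, 1    # reaction 11
    S[i["SHK"], 19], S[i["RRP"], 19], S[i["C_t"], 19] = -1, -1, 1   # reaction 12
    S[i["SHKP"], 20], S[i["RR"], 20], S[i["C_p"], 20] = -1, -1, 1   # reaction 13
    S[i["C_p"], 21], S[i["C_t"], 21] = -1, 1     # reaction 14
    S[i["C_t"], 22], S[i["C_p"], 22] = -1, 1     # reaction 15
    S[i["C_t"], 23], S[i["SHK"], 23], S[i["RRP"], 23] = -1, 1, 1    # reaction 16
    S[i["C_p"], 24], S[i["SHKP"], 24], S[i["RR"], 24] = -1, 1, 1    # reaction 17
    S[i["C_t"], 25], S[i["SHK"], 25], S[i["RR"], 25] = -1, 1, 1     # reaction 18
    S[i["RR"], 26], S[i["RRP"], 26] = -1, 1      # reaction 19
    S[i["RRP"], 27], S[i["RR"], 27] = -1, 1      # reaction 20
    S[i["RRP"], 28], S[i["RRP2"], 28] = -2, 1    # reaction 21
    S[i["RRP2"], 29], S[i["RRP"], 29] = -1, 2    # reaction 22
    return S


def time_derivative(state, params: KineticParameters, topology: CircuitTopology = WILD_TYPE) -> np.ndarray:
    """d(state)/dt of the full network (mass balance over all 22 reactions)."""
    x = _check_state(state)
    f, _ = make_rhs(params, topology)
    return f(0.0, x)


def _rhs_kernel(t, y, c):
    """Right-hand side on a packed constant vector ``c`` (see _pack)."""
    mT = y[0]; mD = y[1]; S = y[2]; Sp = y[3]; R = y[4]
    Rp = y[5]; Ct = y[6]; Cp = y[7]; D2 = y[8]; DS = y[9]
    (kap, kad, kpt, ktp, kb, kd, kb1, kd1, kdm, kmd, ktxn, kbas, Km, KmDS,
     ktsn, mult, kdeg, kexp, Kmexp, kexd, Kmexd, kph, kdil) = c[:23]
    v1 = c[24] if c[23] > 0.0 else (ktxn * D2 / (Km + D2) if D2 > 0 else 0.0)
    v3 = c[25]
    v2 = ktxn * D2 / (KmDS + D2) if D2 > 0 else 0.0
    v6 = c[27] if c[26] > 0.0 else ktsn * mT
    v7 = c[29] if c[28] > 0.0 else mult * ktsn * mT
    v8 = ktsn * mD
    v10 = kap * S
    v11 = kad * Sp
    v12 = kb * S * Rp
    v13 = kb1 * Sp * R
    v14 = kpt * Cp
    v15 = ktp * Ct
    v16 = kd * Ct
    v17 = kd1 * Cp
    v18 = kph * Ct
    v19 = kexp * R / (Kmexp + R) if R > 0 else 0.0
    v20 = kexd * Rp / (Kmexd + Rp) if Rp > 0 else 0.0
    v21 = kdm * Rp * Rp
    v22 = kmd * D2
    out = np.empty(10)
    out[0] = v1 + v3 - kdeg * mT
    out[1] = v2 + kbas - kdeg * mD
    out[2] = v6 - v10 + v11 - v12 + v16 + v18 - kdil * S
    out[3] = v10 - v11 - v13 + v17 - kdil * Sp
    out[4] = v7 - v13 + v17 + v18 - v19 + v20 - kdil * R
    out[5] = -v12 + v16 + v19 - v20 - 2.0 * v21 + 2.0 * v22 - kdil * Rp
    out[6] = v12 + v14 - v15 - v16 - v18 - kdil * Ct
    out[7] = v13 - v14 + v15 - v17 - kdil * Cp
    out[8] = v21 - v22 - kdil * D2
    out[9] = v8 - kdil * DS
    return out


def _jac_kernel(t, y, c):
    """Analytic Jacobian of :func:`_rhs_kernel`."""
    S = y[2]; Sp = y[3]; R = y[4]; Rp = y[5]; D2 = y[8]
    (kap, kad, kpt, ktp, kb, kd, kb1, kd1, kdm, kmd, ktxn, kbas, Km, KmDS,
     ktsn, mult, kdeg, kexp, Kmexp, kexd, Kmexd, kph, kdil) = c[:23]
    J = np.zeros((10, 10))
    if c[23] == 0.0:  # TCS operon regulated by the dimer
        J[0, 8] = ktxn * Km / (Km + D2) ** 2 if D2 > 0 else ktxn / Km
    J[1, 8] = ktxn * KmDS / (KmDS + D2) ** 2 if D2 > 0 else ktxn / KmDS
    J[0, 0] = -kdeg
    J[1, 1] = -kdeg
    d19 = kexp * Kmexp / (Kmexp + R) ** 2 if R > 0 else kexp / Kmexp
    d20 = kexd * Kmexd / (Kmexd + Rp) ** 2 if Rp > 0 else kexd / Kmexd
    # SHK
    if c[26] == 0.0:
        J[2, 0] = ktsn
    J[2, 2] = -kap - kb * Rp - kdil
    J[2, 3] = kad
    J[2, 5] = -kb * S
    J[2, 6] = kd + kph
    # SHKP
    J[3, 2] = kap
    J[3, 3] = -kad - kb1 * R - kdil
    J[3, 4] = -kb1 * Sp
    J[3, 7] = kd1
    # RR
    if c[28] == 0.0:
        J[4, 0] = mult * ktsn
    J[4, 3] = -kb1 * R
    J[4, 4] = -kb1 * Sp - d19 - kdil
    J[4, 5] = d20
    J[4, 6] = kph
    J[4, 7] = kd1
    # RRP
    J[5, 2] = -kb * Rp
    J[5, 4] = d19
    J[5, 5] = -kb * S - d20 - 4.0 * kdm * Rp - kdil
    J[5, 6] = kd
    J[5, 8] = 2.0 * kmd
    # C_t
    J[6, 2] = kb * Rp
    J[6, 5] = kb * S
    J[6, 6] = -ktp - kd - kph - kdil
    J[6, 7] = kpt
    # C_p
    J[7, 3] = kb1 * R
    J[7, 4] = kb1 * Sp
    J[7, 6] = ktp
    J[7, 7] = -kpt - kd1 - kdil
    # RRP2
    J[8, 5] = 2.0 * kdm * Rp
    J[8, 8] = -kmd - kdil
    # DS
    J[9, 1] = ktsn
    J[9, 9] = -kdil
    return J


try:  # JIT-compile the kernels when numba is available (pure-python fallback)
    from numba import njit as _njit

    _rhs_kernel = _njit(cache=True)(_rhs_kernel)
    _jac_kernel = _njit(cache=True)(_jac_kernel)
except ImportError:  # pragma: no cover
    pass


def _pack(params: KineticParameters, topology: CircuitTopology,
          k_ph: Optional[float], k_ap: Optional[float]) -> np.ndarray:
    """Pack rate constants and topology flags for the ODE kernels.

    Slots 0-22: rate constants with the binding/dissociation pairs
    indexed by complex (4-5 act on C_t via the primed printed constants,
    6-7 on C_p via the unprimed ones).  Slots 23-29: flag/value pairs
    for a fixed TCS transcription flux, fixed SHK production and fixed
    RR production, plus the basal TCS transcription actually in force.
    """
    p = params
    variant = topology.variant
    if variant == "open_loop":
        if topology.R0 is None:
            raise ConfigurationError("open_loop requires R0")
        R0 = topology.R0
        v1_flag, v1 = 1.0, (p.k_txn * R0 / (p.K_m + R0) if R0 > 0 else 0.0)
        v3 = p.k_txnbasal
    elif variant == "no_feedback":
        if topology.const_tcs_txn is None:
            raise ConfigurationError("no_feedback requires const_tcs_txn")
        v1_flag, v1 = 1.0, topology.const_tcs_txn
        v3 = 0.0
    else:
        v1_flag, v1 = 0.0, 0.0
        v3 = p.k_txnbasal
    if variant == "circuit_I":
        if topology.const_shk_txn is None:
            raise ConfigurationError("circuit_I requires const_shk_txn")
        shk_flag, shk = 1.0, topology.const_shk_txn
    else:
        shk_flag, shk = 0.0, 0.0
    if variant == "circuit_II":
        if topology.const_rr_txn is None:
            raise ConfigurationError("circuit_II requires const_rr_txn")
        rr_flag, rr = 1.0, topology.const_rr_txn
    else:
        rr_flag, rr = 0.0, 0.0
    return np.array([
        p.k_ap if k_ap is None else k_ap, p.k_ad, p.k_pt, p.k_tp,
        p.k_b1, p.k_d1,   # C_t (SHK·RRP) binding/dissociation
        p.k_b, p.k_d,     # C_p (SHKP·RR) binding/dissociation
        p.k_RRPdm, p.k_RRPmd, p.k_txn, p.k_txnbasal, p.K_m, p.K_mDS,
        p.k_SKtsn, p.tsn_mult, p.k_mRNAdeg, p.k_exp, p.K_mexp,
        p.k_exd, p.K_mexd,
        p.k_ph if k_ph is None else k_ph, p.k_dil,
        v1_flag, v1, v3, shk_flag, shk, rr_flag, rr,
    ])


def make_rhs(params: KineticParameters, topology: CircuitTopology = WILD_TYPE,
             k_ph: Optional[float] = None, k_ap: Optional[float] = None):
    """Build fast ``(f, jac)`` callables for the ODE right-hand side.

    Optional ``k_ph``/``k_ap`` override the values carried by ``params``
    (used by signal protocols).  The callables take ``(t, y)`` and never
    validate their input, so they are safe inside stiff integrators that
    probe slightly negative states.
    """
    c = _pack(params, topology, k_ph, k_ap)

    def f(t, y):
        return _rhs_kernel(t, y, c)

    def jac(t, y):
        return _jac_kernel(t, y, c)

    return f, jac


def make_topology(variant: str,
                  calibration_params: Optional[KineticParameters] = None,
                  calibration_signal: float = 0.1,
                  R0: Optional[float] = None,
                  rest_state: Optional[np.ndarray] = None,
                  calibration_state: Optional[np.ndarray] = None) -> CircuitTopology:
    """Construct a circuit variant, calibrating constitutive rates.

    For ``no_feedback``, ``circuit_I`` and ``circuit_II`` the constitutive
    production flux is set equal to the corresponding wild-type production
    flux at the wild-type steady state under ``calibration_signal``
    (k_ph = 0.1/s by default, the activated level).  For ``open_loop``,
    ``R0`` defaults to the wild-type steady-state RRP2 at the calibration
    signal when not given explicitly.  Precomputed wild-type steady
    states (``rest_state`` at k_ph = 10, ``calibration_state`` at the
    calibration signal) skip the corresponding solves.
    """
    if variant == "wild_type":
        return WILD_TYPE
    if variant == "open_loop" and R0 is not None:
        return CircuitTopology("open_loop", R0=float(R0))
    if calibration_params is None:
        raise ConfigurationError(f"variant {variant!r} requires calibration parameters")

    from .simulation import solve_steady_state  # deferred: avoids an import cycle

    p = calibration_params
    if calibration_state is None:
        if rest_state is None:
            rest = solve_steady_state(p, WILD_TYPE, k_ph=10.0)
            if not rest.success:
                raise RuntimeError("wild-type resting steady state not found "
                                   "during calibration")
            rest_state = rest.state
        cal = solve_steady_state(p, WILD_TYPE, k_ph=calibration_signal,
                                 initial_state=rest_state)
        if not cal.success:
            raise RuntimeError("wild-type calibration steady state not found")
        calibration_state = cal.state
    x = calibration_state
    if variant == "open_loop":
        return CircuitTopology("open_loop", R0=float(x[8]))
    if variant == "no_feedback":
        flux = _tcs_txn_flux(x, p, WILD_TYPE) + p.k_txnbasal
        return CircuitTopology("no_feedback", const_tcs_txn=float(flux))
    if variant == "circuit_I":
        return CircuitTopology("circuit_I", const_shk_txn=float(p.k_SKtsn * x[0]))
    if variant == "circuit_II":
        return CircuitTopology("circuit_II", const_rr_txn=float(p.tsn_mult * p.k_SKtsn * x[0]))
    raise ConfigurationError(f"unknown circuit variant {variant!r}")
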