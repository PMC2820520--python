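"""Independent oracles for cross-checking the implementation.

Everything here is written directly from the reaction mechanisms,
deliberately *not* sharing code with the package: a dict-based flux
evaluator, a per-species mass-balance assembler, finite-difference
Jacobians and an implicit-differentiation route to the open-loop gain.
"""

import numpy as np

IDX = {name: i for i, name in enumerate(
    ["mRNA_tcs", "mRNA_ds", "SHK", "SHKP", "RR", "RRP", "C_t", "C_p", "RRP2", "DS"])}


def independent_fluxes(state, p, R0=None):
    """All reaction fluxes as a dict keyed by reaction number.

    Families 5 and 9 are returned per species as e.g. ``"5:mRNA_tcs"``.
    ``R0`` switches the TCS operon to open-loop control.
    """
    s = {name: state[i] for name, i in IDX.items()}
    mm = lambda vmax, x, K: vmax * x / (K + x) if x > 0 else 0.0
    act = R0 if R0 is not None else s["RRP2"]
    v = {
        1: mm(p.k_txn, act, p.K_m),
        2: mm(p.k_txn, s["RRP2"], p.K_mDS),
        3: p.k_txnbasal,
        4: p.k_txnbasal,
        6: p.k_SKtsn * s["mRNA_tcs"],
        7: p.tsn_mult * p.k_SKtsn * s["mRNA_tcs"],
        8: p.k_SKtsn * s["mRNA_ds"],
        10: p.k_ap * s["SHK"],
        11: p.k_ad * s["SHKP"],
        12: p.k_b1 * s["SHK"] * s["RRP"],    # phosphatase-complex formation
        13: p.k_b * s["SHKP"] * s["RR"],     # kinase-complex formation
        14: p.k_pt * s["C_p"],
        15: p.k_tp * s["C_t"],
        16: p.k_d1 * s["C_t"],
        17: p.k_d * s["C_p"],
        18: p.k_ph * s["C_t"],
        19: mm(p.k_exp, s["RR"], p.K_mexp),
        20: mm(p.k_exd, s["RRP"], p.K_mexd),
        21: p.k_RRPdm * s["RRP"] ** 2,
        22: p.k_RRPmd * s["RRP2"],
    }
    for name in ("mRNA_tcs", "mRNA_ds"):
        v[f"5:{name}"] = p.k_mRNAdeg * s[name]
    for name in ("SHK", "SHKP", "RR", "RRP", "C_t", "C_p", "RRP2", "DS"):
        v[f"9:{name}"] = p.k_dil * s[name]
    return v


def mass_balance(state, p, R0=None):
    """d(state)/dt assembled species by species from independent_fluxes."""
    v = independent_fluxes(state, p, R0=R0)
    d = np.zeros(10)
    d[IDX["mRNA_tcs"]] = v[1] + v[3] - v["5:mRNA_tcs"]
    d[IDX["mRNA_ds"]] = v[2] + v[4] - v["5:mRNA_ds"]
    d[IDX["SHK"]] = v[6] - v[10] + v[11] - v[12] + v[16] + v[18] - v["9:SHK"]
    d[IDX["SHKP"]] = v[10] - v[11] - v[13] + v[17] - v["9:SHKP"]
    d[IDX["RR"]] = v[7] - v[13] + v[17] + v[18] - v[19] + v[20] - v["9:RR"]
    d[IDX["RRP"]] = (-v[12] + v[16] + v[19] - v[20]
                     - 2 * v[21] + 2 * v[22] - v["9:RRP"])
    d[IDX["C_t"]] = v[12] + v[14] - v[15] - v[16] - v[18] - v["9:C_t"]
    d[IDX["C_p"]] = v[13] - v[14] + v[15] - v[17] - v["9:C_p"]
    d[IDX["RRP2"]] = v[21] - v[22] - v["9:RRP2"]
    d[IDX["DS"]] = v[8] - v["9:DS"]
    return d


def fd_jacobian(fun, x, eps=1e-7):
    """Central-difference Jacobian of a vector function."""
    x = np.asarray(x, dtype=float)
    n = x.size
    J = np.zeros((fun(x).size, n))
    for j in range(n):
        h = eps * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (fun(xp) - fun(xm)) / (2 * h)
    return J


def sensitivity_gain(p, closed_state, k_ph):
    """Open-loop gain by implicit differentiation of the steady state.

    At the open-loop steady state f(x; R0) = 0, so
    dx/dR0 = -J^-1 df/dR0 with both derivatives taken by finite
    differences of the independent mass balance.  The gain is the
    log-log sensitivity of RRP2 at R0 = closed-loop RRP2 (where the
    open-loop fixed point coincides with the closed-loop state).
    """
    ps = p.with_signal(k_ph=k_ph)
    R0 = closed_state[IDX["RRP2"]]
    x = np.asarray(closed_state, dtype=float)
    J = fd_jacobian(lambda y: mass_balance(y, ps, R0=R0), x)
    h = 1e-6 * R0
    dfdR0 = (mass_balance(x, ps, R0=R0 + h) - mass_balance(x, ps, R0=R0 - h)) / (2 * h)
    dxdR0 = np.linalg.solve(J, -dfdR0)
    return float(R0 / x[IDX["RRP2"]] * dxdR0[IDX["RRP2"]])
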