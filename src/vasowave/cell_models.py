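"""Single-cell right-hand sides for the coupled EC/SMC calcium model.

The endothelial cell (EC) carries cytosolic Ca2+, store Ca2+, IP3, membrane
potential and an activated G-protein count; the smooth muscle cell (SMC)
carries cytosolic Ca2+, store Ca2+, IP3, membrane potential and the open
fraction of its Ca2+-activated K+ channels.

Luminal ATP drives endothelial IP3 production through a P2Y receptor /
G-protein / PLC cascade:

    rho_P2Y = [ATP] / (K_ATP + [ATP])
    dG/dt   = k_a (delta + rho) (G_tot - G) - k_d G
    r_h     = alpha * c/(c + K_Ca) * G
    dI/dt   = eps * r_h * PIP2_tot - k_deg * I + coupling

SMC IP3 has no intrinsic production; it arrives only through gap-junctional
coupling from the endothelium and decays first order.

All functions are vectorised: scalars or same-shaped numpy arrays go in,
derivatives of the same shape come out.
"""

from __future__ import annotations

import numpy as np

from .params import ECParams, IP3PathwayParams, ModelParams, SMCParams

EC_VARS = ("ca_cyt", "ca_store", "ip3", "v_m", "g_prot")
SMC_VARS = ("ca_cyt", "ca_store", "ip3", "v_m", "w_k")
EC_DIM = len(EC_VARS)
SMC_DIM = len(SMC_VARS)

# floor protecting log10(ca) in the EC gating terms from non-physical excursions
_CA_FLOOR = 1e-12


class CellStateError(ValueError):
    """Raised when a state vector is non-finite or out of its valid domain."""


# ---------------------------------------------------------------------------
# agonist -> IP3 pathway
# ---------------------------------------------------------------------------

def rho_p2y(atp, K_ATP: float):
    """Fraction of agonist-bound P2Y receptors, [ATP]/(K_ATP + [ATP])."""
    atp = np.asarray(atp, dtype=float)
    if np.any(atp < 0):
        raise CellStateError("ATP concentration must be >= 0")
    if not K_ATP > 0:
        raise CellStateError("K_ATP must be > 0")
    out = atp / (K_ATP + atp)
    return float(out) if out.ndim == 0 else out


def g_protein_rate(g_prot, rho, p: IP3PathwayParams):
    """dG/dt of the activated G-protein pool (molecules/s)."""
    return p.k_a * (p.delta + rho) * (p.G_prot_tot - g_prot) - p.k_d * g_prot


def g_protein_steady(rho, p: IP3PathwayParams):
    """Fixed point of the G-protein kinetics at constant receptor occupancy."""
    a = p.k_a * (p.delta + rho)
    return a * p.G_prot_tot / (a + p.k_d)


def plc_hydrolysis_rate(ca_cyt, g_prot, p: IP3PathwayParams):
    """PIP2 hydrolysis rate r_h by Ca2+-dependent, G-protein-activated PLC (1/s)."""
    return p.alpha * ca_cyt / (ca_cyt + p.K_Ca) * g_prot


def ec_ip3_rate(ip3, r_h, coupling_flux, p: IP3PathwayParams):
    """Endothelial dI/dt: PLC production minus first-order degradation plus coupling."""
    return p.epsilon * r_h * p.PIP2_tot - p.k_deg * ip3 + coupling_flux


def ec_ip3_production(atp, ca_cyt, p: IP3PathwayParams):
    """Quasi-steady IP3 production rate (uM/s) at constant ATP and EC Ca2+.

    Convenience closed form used for calibration and the frequency/production
    monotonicity analysis: G-protein at its fixed point for the given receptor
    occupancy.
    """
    g = g_protein_steady(rho_p2y(atp, p.K_ATP), p)
    return p.epsilon * plc_hydrolysis_rate(ca_cyt, g, p) * p.PIP2_tot


# ---------------------------------------------------------------------------
# EC fluxes
# ---------------------------------------------------------------------------

def ec_fluxes(ca, st, ip3, vm, p: ECParams) -> dict[str, np.ndarray]:
    """All endothelial ionic/store fluxes (uM/s, potentials as noted)."""
    ca_s = np.maximum(ca, _CA_FLOOR)
    logc = np.log10(ca_s)
    j_ip3 = p.F_ip3 * ip3**2 / (p.K_r**2 + ip3**2)
    j_serca = p.B * ca**2 / (p.c_b**2 + ca**2)
    j_cicr = p.C_cicr * (st**2 / (p.s_c**2 + st**2)) * (ca**4 / (p.c_c**4 + ca**4))
    j_extr = p.D_extr * ca
    j_leak = p.L * st
    j_cat = p.G_cat * (p.E_Ca - vm) * 0.5 * (1.0 + np.tanh((logc - p.m3_cat) / p.m4_cat))
    # BKCa + SKCa open probabilities (Schuster-style gating in log10[Ca])
    num = (logc - p.c1) * (vm - p.b1) - p.a1
    den = p.m3b * (vm + p.a2 * (logc - p.c1) - p.b1) ** 2 + p.m4b
    o_bk = 0.2 * (1.0 + np.tanh(num / den))
    o_sk = 0.3 * (1.0 + np.tanh((logc - p.m3s) / p.m4s))
    i_k = p.G_tot * (vm - p.v_K) * (o_bk + o_sk)    # pA-scale, pS*mV
    i_r = p.G_R * (vm - p.v_rest)
    return {"ip3_release": j_ip3, "serca": j_serca, "cicr": j_cicr,
            "extrusion": j_extr, "leak": j_leak, "cation": j_cat,
            "i_K": i_k, "i_R": i_r}


def ec_rhs(state: np.ndarray, atp, coupling, ip3p: IP3PathwayParams,
           p: ECParams) -> np.ndarray:
    """Time derivative of the EC state array.

    ``state`` has shape (5, n): rows ca_cyt, ca_store, ip3, v_m, g_prot.
    ``coupling`` is ``(ca_flux, ip3_flux, vm_flux)`` in (uM/s, uM/s, mV/s),
    each scalar 0 or shape (n,).
    """
    ca, st, ip3, vm, g = state
    _check_finite(state, "EC")
    cpl_ca, cpl_ip3, cpl_vm = coupling
    fx = ec_fluxes(ca, st, ip3, vm, p)
    rho = rho_p2y(atp, ip3p.K_ATP)
    r_h = plc_hydrolysis_rate(ca, g, ip3p)
    dca = (fx["ip3_release"] - fx["serca"] + fx["cicr"] - fx["extrusion"]
           + fx["leak"] + fx["cation"] + p.J0 + cpl_ca)
    dst = fx["serca"] - fx["cicr"] - fx["leak"]
    dip3 = ec_ip3_rate(ip3, r_h, cpl_ip3, ip3p)
    dvm = -(fx["i_K"] + fx["i_R"]) / p.C_m + cpl_vm
    dg = g_protein_rate(g, rho, ip3p)
    return np.stack(np.broadcast_arrays(dca, dst, dip3, dvm, dg))


# ---------------------------------------------------------------------------
# SMC fluxes
# ---------------------------------------------------------------------------

def smc_fluxes(ca, st, ip3, vm, w, p: SMCParams) -> dict[str, np.ndarray]:
    """All smooth-muscle ionic/store fluxes (uM/s)."""
    j_ip3 = p.F_ip3 * ip3**2 / (p.K_r**2 + ip3**2)
    j_vocc = p.G_Ca * (vm - p.v_Ca1) / (1.0 + np.exp(-(vm - p.v_Ca2) / p.R_Ca))
    j_naca = p.G_NaCa * ca / (ca + p.c_NaCa) * (vm - p.v_NaCa)
    j_serca = p.B * ca**2 / (p.c_b**2 + ca**2)
    j_cicr = p.C_cicr * (st**2 / (p.s_c**2 + st**2)) * (ca**4 / (p.c_c**4 + ca**4))
    j_extr = p.D_extr * ca * (1.0 + (vm - p.v_d) / p.R_d)
    j_leak = p.L * st
    j_cl = p.G_Cl * (vm - p.v_Cl)
    j_k = p.G_K * w * (vm - p.v_K)
    k_act = (ca + p.c_w) ** 2 / ((ca + p.c_w) ** 2
                                 + p.beta * np.exp(-(vm - p.v_Ca3) / p.R_K))
    return {"ip3_release": j_ip3, "vocc": j_vocc, "naca": j_naca,
            "serca": j_serca, "cicr": j_cicr, "extrusion": j_extr,
            "leak": j_leak, "cl": j_cl, "k": j_k, "k_act": k_act}


def smc_rhs(state: np.ndarray, coupling, p: SMCParams) -> np.ndarray:
    """Time derivative of the SMC state array, shape (5, n)."""
    ca, st, ip3, vm, w = state
    _check_finite(state, "SMC")
    cpl_ca, cpl_ip3, cpl_vm = coupling
    fx = smc_fluxes(ca, st, ip3, vm, w, p)
    dca = (fx["ip3_release"] - fx["serca"] + fx["cicr"] - fx["extrusion"]
           + fx["leak"] - fx["vocc"] + fx["naca"] + cpl_ca)
    dst = fx["serca"] - fx["cicr"] - fx["leak"]
    dip3 = -p.k_deg * ip3 + cpl_ip3
    dvm = p.gamma * (-p.F_NaK - fx["cl"] - 2.0 * fx["vocc"] - fx["naca"]
                     - fx["k"]) + cpl_vm
    dw = p.lam * (fx["k_act"] - w)
    return np.stack(np.broadcast_arrays(dca, dst, dip3, dvm, dw))


# ---------------------------------------------------------------------------
# rest states
# ---------------------------------------------------------------------------

def rest_state(params: ModelParams, atp: float = 0.0,
               t_relax: float = 2000.0) -> tuple[np.ndarray, np.ndarray]:
    """Numerically locate the coupled EC/SMC rest state at constant ATP.

    Relaxes a single heterocellularly coupled EC/SMC pair from a nominal
    interior point and polishes the fixed point with a root find.  Returns
    ``(ec_state, smc_state)`` as flat arrays of length 5.
    """
    from scipy.integrate import solve_ivp
    from scipy.optimize import fsolve

    cp = params.coupling

    def rhs(_t, y):
        ec = y[:EC_DIM].reshape(EC_DIM, 1)
        smc = y[EC_DIM:].reshape(SMC_DIM, 1)
        drift = (cp.drift_factor_ca * 0.5 * (ec[0] + smc[0])
                 * (smc[3] - ec[3]))
        d_ca = cp.p_ca_hetero * ((smc[0] - ec[0]) + drift)
        d_ip3 = cp.p_ip3_hetero * (smc[2] - ec[2])
        d_vm = cp.g_hetero * (smc[3] - ec[3])
        dec = ec_rhs(ec, atp, (d_ca, d_ip3, d_vm), params.ip3, params.ec)
        dsm = smc_rhs(smc, (-d_ca, -d_ip3, -d_vm), params.smc)
        return np.concatenate([dec.ravel(), dsm.ravel()])

    y0 = np.array([0.3, 1.0, 0.1, -60.0, g_protein_steady(rho_p2y(atp, params.ip3.K_ATP), params.ip3),
                   0.2, 1.0, 0.1, -50.0, 0.1])
    sol = solve_ivp(rhs, (0.0, t_relax), y0, method="BDF", rtol=1e-8, atol=1e-10)
    y = sol.y[:, -1]
    y_fix, info, ier, _ = fsolve(lambda v: rhs(0.0, v), y, full_output=True)
    if ier == 1 and np.max(np.abs(rhs(0.0, y_fix))) < 1e-9:
        y = y_fix
    return y[:EC_DIM].copy(), y[EC_DIM:].copy()


def _check_finite(state: np.ndarray, kind: str) -> None:
    if not np.all(np.isfinite(state)):
        bad = np.argwhere(~np.isfinite(np.asarray(state)))
        var_names = EC_VARS if kind == "EC" else SMC_VARS
        first = bad[0]
        raise CellStateError(
            f"non-finite {kind} state: variable {var_names[int(first[0])]} "
            f"at cell index {int(first[1]) if len(first) > 1 else 0}")
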