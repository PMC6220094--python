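"""Gap-junctional exchange between neighbouring cells.

Charged species (Ca2+) and membrane potential couple electro-diffusively:
the gap current between cells a and b carries a Fickian term driven by the
concentration difference and a drift term driven by the membrane-potential
difference weighted by the mean concentration,

    I_gap = P_x sigma A F [ grad[phi] + (zF/RT) mean[phi] grad[Vm] ].

IP3 has zero valence, so its exchange is purely Fickian.  At the network
level the lumped coefficient p = P_x sigma A / (V_cell dx) multiplies the
neighbour differences directly, which reproduces the published 1/s coupling
coefficients (electrical g = G/C_m = 1000 1/s homocellular, 50 1/s
heterocellular; Ca2+ and IP3 p = 0.05 1/s).
"""

from __future__ import annotations

import numpy as np

from .params import CouplingParams, FARADAY, GAS_CONSTANT, ParameterError

_ION_VALENCE = {"ca": 2, "ip3": 0, "k": 1, "na": 1, "cl": -1}


def membrane_coupling_coefficient(G_nS: float, C_m_pF: float) -> float:
    """Electrical coupling coefficient g = G / C_m in 1/s.

    nS / pF = 1e-9 S / 1e-12 F = 1000 1/s, so 30 nS across a 30 pF membrane
    gives the published homocellular 1000 1/s.
    """
    if C_m_pF <= 0:
        raise ParameterError("membrane capacitance must be > 0")
    return G_nS / C_m_pF * 1000.0


def conductance_from_resistance(R_MOhm: float) -> float:
    """Gap-junctional conductance in nS from a resistance in MOhm."""
    if R_MOhm <= 0:
        raise ParameterError("resistance must be > 0")
    return 1000.0 / R_MOhm


def electro_diffusive_current(conc_a, conc_b, vm_a, vm_b, ion: str,
                              params: CouplingParams):
    """Gap-junction current from cell a to cell b (amperes).

    Concentrations in uM, potentials in mV.  Positive sign = flux of positive
    charge out of a toward b for a positive concentration/potential excess in
    a.  Antisymmetric under exchange of the two cells; for a neutral species
    (z = 0) the drift term vanishes and the current reduces to the Fickian
    term.
    """
    if ion not in _ION_VALENCE:
        raise ParameterError(f"unknown ion {ion!r}; known: {sorted(_ION_VALENCE)}")
    conc_a, conc_b = np.asarray(conc_a, float), np.asarray(conc_b, float)
    if np.any(conc_a < 0) or np.any(conc_b < 0):
        raise ParameterError("gap-junction concentrations must be >= 0")
    z = _ION_VALENCE[ion]
    # SI: uM -> mol/m^3 is *1e-3; um -> m is *1e-6; um^2 -> m^2 is *1e-12
    p_si = params.sigma * params.A_segment * 1e-12 / (params.dx * 1e-6)  # m^3/s per (P_x in um/s)*1e-6... folded below
    grad = (conc_a - conc_b) * 1e-3          # mol/m^3 difference
    mean = 0.5 * (conc_a + conc_b) * 1e-3    # mol/m^3
    dvm = (vm_a - vm_b) * 1e-3               # V
    drift = z * FARADAY / (GAS_CONSTANT * params.T) * mean * dvm
    # P_x carried in um/s -> m/s
    current = 1e-6 * p_si * FARADAY * (grad + drift)
    out = current
    return float(out) if np.ndim(out) == 0 else out


def membrane_potential_coupling(vm_a, vm_b, coefficient: float):
    """Electrical coupling rate contribution to cell a, g * (vm_b - vm_a), mV/s."""
    if coefficient < 0:
        raise ParameterError("electrical coupling coefficient must be >= 0")
    return coefficient * (np.asarray(vm_b, float) - np.asarray(vm_a, float))


def _neighbor_sums(x: np.ndarray, nbr: np.ndarray) -> np.ndarray:
    """Sum of (x[neighbor] - x[cell]) over the 4-neighbourhood.

    ``nbr`` is (n, 4) with missing neighbours padded by the cell's own index,
    which contributes exactly zero.
    """
    return (x[nbr] - x[:, None]).sum(axis=1)


def _drift_sum(c: np.ndarray, v: np.ndarray, nbr: np.ndarray) -> np.ndarray:
    """Sum over neighbours of mean-concentration-weighted potential differences."""
    cbar = 0.5 * (c[nbr] + c[:, None])
    return (cbar * (v[nbr] - v[:, None])).sum(axis=1)


def coupling_terms(lattice, ec_state: np.ndarray, smc_state: np.ndarray,
                   cp: CouplingParams):
    """Per-cell coupling fluxes for both layers.

    ``ec_state`` is (5, n_ec) [ca, store, ip3, vm, g]; ``smc_state`` is
    (5, n_smc) [ca, store, ip3, vm, w].  Returns two triples
    ``(ca_flux, ip3_flux, vm_flux)``, one for the EC layer and one for the
    SMC layer (uM/s, uM/s, mV/s).  Pairwise antisymmetry makes every
    species' global flux sum vanish.
    """
    ec_ca, _, ec_ip3, ec_vm = ec_state[0], ec_state[1], ec_state[2], ec_state[3]
    smc_ca, _, smc_ip3, smc_vm = smc_state[0], smc_state[1], smc_state[2], smc_state[3]
    n_ec, n_smc = ec_ca.shape[0], smc_ca.shape[0]
    enb, snb = lattice.ec_neighbors, lattice.smc_neighbors
    if enb.size and enb.max() >= n_ec:
        raise IndexError("dangling EC neighbour index in lattice")
    if snb.size and snb.max() >= n_smc:
        raise IndexError("dangling SMC neighbour index in lattice")
    df = cp.drift_factor_ca

    # --- homocellular ---
    ec_ca_f = cp.p_ca_homo_ec * (_neighbor_sums(ec_ca, enb)
                                 + df * _drift_sum(ec_ca, ec_vm, enb))
    ec_ip3_f = cp.p_ip3_homo_ec * _neighbor_sums(ec_ip3, enb)
    ec_vm_f = cp.g_homo_ec * _neighbor_sums(ec_vm, enb)
    smc_ca_f = cp.p_ca_homo_smc * (_neighbor_sums(smc_ca, snb)
                                   + df * _drift_sum(smc_ca, smc_vm, snb))
    smc_ip3_f = cp.p_ip3_homo_smc * _neighbor_sums(smc_ip3, snb)
    smc_vm_f = cp.g_homo_smc * _neighbor_sums(smc_vm, snb)

    # --- heterocellular (myoendothelial), weighted links ---
    W = lattice.hetero_w          # (n_ec, n_smc) sparse, row sums 1
    WT = lattice.hetero_wt
    row = lattice.hetero_rowsum   # (n_ec,)
    col = lattice.hetero_colsum   # (n_smc,)

    ec_ca_f += cp.p_ca_hetero * ((W @ smc_ca - row * ec_ca)
                                 + df * _hetero_drift(W, ec_ca, ec_vm,
                                                      smc_ca, smc_vm, row))
    smc_ca_f += cp.p_ca_hetero * ((WT @ ec_ca - col * smc_ca)
                                  + df * _hetero_drift(WT, smc_ca, smc_vm,
                                                       ec_ca, ec_vm, col))
    ec_ip3_f += cp.p_ip3_hetero * (W @ smc_ip3 - row * ec_ip3)
    smc_ip3_f += cp.p_ip3_hetero * (WT @ ec_ip3 - col * smc_ip3)
    ec_vm_f += cp.g_hetero * (W @ smc_vm - row * ec_vm)
    smc_vm_f += cp.g_hetero * (WT @ ec_vm - col * smc_vm)

    return (ec_ca_f, ec_ip3_f, ec_vm_f), (smc_ca_f, smc_ip3_f, smc_vm_f)


def _hetero_drift(W, c_self, v_self, c_other, v_other, rowsum):
    """Sum over weighted links of 0.5 (c_a + c_b) (v_b - v_a) for the a-side."""
    return 0.5 * (c_self * (W @ v_other - rowsum * v_self)
                  + W @ (c_other * v_other) - v_self * (W @ c_other))
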