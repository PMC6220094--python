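"""Model parameter containers and the packaged reference parameter set.

Unit conventions used throughout the package: concentrations in uM,
membrane potential in mV, time in s, lengths in mm (geometry) or um
(single-cell dimensions), capacitance in pF, conductance in nS or pS
as stated per field.

The single-cell flux constants follow the published Koenigsberger-family
coupled EC/SMC formulations (SMC dynamics after Parthimos; EC
electrophysiology after Schuster), with the endothelial agonist->IP3
limb replaced by an explicit P2Y/G-protein/PLC cascade in the style of
Lemon and Bennett.  Every constant lives in ``data/reference_params.yaml``
so a run can pin and hash the exact physiology it used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Faraday constant, C/mol
FARADAY = 96485.33212
#: Gas constant, J/(mol K)
GAS_CONSTANT = 8.31446261815324
#: Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23


class ParameterError(ValueError):
    """Raised for invalid, unknown or non-physical parameter values."""


@dataclass(frozen=True)
class IP3PathwayParams:
    """Constants of the endothelial ATP -> P2Y -> G-protein -> PLC -> IP3 limb.

    ``epsilon = u_c / (N_a * V_EC)`` converts a molecule count rate into a
    cytosolic concentration rate (uM/s per molecule/s).
    """

    alpha: float = 2.8e-7        # effective PLC signal gain, 1/s per G-protein molecule
    K_Ca: float = 0.4            # Ca2+-PLC dissociation constant, uM
    k_a: float = 0.017           # G-protein activation rate, 1/s
    k_d: float = 0.15            # G-protein deactivation rate, 1/s
    delta: float = 1.234e-3      # intrinsic (agonist-free) G-protein activity, dimensionless
    G_prot_tot: float = 1.0e5    # total G-protein molecules per EC
    K_ATP: float = 0.025         # effective Michaelis constant of ATP-P2Y binding, uM
    PIP2_tot: float = 5.0e7      # total PIP2 molecules per EC (treated as constant)
    u_c: float = 1.0e6           # unit conversion mol/L -> uM
    V_EC: float = 1.0e-12        # EC cytosolic volume, L
    k_deg: float = 0.1           # first-order IP3 degradation rate, 1/s

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "delta":
                if v < 0:
                    raise ParameterError("delta must be >= 0")
            elif not v > 0:
                raise ParameterError(f"IP3 pathway constant {f.name} must be > 0, got {v}")

    @property
    def epsilon(self) -> float:
        """Molecules -> uM conversion factor, uM per molecule."""
        return self.u_c / (AVOGADRO * self.V_EC)


@dataclass(frozen=True)
class ECParams:
    """Endothelial single-cell flux constants (Schuster-style electrophysiology)."""

    F_ip3: float = 0.23     # max IP3R store release, uM/s
    K_r: float = 1.0        # IP3R half-activation, uM
    B: float = 0.5          # max SERCA uptake, uM/s
    c_b: float = 1.0        # SERCA half-activation, uM
    C_cicr: float = 5.0     # max CICR release, uM/s
    s_c: float = 2.0        # CICR store half-activation, uM
    c_c: float = 0.9        # CICR cytosolic half-activation, uM
    D_extr: float = 0.24    # Ca2+ extrusion rate, 1/s
    L: float = 0.025        # store leak rate, 1/s
    G_cat: float = 6.6e-4   # nonselective cation conductance, uM/(mV s)
    E_Ca: float = 50.0      # Ca2+ Nernst potential, mV
    m3_cat: float = -0.18   # cation-channel activation midpoint, log10(uM)
    m4_cat: float = 0.37    # cation-channel activation slope, log10(uM)
    J0: float = 0.029       # constant background Ca2+ influx, uM/s
    G_tot: float = 6927.0   # total K+ (BKCa+SKCa) conductance, pS
    v_K: float = -80.0      # K+ Nernst potential, mV
    a1: float = 53.3        # BKCa gating constant, mV
    a2: float = 53.3        # BKCa gating constant, mV per log10(uM)
    b1: float = -80.8       # BKCa gating constant, mV
    c1: float = -0.4        # BKCa Ca2+ offset, log10(uM)
    m3b: float = 1.32e-3    # BKCa gating curvature, 1/mV^2
    m4b: float = 0.30       # BKCa gating floor, mV... dimensionless denominator floor
    m3s: float = -0.28      # SKCa activation midpoint, log10(uM)
    m4s: float = 0.389      # SKCa activation slope, log10(uM)
    G_R: float = 955.0      # residual (monovalent) conductance, pS
    v_rest: float = -31.1   # residual-current reversal, mV
    C_m: float = 25.8       # EC membrane capacitance, pF

    def __post_init__(self) -> None:
        positive = ("F_ip3", "K_r", "B", "c_b", "C_cicr", "s_c", "c_c", "D_extr",
                    "L", "G_cat", "G_tot", "G_R", "C_m", "m4_cat", "m4s", "m3b", "m4b")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"EC constant {name} must be > 0")


@dataclass(frozen=True)
class SMCParams:
    """Smooth-muscle single-cell flux constants (Parthimos-style dynamics)."""

    F_ip3: float = 0.23       # max IP3R store release, uM/s
    K_r: float = 1.0          # IP3R half-activation, uM
    G_Ca: float = 1.29e-3     # VOCC conductance, uM/(mV s)
    v_Ca1: float = 100.0      # VOCC reversal, mV
    v_Ca2: float = -24.0      # VOCC activation midpoint, mV
    R_Ca: float = 8.5         # VOCC activation slope, mV
    G_NaCa: float = 3.16e-3   # Na+/Ca2+ exchanger conductance, uM/(mV s)
    c_NaCa: float = 0.5       # exchanger Ca2+ half-activation, uM
    v_NaCa: float = -30.0     # exchanger reversal, mV
    B: float = 2.025          # max SERCA uptake, uM/s
    c_b: float = 1.0          # SERCA half-activation, uM
    C_cicr: float = 55.0      # max CICR release, uM/s
    s_c: float = 2.0          # CICR store half-activation, uM
    c_c: float = 0.9          # CICR cytosolic half-activation, uM
    D_extr: float = 0.24      # Ca2+ extrusion rate, 1/s
    v_d: float = -100.0       # extrusion voltage offset, mV
    R_d: float = 250.0        # extrusion voltage scale, mV
    L: float = 0.025          # store leak rate, 1/s
    gamma: float = 1970.0     # flux -> membrane-potential conversion, mV/uM
    F_NaK: float = 0.0432     # Na+/K+-ATPase current term, uM/s
    G_Cl: float = 1.34e-3     # Cl- conductance, uM/(mV s)
    v_Cl: float = -25.0       # Cl- reversal, mV
    G_K: float = 4.46e-3      # K+ conductance, uM/(mV s)
    v_K: float = -94.0        # K+ reversal, mV
    lam: float = 45.0         # K+ open-state relaxation rate, 1/s
    c_w: float = 0.0          # Ca2+ shift of K+ activation, uM
    beta: float = 0.13        # K+ activation voltage weight, uM^2
    v_Ca3: float = -27.0      # K+ activation midpoint, mV
    R_K: float = 12.0         # K+ activation slope, mV
    k_deg: float = 0.1        # first-order IP3 degradation, 1/s
    C_m: float = 10.0         # SMC membrane capacitance, pF

    def __post_init__(self) -> None:
        positive = ("F_ip3", "K_r", "G_Ca", "R_Ca", "G_NaCa", "c_NaCa", "B", "c_b",
                    "C_cicr", "s_c", "c_c", "D_extr", "R_d", "L", "gamma", "F_NaK",
                    "G_Cl", "G_K", "lam", "beta", "R_K", "k_deg", "C_m")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"SMC constant {name} must be > 0")


@dataclass(frozen=True)
class CouplingParams:
    """Gap-junction coupling coefficients and electro-diffusion constants.

    The electrical coefficients are g = G/C_m rates (1/s); the Ca2+ and IP3
    coefficients are the dimensionless-per-second lumped permeabilities
    p = P_x sigma A_segment / (V_cell dx) applied to neighbour concentration
    differences.  The drift (electro-diffusive) term of the gap current adds
    z F / (R T) * mean-concentration * neighbour potential difference.
    """

    g_homo_smc: float = 1000.0   # SMC-SMC electrical coupling, 1/s
    g_homo_ec: float = 1000.0    # EC-EC electrical coupling, 1/s
    g_hetero: float = 50.0       # EC-SMC electrical coupling, 1/s
    p_ca_homo_smc: float = 0.05  # SMC-SMC Ca2+ coupling, 1/s
    p_ca_homo_ec: float = 0.05   # EC-EC Ca2+ coupling, 1/s
    p_ca_hetero: float = 0.05    # EC-SMC Ca2+ coupling, 1/s
    p_ip3_homo_smc: float = 0.05   # SMC-SMC IP3 coupling, 1/s
    p_ip3_homo_ec: float = 0.05    # EC-EC IP3 coupling, 1/s
    p_ip3_hetero: float = 0.05   # EC-SMC IP3 coupling, 1/s
    z_ca: int = 2                # Ca2+ valence
    z_ip3: int = 0               # IP3 valence (Fickian only)
    T: float = 293.0             # absolute temperature, K
    sigma: float = 1.0           # gap-junction scaling factor in the current form
    A_segment: float = 50.0      # neighbour interface area, um^2
    dx: float = 0.8              # intercellular (junctional) distance, um
    V_cell: float = 1.0e-12      # cell volume used for current->rate conversion, L

    def __post_init__(self) -> None:
        for name in ("g_homo_smc", "g_homo_ec", "g_hetero", "p_ca_homo_smc",
                     "p_ca_homo_ec", "p_ca_hetero", "p_ip3_homo_smc",
                     "p_ip3_homo_ec", "p_ip3_hetero", "sigma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"coupling coefficient {name} must be >= 0")
        if not self.T > 0:
            raise ParameterError("temperature must be > 0 K")

    @property
    def drift_factor_ca(self) -> float:
        """z F / (R T) in 1/mV, the electro-diffusive drift weight for Ca2+."""
        return self.z_ca * FARADAY / (GAS_CONSTANT * self.T) * 1e-3


@dataclass(frozen=True)
class PhosphoParams:
    """Zero-order ultrasensitive phosphorylation cycle driven by cytosolic Ca2+.

    W* is the phosphorylated fraction; with W_T normalised to 1 both maximum
    rates are in 1/s.  K_1, K_2 << 1 put the cycle in the zero-order regime
    where the steady state switches sharply at v_k / v_p = 1.
    """

    v_p: float = 1.0     # max phosphatase rate (x W_T), 1/s
    W_T: float = 1.0     # total protein, normalised
    K_1: float = 0.01    # reduced kinase Michaelis constant
    K_2: float = 0.01    # reduced phosphatase Michaelis constant
    V_MK: float = 2.5    # max kinase rate (x W_T), 1/s
    K_a: float = 0.5     # Ca2+ half-activation of the kinase, uM

    def __post_init__(self) -> None:
        for f in fields(self):
            if not getattr(self, f.name) > 0:
                raise ParameterError(f"phosphorylation constant {f.name} must be > 0")


@dataclass(frozen=True)
class ModelParams:
    """Bundle of every physiological constant a simulation consumes."""

    ip3: IP3PathwayParams = IP3PathwayParams()
    ec: ECParams = ECParams()
    smc: SMCParams = SMCParams()
    coupling: CouplingParams = CouplingParams()
    phospho: PhosphoParams = PhosphoParams()

    def to_dict(self) -> dict[str, dict[str, Any]]:
        return {name: dataclasses.asdict(getattr(self, name))
                for name in ("ip3", "ec", "smc", "coupling", "phospho")}


_BLOCKS = {
    "ip3": IP3PathwayParams,
    "ec": ECParams,
    "smc": SMCParams,
    "coupling": CouplingParams,
    "phospho": PhosphoParams,
}


def params_from_dict(d: Mapping[str, Any]) -> ModelParams:
    """Build a :class:`ModelParams` from nested dicts; unknown keys are errors."""
    kwargs = {}
    for block, payload in d.items():
        if block not in _BLOCKS:
            raise ParameterError(f"unknown parameter block {block!r}")
        cls = _BLOCKS[block]
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ParameterError(
                f"unknown key(s) {sorted(unknown)} in parameter block {block!r}")
        kwargs[block] = cls(**payload)
    return ModelParams(**kwargs)


def load_params(path: str | Path) -> ModelParams:
    """Load a parameter file (YAML, nested block/key/value)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParameterError(f"parameter file {path} does not hold a mapping")
    return params_from_dict(data)


def save_params(params: ModelParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def reference_params() -> ModelParams:
    """The packaged reference parameter set."""
    ref = resources.files("vasowave").joinpath("data/reference_params.yaml")
    with resources.as_file(ref) as p:
        return load_params(p)
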