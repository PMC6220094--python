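import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from vasowave import cell_models as cm
from vasowave.agonist import uniform_atp_map
from vasowave.coupling import (conductance_from_resistance, coupling_terms,
                               electro_diffusive_current,
                               membrane_coupling_coefficient,
                               membrane_potential_coupling)
from vasowave.fixtures import chain_lattice, pair_lattice, patch_lattice
from vasowave.params import CouplingParams, ParameterError
from vasowave.simulator import CoupledSystem, SimulationConfig, run_simulation


class TestCouplingCoefficients:
    def test_homocellular_electrical_coefficient(self):
        """30 nS across a 30 pF membrane gives the published 1000 1/s."""
        assert membrane_coupling_coefficient(30.0, 30.0) == pytest.approx(1000.0)

    def test_conductance_from_resistance(self):
        """A 3 MOhm junction corresponds to 333 nS."""
        assert conductance_from_resistance(3.0) == pytest.approx(333.33, rel=1e-3)

    def test_heterocellular_coefficient_order_50(self):
        """900 MOhm / ~20 pF myoendothelial junction -> ~50 1/s."""
        g = membrane_coupling_coefficient(conductance_from_resistance(900.0), 20.0)
        assert g == pytest.approx(55.6, rel=0.01)
        assert abs(g - 50.0) / 50.0 < 0.15

    def test_no_gradient_no_coupling(self):
        assert membrane_potential_coupling(-40.0, -40.0, 1000.0) == 0.0

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ParameterError):
            membrane_potential_coupling(-40.0, -50.0, -1.0)


class TestElectroDiffusiveCurrent:
    def test_zero_at_equal_states(self, params):
        cp = params.coupling
        assert electro_diffusive_current(0.5, 0.5, -40.0, -40.0, "ca", cp) == 0.0

    def test_neutral_species_is_pure_fickian(self, params):
        """Zero valence kills the drift term: the current ignores Vm."""
        cp = params.coupling
        i1 = electro_diffusive_current(1.0, 0.2, -40.0, -80.0, "ip3", cp)
        i2 = electro_diffusive_current(1.0, 0.2, 0.0, 0.0, "ip3", cp)
        assert i1 == pytest.approx(i2)
        assert i1 != 0.0

    @given(st.floats(0.0, 2.0), st.floats(0.0, 2.0),
           st.floats(-80.0, 0.0), st.floats(-80.0, 0.0))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_exchange(self, ca, cb, va, vb):
        cp = CouplingParams()
        fwd = electro_diffusive_current(ca, cb, va, vb, "ca", cp)
        bwd = electro_diffusive_current(cb, ca, vb, va, "ca", cp)
        assert fwd == pytest.approx(-bwd, abs=1e-18)

    def test_drift_term_follows_potential_gradient(self, params):
        cp = params.coupling
        base = electro_diffusive_current(0.5, 0.5, -40.0, -50.0, "ca", cp)
        assert base > 0.0      # positive charge flows down the potential drop

    def test_unknown_ion_rejected(self, params):
        with pytest.raises(ParameterError, match="unknown ion"):
            electro_diffusive_current(0.5, 0.5, -40.0, -40.0, "mg", params.coupling)


class TestNetworkCouplingTerms:
    def test_uniform_state_gives_zero_flux(self, one_domain, params):
        ec = np.tile(np.array([0.5, 1.0, 0.3, -40.0, 100.0])[:, None],
                     (1, one_domain.n_ec))
        smc = np.tile(np.array([0.2, 1.2, 0.1, -45.0, 0.1])[:, None],
                      (1, one_domain.n_smc))
        (eca, eip, evm), (sca, sip, svm) = coupling_terms(
            one_domain, ec, smc, params.coupling)
        # homocellular terms vanish; heterocellular terms see the EC/SMC offset
        ec2 = ec.copy()
        ec2[0] = smc[0, 0]
        ec2[2] = smc[2, 0]
        ec2[3] = smc[3, 0]
        (eca, eip, evm), (sca, sip, svm) = coupling_terms(
            one_domain, ec2, smc, params.coupling)
        for arr in (eca, eip, evm, sca, sip, svm):
            assert np.allclose(arr, 0.0, atol=1e-9)

    def test_global_flux_sums_vanish(self, one_domain, params, rng):
        """Pairwise antisymmetry conserves every species globally."""
        ec = np.abs(rng.normal(0.5, 0.2, (5, one_domain.n_ec)))
        smc = np.abs(rng.normal(0.3, 0.1, (5, one_domain.n_smc)))
        ec[3] = rng.normal(-40, 5, one_domain.n_ec)
        smc[3] = rng.normal(-45, 5, one_domain.n_smc)
        (eca, eip, evm), (sca, sip, svm) = coupling_terms(
            one_domain, ec, smc, params.coupling)
        assert eca.sum() + sca.sum() == pytest.approx(0.0, abs=1e-9)
        assert eip.sum() + sip.sum() == pytest.approx(0.0, abs=1e-9)
        # electrical coupling is antisymmetric per medium as well
        cp0 = dataclasses.replace(params.coupling, p_ca_homo_ec=0.0,
                                  p_ca_homo_smc=0.0, p_ca_hetero=0.0)
        (_, _, evm), (_, _, svm) = coupling_terms(one_domain, ec, smc, cp0)
        assert evm.sum() + svm.sum() == pytest.approx(0.0, abs=1e-7)

    def test_dangling_neighbor_rejected(self, params):
        lat = pair_lattice()
        lat.ec_neighbors = np.array([[0, 0, 0, 5]])
        ec = np.zeros((5, 1))
        smc = np.zeros((5, 1))
        with pytest.raises(IndexError, match="dangling"):
            coupling_terms(lat, ec, smc, params.coupling)

    def test_two_cell_closed_system_conserves_species(self, params):
        """Two SMCs exchanging Ca2+/IP3 with degradation and membrane fluxes
        disabled keep their summed concentrations constant."""
        off = 1e-300
        smc = dataclasses.replace(
            params.smc, F_ip3=off, G_Ca=off, G_NaCa=off, D_extr=off,
            F_NaK=off, G_Cl=off, G_K=off, k_deg=off, B=off, C_cicr=off, L=off)
        p = dataclasses.replace(params, smc=smc)
        lat = chain_lattice(2, "smc")
        system = CoupledSystem(lat, np.empty(0), p)
        y0 = system.pack(np.empty((5, 0)),
                         np.array([[0.8, 0.2], [1.0, 1.0], [0.5, 0.1],
                                   [-40.0, -40.0], [0.1, 0.1]]))
        sol = solve_ivp(system.rhs, (0, 50), y0, method="BDF",
                        rtol=1e-10, atol=1e-12)
        _, smc_t = system.unpack(sol.y[:, -1])
        assert smc_t[0].sum() + 0.0 == pytest.approx(1.0, abs=1e-6)   # Ca
        assert smc_t[2].sum() == pytest.approx(0.6, abs=1e-6)         # IP3


class TestDecouplingLimit:
    def test_zero_coupling_equals_independent_rhs(self, params, rng):
        """With every coefficient zero the network RHS is exactly the
        concatenation of the single-cell RHS."""
        cp0 = CouplingParams(g_homo_smc=0, g_homo_ec=0, g_hetero=0,
                             p_ca_homo_smc=0, p_ca_homo_ec=0, p_ca_hetero=0,
                             p_ip3_homo_smc=0, p_ip3_homo_ec=0, p_ip3_hetero=0)
        p = dataclasses.replace(params, coupling=cp0)
        lat = patch_lattice(1, 1)
        atp = uniform_atp_map(lat.n_ec, 0.7)
        system = CoupledSystem(lat, atp, p)
        ec = np.abs(rng.normal(0.5, 0.1, (5, lat.n_ec)))
        smc = np.abs(rng.normal(0.3, 0.1, (5, lat.n_smc)))
        ec[3], smc[3] = -40.0, -45.0
        ec[4] = 50.0
        y = system.pack(ec, smc)
        full = system.rhs(0.0, y)
        dec = cm.ec_rhs(ec, atp.atp, (0.0, 0.0, 0.0), p.ip3, p.ec)
        dsm = cm.smc_rhs(smc, (0.0, 0.0, 0.0), p.smc)
        assert np.array_equal(full, system.pack(dec, dsm))


class TestSynchronization:
    def test_five_coupled_smcs_synchronize(self, params):
        """Ca2+ + electrical coupling phase-locks five oscillating SMCs.

        The five SMC oscillators sit in their wall unit (each with its
        myoendothelial EC partner, as on the vessel); homocellular Ca2+ and
        electrical coupling then pull the initially dephased oscillations
        into a common phase.
        """
        lat = chain_lattice(5, "both")
        system = CoupledSystem(lat, uniform_atp_map(5, 0.0), params,
                               smc_ip3_clamp=1.0)
        cfg = SimulationConfig(duration=400.0, record_interval=0.5, seed=11,
                               ic_perturbation=0.02)
        rec = run_simulation(system, cfg)
        ca = rec.smc[:, 0, :]
        t = rec.times
        early = ca[(t >= 20) & (t < 70)]
        late = ca[t >= 340]
        spread_early = np.ptp(early, axis=1).max()
        spread_late = np.ptp(late, axis=1).max()
        assert spread_early > 0.05               # started dephased
        assert spread_late < 0.02                # phase differences -> 0
        assert np.ptp(late[:, 2]) > 0.3          # still oscillating

    def test_perturbation_spreads_monotonically_outward(self, params):
        """A local Ca2+ kick in a quiescent chain diffuses outward without
        exciting remote cells first."""
        lat = chain_lattice(9, "smc")
        system = CoupledSystem(lat, np.empty(0), params, smc_ip3_clamp=0.3)
        y0 = system.initial_state(seed=0, perturbation=0.0)
        _, smc0 = system.unpack(y0.copy())
        smc0 = smc0.copy()
        smc0[0, 4] += 0.4                         # kick the centre cell
        y0 = system.pack(np.empty((5, 0)), smc0)
        rec = run_simulation(system, SimulationConfig(
            duration=5.0, record_interval=0.25, seed=0, ic_perturbation=0.0),
            y0=y0)
        dev = np.abs(rec.smc[:, 0, :] - rec.smc[0, 0, :][None, :])
        profile = dev[4] - dev[4, 0]              # snapshot at 1 s, drift removed
        left, right = profile[:5], profile[4:]
        tol = 1e-3                                 # collective relaxation noise
        assert np.all(np.diff(left) >= -tol)      # grows toward the centre
        assert np.all(np.diff(right) <= tol)      # decays away from it
        assert profile[4] > 10 * max(profile[0], profile[-1])
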