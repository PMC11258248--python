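"""Surface-hopping engine: electronic propagation, hops, decoherence,
initial sampling and trajectory-level invariants."""

import numpy as np
import pytest

from polyhop.constants import AMU_A2_FS2_TO_EV, HBAR_EV_FS
from polyhop.fssh import (InitialCondition, SHSettings, apply_hop,
                          decoherence_correct, electronic_step,
                          hop_probabilities, propagate_trajectory,
                          run_ensemble, sample_initial_conditions)
from polyhop.models import AvoidedCrossing1D, HarmonicModel

import oracles


def uncoupled_two_state():
    return HarmonicModel(offsets=[0.0, 1.0], curvatures=[[1.0], [1.0]],
                         centers=[[0.0], [0.1]], masses=[10.0], coupling=0.0)


class TestElectronicStep:
    def test_identity_overlap_equal_energies_is_global_phase(self):
        c0 = np.array([0.6, 0.8], dtype=complex)
        c1, _ = electronic_step(c0, np.eye(2), [1.3, 1.3], [1.3, 1.3],
                                0.1, substeps=10)
        phase = c1[0] / c0[0]
        assert abs(abs(phase) - 1) < 1e-12
        np.testing.assert_allclose(c1, phase * c0, atol=1e-12)

    def test_free_evolution_relative_phase(self):
        gap = 0.5
        dt = 0.2
        c0 = np.array([1.0, 1.0], dtype=complex) / np.sqrt(2)
        c1, _ = electronic_step(c0, np.eye(2), [0.0, gap], [0.0, gap],
                                dt, substeps=20)
        rel = np.angle(c1[1] / c1[0])
        assert rel == pytest.approx(-gap * dt / HBAR_EV_FS, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_expm_oracle(self, seed):
        rng = np.random.default_rng(seed)
        th = rng.normal(0.0, 0.03)
        overlap = np.array([[np.cos(th), -np.sin(th)],
                            [np.sin(th), np.cos(th)]])
        e0 = rng.normal(0.0, 1.0, 2)
        e1 = e0 + rng.normal(0.0, 0.05, 2)
        c0 = rng.normal(size=2) + 1j * rng.normal(size=2)
        c0 /= np.linalg.norm(c0)
        c1, _ = electronic_step(c0, overlap, e0, e1, 0.1, substeps=400)
        ref = oracles.expm_propagate(c0, overlap, e0, e1, 0.1)
        np.testing.assert_allclose(c1, ref, atol=1e-8)

    def test_norm_conserved_tightly(self, rng):
        c0 = rng.normal(size=3) + 1j * rng.normal(size=3)
        c0 /= np.linalg.norm(c0)
        th = 0.02
        overlap = np.eye(3)
        overlap[:2, :2] = [[np.cos(th), -np.sin(th)],
                           [np.sin(th), np.cos(th)]]
        c1, _ = electronic_step(c0, overlap, [0, 1, 2], [0, 1.1, 2], 0.1)
        assert abs(np.sum(np.abs(c1) ** 2) - 1.0) < 1e-10


class TestHopProbabilities:
    def test_no_flux_out_of_active_gives_zero(self):
        c = np.array([1.0, 0.0], dtype=complex)
        flux = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert np.all(hop_probabilities(0, c, flux) == 0)

    def test_contrived_flux_clipped_to_sum_one(self):
        c = np.array([0.9, np.sqrt(1 - 0.81), 0.0], dtype=complex)
        # active loses nearly everything; attributions exceed the loss
        flux = np.array([[0.01, 0.0, 0.0],
                         [5.0, 0.0, 0.0],
                         [5.0, 0.0, 0.0]])
        g = hop_probabilities(0, c, flux)
        assert np.all((g >= 0) & (g <= 1))
        assert g.sum() <= 1.0 + 1e-12

    def test_two_state_probability_equals_population_loss_fraction(self):
        # Rabi-type mixing through an overlap rotation
        rng = np.random.default_rng(5)
        th = 0.04
        overlap = np.array([[np.cos(th), -np.sin(th)],
                            [np.sin(th), np.cos(th)]])
        c0 = np.array([0.9, 0.1 + 0.2j], dtype=complex)
        c0 /= np.linalg.norm(c0)
        e0, e1 = [0.0, 0.4], [0.0, 0.45]
        c1, flux = electronic_step(c0, overlap, e0, e1, 0.1, substeps=100)
        g = hop_probabilities(0, c0, flux)
        ref = oracles.expm_propagate(c0, overlap, e0, e1, 0.1)
        loss = 1.0 - abs(ref[0]) ** 2 / abs(c0[0]) ** 2
        assert g[1] == pytest.approx(max(loss, 0.0), abs=1e-6)

    def test_vanishing_active_population_warns_and_zeroes(self):
        c = np.array([0.0, 1.0], dtype=complex)
        with pytest.warns(RuntimeWarning):
            g = hop_probabilities(0, c, np.zeros((2, 2)))
        assert np.all(g == 0)


class TestApplyHop:
    masses = np.array([10.0])

    def kinetic(self, v):
        return 0.5 * float(self.masses[0]) * v ** 2 * AMU_A2_FS2_TO_EV

    def test_downhill_hop_gains_exactly_the_gap(self):
        v = np.array([0.05])
        energies = np.array([0.0, 1.0])
        ke0 = self.kinetic(v[0])
        v1, new, frustrated = apply_hop(None, v, 1, 0, energies, self.masses)
        assert not frustrated and new == 0
        assert self.kinetic(v1[0]) == pytest.approx(ke0 + 1.0, rel=1e-12)

    def test_uphill_without_kinetic_energy_is_frustrated(self):
        v = np.array([0.01])
        energies = np.array([0.0, 1.0])
        v1, new, frustrated = apply_hop(None, v, 0, 1, energies, self.masses)
        assert frustrated and new == 0
        np.testing.assert_array_equal(v1, v)
        v2, _, _ = apply_hop(None, v, 0, 1, energies, self.masses,
                             policy="reverse")
        np.testing.assert_array_equal(v2, -v)

    def test_uphill_rescale_factor_closed_form(self):
        v = np.array([0.2])
        energies = np.array([0.0, 1.0])
        ke = self.kinetic(v[0])
        v1, new, frustrated = apply_hop(None, v, 0, 1, energies, self.masses)
        assert not frustrated and new == 1
        assert v1[0] / v[0] == pytest.approx(np.sqrt(1 - 1.0 / ke), rel=1e-12)


class TestDecoherence:
    def test_scheme_none_leaves_coeffs_unchanged(self):
        c = np.array([0.6, 0.8j], dtype=complex)
        out = decoherence_correct(c, 0, "none", {}, {})
        np.testing.assert_array_equal(out, c)

    def test_overlap_collapse_puts_all_population_on_active(self):
        c = np.array([0.6, 0.8], dtype=complex)
        out = decoherence_correct(c, 0, "overlap", {"collapse_threshold": 1e-3},
                                  {"overlaps": np.array([1.0, 1e-5])})
        assert abs(out[0]) == pytest.approx(1.0, abs=1e-12)
        assert out[1] == 0

    def test_energy_based_damping_matches_closed_form(self):
        gap, ekin, dt, cconst = 0.8, 0.5, 0.1, 2.72114
        c = np.array([np.sqrt(0.7), np.sqrt(0.3)], dtype=complex)
        out = decoherence_correct(
            c, 0, "energy_based", {"energy_constant": cconst},
            {"dt": dt, "gaps": np.array([0.0, gap]), "kinetic_energy": ekin})
        tau = HBAR_EV_FS / gap * (1 + cconst / ekin)
        expected = np.sqrt(0.3) * np.exp(-dt / tau)
        assert abs(out[1]) == pytest.approx(expected, rel=1e-12)
        assert np.sum(np.abs(out) ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            decoherence_correct(np.array([1.0 + 0j, 0]), 0, "magic", {}, {})


class TestInitialSampling:
    coords = np.zeros((50, 1))
    vels = np.zeros((50, 1))

    def test_single_nonzero_dipole_always_chosen(self):
        mu = np.tile([0.0, 0.0, 1.4], (50, 1))
        out = sample_initial_conditions(self.coords, self.vels, mu, 200, 3)
        assert all(ic.state == 2 for ic in out)

    def test_equal_dipoles_split_evenly(self):
        mu = np.tile([0.0, 1.0, 1.0], (50, 1))
        out = sample_initial_conditions(self.coords, self.vels, mu, 10000, 4)
        frac = np.mean([ic.state == 1 for ic in out])
        assert abs(frac - 0.5) < 0.02

    def test_one_two_dipole_weights_within_binomial_3sigma(self):
        mu = np.tile([0.0, 1.0, np.sqrt(2.0)], (50, 1))  # |μ|² weights 1:2
        n = 8000
        out = sample_initial_conditions(self.coords, self.vels, mu, n, 5)
        frac = np.mean([ic.state == 2 for ic in out])
        sigma = np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(frac - 2 / 3) < 3 * sigma

    def test_all_zero_dipoles_raise(self):
        with pytest.raises(ValueError):
            sample_initial_conditions(self.coords, self.vels,
                                      np.zeros((50, 3)), 5, 0)

    def test_reproducible_under_seed(self):
        mu = np.tile([0.0, 1.0, 1.0], (50, 1))
        a = sample_initial_conditions(self.coords, self.vels, mu, 50, 11)
        b = sample_initial_conditions(self.coords, self.vels, mu, 50, 11)
        assert [x.state for x in a] == [x.state for x in b]


class TestPropagation:
    def test_uncoupled_model_never_hops(self):
        model = uncoupled_two_state()
        init = InitialCondition(np.array([0.05]), np.array([0.01]), 1)
        st = SHSettings(total_time=50.0, decoherence_scheme="none",
                        rng_seed=0, electronic_substeps=20)
        rec, hops = propagate_trajectory(init, model, st)
        assert hops == []
        assert rec.active[-1] == 1
        assert np.abs(rec.coeffs[-1, 1]) ** 2 >= 1 - 1e-8
        assert rec.n_frames == st.n_steps + 1

    def test_single_state_harmonic_energy_conservation(self):
        # soft mode: period ~640 fs, velocity-Verlet error well below 1e-6
        model = HarmonicModel(offsets=[0.0], curvatures=[[0.1]],
                              centers=[[0.0]], masses=[10.0])
        init = InitialCondition(np.array([0.3]), np.array([0.0]), 0)
        st = SHSettings(total_time=1000.0, decoherence_scheme="none",
                        electronic_substeps=1, rng_seed=0)
        rec, _ = propagate_trajectory(init, model, st)
        etot = (rec.energies[:, 0]
                + 0.5 * 10.0 * rec.velocities[:, 0] ** 2 * AMU_A2_FS2_TO_EV)
        assert np.max(np.abs(etot - etot[0])) < 1e-6 * abs(etot[0])

    def test_same_seed_bitwise_identical(self):
        model = AvoidedCrossing1D()
        init = InitialCondition(np.array([-6.0]), np.array([0.22]), 0)
        st = SHSettings(total_time=40.0, decoherence_scheme="overlap",
                        electronic_substeps=20, rng_seed=17)
        rec1, _ = propagate_trajectory(init, model, st)
        rec2, _ = propagate_trajectory(init, model, st)
        assert np.array_equal(rec1.coords, rec2.coords)
        assert np.array_equal(rec1.coeffs, rec2.coeffs)
        assert np.array_equal(rec1.active, rec2.active)

    def test_hops_conserve_energy_and_change_state(self):
        model = AvoidedCrossing1D()
        rng = np.random.default_rng(2)
        inits = [InitialCondition(np.array([-6.0 + rng.normal(0, 1.0)]),
                                  np.array([0.22]), 0) for _ in range(20)]
        st = SHSettings(total_time=80.0, decoherence_scheme="none",
                        electronic_substeps=20, rng_seed=0)
        recs = run_ensemble(inits, model, st, base_seed=50)
        n_hops = 0
        for rec in recs:
            rec.validate()
            ke = 0.5 * 1.0972 * rec.velocities[:, 0] ** 2 * AMU_A2_FS2_TO_EV
            etot = ke + rec.energies[np.arange(rec.n_frames), rec.active]
            # total energy conserved through hops (NVE + rescaling)
            assert np.max(np.abs(etot - etot[0])) < 2e-3
            for h in rec.hops:
                assert h.from_state != h.to_state
                n_hops += len(rec.hops)
        assert n_hops > 0  # the ensemble actually crossed

    def test_coefficient_norm_along_trajectory(self):
        model = AvoidedCrossing1D()
        init = InitialCondition(np.array([-6.0]), np.array([0.22]), 0)
        st = SHSettings(total_time=60.0, decoherence_scheme="overlap",
                        electronic_substeps=20, rng_seed=4)
        rec, _ = propagate_trajectory(init, model, st)
        norms = np.sum(np.abs(rec.coeffs) ** 2, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-8)


class TestSettingsValidation:
    def test_total_time_must_be_multiple_of_timestep(self):
        with pytest.raises(ValueError):
            SHSettings(nuclear_timestep=0.3, total_time=1.0)

    def test_unknown_enums_rejected(self):
        with pytest.raises(ValueError):
            SHSettings(decoherence_scheme="both")
        with pytest.raises(ValueError):
            SHSettings(frustrated_hop_policy="retry")
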