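"""n-mode representation, DVR oracle, VSCF, VCI, Watson terms, assignment."""

import numpy as np
import pytest

from pipvib import model_systems as ms
from pipvib import normal_modes as nm
from pipvib.constants import HARTREE_TO_INVCM as H2CM
from pipvib.vscf_vci import (
    VCISpaceSpec,
    assemble_and_solve,
    assign_states,
    build_nmode,
    build_watson,
    config_label,
    count_space,
    dvr_levels,
    enumerate_space,
    truncated_nmode_potential,
    vscf_ground,
)


class TestDVR:
    def test_morse_closed_form(self, morse):
        """Converged sinc-DVR reproduces Morse levels to < 0.01 cm^-1."""
        levels = dvr_levels(morse, [(-50, 150, 700)], n_states=6)
        assert np.max(np.abs(levels - morse.levels(5))) * H2CM < 0.01

    def test_harmonic_2d_ladder(self):
        model = ms.make_harmonic([0.01, 0.02])
        levels = dvr_levels(model, [(-60, 60, 64), (-40, 40, 64)], n_states=5)
        expected = sorted(0.01 * (n + 0.5) + 0.02 * (m + 0.5)
                          for n in range(4) for m in range(3))[:5]
        assert levels * H2CM == pytest.approx(
            np.array(expected) * H2CM, abs=1e-6)

    def test_grid_refinement_stability(self, morse):
        a = dvr_levels(morse, [(-50, 150, 560)], n_states=4)
        b = dvr_levels(morse, [(-50, 150, 700)], n_states=4)
        assert np.max(np.abs(a - b)) * H2CM < 0.01

    def test_oracle_dimension_guard(self):
        with pytest.raises(ValueError):
            dvr_levels(ms.make_harmonic([0.01] * 4), [(-5, 5, 8)] * 4)


class TestNMode:
    def test_separable_potential_has_no_pair_terms(self):
        model = ms.make_harmonic([0.01, 0.02, 0.015])
        rep = build_nmode(model, model.omegas, n_max=2, grid_points_per_mode=12)
        for subset, tensor in rep.terms.items():
            if len(subset) == 2:
                assert np.max(np.abs(tensor)) < 1e-12

    def test_pairwise_potential_exact_at_2mr(self, three_mode):
        """A sum of pairwise couplings is reproduced exactly by the 2MR."""
        v2 = truncated_nmode_potential(three_mode, 3, n_max=2)
        rng = np.random.default_rng(8)
        for q in rng.normal(0, 6, (20, 3)):
            assert v2(q) == pytest.approx(three_mode.energy(q),
                                          rel=1e-12, abs=1e-15)

    def test_intrinsic_terms_vanish_with_zero_argument(self, fermi):
        """1MR truncation equals the full potential along single-mode cuts."""
        v1 = truncated_nmode_potential(fermi, 2, n_max=1)
        for q1 in (-3.0, 2.0, 7.5):
            assert v1([q1, 0.0]) == pytest.approx(fermi.energy([q1, 0.0]),
                                                  abs=1e-15)
        # and the intrinsic pair term is the remainder, zero on the axes
        v2 = truncated_nmode_potential(fermi, 2, n_max=2)
        for q in ([4.0, 0.0], [0.0, -6.0], [0.0, 0.0]):
            assert v2(q) - v1(q) == pytest.approx(0.0, abs=1e-15)

    def test_representation_value_at_origin_is_zero(self, fermi):
        rep = build_nmode(fermi, [fermi.omega_s, fermi.omega_b], n_max=2,
                          grid_points_per_mode=12)
        assert rep.v0 == 0.0

    def test_grid_size_guard(self, fermi):
        with pytest.raises(ValueError):
            build_nmode(fermi, [fermi.omega_s, fermi.omega_b],
                        grid_points_per_mode=4)


class TestVSCF:
    def test_uncoupled_harmonic_energy_exact(self):
        model = ms.make_harmonic([0.01, 0.02])
        rep = build_nmode(model, model.omegas, n_max=2, grid_points_per_mode=16)
        scf = vscf_ground(rep, n_prim=10, n_modal=6)
        assert scf.energy == pytest.approx(0.015, abs=1e-12)
        assert scf.converged

    def test_morse_matches_closed_form(self, morse):
        rep = build_nmode(morse, [morse.omega], n_max=1,
                          grid_points_per_mode=48)
        scf = vscf_ground(rep, n_prim=32, n_modal=16)
        assert abs(scf.energy - morse.level(0)) * H2CM < 0.01

    def test_vscf_above_exact_ground(self, fermi):
        """Mean field is variational: E_VSCF >= exact ground energy."""
        rep = build_nmode(fermi, [fermi.omega_s, fermi.omega_b], n_max=2,
                          grid_points_per_mode=32)
        scf = vscf_ground(rep, n_prim=20, n_modal=12)
        exact = dvr_levels(fermi, [(-32, 60, 90), (-58, 58, 90)], n_states=1)[0]
        assert scf.energy >= exact - 1e-9


class TestSpaceEnumeration:
    def test_two_mode_example(self):
        spec = VCISpaceSpec(2, (2, 2), 5)
        cfgs = enumerate_space(spec)
        assert len(cfgs) == 6
        assert {tuple(c) for c in cfgs} == {
            (0, 0), (1, 0), (2, 0), (0, 1), (0, 2), (1, 1)}
        assert tuple(cfgs[0]) == (0, 0)  # ground configuration first

    def test_zero_caps_ground_only(self):
        assert len(enumerate_space(VCISpaceSpec(3, (), 5))) == 1

    def test_caps_exceeding_modals_rejected(self):
        with pytest.raises(ValueError):
            VCISpaceSpec(3, (8, 8), 5)

    def test_duplicate_free_and_deterministic(self):
        spec = VCISpaceSpec(4, (5, 5, 4), 8)
        a = enumerate_space(spec)
        b = enumerate_space(spec)
        assert np.array_equal(a, b)
        assert len(np.unique(a, axis=0)) == len(a)

    @pytest.mark.parametrize("spec", [
        VCISpaceSpec(3, (4, 4, 3), 5),
        VCISpaceSpec(5, (6, 5, 4, 3), 7),
        VCISpaceSpec(2, (9, 9), 10),
    ])
    def test_count_formula_matches_enumeration(self, spec):
        assert count_space(spec) == len(enumerate_space(spec))

    def test_labels(self):
        assert config_label([0, 0, 0]) == "GS"
        assert config_label([0, 1, 0]) == "nu2"
        assert config_label([0, 2, 1]) == "2nu2+nu3"
        assert config_label([1, 0, 2], mode_numbers=[15, 16, 17]) \
            == "nu15+2nu17"


@pytest.fixture(scope="module")
def fermi_solution(fermi):
    rep = build_nmode(fermi, [fermi.omega_s, fermi.omega_b], n_max=2,
                      grid_points_per_mode=40)
    scf = vscf_ground(rep, n_prim=24, n_modal=16)
    sol = assemble_and_solve(rep, scf, VCISpaceSpec(2, (12, 12), 16))
    return rep, scf, sol


@pytest.fixture(scope="module")
def harmonic_solution():
    model = ms.make_harmonic([0.01, 0.02])
    rep = build_nmode(model, model.omegas, n_max=2, grid_points_per_mode=16)
    scf = vscf_ground(rep, n_prim=12, n_modal=8)
    return assemble_and_solve(rep, scf, VCISpaceSpec(2, (4, 4), 8))


@pytest.fixture(scope="module")
def triatomic_watson(triatomic, triatomic_modes):
    mss = nm.ModeSpaceSurface(triatomic, triatomic_modes)
    rep = build_nmode(mss, mss.omegas_au, n_max=3, grid_points_per_mode=14)
    scf = vscf_ground(rep, n_prim=10, n_modal=7)
    watson = build_watson(mss, scf, rep)
    return rep, scf, watson


class TestVCI:
    def test_uncoupled_harmonic_fundamentals(self):
        model = ms.make_harmonic([0.01, 0.02])
        rep = build_nmode(model, model.omegas, n_max=2, grid_points_per_mode=16)
        scf = vscf_ground(rep, n_prim=12, n_modal=8)
        sol = assemble_and_solve(rep, scf, VCISpaceSpec(2, (6, 6), 8))
        assert sol.energies_cm[1] == pytest.approx(0.01 * H2CM, abs=1e-6)
        assert sol.energies_cm[2] == pytest.approx(0.02 * H2CM, abs=1e-6)

    def test_fermi_levels_match_dvr(self, fermi, fermi_solution):
        """All levels through the bend's fourth overtone agree with exact
        grid diagonalization to better than 1 cm^-1."""
        _, _, sol = fermi_solution
        exact = dvr_levels(fermi, [(-35, 70, 120), (-70, 70, 120)],
                           n_states=11)
        assert np.max(np.abs(sol.energies[:11] - exact)) * H2CM < 1.0

    def test_variational_ordering(self, fermi_solution):
        rep, scf, sol = fermi_solution
        assert scf.energy >= sol.energies[0]
        assert np.all(np.diff(sol.energies) > -1e-12)

    def test_variational_monotonicity_under_caps(self, fermi_solution):
        """Enlarging the excitation space never raises a retained level."""
        rep, scf, _ = fermi_solution
        prev = None
        for caps in ((4, 4), (8, 8), (12, 12)):
            sol = assemble_and_solve(rep, scf, VCISpaceSpec(2, caps, 16))
            if prev is not None:
                k = min(len(prev), 6)
                assert np.all(sol.energies[:k] <= prev[:k] + 1e-12)
            prev = sol.energies

    def test_eigenvector_orthonormality(self, fermi_solution):
        _, _, sol = fermi_solution
        gram = sol.coefficients.T @ sol.coefficients
        assert gram == pytest.approx(np.eye(gram.shape[0]), abs=1e-10)

    def test_fermi_doublet_mixing(self):
        """At exact quantum 2:1 resonance the stretch fundamental and bend
        overtone mix half-and-half."""
        model = ms.CoupledMorseFermi(0.012, 0.0054, 5e-7, D=0.06)
        rep = build_nmode(model, [model.omega_s, model.omega_b], n_max=2,
                          grid_points_per_mode=40)
        scf = vscf_ground(rep, n_prim=24, n_modal=16)
        sol = assemble_and_solve(rep, scf, VCISpaceSpec(2, (12, 12), 16))
        cfgs = [tuple(c) for c in sol.configs]
        i10, i02 = cfgs.index((1, 0)), cfgs.index((0, 2))
        # locate the two eigenstates dominated by the pair
        pair_weight = (np.abs(sol.coefficients[i10]) ** 2
                       + np.abs(sol.coefficients[i02]) ** 2)
        states = np.argsort(-pair_weight)[:2]
        for s in states:
            w10 = abs(sol.coefficients[i10, s]) ** 2
            w02 = abs(sol.coefficients[i02, s]) ** 2
            assert w10 == pytest.approx(0.5, abs=0.12)
            assert w02 == pytest.approx(0.5, abs=0.12)

    def test_three_mode_vs_dvr(self, three_mode):
        rep = build_nmode(three_mode, three_mode.omegas, n_max=2,
                          grid_points_per_mode=32)
        scf = vscf_ground(rep, n_prim=20, n_modal=12)
        sol = assemble_and_solve(rep, scf, VCISpaceSpec(3, (10, 10, 10), 12))
        exact = dvr_levels(three_mode,
                           [(-24, 50, 44), (-55, 55, 44), (-60, 60, 44)],
                           n_states=5)
        assert np.max(np.abs(sol.energies[:5] - exact)) * H2CM < 1.0


class TestAssignment:
    def test_pure_fundamental_full_weight(self, harmonic_solution):
        assignment = assign_states(harmonic_solution, {"A": [0], "B": [1]})
        fund_a = assignment.states[1]
        assert fund_a["band_weights"]["A"] == pytest.approx(1.0, abs=1e-10)
        assert fund_a["band_weights"]["B"] == pytest.approx(0.0, abs=1e-10)

    def test_zero_threshold_lists_every_state(self, harmonic_solution):
        assignment = assign_states(harmonic_solution, {"A": [0]}, threshold=0.0)
        e, w = assignment.band_sticks("A")
        assert len(e) == harmonic_solution.n_states

    def test_weights_sum_to_one(self, harmonic_solution):
        assignment = assign_states(harmonic_solution, {"A": [0]})
        for st in assignment.states:
            assert -1e-12 <= st["band_weights"]["A"] <= 1.0 + 1e-12
        total = np.sum(np.abs(harmonic_solution.coefficients[:, 0]) ** 2)
        assert total == pytest.approx(1.0, abs=1e-10)


class TestWatson:
    def test_zeta_antisymmetry(self, triatomic_watson):
        _, _, watson = triatomic_watson
        assert watson.zeta == pytest.approx(
            -np.swapaxes(watson.zeta, 1, 2), abs=1e-12)

    def test_mu_matches_equilibrium_inertia(self, triatomic, triatomic_modes):
        from pipvib.vscf_vci.watson import inverse_inertia
        mu = inverse_inertia(triatomic_modes.geometry, triatomic_modes.masses)
        assert mu == pytest.approx(mu.T, abs=1e-14)
        assert np.all(np.linalg.eigvalsh(mu) > 0)

    def test_toggles_shift_levels_by_bounded_amounts(self, triatomic_watson):
        """VAM and mass-term corrections are real but small (< 50 cm^-1)."""
        rep, scf, watson = triatomic_watson
        spec = VCISpaceSpec(3, (5, 5, 5), 7)
        plain = assemble_and_solve(rep, scf, spec)
        with_mass = assemble_and_solve(rep, scf, spec,
                                       **watson.vci_kwargs(False, True))
        full = assemble_and_solve(rep, scf, spec,
                                  **watson.vci_kwargs(True, True))
        d_mass = (with_mass.zpe - plain.zpe) * H2CM
        d_vam = np.abs(full.energies_cm[1:4] - with_mass.energies_cm[1:4])
        assert 0.01 < abs(d_mass) < 50
        assert np.all(d_vam > 1e-3) and np.all(d_vam < 50)

    def test_vam_matrix_is_hermitian_assembly(self, triatomic_watson):
        # assemble_and_solve raises on non-Hermitian assembly; a successful
        # solve with complex VAM operators exercises that trap
        rep, scf, watson = triatomic_watson
        sol = assemble_and_solve(rep, scf, VCISpaceSpec(3, (4, 4), 7),
                                 **watson.vci_kwargs(True, True))
        assert np.all(np.diff(sol.energies) > -1e-12)
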