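"""AS-SCIVR: switching, tangent dynamics, coherent states, spectra."""

import numpy as np
import pytest

from pipvib import model_systems as ms
from pipvib import semiclassical as sc
from pipvib.constants import HARTREE_TO_INVCM as H2CM


class TestSwitchingSchedule:
    def test_endpoint_values(self):
        sch = sc.SwitchingSchedule(T_as=25000.0, dt=10.0)
        assert sch.lam(0.0) == 0.0
        assert sch.lam(25000.0) == pytest.approx(1.0, abs=1e-14)
        assert sch.lam(12500.0) == pytest.approx(0.5, abs=1e-14)

    def test_monotone_with_flat_ends(self):
        sch = sc.SwitchingSchedule(T_as=1000.0, dt=1.0)
        t = np.linspace(0, 1000.0, 2001)
        lam = sch.lam(t)
        assert np.all(np.diff(lam) >= -1e-15)
        eps = 1e-4
        assert (sch.lam(eps) - sch.lam(0.0)) / eps < 1e-9
        assert (sch.lam(1000.0) - sch.lam(1000.0 - eps)) / eps < 1e-9

    def test_dt_must_divide(self):
        with pytest.raises(ValueError):
            sc.SwitchingSchedule(T_as=1000.0, dt=7.0)


class TestInitialConditions:
    def test_quantized_mode_energies(self):
        omegas = np.array([0.01, 0.02])
        p, q = sc.harmonic_initial_conditions(omegas, [0, 1], 64, seed=4)
        e = 0.5 * p ** 2 + 0.5 * omegas ** 2 * q ** 2
        assert e[:, 0] == pytest.approx(0.5 * 0.01, abs=1e-14)
        assert e[:, 1] == pytest.approx(1.5 * 0.02, abs=1e-14)

    def test_seeded_reproducibility(self):
        a = sc.harmonic_initial_conditions([0.01], [0], 10, seed=5)
        b = sc.harmonic_initial_conditions([0.01], [0], 10, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_negative_quanta_rejected(self):
        with pytest.raises(ValueError):
            sc.harmonic_initial_conditions([0.01], [-1], 5)


class TestAdiabaticSwitch:
    def test_identity_switch_preserves_actions(self):
        """Switching harmonic -> harmonic leaves per-mode actions unchanged.

        A fine step isolates the switching error from the integrator's
        O(dt^2) energy oscillation.
        """
        omegas = np.array([0.01])
        model = ms.make_harmonic(omegas)
        p0, q0 = sc.harmonic_initial_conditions(omegas, [0], 8, seed=2)
        sch = sc.SwitchingSchedule(T_as=200.0, dt=0.02)
        p1, q1, ok = sc.adiabatic_switch(p0, q0, omegas, model, sch)
        assert np.all(ok)
        e0 = 0.5 * p0 ** 2 + 0.5 * omegas ** 2 * q0 ** 2
        e1 = 0.5 * p1 ** 2 + 0.5 * omegas ** 2 * q1 ** 2
        assert np.max(np.abs(e1 - e0) / e0) < 1e-8

    def test_morse_switch_lands_near_exact_zpe(self, morse):
        """Adiabatic invariance: ZPE-torus starts exit near the Morse E_0."""
        p0, q0 = sc.harmonic_initial_conditions([morse.omega], [0], 40, seed=7)
        p1, q1, ok = sc.adiabatic_switch(p0, q0, [morse.omega], morse,
                                         sc.SwitchingSchedule(25000.0, 10.0))
        e = 0.5 * p1[:, 0] ** 2 + morse.energy_batch(q1[:, 0])
        assert abs(np.mean(e) - morse.level(0)) * H2CM < 3.0

    def test_slower_switching_tightens_energy_spread(self, morse):
        """Doubling T_AS reduces the exit-energy spread (adiabatic limit)."""
        spreads = {}
        for t_as in (6250.0, 50000.0):
            p0, q0 = sc.harmonic_initial_conditions([morse.omega], [0], 60,
                                                    seed=7)
            p1, q1, _ = sc.adiabatic_switch(p0, q0, [morse.omega], morse,
                                            sc.SwitchingSchedule(t_as, 10.0))
            e = 0.5 * p1[:, 0] ** 2 + morse.energy_batch(q1[:, 0])
            spreads[t_as] = np.std(e)
        assert spreads[50000.0] < spreads[6250.0]

    def test_dissociation_guard_flags_escapees(self, morse):
        p0, q0 = sc.harmonic_initial_conditions([morse.omega], [8], 10, seed=1)
        _, _, ok = sc.adiabatic_switch(p0, q0, [morse.omega], morse,
                                       sc.SwitchingSchedule(2000.0, 10.0),
                                       guard_energy=morse.level(2))
        assert not np.all(ok)


@pytest.fixture(scope="module")
def harmonic_records():
    omegas = np.array([0.01, 0.02])
    model = ms.make_harmonic(omegas)
    p0, q0 = sc.harmonic_initial_conditions(omegas, [0, 0], 3, seed=9)
    # a fine step keeps the integrator's O(dt^2) frequency error below
    # the analytic-comparison tolerances
    return omegas, sc.propagate_with_stability(p0, q0, model, T=2000.0,
                                               dt=1.0, gamma=omegas)


class TestStabilityPropagation:
    def test_monodromy_is_analytic_rotation(self, harmonic_records):
        """For uncoupled harmonic motion the monodromy blocks are the exact
        phase-space rotation matrices (up to the integrator's dt^2 error)."""
        omegas, records = harmonic_records
        t = records[0].times[-1]
        m = records[0].monodromy
        for k, w in enumerate(omegas):
            assert m["qq"][k, k] == pytest.approx(np.cos(w * t), abs=5e-3)
            assert m["qp"][k, k] == pytest.approx(np.sin(w * t) / w, rel=6e-3)
            assert m["pq"][k, k] == pytest.approx(-w * np.sin(w * t), rel=6e-3)

    def test_symplectic_determinant(self, harmonic_records):
        _, records = harmonic_records
        assert max(r.max_det_deviation for r in records) < 1e-10

    def test_hk_phase_slope_is_half_trace_frequency(self, harmonic_records):
        """phi_t = -(1/2) sum_k omega_k t for harmonic dynamics."""
        omegas, records = harmonic_records
        slope = np.polyfit(records[0].times, records[0].hk_phase, 1)[0]
        assert slope == pytest.approx(-0.5 * omegas.sum(), rel=1e-3)

    def test_energy_drift_bounded_and_second_order(self):
        """Verlet energy error is bounded and shrinks ~dt^2."""
        model = ms.make_harmonic([0.01])
        p0, q0 = sc.harmonic_initial_conditions([0.01], [0], 1, seed=3)
        drifts = {}
        for dt in (10.0, 2.5):
            rec = sc.propagate_with_stability(p0, q0, model, T=5000.0,
                                              dt=dt)[0]
            drifts[dt] = rec.energy_drift
        assert drifts[10.0] < 5e-3
        assert drifts[2.5] < drifts[10.0] / 8  # ~dt^2 scaling (factor 16)

    def test_stationary_trajectory_action(self):
        """Zero momentum at the minimum of a lifted potential: S_t = -V0 t."""
        class Lifted(ms.HarmonicModel):
            v0 = -0.004

            def energy_batch(self, q):
                return super().energy_batch(q) + self.v0

        model = Lifted([0.01])
        rec = sc.propagate_with_stability(np.zeros((1, 1)), np.zeros((1, 1)),
                                          model, T=5000.0, dt=10.0)[0]
        assert rec.action[-1] == pytest.approx(-model.v0 * 5000.0, rel=1e-12)


class TestRejection:
    def test_integrable_record_accepted(self, morse):
        p0, q0 = sc.harmonic_initial_conditions([morse.omega], [0], 1, seed=0)
        rec = sc.propagate_with_stability(p0, q0, morse, T=5000.0, dt=10.0)[0]
        assert sc.reject(rec, 0.01) is True

    def test_injected_drift_rejected(self, morse):
        p0, q0 = sc.harmonic_initial_conditions([morse.omega], [0], 1, seed=0)
        rec = sc.propagate_with_stability(p0, q0, morse, T=1000.0, dt=10.0)[0]
        rec.det_deviation[-1] = 0.05
        assert sc.reject(rec, 0.01) is False

    def test_zero_tolerance_is_degenerate(self, morse):
        # machine-precision symplecticity still fails an exactly-zero gate
        p0, q0 = sc.harmonic_initial_conditions([morse.omega], [0], 1, seed=0)
        rec = sc.propagate_with_stability(p0, q0, morse, T=1000.0, dt=10.0)[0]
        assert rec.max_det_deviation > 0.0
        assert sc.reject(rec, 0.0) is False


class TestCoherentStates:
    def test_self_overlap_is_one(self):
        g = sc.CoherentState([0.3, -0.2], [1.0, 2.0], [0.01, 0.02])
        assert sc.coherent_overlap(g, g) == pytest.approx(1.0)

    def test_distant_states_decouple(self):
        gamma = [0.01]
        a = sc.CoherentState([0.0], [0.0], gamma)
        b = sc.CoherentState([0.0], [100.0], gamma)
        assert abs(sc.coherent_overlap(a, b)) < 1e-8

    def test_width_mismatch_rejected(self):
        a = sc.CoherentState([0.0], [0.0], [0.01])
        b = sc.CoherentState([0.0], [0.0], [0.02])
        with pytest.raises(ValueError):
            sc.coherent_overlap(a, b)

    def test_against_quadrature_oracle(self):
        """Closed form matches direct 1D numerical integration to 1e-10."""
        gamma = 0.013
        a = sc.CoherentState([0.21], [1.3], [gamma])
        b = sc.CoherentState([-0.35], [-2.1], [gamma])

        q = np.linspace(-250, 250, 400001)
        psi_a = (gamma / np.pi) ** 0.25 * np.exp(
            -0.5 * gamma * (q - a.q[0]) ** 2 + 1j * a.p[0] * (q - a.q[0]))
        psi_b = (gamma / np.pi) ** 0.25 * np.exp(
            -0.5 * gamma * (q - b.q[0]) ** 2 + 1j * b.p[0] * (q - b.q[0]))
        numeric = np.trapezoid(np.conj(psi_a) * psi_b, q)
        assert sc.coherent_overlap(a, b) == pytest.approx(numeric, abs=1e-10)


class TestSpectra:
    def test_harmonic_zpe_peak(self):
        """SC is exact for harmonic systems: ZPE peak at omega/2 within one
        Fourier grid spacing."""
        model = ms.make_harmonic([0.01])
        spacing = 2 * np.pi / 25000.0
        grid = np.arange(0.0, 0.02, spacing)
        run, _ = sc.run_as_scivr(model, [0.01], n_traj=16, T_as=5000.0,
                                 T=25000.0, dt=10.0, seed=1, energy_grid=grid)
        peak = run.peaks(0.3)[0]
        assert abs(peak - 0.005) <= spacing

    def test_spectral_positivity(self):
        model = ms.make_harmonic([0.01])
        run, _ = sc.run_as_scivr(model, [0.01], n_traj=8, T_as=2000.0,
                                 T=10000.0, dt=10.0, seed=2)
        assert np.all(run.intensity >= 0.0)

    def test_resolution_narrows_with_time(self):
        """Peak width shrinks ~1/T as the evolution time doubles."""
        model = ms.make_harmonic([0.01])
        widths = {}
        for T in (12500.0, 25000.0):
            grid = np.arange(0.004, 0.006, 2e-7)
            run, _ = sc.run_as_scivr(model, [0.01], n_traj=8, T_as=2000.0,
                                     T=T, dt=10.0, seed=3, energy_grid=grid)
            y = run.intensity
            half = y >= 0.5 * y.max()
            widths[T] = np.sum(half) * 2e-7
        ratio = widths[25000.0] / widths[12500.0]
        assert ratio == pytest.approx(0.5, abs=0.15)

    def test_empty_accepted_set_raises(self, morse):
        p0, q0 = sc.harmonic_initial_conditions([morse.omega], [0], 1, seed=0)
        rec = sc.propagate_with_stability(p0, q0, morse, T=1000.0, dt=10.0)[0]
        rec.accepted = False
        ref = sc.CoherentState([np.sqrt(morse.omega)], [0.0], [morse.omega])
        with pytest.raises(ValueError):
            sc.accumulate_spectrum([rec], ref, np.linspace(0, 0.01, 50))

    def test_zpe_peak_stable_across_seeds(self, fermi):
        """Ensemble-statistical jitter of the 2-mode ZPE peak stays < 2 cm^-1
        across seeds for 100-trajectory runs (evolution long enough that the
        Fourier width does not dominate the comparison)."""
        omegas = [fermi.omega_s, fermi.omega_b]
        grid = np.arange(0.0080, 0.0105, 1e-7)
        peaks = []
        for seed in (1, 2, 3):
            run, _ = sc.run_as_scivr(fermi, omegas, quanta=[0, 0], n_traj=100,
                                     T_as=25000.0, T=50000.0, dt=10.0,
                                     seed=seed, energy_grid=grid)
            peaks.append(run.peaks(0.5)[0] * H2CM)
        assert max(peaks) - min(peaks) < 2.0
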