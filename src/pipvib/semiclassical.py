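"""Adiabatically switched semiclassical IVR (AS-SCIVR) power spectra.

Two-step procedure over mass-scaled normal coordinates (hbar = 1):

1. *Adiabatic switching*: trajectories start on the harmonic torus with
   quantized actions (n_k + 1/2) and random phases, then evolve under
   H(t) = [1 - lambda(t)] H_harm + lambda(t) H_anh with the smooth switching
   function lambda(t) = t/T_AS - sin(2 pi t / T_AS) / (2 pi), approximately
   preserving the actions and so delivering quantized anharmonic initial
   conditions.
2. *Semiclassical propagation*: each switched trajectory evolves under the
   anharmonic Hamiltonian while accumulating the classical action S_t, the
   monodromy (stability) blocks, and the continuous phase phi_t of the
   Herman--Kluk prefactor.  The time-averaged spectral density is

   I(E) = (1/2 pi)^F sum_j (1/2 pi T) | int_0^T dt e^{i (S_t + E t + phi_t)}
          <Psi | g(p_t, q_t)> |^2

   with coherent states of diagonal width matrix Gamma = diag(omega) and a
   reference coherent state at the equilibrium geometry with
   harmonic-approximation momenta.

Symplectic velocity-Verlet integration keeps det M = 1 to machine precision
for the tangent dynamics; chaotic trajectories are rejected when the
monodromy determinant drifts beyond a tolerance (1% by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .surface import Surface

__all__ = [
    "SwitchingSchedule", "CoherentState", "TrajectoryRecord",
    "SemiclassicalRun", "harmonic_initial_conditions", "adiabatic_switch",
    "propagate_with_stability", "reject", "coherent_overlap",
    "accumulate_spectrum", "run_as_scivr",
]

DEFAULT_T_AS = 25000.0   # a.u., switching time
DEFAULT_T = 25000.0      # a.u., semiclassical evolution time
DEFAULT_DT = 10.0        # a.u., time step
DEFAULT_N_TRAJ = 4000
DEFAULT_DET_TOL = 0.01   # monodromy determinant acceptance threshold


@dataclass(frozen=True)
class SwitchingSchedule:
    """lambda(t) = t/T_AS - sin(2 pi t / T_AS)/(2 pi) over [0, T_AS]."""

    T_as: float = DEFAULT_T_AS
    dt: float = DEFAULT_DT

    def __post_init__(self):
        if self.T_as <= 0 or self.dt <= 0:
            raise ValueError("T_as and dt must be positive")
        n = self.T_as / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("dt must divide T_as")

    @property
    def n_steps(self) -> int:
        return int(round(self.T_as / self.dt))

    def lam(self, t):
        x = np.asarray(t, dtype=float) / self.T_as
        return x - np.sin(2.0 * np.pi * x) / (2.0 * np.pi)


def harmonic_initial_conditions(omegas, quanta, n_traj: int, seed=None):
    """Phase-space samples on the harmonic torus with quantized actions.

    Mode k carries action (n_k + 1/2): Q_k = sqrt((2n_k+1)/w_k) sin(theta),
    P_k = sqrt((2n_k+1) w_k) cos(theta), with independent uniform phases.
    Returns (p0, q0), each (n_traj, F).
    """
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    quanta = np.atleast_1d(np.asarray(quanta, dtype=int))
    if np.any(quanta < 0):
        raise ValueError("quanta must be nonnegative integers")
    if quanta.size != omegas.size:
        raise ValueError("quanta vector length must match mode count")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_traj, omegas.size))
    amp = np.sqrt((2.0 * quanta + 1.0) / omegas)
    q0 = amp * np.sin(theta)
    p0 = np.sqrt((2.0 * quanta + 1.0) * omegas) * np.cos(theta)
    return p0, q0


def adiabatic_switch(p0, q0, omegas, surface: Surface,
                     schedule: SwitchingSchedule | None = None,
                     guard_energy: float | None = None):
    """Propagate under the switching Hamiltonian; returns (p_as, q_as, ok).

    Velocity-Verlet with the time-dependent force
    F(t, q) = -[(1 - lambda) w^2 q + lambda grad V(q)].  Trajectories whose
    energy exceeds ``guard_energy`` (a dissociation guard, hartree) at any
    step are flagged False in ``ok`` and should be discarded.
    """
    schedule = schedule or SwitchingSchedule()
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    p = np.atleast_2d(np.asarray(p0, dtype=float)).copy()
    q = np.atleast_2d(np.asarray(q0, dtype=float)).copy()
    dt = schedule.dt
    ok = np.ones(p.shape[0], dtype=bool)

    def force(t, qq):
        lam = schedule.lam(t)
        return -((1.0 - lam) * omegas ** 2 * qq
                 + lam * surface.gradient_batch(qq))

    a = force(0.0, q)
    for step in range(schedule.n_steps):
        t = step * dt
        q += dt * p + 0.5 * dt * dt * a
        a_new = force(t + dt, q)
        p += 0.5 * dt * (a + a_new)
        a = a_new
        if guard_energy is not None:
            e = 0.5 * np.sum(p ** 2, axis=1) + surface.energy_batch(q)
            ok &= e < guard_energy
    return p, q, ok


@dataclass
class TrajectoryRecord:
    """One semiclassical trajectory with action, HK phase, and stability data.

    ``det_deviation`` tracks |det M(t) - 1| along the trajectory (the
    rejection statistic); ``hk_phase`` is the continuous half-argument of the
    Herman--Kluk prefactor determinant.
    """

    times: np.ndarray = field(repr=False)
    q: np.ndarray = field(repr=False)        # (n_steps+1, F)
    p: np.ndarray = field(repr=False)
    action: np.ndarray = field(repr=False)   # S_t
    hk_phase: np.ndarray = field(repr=False)  # phi_t
    energy: np.ndarray = field(repr=False)
    det_deviation: np.ndarray = field(repr=False)
    monodromy: dict = field(repr=False, default=None)  # final blocks
    accepted: bool | None = None

    @property
    def energy_drift(self) -> float:
        scale = max(abs(self.energy[0]), 1e-12)
        return float(np.max(np.abs(self.energy - self.energy[0])) / scale)

    @property
    def max_det_deviation(self) -> float:
        return float(np.max(self.det_deviation))


def propagate_with_stability(p_as, q_as, surface: Surface, T: float = DEFAULT_T,
                             dt: float = DEFAULT_DT, gamma=None) -> list:
    """Symplectic propagation with concurrent tangent (monodromy) dynamics.

    Velocity Verlet for (p, q); the tangent map uses the same update so the
    monodromy matrix stays exactly symplectic for symmetric Hessians.  The
    classical action S_t = int (p q_dot - H) dt accumulates by the trapezoid
    rule; the HK phase is tracked continuously (argument increments wrapped
    to (-pi, pi], then halved for the prefactor square root).

    Returns one :class:`TrajectoryRecord` per input trajectory.
    """
    n_steps = int(round(T / dt))
    if abs(n_steps * dt - T) > 1e-9:
        raise ValueError("dt must divide T")
    p = np.atleast_2d(np.asarray(p_as, dtype=float)).copy()
    q = np.atleast_2d(np.asarray(q_as, dtype=float)).copy()
    n, f = q.shape
    gamma = (np.ones(f) if gamma is None
             else np.atleast_1d(np.asarray(gamma, dtype=float)))
    g_ratio = gamma[None, :] / gamma[:, None]       # (i, j) -> gamma_j/gamma_i

    eye = np.broadcast_to(np.eye(f), (n, f, f)).copy()
    A = eye.copy()              # dq_t / dq_0
    B = np.zeros((n, f, f))     # dq_t / dp_0
    C = np.zeros((n, f, f))     # dp_t / dq_0
    D = eye.copy()              # dp_t / dp_0

    qs = np.empty((n_steps + 1, n, f))
    ps = np.empty((n_steps + 1, n, f))
    actions = np.empty((n_steps + 1, n))
    phases = np.empty((n_steps + 1, n))
    energies = np.empty((n_steps + 1, n))
    det_dev = np.empty((n_steps + 1, n))

    def hk_det(Ab, Bb, Cb, Db):
        m = 0.5 * (Ab + Db * g_ratio[None] - 1j * Bb * gamma[None, None, :]
                   + 1j * Cb / gamma[None, :, None])
        return np.linalg.det(m)

    def full_det(Ab, Bb, Cb, Db):
        m = np.empty((n, 2 * f, 2 * f))
        m[:, :f, :f] = Ab
        m[:, :f, f:] = Bb
        m[:, f:, :f] = Cb
        m[:, f:, f:] = Db
        return np.linalg.det(m)

    v = surface.energy_batch(q)
    grad = surface.gradient_batch(q)
    K = surface.hessian_batch(q)
    lagr = 0.5 * np.sum(p ** 2, axis=1) - v

    qs[0], ps[0] = q, p
    actions[0] = 0.0
    phases[0] = 0.0
    energies[0] = 0.5 * np.sum(p ** 2, axis=1) + v
    det_dev[0] = np.abs(full_det(A, B, C, D) - 1.0)
    det_prev = hk_det(A, B, C, D)
    phi_acc = np.zeros(n)

    for step in range(n_steps):
        a_force = -grad
        q_new = q + dt * p + 0.5 * dt * dt * a_force
        grad_new = surface.gradient_batch(q_new)
        K_new = surface.hessian_batch(q_new)
        p_new = p + 0.5 * dt * (a_force - grad_new)

        KA = np.einsum("nij,njk->nik", K, A)
        KB = np.einsum("nij,njk->nik", K, B)
        A_new = A + dt * C - 0.5 * dt * dt * KA
        B_new = B + dt * D - 0.5 * dt * dt * KB
        C_new = C - 0.5 * dt * (KA + np.einsum("nij,njk->nik", K_new, A_new))
        D_new = D - 0.5 * dt * (KB + np.einsum("nij,njk->nik", K_new, B_new))

        v_new = surface.energy_batch(q_new)
        lagr_new = 0.5 * np.sum(p_new ** 2, axis=1) - v_new
        actions[step + 1] = actions[step] + 0.5 * dt * (lagr + lagr_new)

        det_new = hk_det(A_new, B_new, C_new, D_new)
        dphi = np.angle(det_new / det_prev)
        phi_acc += dphi
        phases[step + 1] = 0.5 * phi_acc
        det_prev = det_new

        q, p, v, grad, K, lagr = q_new, p_new, v_new, grad_new, K_new, lagr_new
        A, B, C, D = A_new, B_new, C_new, D_new
        qs[step + 1], ps[step + 1] = q, p
        energies[step + 1] = 0.5 * np.sum(p ** 2, axis=1) + v
        det_dev[step + 1] = np.abs(full_det(A, B, C, D) - 1.0)

    times = np.arange(n_steps + 1) * dt
    records = []
    for j in range(n):
        records.append(TrajectoryRecord(
            times=times, q=qs[:, j], p=ps[:, j], action=actions[:, j],
            hk_phase=phases[:, j], energy=energies[:, j],
            det_deviation=det_dev[:, j],
            monodromy={"qq": A[j], "qp": B[j], "pq": C[j], "pp": D[j]},
        ))
    return records


def reject(record: TrajectoryRecord, tolerance: float = DEFAULT_DET_TOL) -> bool:
    """Accept iff max_t |det M(t) - 1| <= tolerance; sets ``record.accepted``."""
    record.accepted = bool(record.max_det_deviation <= tolerance)
    return record.accepted


@dataclass(frozen=True)
class CoherentState:
    """Gaussian wavepacket centered at (p, q) with diagonal width Gamma."""

    p: np.ndarray
    q: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "p", np.atleast_1d(np.asarray(self.p, float)))
        object.__setattr__(self, "q", np.atleast_1d(np.asarray(self.q, float)))
        object.__setattr__(self, "gamma",
                           np.atleast_1d(np.asarray(self.gamma, float)))
        if np.any(self.gamma <= 0):
            raise ValueError("Gamma must be positive definite")


def coherent_overlap(a: CoherentState, b: CoherentState):
    """Closed-form <g_a | g_b> for coherent states sharing a diagonal Gamma."""
    if a.gamma.shape != b.gamma.shape or not np.allclose(a.gamma, b.gamma):
        raise ValueError("coherent states must share the same width matrix")
    g = a.gamma
    dq = b.q - a.q
    dp = b.p - a.p
    return np.exp(-0.25 * np.sum(g * dq ** 2)
                  - 0.25 * np.sum(dp ** 2 / g)
                  - 0.5j * np.sum((a.p + b.p) * dq))


def _overlap_series(record: TrajectoryRecord, ref: CoherentState) -> np.ndarray:
    """<Psi | g(p_t, q_t)> along the trajectory, vectorized over time."""
    g = ref.gamma
    dq = record.q - ref.q[None, :]
    dp = record.p - ref.p[None, :]
    return np.exp(-0.25 * np.sum(g * dq ** 2, axis=1)
                  - 0.25 * np.sum(dp ** 2 / g, axis=1)
                  - 0.5j * np.sum((ref.p[None, :] + record.p) * dq, axis=1))


@dataclass
class SemiclassicalRun:
    """Accumulated spectral density I(E) >= 0 with run statistics."""

    energy_grid: np.ndarray     # hartree
    intensity: np.ndarray
    n_accepted: int
    n_total: int
    F: int
    T: float
    seed: int | None = None

    @property
    def rejection_fraction(self) -> float:
        return 1.0 - self.n_accepted / self.n_total if self.n_total else 0.0

    def peaks(self, rel_threshold: float = 0.05) -> np.ndarray:
        """Energies of local maxima above rel_threshold * max(I) (hartree)."""
        y = self.intensity
        floor = rel_threshold * y.max()
        idx = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
                             & (y[1:-1] > floor)) + 1
        return self.energy_grid[idx]


def accumulate_spectrum(records, reference: CoherentState, energy_grid,
                        energy_chunk: int = 512) -> SemiclassicalRun:
    """Time-averaged SC spectral density over the accepted trajectories.

    For each accepted record the discrete-time integral of
    e^{i (S_t + E t + phi_t)} <Psi|g_t> is evaluated on the energy grid
    (trapezoid in time), squared, and averaged with the (1/2 pi)^F (1/2 pi T)
    prefactors.
    """
    accepted = [r for r in records if r.accepted]
    if not accepted:
        raise ValueError("no accepted trajectories to accumulate")
    energy_grid = np.asarray(energy_grid, dtype=float)
    times = accepted[0].times
    dt = times[1] - times[0]
    T = times[-1]
    f = accepted[0].q.shape[1]

    w = np.full(times.size, dt)
    w[0] = w[-1] = 0.5 * dt
    series = np.array([
        w * np.exp(1j * (r.action + r.hk_phase)) * _overlap_series(r, reference)
        for r in accepted
    ])  # (n_acc, n_t)

    intensity = np.empty(energy_grid.size)
    pref = (1.0 / (2.0 * np.pi)) ** f / (2.0 * np.pi * T)
    for start in range(0, energy_grid.size, energy_chunk):
        e_blk = energy_grid[start:start + energy_chunk]
        phase = np.exp(1j * np.outer(e_blk, times))  # (nE, nT)
        amp = series @ phase.T                        # (n_acc, nE)
        intensity[start:start + energy_chunk] = pref * np.sum(
            np.abs(amp) ** 2, axis=0)

    return SemiclassicalRun(energy_grid=energy_grid, intensity=intensity,
                            n_accepted=len(accepted), n_total=len(records),
                            F=f, T=T)


def run_as_scivr(surface: Surface, omegas, quanta=None,
                 n_traj: int = 100, T_as: float = DEFAULT_T_AS,
                 T: float = DEFAULT_T, dt: float = DEFAULT_DT,
                 seed: int | None = None, energy_grid=None,
                 det_tolerance: float = DEFAULT_DET_TOL,
                 guard_energy: float | None = None):
    """Full AS-SCIVR pipeline on a mode-space surface.

    Returns ``(SemiclassicalRun, records)``.  The default energy grid spans
    zero to twice the harmonic estimate of the state's energy at the
    Fourier-limited spacing 2 pi / T; pass an explicit grid for finer peak
    location.
    """
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    f = omegas.size
    quanta = np.zeros(f, dtype=int) if quanta is None else np.asarray(quanta, int)

    p0, q0 = harmonic_initial_conditions(omegas, quanta, n_traj, seed)
    schedule = SwitchingSchedule(T_as=T_as, dt=dt)
    p_as, q_as, ok = adiabatic_switch(p0, q0, omegas, surface, schedule,
                                      guard_energy=guard_energy)
    records = propagate_with_stability(p_as[ok], q_as[ok], surface, T=T, dt=dt,
                                       gamma=omegas)
    for r in records:
        reject(r, det_tolerance)

    reference = CoherentState(p=np.sqrt((2 * quanta + 1) * omegas),
                              q=np.zeros(f), gamma=omegas)
    if energy_grid is None:
        e_harm = float(np.sum(omegas * (quanta + 0.5)))
        spacing = 2.0 * np.pi / T
        energy_grid = np.arange(0.0, 2.0 * e_harm + 10 * spacing, spacing)
    run = accumulate_spectrum(records, reference, energy_grid)
    run.seed = seed
    run.n_total = n_traj
    return run, records
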