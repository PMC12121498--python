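"""Vibrational self-consistent field ground state.

One-mode functions (modals) are expanded in harmonic-oscillator primitives
at each mode's harmonic frequency and relaxed in the mean field of the other
modes' ground-state densities, with all averages taken over the n-mode
representation's quadrature grids.  The converged virtual modals span the
configuration space for the subsequent VCI step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .nmode import ModeGrid, NModeRepresentation

__all__ = ["ModeBasis", "VSCFResult", "vscf_ground", "VSCFConvergenceError"]


class VSCFConvergenceError(RuntimeError):
    pass


class ModeBasis:
    """Harmonic-oscillator primitives for one mode, tabulated on its grid."""

    def __init__(self, grid: ModeGrid, n_prim: int):
        self.grid = grid
        self.omega = grid.omega
        self.n_prim = n_prim
        self.psi = self._ho_functions(grid.omega, n_prim, grid.points)
        self.kinetic = self._kinetic_matrix(grid.omega, n_prim)

    @staticmethod
    def _ho_functions(omega: float, n: int, q: np.ndarray) -> np.ndarray:
        """psi[k, g]: normalized HO eigenfunctions at frequency omega."""
        x = np.sqrt(omega) * q
        h = np.empty((n, len(q)))
        h[0] = np.pi ** -0.25 * np.exp(-0.5 * x ** 2)
        if n > 1:
            h[1] = np.sqrt(2.0) * x * h[0]
        for k in range(2, n):
            h[k] = np.sqrt(2.0 / k) * x * h[k - 1] - np.sqrt((k - 1) / k) * h[k - 2]
        return omega ** 0.25 * h

    @staticmethod
    def _kinetic_matrix(omega: float, n: int) -> np.ndarray:
        """<a| p^2/2 |b> in the HO basis (mass-scaled, hbar = 1)."""
        t = np.zeros((n, n))
        k = np.arange(n)
        t[k, k] = omega * (2 * k + 1) / 4.0
        for a in range(n - 2):
            t[a, a + 2] = t[a + 2, a] = -omega * np.sqrt((a + 1) * (a + 2)) / 4.0
        return t

    def q_matrix(self) -> np.ndarray:
        n = self.n_prim
        q = np.zeros((n, n))
        for a in range(n - 1):
            q[a, a + 1] = q[a + 1, a] = np.sqrt((a + 1) / (2.0 * self.omega))
        return q

    def p_matrix(self) -> np.ndarray:
        """<a| p |b>, purely imaginary and anti-Hermitian-symmetric."""
        n = self.n_prim
        p = np.zeros((n, n), dtype=complex)
        for a in range(n - 1):
            p[a + 1, a] = 1j * np.sqrt(self.omega * (a + 1) / 2.0)
            p[a, a + 1] = -1j * np.sqrt(self.omega * (a + 1) / 2.0)
        return p


@dataclass
class VSCFResult:
    energy: float                      # hartree, above the expansion point
    modal_coeffs: list = field(repr=False)   # per mode: (n_prim, n_modal)
    modal_energies: list = field(repr=False)
    bases: list = field(repr=False)
    nmode: NModeRepresentation = field(repr=False, default=None)
    n_iterations: int = 0
    converged: bool = True

    @property
    def n_modes(self) -> int:
        return len(self.modal_coeffs)

    def modal_values(self, i: int) -> np.ndarray:
        """phi[a, g]: modal functions of mode i on its quadrature grid."""
        return self.modal_coeffs[i].T @ self.bases[i].psi


def _ground_densities(modal_values, grids):
    """Per-mode quadrature densities d[g] = phi_0(Q_g)^2 W_g (sum ~ 1)."""
    return [mv[0] ** 2 * g.weights for mv, g in zip(modal_values, grids)]


def _mean_field(nmode: NModeRepresentation, dens, i: int) -> np.ndarray:
    """Average of all terms containing mode i over the other modes' densities."""
    vbar = np.zeros(nmode.grids[i].n)
    for subset, tensor in nmode.terms.items():
        if i not in subset:
            continue
        pos = subset.index(i)
        t = tensor
        # contract from the highest axis down so lower axis indices stay valid
        for ax in reversed(range(len(subset))):
            if ax == pos:
                continue
            t = np.tensordot(t, dens[subset[ax]], axes=([ax], [0]))
        vbar += t
    return vbar


def _scf_energy(nmode, dens, modal_coeffs, bases) -> float:
    e = 0.0
    for i, (c, b) in enumerate(zip(modal_coeffs, bases)):
        e += float(c[:, 0] @ b.kinetic @ c[:, 0])
    for subset, tensor in nmode.terms.items():
        t = tensor
        for ax in reversed(range(len(subset))):
            t = np.tensordot(t, dens[subset[ax]], axes=([ax], [0]))
        e += float(t)
    return e


def vscf_ground(nmode: NModeRepresentation, n_prim: int = 16, n_modal: int = 12,
                tol: float = 1e-8, max_iter: int = 200,
                damping_after: int = 50) -> VSCFResult:
    """Converge the VSCF ground state on an n-mode representation.

    Iterates mode-by-mode mean-field updates until successive total energies
    differ by less than ``tol`` hartree.  If the cycle oscillates, density
    damping (50% mixing) kicks in after ``damping_after`` iterations; failure
    to converge within ``max_iter`` raises :class:`VSCFConvergenceError`.
    """
    if n_modal > n_prim:
        raise ValueError("n_modal cannot exceed n_prim")
    f = nmode.n_modes
    bases = [ModeBasis(g, n_prim) for g in nmode.grids]
    # initial modals: eigenstates of T + V1
    modal_coeffs, modal_energies = [], []
    for i, b in enumerate(bases):
        v1 = nmode.terms[(i,)]
        h = b.kinetic + (b.psi * (b.grid.weights * v1)) @ b.psi.T
        w, c = np.linalg.eigh(h)
        modal_coeffs.append(c[:, :n_modal])
        modal_energies.append(w[:n_modal])

    modal_values = [modal_coeffs[i].T @ bases[i].psi for i in range(f)]
    dens = _ground_densities(modal_values, nmode.grids)
    e_old = _scf_energy(nmode, dens, modal_coeffs, bases)

    for it in range(1, max_iter + 1):
        for i, b in enumerate(bases):
            vbar = _mean_field(nmode, dens, i)
            h = b.kinetic + (b.psi * (b.grid.weights * vbar)) @ b.psi.T
            w, c = np.linalg.eigh(h)
            modal_coeffs[i] = c[:, :n_modal]
            modal_energies[i] = w[:n_modal]
            new_val = modal_coeffs[i].T @ b.psi
            new_dens = new_val[0] ** 2 * b.grid.weights
            if it > damping_after:
                new_dens = 0.5 * new_dens + 0.5 * dens[i]
            modal_values[i] = new_val
            dens[i] = new_dens
        e_new = _scf_energy(nmode, dens, modal_coeffs, bases)
        if abs(e_new - e_old) < tol:
            return VSCFResult(energy=float(e_new), modal_coeffs=modal_coeffs,
                              modal_energies=modal_energies, bases=bases,
                              nmode=nmode, n_iterations=it, converged=True)
        e_old = e_new

    raise VSCFConvergenceError(
        f"VSCF did not converge within {max_iter} cycles (last dE around "
        f"{abs(e_new - e_old):.2e} hartree)")
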