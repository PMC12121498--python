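"""Watson Hamiltonian rotational-vibrational terms at J = 0.

For a nonlinear molecule in mass-scaled normal coordinates the exact
vibrational Hamiltonian contains, beyond kinetic + V(Q), the vibrational
angular momentum (VAM) coupling 1/2 sum_ab pi_a mu_ab(Q) pi_b and the
mass-dependent correction -1/8 sum_a mu_aa(Q), with mu the inverse effective
inertia tensor and

    pi_a = sum_{k<l} zeta^a_kl (Q_k P_l - Q_l P_k)

built from the Coriolis zeta constants of the normal-mode frame.  Here the
mass term is treated exactly as a potential-like function of Q (tabulated in
a 2-mode representation on the same grids as the potential), while the VAM
coupling uses the equilibrium inverse inertia tensor mu_ab(0): pi is itself
first order in the displacements, so the Q-dependence of mu in pi-mu-pi is a
higher-order effect.  The two contributions carry independent toggles so
their separate influence on the spectrum can be reported.

Displacements along the mass-weighted normal-mode vectors satisfy the Eckart
conditions exactly, so the instantaneous inertia tensor is evaluated in the
Eckart frame by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..normal_modes import ModeSpaceSurface, NormalModeModel
from ..surface import Surface
from .nmode import NModeRepresentation, build_nmode
from .vscf import VSCFResult

__all__ = ["WatsonOperator", "zeta_constants", "inverse_inertia",
           "watson_mass_term_surface", "build_watson"]


def zeta_constants(modes: NormalModeModel) -> np.ndarray:
    """Coriolis coupling constants zeta[alpha, k, l] (antisymmetric in k, l)."""
    if modes.masses is None:
        raise ValueError("zeta constants require a Cartesian normal-mode model")
    n_atoms = len(modes.masses)
    L = modes.L.reshape(n_atoms, 3, modes.F)
    zeta = np.einsum("iak,ibl->abkl", L, L)
    # cross product structure: zeta^x = sum_i (L_k^y L_l^z - L_k^z L_l^y), etc.
    out = np.empty((3, modes.F, modes.F))
    out[0] = zeta[1, 2] - zeta[2, 1]
    out[1] = zeta[2, 0] - zeta[0, 2]
    out[2] = zeta[0, 1] - zeta[1, 0]
    return out


def inverse_inertia(geometry: np.ndarray, masses_me: np.ndarray) -> np.ndarray:
    """Inverse inertia tensor (a.u.) of a geometry, about its center of mass."""
    geom = np.asarray(geometry, dtype=float).reshape(-1, 3)
    m = np.asarray(masses_me, dtype=float)
    com = (m[:, None] * geom).sum(axis=0) / m.sum()
    x = geom - com
    r2 = np.sum(x ** 2, axis=1)
    inertia = np.einsum("i,ab->ab", m * r2, np.eye(3)) - np.einsum(
        "i,ia,ib->ab", m, x, x)
    return np.linalg.inv(inertia)


class _MassTermSurface(Surface):
    """U(Q) = -1/8 Tr mu(Q) as a potential-like function over mode space."""

    def __init__(self, mode_surface: ModeSpaceSurface):
        self.ms = mode_surface
        self.n_dof = mode_surface.n_dof
        self._masses = mode_surface.modes.masses

    def energy(self, q) -> float:
        geom = self.ms.to_cartesian(np.asarray(q, dtype=float).ravel())
        return float(-0.125 * np.trace(inverse_inertia(geom, self._masses)))

    def gradient(self, q) -> np.ndarray:  # only ever tabulated, never descended
        raise NotImplementedError("mass term exposes energies only")


def watson_mass_term_surface(mode_surface: ModeSpaceSurface) -> Surface:
    return _MassTermSurface(mode_surface)


@dataclass
class WatsonOperator:
    """Assembled Watson corrections for a mode subset.

    ``mass_terms`` is an n-mode-representation terms dict (including the
    constant shift stored separately in ``mass_term_const``) for
    -1/8 sum_a mu_aa(Q); ``vam_ops`` is the product-operator list for
    1/2 sum_ab mu_ab(0) pi_a pi_b in the VSCF modal basis.
    """

    mu_eq: np.ndarray
    zeta: np.ndarray = field(repr=False)
    mass_terms: dict = field(repr=False, default=None)
    mass_term_const: float = 0.0
    vam_ops: list = field(repr=False, default=None)

    def vci_kwargs(self, include_vam: bool = True,
                   include_mass_term: bool = True) -> dict:
        """Keyword arguments for :func:`assemble_and_solve`, honoring toggles."""
        kw = {"extra_terms": None, "product_ops": None, "energy_shift": 0.0}
        if include_mass_term and self.mass_terms:
            kw["extra_terms"] = self.mass_terms
            kw["energy_shift"] = self.mass_term_const
        if include_vam and self.vam_ops:
            kw["product_ops"] = self.vam_ops
        return kw


def _pi_terms(zeta: np.ndarray, mode_subset) -> list:
    """pi_a as [(coef, ((mode, 'Q'), (mode, 'P'))), ...] over kept modes."""
    subset = list(mode_subset)
    out = [[] for _ in range(3)]
    for a in range(3):
        for p, k in enumerate(subset):
            for q, l in enumerate(subset):
                if p >= q:
                    continue
                z = zeta[a, k, l]
                if abs(z) < 1e-14:
                    continue
                out[a].append((z, ((p, "Q"), (q, "P"))))
                out[a].append((-z, ((q, "Q"), (p, "P"))))
    return out


def build_watson(mode_surface: ModeSpaceSurface, vscf: VSCFResult,
                 nmode: NModeRepresentation,
                 mass_term_order: int = 2) -> WatsonOperator:
    """Construct the Watson corrections for a molecular mode-space surface.

    The mass term is tabulated on the existing n-mode grids up to
    ``mass_term_order`` (2-mode by default); the VAM coupling is expanded
    into one-mode operator products in the converged VSCF modal basis.
    """
    modes = mode_surface.modes
    if modes.masses is None:
        raise ValueError("Watson terms require a Cartesian normal-mode model")
    subset = mode_surface.mode_subset
    zeta = zeta_constants(modes)
    mu_eq = inverse_inertia(modes.geometry, modes.masses)

    # ---- mass term as an n-mode expansion on the shared grids -------------
    u_surface = _MassTermSurface(mode_surface)
    u_rep = build_nmode(u_surface, nmode.omegas,
                        n_max=min(mass_term_order, nmode.n_modes),
                        grid_points_per_mode=nmode.grids[0].n)
    # build_nmode regenerates identical Gauss-Hermite grids from the same
    # omegas and point count, so these tensors share the potential's quadrature

    # ---- VAM product operators in the modal basis --------------------------
    q_mod, p_mod = [], []
    for i in range(nmode.n_modes):
        c = vscf.modal_coeffs[i]
        b = vscf.bases[i]
        q_mod.append(c.T @ b.q_matrix() @ c)
        p_mod.append(c.T @ b.p_matrix() @ c)

    def _mat(mode, kind):
        return q_mod[mode] if kind == "Q" else p_mod[mode]

    pi = _pi_terms(zeta, subset)
    vam_ops = []
    for a in range(3):
        for b in range(3):
            mu_ab = mu_eq[a, b]
            if abs(mu_ab) < 1e-14:
                continue
            for c1, ops1 in pi[a]:
                for c2, ops2 in pi[b]:
                    coef = 0.5 * mu_ab * c1 * c2
                    # multiply one-mode factors in operator order
                    mats: dict[int, np.ndarray] = {}
                    for mode, kind in (*ops1, *ops2):
                        m = _mat(mode, kind)
                        mats[mode] = mats[mode] @ m if mode in mats else m
                    vam_ops.append((coef, mats))

    return WatsonOperator(mu_eq=mu_eq, zeta=zeta,
                          mass_terms=dict(u_rep.terms),
                          mass_term_const=u_rep.v0,
                          vam_ops=vam_ops)
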