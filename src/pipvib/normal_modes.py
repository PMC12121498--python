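"""Stationary points, Hessians, and harmonic normal-mode analysis.

Works on any :class:`~pipvib.surface.Surface`.  For Cartesian molecular
surfaces the analysis mass-weights the Hessian, projects out rigid
translations and rotations (Eckart projector at the reference geometry), and
reports frequencies in cm^-1, with imaginary frequencies carried as negative
numbers.  Mode-space model potentials (already mass-scaled) are analyzed
without projection.

The resulting :class:`NormalModeModel` is the hand-off object to the VSCF/VCI
and semiclassical stages: it defines the mass-scaled normal coordinates Q and
the mapping back to Cartesians, R(Q) = R_eq + M^{-1/2} L Q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .constants import AMU_TO_ME, HARTREE_TO_INVCM
from .surface import Surface

__all__ = [
    "StationaryPoint",
    "NormalModeModel",
    "FrequencyComparison",
    "optimize",
    "hessian",
    "harmonic_analysis",
    "mode_analysis",
    "compare_frequencies",
    "ModeSpaceSurface",
]


@dataclass
class StationaryPoint:
    geometry: np.ndarray          # flat coordinate vector (bohr)
    energy: float                 # hartree
    gradient_norm: float          # max-norm, hartree/bohr
    converged: bool
    n_iterations: int
    surface: Surface = field(repr=False, default=None)


def optimize(surface: Surface, start_geometry, grad_tol: float = 1e-7,
             max_iter: int = 500) -> StationaryPoint:
    """Quasi-Newton (BFGS) descent to |grad|_inf < grad_tol.

    Exceeding the iteration budget yields an unconverged flag rather than an
    exception, so callers can inspect partial progress.
    """
    x0 = np.asarray(start_geometry, dtype=float).ravel()
    res = scipy.optimize.minimize(
        lambda x: surface.energy(x), x0, jac=lambda x: surface.gradient(x),
        method="BFGS", options={"gtol": grad_tol, "maxiter": max_iter},
    )
    gnorm = float(np.max(np.abs(surface.gradient(res.x))))
    return StationaryPoint(
        geometry=res.x, energy=float(res.fun), gradient_norm=gnorm,
        converged=bool(gnorm < grad_tol), n_iterations=int(res.nit),
        surface=surface,
    )


def hessian(surface: Surface, geometry, step: float = 1e-3) -> np.ndarray:
    """Symmetrized Cartesian Hessian from central differences of gradients."""
    return surface.hessian(np.asarray(geometry, dtype=float).ravel(), step=step)


@dataclass
class NormalModeModel:
    """Harmonic frequencies and the mass-scaled normal-coordinate frame.

    ``frequencies_cm`` are sorted ascending with imaginary modes as negative
    numbers; ``L`` holds orthonormal mass-weighted displacement vectors as
    columns (3N x F for Cartesian systems).  Masses are in electron masses;
    ``masses`` is None for abstract mode-space models.
    """

    frequencies_cm: np.ndarray
    L: np.ndarray = field(repr=False)
    geometry: np.ndarray = field(repr=False)
    masses: np.ndarray | None = None
    energy: float = 0.0

    @property
    def F(self) -> int:
        return len(self.frequencies_cm)

    @property
    def imaginary(self) -> np.ndarray:
        return self.frequencies_cm < 0

    @property
    def omegas_au(self) -> np.ndarray:
        """|frequencies| as angular frequencies in atomic units."""
        return np.abs(self.frequencies_cm) / HARTREE_TO_INVCM

    def cartesian_displacement(self, Q: np.ndarray) -> np.ndarray:
        """R(Q) = R_eq + M^{-1/2} L Q, flat Cartesian vector."""
        if self.masses is None:
            return self.geometry + self.L @ np.asarray(Q, dtype=float)
        inv_sqrt_m = 1.0 / np.sqrt(np.repeat(self.masses, 3))
        return self.geometry + inv_sqrt_m * (self.L @ np.asarray(Q, dtype=float))

    def report(self) -> str:
        lines = ["mode  frequency/cm^-1  imaginary"]
        for k, f in enumerate(self.frequencies_cm, start=1):
            lines.append(f"{k:4d}  {abs(f):14.2f}  {'yes' if f < 0 else 'no'}")
        return "\n".join(lines)

    # -- archive --------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "pipvib-modes-1",
            "frequencies_cm": self.frequencies_cm.tolist(),
            "L": self.L.tolist(),
            "geometry": self.geometry.tolist(),
            "masses": None if self.masses is None else self.masses.tolist(),
            "energy": self.energy,
        }

    def save(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "NormalModeModel":
        if d.get("format") != "pipvib-modes-1":
            raise ValueError("not a pipvib normal-mode archive")
        masses = d.get("masses")
        return cls(np.array(d["frequencies_cm"]), np.array(d["L"]),
                   np.array(d["geometry"]),
                   None if masses is None else np.array(masses),
                   d.get("energy", 0.0))

    @classmethod
    def load(cls, path) -> "NormalModeModel":
        import json
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _external_space(geometry: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation + rotation vectors (3N, 5 or 6)."""
    geom = geometry.reshape(-1, 3)
    n = geom.shape[0]
    sqrt_m = np.sqrt(masses)
    com = (masses[:, None] * geom).sum(axis=0) / masses.sum()
    x = geom - com
    vecs = []
    for alpha in range(3):
        t = np.zeros((n, 3))
        t[:, alpha] = sqrt_m
        vecs.append(t.ravel())
    for alpha in range(3):
        axis = np.zeros(3)
        axis[alpha] = 1.0
        r = np.cross(np.broadcast_to(axis, (n, 3)), x) * sqrt_m[:, None]
        vecs.append(r.ravel())
    V = np.array(vecs).T
    # QR with column pivoting via SVD: drop near-null rotations (linear case)
    u, s, _ = np.linalg.svd(V, full_matrices=False)
    keep = s > 1e-8 * s.max()
    return u[:, keep]


def harmonic_analysis(hess_cart: np.ndarray, masses_amu, geometry,
                      project: bool = True, energy: float = 0.0,
                      zero_tol_cm: float = 1.0) -> NormalModeModel:
    """Mass-weight, project out rigid motions, diagonalize, convert to cm^-1.

    ``hess_cart`` is the plain Cartesian Hessian (hartree/bohr^2); masses are
    given in amu.  Negative Hessian eigenvalues are reported as imaginary
    (negative) frequencies.
    """
    geometry = np.asarray(geometry, dtype=float).ravel()
    masses = np.asarray(masses_amu, dtype=float) * AMU_TO_ME
    n3 = hess_cart.shape[0]
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(masses, 3))
    h_mw = hess_cart * np.outer(inv_sqrt_m, inv_sqrt_m)
    h_mw = 0.5 * (h_mw + h_mw.T)

    if project:
        ext = _external_space(geometry, masses)
        # orthonormal basis of the internal (vibrational) complement
        proj = np.eye(n3) - ext @ ext.T
        u, s, _ = np.linalg.svd(proj)
        internal = u[:, s > 0.5]
        h_int = internal.T @ h_mw @ internal
        evals, evecs = np.linalg.eigh(h_int)
        L = internal @ evecs
        # count additional near-zero internal roots
        freqs = np.sign(evals) * np.sqrt(np.abs(evals)) * HARTREE_TO_INVCM
        n_extra_zero = int(np.sum(np.abs(freqs) < zero_tol_cm))
        if n_extra_zero:
            warnings.warn(f"{n_extra_zero} near-zero vibrational root(s) beyond "
                          "the 6 projected rigid motions")
    else:
        evals, L = np.linalg.eigh(h_mw)
        freqs = np.sign(evals) * np.sqrt(np.abs(evals)) * HARTREE_TO_INVCM

    order = np.argsort(freqs)
    return NormalModeModel(frequencies_cm=freqs[order], L=L[:, order],
                           geometry=geometry, masses=masses, energy=energy)


def mode_analysis(surface: Surface, x0=None, grad_tol: float = 1e-7) -> NormalModeModel:
    """Harmonic analysis of a mass-scaled mode-space model at its minimum.

    Convenience for abstract model potentials: no masses, no projection; the
    Hessian eigenvalues are squared angular frequencies directly.
    """
    if x0 is None:
        x0 = np.zeros(surface.n_dof)
    sp = optimize(surface, x0, grad_tol=grad_tol)
    h = surface.hessian(sp.geometry)
    evals, L = np.linalg.eigh(0.5 * (h + h.T))
    freqs = np.sign(evals) * np.sqrt(np.abs(evals)) * HARTREE_TO_INVCM
    order = np.argsort(freqs)
    return NormalModeModel(frequencies_cm=freqs[order], L=L[:, order],
                           geometry=sp.geometry, masses=None, energy=sp.energy)


@dataclass
class FrequencyComparison:
    """Aligned per-mode deviations between two frequency lists (cm^-1)."""

    a: np.ndarray
    b: np.ndarray
    deviations: np.ndarray
    mae_raw: float
    max_deviation: float
    excluded: np.ndarray

    @property
    def mae(self) -> int:
        """MAE rounded to integer cm^-1, the usual table convention."""
        return int(round(self.mae_raw))


def compare_frequencies(list_a, list_b, exclusions=None) -> FrequencyComparison:
    """Per-mode |a - b|, MAE and max deviation, with an optional exclusion mask.

    ``exclusions`` is a boolean mask (True = drop the mode, e.g. an imaginary
    torsional root) or an index list.  Raw (unrounded) MAE is always exposed
    so that rounding conventions in published tables can be audited.
    """
    a = np.asarray(list_a, dtype=float)
    b = np.asarray(list_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frequency lists have different lengths")
    mask = np.zeros(a.size, dtype=bool)
    if exclusions is not None:
        excl = np.asarray(exclusions)
        if excl.dtype == bool:
            mask = excl.copy()
        else:
            mask[excl] = True
    dev = np.abs(a[~mask] - b[~mask])
    if dev.size == 0:
        raise ValueError("no modes left after exclusions")
    return FrequencyComparison(a=a, b=b, deviations=dev,
                               mae_raw=float(dev.mean()),
                               max_deviation=float(dev.max()),
                               excluded=mask)


class ModeSpaceSurface(Surface):
    """A Cartesian surface re-expressed in mass-scaled normal coordinates.

    Freezes the modes outside ``mode_subset`` at Q = 0 and references the
    energy to the expansion point, so V(0) = 0.  This is the object the
    n-mode builder and the semiclassical propagator consume for molecular
    surfaces; abstract models are already in mode space and skip this wrapper.
    """

    def __init__(self, surface: Surface, modes: NormalModeModel,
                 mode_subset=None):
        self.parent = surface
        self.modes = modes
        all_modes = np.arange(modes.F)
        self.mode_subset = np.asarray(
            all_modes if mode_subset is None else mode_subset, dtype=int)
        self.n_dof = len(self.mode_subset)
        self._e0 = surface.energy(modes.geometry)
        if modes.masses is None:
            self._inv_sqrt_m = None
        else:
            self._inv_sqrt_m = 1.0 / np.sqrt(np.repeat(modes.masses, 3))
        self._Lsub = modes.L[:, self.mode_subset]

    @property
    def omegas_au(self) -> np.ndarray:
        return self.modes.omegas_au[self.mode_subset]

    def to_cartesian(self, q: np.ndarray) -> np.ndarray:
        disp = self._Lsub @ np.asarray(q, dtype=float)
        if self._inv_sqrt_m is not None:
            disp = disp * self._inv_sqrt_m
        return self.modes.geometry + disp

    def energy(self, q) -> float:
        return self.parent.energy(self.to_cartesian(np.asarray(q, float).ravel())) - self._e0

    def gradient(self, q) -> np.ndarray:
        g = self.parent.gradient(self.to_cartesian(np.asarray(q, float).ravel()))
        if self._inv_sqrt_m is not None:
            g = g * self._inv_sqrt_m
        return self._Lsub.T @ g
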