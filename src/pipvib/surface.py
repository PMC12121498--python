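"""Common interface for potential energy surfaces.

A surface maps a coordinate vector (flat, atomic units) to an energy in
hartree and exposes an analytic gradient.  Cartesian surfaces (e.g. fitted
PIP surfaces) take flattened ``3N`` vectors; model potentials defined
directly in mass-scaled normal coordinates take ``F``-vectors.  Everything
downstream (optimization, Hessians, n-mode representations, semiclassical
propagation) is written against this interface.
"""

from __future__ import annotations

import abc

import numpy as np


class Surface(abc.ABC):
    """A potential energy surface V(x) with analytic gradient."""

    #: number of scalar degrees of freedom of the coordinate vector
    n_dof: int

    @abc.abstractmethod
    def energy(self, x: np.ndarray) -> float:
        """Potential energy (hartree) at flat coordinate vector ``x``."""

    @abc.abstractmethod
    def gradient(self, x: np.ndarray) -> np.ndarray:
        """Analytic gradient dV/dx (hartree per a.u.), same shape as ``x``."""

    def hessian(self, x: np.ndarray, step: float = 1e-3) -> np.ndarray:
        """Hessian by central finite differences of the analytic gradient.

        Subclasses with analytic second derivatives override this.
        """
        x = np.asarray(x, dtype=float).ravel()
        n = x.size
        h = np.empty((n, n))
        for i in range(n):
            xp = x.copy()
            xp[i] += step
            xm = x.copy()
            xm[i] -= step
            h[i] = (self.gradient(xp) - self.gradient(xm)) / (2.0 * step)
        return 0.5 * (h + h.T)

    # Batched evaluation over an ensemble of points; the default loops, and
    # performance-sensitive surfaces (analytic models) override with
    # vectorized implementations.
    def energy_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return np.array([self.energy(xi) for xi in x])

    def gradient_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return np.array([self.gradient(xi) for xi in x])

    def hessian_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return np.array([self.hessian(xi) for xi in x])


def check_gradient(surface: Surface, x: np.ndarray, step: float = 1e-5) -> float:
    """Max relative deviation between analytic and central-difference gradient."""
    x = np.asarray(x, dtype=float).ravel()
    g = surface.gradient(x)
    num = np.empty_like(g)
    for i in range(x.size):
        xp = x.copy()
        xp[i] += step
        xm = x.copy()
        xm[i] -= step
        num[i] = (surface.energy(xp) - surface.energy(xm)) / (2.0 * step)
    scale = max(np.max(np.abs(num)), 1e-10)
    return float(np.max(np.abs(g - num)) / scale)
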