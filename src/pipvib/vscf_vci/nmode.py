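"""Hierarchical n-mode representation of a potential over normal coordinates.

The potential is expanded as

    V(Q) = sum_i V1_i(Q_i) + sum_{i<j} V2_ij(Q_i, Q_j) + ... (up to n_max <= 4)

where each term is *intrinsic*: it vanishes whenever any of its arguments is
zero, enforced by inclusion--exclusion over the lower-order terms.  Terms are
tabulated on direct-product Gauss--Hermite grids matched to each mode's
harmonic frequency, which later double as the quadrature for all VSCF/VCI
matrix elements.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ..surface import Surface

__all__ = ["ModeGrid", "NModeRepresentation", "build_nmode",
           "truncated_nmode_potential"]

_BATCH = 8192  # chunk size for surface evaluation on large meshes


@dataclass
class ModeGrid:
    """Gauss--Hermite quadrature for one mode at harmonic frequency omega.

    ``points`` are coordinates Q_g = x_g / sqrt(omega); ``weights`` are
    effective dQ weights W_g = w_g e^{x_g^2} / sqrt(omega), exact for
    integrands that decay at least like the mode's harmonic ground-state
    density.
    """

    omega: float
    points: np.ndarray
    weights: np.ndarray

    @classmethod
    def gauss_hermite(cls, omega: float, n: int) -> "ModeGrid":
        x, w = np.polynomial.hermite.hermgauss(n)
        s = np.sqrt(omega)
        return cls(omega=omega, points=x / s,
                   weights=np.exp(np.log(w) + x ** 2) / s)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class NModeRepresentation:
    """Tabulated intrinsic terms V^(n) on mode grids.

    ``terms[(i, j, ...)]`` is the intrinsic tensor on the product grid of the
    (sorted) mode tuple; indices refer to positions within ``mode_labels``.
    """

    mode_labels: tuple          # external mode identifiers (bookkeeping only)
    omegas: np.ndarray          # harmonic frequencies (a.u.) of the kept modes
    n_max: int
    grids: list = field(repr=False)
    terms: dict = field(repr=False)
    v0: float = 0.0             # potential at the expansion point

    @property
    def n_modes(self) -> int:
        return len(self.omegas)

    def term_orders(self):
        return sorted({len(k) for k in self.terms})

    def evaluate_on_grid_index(self, subset: tuple, idx: tuple) -> float:
        return float(self.terms[tuple(sorted(subset))][idx])


def _eval_batched(surface: Surface, points: np.ndarray) -> np.ndarray:
    out = np.empty(points.shape[0])
    for start in range(0, points.shape[0], _BATCH):
        out[start:start + _BATCH] = surface.energy_batch(points[start:start + _BATCH])
    return out


def build_nmode(surface_q: Surface, omegas, n_max: int = 4,
                grid_points_per_mode: int = 20, mode_labels=None) -> NModeRepresentation:
    """Tabulate intrinsic 1..n_max-mode terms of a mode-space potential.

    ``surface_q`` is a potential over the mass-scaled normal coordinates of
    the kept modes (e.g. a :class:`~pipvib.normal_modes.ModeSpaceSurface` or
    an analytic model); ``omegas`` are the harmonic frequencies (a.u.) that
    set the quadrature scaling.  Each unique cut is evaluated exactly once.
    """
    omegas = np.asarray(omegas, dtype=float)
    f = len(omegas)
    if surface_q.n_dof != f:
        raise ValueError("surface dimensionality does not match omegas")
    if not 1 <= n_max <= 4:
        raise ValueError("n_max must be between 1 and 4")
    if grid_points_per_mode < 8:
        raise ValueError("grid sizes below 8 points are not meaningful")
    n_max = min(n_max, f)
    mode_labels = tuple(range(f)) if mode_labels is None else tuple(mode_labels)

    grids = [ModeGrid.gauss_hermite(w, grid_points_per_mode) for w in omegas]
    v0 = float(surface_q.energy(np.zeros(f)))

    terms: dict[tuple, np.ndarray] = {}
    for order in range(1, n_max + 1):
        for subset in itertools.combinations(range(f), order):
            shape = tuple(grids[i].n for i in subset)
            mesh = np.meshgrid(*[grids[i].points for i in subset], indexing="ij")
            pts = np.zeros((int(np.prod(shape)), f))
            for ax, i in enumerate(subset):
                pts[:, i] = mesh[ax].ravel()
            raw = _eval_batched(surface_q, pts).reshape(shape) - v0
            # subtract every lower-order intrinsic term on the matching axes
            for sub_order in range(1, order):
                for t in itertools.combinations(subset, sub_order):
                    lower = terms[t]
                    expand = [slice(None) if i in t else None for i in subset]
                    raw = raw - lower[tuple(expand)]
            terms[subset] = raw

    return NModeRepresentation(mode_labels=mode_labels, omegas=omegas,
                               n_max=n_max, grids=grids, terms=terms, v0=v0)


def truncated_nmode_potential(surface_q: Surface, f: int, n_max: int):
    """Exact n-mode-truncated potential as a callable on arbitrary points.

    Computes the inclusion--exclusion hierarchy on the fly (caching cuts per
    point), so the truncation itself -- not a grid interpolation -- can be
    compared against the full potential.  Used to verify, e.g., that a sum of
    pairwise couplings is reproduced exactly at 2-mode truncation.
    """

    def v_truncated(q):
        q = np.asarray(q, dtype=float).ravel()
        if q.size != f:
            raise ValueError("point dimensionality mismatch")
        v0 = float(surface_q.energy(np.zeros(f)))
        intrinsic: dict[tuple, float] = {(): 0.0}
        total = 0.0
        for order in range(1, min(n_max, f) + 1):
            for subset in itertools.combinations(range(f), order):
                pt = np.zeros(f)
                pt[list(subset)] = q[list(subset)]
                raw = float(surface_q.energy(pt)) - v0
                for sub_order in range(1, order):
                    for t in itertools.combinations(subset, sub_order):
                        raw -= intrinsic[t]
                intrinsic[subset] = raw
                total += raw
        return total + v0

    return v_truncated
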