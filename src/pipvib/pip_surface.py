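"""Permutationally invariant polynomial (PIP) surfaces.

A PIP basis is built over Morse variables x_ab = exp(-r_ab / lambda), one per
unordered atom pair.  Permutations of like atoms (a "like-atom partition"
such as ``22222``) induce a permutation group on the pair variables; each
basis function is the sum of a monomial over its orbit under that group, so
the fitted potential

    V(x) = c_0 + sum_i c_i p_i(x)

is exactly invariant under any like-atom exchange.  Coefficients are obtained
by weighted linear least squares on energies and forces jointly.

Conventions
-----------
* The enumerated basis contains the orbits of monomials of total degree
  1..max_order; the constant (degree-0) polynomial is handled as an explicit
  intercept so that the total coefficient count is ``n_p + 1``.  For a
  10-atom system with partition 22222 at order 4 this gives 16,980 + 1 =
  16,981 linear coefficients.
* Orbit functions are sums over the *distinct* monomials of the orbit; any
  normalization difference with respect to a sum over group elements is a
  per-orbit constant absorbed by the linear coefficient.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist

from .surface import Surface

__all__ = [
    "LikeAtomPartition",
    "PIPBasis",
    "PIPSurface",
    "FitProblem",
    "FitReport",
    "generate_basis",
    "morse_variables",
    "build_fit_problem",
    "solve_fit",
]

DEFAULT_LAMBDA = 2.0  # bohr, Morse range hyperparameter


# ----------------------------------------------------------------------------
# like-atom partitions and the induced action on atom pairs
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class LikeAtomPartition:
    """Grouping of atoms into blocks of interchangeable (like) atoms.

    ``sizes`` are the ordered block sizes, e.g. ``(2, 2, 2, 2, 2)`` written
    "22222"; atoms are assigned to blocks consecutively in input order.
    """

    sizes: tuple[int, ...]

    @classmethod
    def parse(cls, spec) -> "LikeAtomPartition":
        if isinstance(spec, LikeAtomPartition):
            return spec
        if isinstance(spec, str):
            if not spec.isdigit():
                raise ValueError(f"cannot parse partition string {spec!r}")
            return cls(tuple(int(ch) for ch in spec))
        return cls(tuple(int(s) for s in spec))

    @property
    def n_atoms(self) -> int:
        return sum(self.sizes)

    @property
    def blocks(self) -> list[list[int]]:
        out, start = [], 0
        for s in self.sizes:
            out.append(list(range(start, start + s)))
            start += s
        return out

    @property
    def group_order(self) -> int:
        return math.prod(math.factorial(s) for s in self.sizes)

    def group_elements(self) -> list[np.ndarray]:
        """All atom permutations in the direct product of per-block S_k."""
        per_block = [list(itertools.permutations(b)) for b in self.blocks]
        elems = []
        for combo in itertools.product(*per_block):
            perm = np.empty(self.n_atoms, dtype=np.int64)
            for block, image in zip(self.blocks, combo):
                perm[block] = image
            elems.append(perm)
        return elems

    def __str__(self) -> str:
        return "".join(str(s) for s in self.sizes)


def _pair_list(n_atoms: int) -> list[tuple[int, int]]:
    """Canonical (lexicographic) ordering of unordered atom pairs."""
    return list(itertools.combinations(range(n_atoms), 2))


def _induced_pair_permutation(atom_perm: np.ndarray, n_atoms: int) -> np.ndarray:
    pairs = _pair_list(n_atoms)
    index = {p: i for i, p in enumerate(pairs)}
    out = np.empty(len(pairs), dtype=np.int64)
    for i, (a, b) in enumerate(pairs):
        ia, ib = atom_perm[a], atom_perm[b]
        out[i] = index[(ia, ib) if ia < ib else (ib, ia)]
    return out


# ----------------------------------------------------------------------------
# basis enumeration
# ----------------------------------------------------------------------------

@dataclass
class PIPBasis:
    """Symmetrized-monomial basis over pair Morse variables.

    Monomials are stored as rows of variable indices padded with the sentinel
    ``n_pairs`` (which evaluates to the neutral factor 1); rows are grouped
    contiguously by orbit, with ``orbit_ptr[i]:orbit_ptr[i+1]`` delimiting the
    monomials of basis function ``i``.
    """

    n_atoms: int
    partition: LikeAtomPartition
    max_order: int
    lam: float = DEFAULT_LAMBDA
    monomials: np.ndarray = field(repr=False, default=None)
    orbit_ptr: np.ndarray = field(repr=False, default=None)
    degrees: np.ndarray = field(repr=False, default=None)

    @property
    def n_pairs(self) -> int:
        return self.n_atoms * (self.n_atoms - 1) // 2

    @property
    def n_p(self) -> int:
        """Number of symmetrized polynomials (degree >= 1, constant excluded)."""
        return len(self.orbit_ptr) - 1

    def n_coefficients(self, include_constant: bool = True) -> int:
        """Total linear coefficient count of a surface on this basis."""
        return self.n_p + (1 if include_constant else 0)

    @property
    def _mono_basis_index(self) -> np.ndarray:
        counts = np.diff(self.orbit_ptr)
        return np.repeat(np.arange(self.n_p), counts)

    def values(self, x: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at Morse-variable vector ``x``."""
        x_ext = np.append(np.asarray(x, dtype=float), 1.0)
        mono_vals = np.prod(x_ext[self.monomials], axis=1)
        return np.add.reduceat(mono_vals, self.orbit_ptr[:-1])

    def values_and_jacobian(self, x: np.ndarray):
        """Basis values and d(basis)/dx, shape (n_p,) and (n_p, n_pairs)."""
        x_ext = np.append(np.asarray(x, dtype=float), 1.0)
        xa = x_ext[self.monomials]  # (n_mono, max_order)
        n_mono, k = xa.shape
        vals = np.add.reduceat(np.prod(xa, axis=1), self.orbit_ptr[:-1])
        # product over all slots except slot s, via prefix/suffix products
        pref = np.ones((n_mono, k + 1))
        suf = np.ones((n_mono, k + 1))
        np.cumprod(xa, axis=1, out=pref[:, 1:])
        np.cumprod(xa[:, ::-1], axis=1, out=suf[:, 1:])
        jac = np.zeros((self.n_p, self.n_pairs + 1))
        bidx = self._mono_basis_index
        for s in range(k):
            others = pref[:, s] * suf[:, k - 1 - s]
            np.add.at(jac, (bidx, self.monomials[:, s]), others)
        return vals, jac[:, :-1]

    def spec_dict(self) -> dict:
        return {
            "n_atoms": self.n_atoms,
            "partition": str(self.partition),
            "max_order": self.max_order,
            "lambda_bohr": self.lam,
            "n_p": self.n_p,
        }


def _encode_rows(rows: np.ndarray, base: int) -> np.ndarray:
    """Encode sorted monomial rows as comparable int64 keys."""
    k = rows.shape[1]
    keys = np.zeros(rows.shape[0], dtype=np.int64)
    for s in range(k):
        keys = keys * base + rows[:, s]
    return keys


def generate_basis(
    n_atoms: int,
    partition,
    max_order: int,
    lam: float = DEFAULT_LAMBDA,
) -> PIPBasis:
    """Enumerate the orbits of pair-variable monomials of degree 1..max_order.

    Every monomial (multiset of pair-variable indices) is mapped through each
    element of the induced permutation group; its orbit's lexicographically
    smallest image is the canonical representative, and monomials sharing a
    canonical form constitute one symmetrized basis function.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    partition = LikeAtomPartition.parse(partition)
    if partition.n_atoms != n_atoms:
        raise ValueError(
            f"partition {partition} sums to {partition.n_atoms}, expected {n_atoms}"
        )
    n_pairs = n_atoms * (n_atoms - 1) // 2
    sentinel = n_pairs

    rows = []
    for deg in range(1, max_order + 1):
        combos = np.array(
            list(itertools.combinations_with_replacement(range(n_pairs), deg)),
            dtype=np.int64,
        ).reshape(-1, deg)
        padded = np.full((combos.shape[0], max_order), sentinel, dtype=np.int64)
        padded[:, :deg] = combos
        rows.append(padded)
    monomials = np.vstack(rows)
    degrees = np.sum(monomials != sentinel, axis=1)

    base = n_pairs + 1
    canon = _encode_rows(monomials, base)
    for atom_perm in partition.group_elements():
        pair_perm = _induced_pair_permutation(atom_perm, n_atoms)
        pp_ext = np.append(pair_perm, sentinel)
        image = np.sort(pp_ext[monomials], axis=1)
        np.minimum(canon, _encode_rows(image, base), out=canon)

    # group monomials by canonical key, order orbits by (degree, key)
    ukeys, inverse = np.unique(canon, return_inverse=True)
    udeg = np.zeros(len(ukeys), dtype=np.int64)
    udeg[inverse] = degrees
    orbit_order = np.lexsort((ukeys, udeg))
    rank = np.empty(len(ukeys), dtype=np.int64)
    rank[orbit_order] = np.arange(len(ukeys))
    basis_index = rank[inverse]
    mono_order = np.argsort(basis_index, kind="stable")
    monomials = monomials[mono_order]
    counts = np.bincount(basis_index, minlength=len(ukeys))
    orbit_ptr = np.concatenate([[0], np.cumsum(counts)])

    return PIPBasis(
        n_atoms=n_atoms,
        partition=partition,
        max_order=max_order,
        lam=lam,
        monomials=monomials,
        orbit_ptr=orbit_ptr,
        degrees=udeg[orbit_order],
    )


def count_basis_burnside(n_atoms: int, partition, max_order: int) -> int:
    """Orbit count of degree-1..max_order monomials by Burnside's lemma.

    Independent of the explicit enumeration: for each group element the fixed
    monomials are counted from the cycle structure of the induced pair
    permutation via a truncated generating function.
    """
    partition = LikeAtomPartition.parse(partition)
    if partition.n_atoms != n_atoms:
        raise ValueError("partition does not sum to n_atoms")
    total = 0
    for atom_perm in partition.group_elements():
        pair_perm = _induced_pair_permutation(atom_perm, n_atoms)
        seen = np.zeros(len(pair_perm), dtype=bool)
        poly = np.zeros(max_order + 1)
        poly[0] = 1.0
        for i in range(len(pair_perm)):
            if seen[i]:
                continue
            length, j = 0, i
            while not seen[j]:
                seen[j] = True
                j = pair_perm[j]
                length += 1
            new = poly.copy()
            for kk in range(length, max_order + 1, length):
                new[kk:] += poly[: max_order + 1 - kk]
            poly = new
        total += int(round(poly[1:].sum()))
    assert total % partition.group_order == 0
    return total // partition.group_order


# ----------------------------------------------------------------------------
# Morse variables
# ----------------------------------------------------------------------------

_MIN_DISTANCE = 1e-8  # bohr; below this atoms are treated as coincident


def morse_variables(geometry: np.ndarray, lam: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Morse variables exp(-r_ab/lambda) in canonical pair order (bohr in)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    geom = np.asarray(geometry, dtype=float).reshape(-1, 3)
    r = pdist(geom)
    if np.any(r < _MIN_DISTANCE):
        raise ValueError("coincident atoms: zero internuclear distance")
    return np.exp(-r / lam)


def _morse_chain(geometry: np.ndarray, lam: float):
    """Morse variables plus what the Cartesian chain rule needs.

    Returns (x, pair index arrays (a, b), unit vectors u_ab) with
    dx_p/dR_a = -(x_p/lam) u_ab and dx_p/dR_b = +(x_p/lam) u_ab.
    """
    geom = np.asarray(geometry, dtype=float).reshape(-1, 3)
    n = geom.shape[0]
    pairs = np.array(_pair_list(n))
    a, b = pairs[:, 0], pairs[:, 1]
    diff = geom[a] - geom[b]
    r = np.linalg.norm(diff, axis=1)
    if np.any(r < _MIN_DISTANCE):
        raise ValueError("coincident atoms: zero internuclear distance")
    x = np.exp(-r / lam)
    return x, a, b, diff / r[:, None]


def _pair_to_cartesian(dV_dx: np.ndarray, x, a, b, units, lam, n_atoms) -> np.ndarray:
    """Chain dV/dx (per pair) into a Cartesian gradient (N, 3)."""
    g = np.zeros((n_atoms, 3))
    w = (dV_dx * x / lam)[:, None] * units
    np.add.at(g, a, -w)
    np.add.at(g, b, w)
    return g


# ----------------------------------------------------------------------------
# the fitted surface
# ----------------------------------------------------------------------------

class PIPSurface(Surface):
    """V(x) = intercept + sum_i c_i p_i(x) over a PIP basis."""

    def __init__(self, basis: PIPBasis, coefficients: np.ndarray,
                 intercept: float = 0.0, provenance: dict | None = None):
        coefficients = np.asarray(coefficients, dtype=float)
        if coefficients.shape != (basis.n_p,):
            raise ValueError(
                f"expected {basis.n_p} coefficients, got {coefficients.shape}"
            )
        self.basis = basis
        self.coefficients = coefficients
        self.intercept = float(intercept)
        self.provenance = provenance or {}
        self.n_dof = 3 * basis.n_atoms

    def energy(self, geometry: np.ndarray) -> float:
        x = morse_variables(geometry, self.basis.lam)
        return float(self.coefficients @ self.basis.values(x) + self.intercept)

    def gradient(self, geometry: np.ndarray) -> np.ndarray:
        x, a, b, units = _morse_chain(geometry, self.basis.lam)
        _, jac = self.basis.values_and_jacobian(x)
        dV_dx = self.coefficients @ jac
        g = _pair_to_cartesian(dV_dx, x, a, b, units, self.basis.lam,
                               self.basis.n_atoms)
        return g.ravel()

    def design_block(self, geometry: np.ndarray):
        """Per-configuration design rows: basis values and basis gradients.

        Returns ``(values, grad)`` with ``values`` of shape (n_p,) and
        ``grad[i]`` the flattened Cartesian gradient of basis function i,
        shape (n_p, 3N).
        """
        return _design_block(self.basis, geometry)

    # -- serialization: self-describing text archive -------------------------
    def to_dict(self) -> dict:
        return {
            "format": "pipvib-surface-1",
            "basis": self.basis.spec_dict(),
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "provenance": self.provenance,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, data: dict) -> "PIPSurface":
        if data.get("format") != "pipvib-surface-1":
            raise ValueError("not a pipvib surface archive")
        spec = data["basis"]
        basis = generate_basis(spec["n_atoms"], spec["partition"],
                               spec["max_order"], spec["lambda_bohr"])
        if basis.n_p != spec["n_p"]:
            raise ValueError("basis regeneration mismatch: archive corrupt?")
        return cls(basis, np.array(data["coefficients"]),
                   data.get("intercept", 0.0), data.get("provenance"))

    @classmethod
    def load(cls, path) -> "PIPSurface":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _design_block(basis: PIPBasis, geometry: np.ndarray):
    x, a, b, units = _morse_chain(geometry, basis.lam)
    vals, jac = basis.values_and_jacobian(x)  # jac: (n_p, n_pairs)
    n = basis.n_atoms
    grad = np.zeros((basis.n_p, n, 3))
    w = (jac * (x / basis.lam)[None, :])  # (n_p, n_pairs)
    contrib = w[:, :, None] * units[None, :, :]
    np.subtract.at(grad, (slice(None), a), contrib)
    np.add.at(grad, (slice(None), b), contrib)
    return vals, grad.reshape(basis.n_p, 3 * n)


# ----------------------------------------------------------------------------
# weighted least-squares fitting
# ----------------------------------------------------------------------------

@dataclass
class FitProblem:
    """Stacked linear system for joint energy + force fitting.

    Rows per configuration: one energy row followed by 3N force rows carrying
    the *negative* basis gradients (model force = -grad V); the target vector
    holds the energy then the force components.  A per-configuration weight
    wt = E0/(E0 + dE), with dE the energy above the training-set minimum,
    multiplies that configuration's rows.
    """

    design: np.ndarray
    targets: np.ndarray
    row_weights: np.ndarray
    is_energy_row: np.ndarray
    config_index: np.ndarray
    basis: PIPBasis
    E0: float
    eta: float = 0.0
    include_intercept: bool = True

    @property
    def n_rows(self) -> int:
        return self.design.shape[0]

    @property
    def n_coefficients(self) -> int:
        return self.design.shape[1]

    @staticmethod
    def expected_row_count(n_configs: int, n_atoms: int) -> int:
        """Observation count: one energy plus 3N force components each."""
        return n_configs * (1 + 3 * n_atoms)

    @staticmethod
    def expected_gradient_row_count(n_configs: int, n_atoms: int) -> int:
        return n_configs * 3 * n_atoms


def configuration_weights(energies: np.ndarray, E0: float) -> np.ndarray:
    """wt = E0 / (E0 + dE), dE the energy above the set minimum (hartree)."""
    if E0 <= 0:
        raise ValueError("E0 must be positive")
    energies = np.asarray(energies, dtype=float)
    dE = energies - energies.min()
    return E0 / (E0 + dE)


def build_fit_problem(
    training_set,
    basis: PIPBasis,
    E0: float = 1e10,
    eta: float = 0.0,
    w_energy: float = 1.0,
    w_force: float = 1.0,
    include_intercept: bool = True,
) -> FitProblem:
    """Assemble the design matrix / target vector from a training set.

    ``training_set`` provides ``geometries`` (n, N, 3 bohr), ``energies``
    (hartree) and ``gradients`` (n, N, 3 hartree/bohr).  ``E0`` defaults to a
    huge value (all weights ~1, the unweighted fit); E0 = 0.01 hartree is the
    usual weighted choice emphasizing low-energy data.
    """
    geoms = np.asarray(training_set.geometries, dtype=float)
    energies = np.asarray(training_set.energies, dtype=float)
    grads = np.asarray(training_set.gradients, dtype=float)
    n_cfg = len(energies)
    if n_cfg == 0:
        raise ValueError("training set is empty")
    n_atoms = basis.n_atoms
    if geoms.shape[1:] != (n_atoms, 3):
        raise ValueError("geometry shape does not match basis atom count")

    wts = configuration_weights(energies, E0)
    rows_per = 1 + 3 * n_atoms
    n_cols = basis.n_p + (1 if include_intercept else 0)
    design = np.empty((n_cfg * rows_per, n_cols))
    targets = np.empty(n_cfg * rows_per)
    row_w = np.empty(n_cfg * rows_per)
    is_energy = np.zeros(n_cfg * rows_per, dtype=bool)
    cfg_idx = np.repeat(np.arange(n_cfg), rows_per)

    off = 1 if include_intercept else 0
    for i in range(n_cfg):
        vals, bgrad = _design_block(basis, geoms[i])
        r0 = i * rows_per
        if include_intercept:
            design[r0, 0] = 1.0
            design[r0 + 1: r0 + rows_per, 0] = 0.0
        design[r0, off:] = vals
        design[r0 + 1: r0 + rows_per, off:] = -bgrad.T
        targets[r0] = energies[i]
        targets[r0 + 1: r0 + rows_per] = -grads[i].ravel()
        row_w[r0] = w_energy * wts[i]
        row_w[r0 + 1: r0 + rows_per] = w_force * wts[i]
        is_energy[r0] = True

    return FitProblem(design, targets, row_w, is_energy, cfg_idx, basis,
                      E0=E0, eta=eta, include_intercept=include_intercept)


@dataclass
class FitReport:
    """Fit quality metrics; energy RMSEs in cm^-1, force RMSEs in hartree/bohr."""

    rmse_energy_cm: float
    rmse_energy_weighted_cm: float
    rmse_force: float
    rmse_force_weighted: float
    residual_quantiles: dict
    E0: float
    eta: float
    rank: int
    n_rows: int
    n_coefficients: int
    rank_deficient: bool = False

    def summary(self) -> str:
        lines = [
            f"rows x coefficients : {self.n_rows} x {self.n_coefficients}"
            f" (rank {self.rank}{', DEFICIENT' if self.rank_deficient else ''})",
            f"energy RMSE  : {self.rmse_energy_cm:10.3f} cm^-1 (unweighted)",
            f"             : {self.rmse_energy_weighted_cm:10.3f} cm^-1 (weighted, E0={self.E0:g})",
            f"force RMSE   : {self.rmse_force:12.7f} hartree/bohr (unweighted)",
            f"             : {self.rmse_force_weighted:12.7f} hartree/bohr (weighted)",
        ]
        return "\n".join(lines)


def solve_fit(problem: FitProblem, rcond: float = 1e-12):
    """Minimum-norm weighted least squares via SVD (+ optional ridge).

    Singular values below ``rcond`` times the largest are truncated.  With
    ``eta > 0`` the ridge term eta * ||c||^2 is added through augmented rows
    (identity ridge matrix).  Returns ``(PIPSurface, FitReport)``.
    """
    from .constants import HARTREE_TO_INVCM

    sw = np.sqrt(problem.row_weights)
    A = problem.design * sw[:, None]
    b = problem.targets * sw
    n_cols = problem.n_coefficients
    if problem.eta > 0:
        A = np.vstack([A, np.sqrt(problem.eta) * np.eye(n_cols)])
        b = np.concatenate([b, np.zeros(n_cols)])
    elif problem.n_rows < n_cols:
        warnings.warn("fewer rows than coefficients with eta=0; "
                      "returning the minimum-norm solution")

    coeffs, _, rank, _ = scipy.linalg.lstsq(A, b, cond=rcond,
                                            lapack_driver="gelsd")
    rank_deficient = rank < n_cols
    if rank_deficient and problem.eta == 0:
        warnings.warn(f"rank-deficient least squares (rank {rank} < {n_cols}); "
                      "minimum-norm solution returned")

    resid = problem.design @ coeffs - problem.targets
    e_mask = problem.is_energy_row
    w = problem.row_weights

    def _rmse(r, ww=None):
        if ww is None:
            return float(np.sqrt(np.mean(r ** 2))) if r.size else 0.0
        return float(np.sqrt(np.sum(ww * r ** 2) / np.sum(ww))) if r.size else 0.0

    report = FitReport(
        rmse_energy_cm=_rmse(resid[e_mask]) * HARTREE_TO_INVCM,
        rmse_energy_weighted_cm=_rmse(resid[e_mask], w[e_mask]) * HARTREE_TO_INVCM,
        rmse_force=_rmse(resid[~e_mask]),
        rmse_force_weighted=_rmse(resid[~e_mask], w[~e_mask]),
        residual_quantiles={
            q: float(np.quantile(np.abs(resid), q)) for q in (0.5, 0.9, 0.99)
        },
        E0=problem.E0,
        eta=problem.eta,
        rank=int(rank),
        n_rows=problem.n_rows,
        n_coefficients=n_cols,
        rank_deficient=rank_deficient,
    )
    if problem.include_intercept:
        surface = PIPSurface(problem.basis, coeffs[1:], intercept=coeffs[0])
    else:
        surface = PIPSurface(problem.basis, coeffs)
    surface.provenance = {"fit": {"E0": problem.E0, "eta": problem.eta,
                                  "rank": int(rank)}}
    return surface, report
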