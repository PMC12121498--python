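"""Virtual-state configuration interaction on VSCF modals.

Configurations are products of VSCF modals with up to four simultaneously
excited modes; the excitation space is pruned by per-class caps on the total
quanta (e.g. "10 10 10 8": singles through triples up to 10 quanta,
quadruples up to 8).  Matrix elements over the n-mode terms factorize into
one-mode quadratures; optional extra operators (the Watson vibrational
angular momentum terms) enter as products of one-mode matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg

from ..constants import HARTREE_TO_INVCM
from .nmode import NModeRepresentation
from .vscf import VSCFResult

__all__ = [
    "VCISpaceSpec", "VCISolution", "StateAssignment",
    "enumerate_space", "count_space", "assemble_and_solve", "assign_states",
    "config_label",
]

_DENSE_LIMIT = 2000
_MODAL_TENSOR_BUDGET = 4e7  # floats; guards n_modal^(2*order) precomputation


@dataclass(frozen=True)
class VCISpaceSpec:
    """Pruned excitation space: per-class total-quanta caps.

    ``caps[k-1]`` bounds the total quanta of configurations with exactly k
    excited modes; the class list may be shorter than 4 (no higher
    excitations then).  ``n_modals`` bounds the per-mode quantum number.
    """

    n_modes: int
    caps: tuple
    n_modals: int

    def __post_init__(self):
        if len(self.caps) > 4:
            raise ValueError("at most quadruple excitations are supported")
        if any(c > self.n_modals - 1 for c in self.caps):
            raise ValueError(
                f"caps {self.caps} exceed the modal range (n_modals={self.n_modals})")


def enumerate_space(spec: VCISpaceSpec) -> np.ndarray:
    """All configurations respecting the caps, in canonical order.

    Order: by excitation class, then total quanta, then lexicographically by
    (mode tuple, quanta tuple).  The ground configuration comes first.
    """
    f = spec.n_modes
    configs = [tuple([0] * f)]
    for k, cap in enumerate(spec.caps, start=1):
        if k > f:
            break
        block = []
        for total in range(k, cap + 1):
            for modes in itertools.combinations(range(f), k):
                # compositions of `total` into k parts, each 1..n_modals-1
                for cuts in itertools.combinations(range(1, total), k - 1):
                    parts = np.diff((0, *cuts, total))
                    if np.any(parts > spec.n_modals - 1):
                        continue
                    cfg = [0] * f
                    for m, q in zip(modes, parts):
                        cfg[m] = int(q)
                    block.append((total, modes, tuple(cfg)))
        block.sort()
        configs.extend(c for _, _, c in block)
    return np.array(configs, dtype=np.int32)


def count_space(spec: VCISpaceSpec) -> int:
    """Configuration count by closed-form combinatorics (enumeration oracle).

    Per class k: sum over totals q of C(F, k) * (compositions of q into k
    positive parts bounded by n_modals - 1).
    """
    from math import comb

    f = spec.n_modes
    nmax = spec.n_modals - 1
    total = 1
    for k, cap in enumerate(spec.caps, start=1):
        if k > f:
            break
        for q in range(k, cap + 1):
            # bounded compositions via inclusion-exclusion
            comps = sum((-1) ** j * comb(k, j) * comb(q - j * nmax - 1, k - 1)
                        for j in range(k + 1) if q - j * nmax - 1 >= k - 1)
            total += comb(f, k) * comps
    return total


# ----------------------------------------------------------------------------
# matrix assembly
# ----------------------------------------------------------------------------

_EINSUM = {
    1: "abg,g->ab",
    2: "abg,cdh,gh->abcd",
    3: "abg,cdh,efk,ghk->abcdef",
    4: "abg,cdh,efk,lmo,ghko->abcdeflm",
}


def _modal_term_tensor(term: np.ndarray, dmats: list) -> np.ndarray:
    """Contract a grid tensor with transition densities into modal space."""
    order = term.ndim
    size = dmats[0].shape[0] ** (2 * order)
    if size > _MODAL_TENSOR_BUDGET:
        raise MemoryError(
            "modal tensor too large; reduce n_modal or the coupling order")
    return np.einsum(_EINSUM[order], *dmats, term, optimize=True)


def _config_groups(configs: np.ndarray, involved) -> list:
    """Indices of configurations identical outside the involved modes."""
    masked = configs.copy()
    masked[:, list(involved)] = 0
    _, inverse = np.unique(masked, axis=0, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    sorted_inv = inverse[order]
    boundaries = np.flatnonzero(np.diff(sorted_inv)) + 1
    return np.split(order, boundaries)


def _term_block(vs: np.ndarray, sub: np.ndarray) -> np.ndarray:
    """Matrix block of a modal-space term over a group's sub-configurations."""
    order = sub.shape[1]
    idx = []
    for k in range(order):
        idx.append(sub[:, None, k])
        idx.append(sub[None, :, k])
    return vs[tuple(idx)]


@dataclass
class VCISolution:
    """Eigenvalues and expansion coefficients of the VCI matrix.

    ``energies`` are absolute (hartree above the potential expansion point);
    ``energies_cm`` are relative to the zero-point level.  ``coefficients``
    is (n_configs, n_states) with unit-norm columns.
    """

    energies: np.ndarray
    coefficients: np.ndarray = field(repr=False)
    configs: np.ndarray = field(repr=False)
    spec: VCISpaceSpec = None
    vscf_energy: float = 0.0

    @property
    def zpe(self) -> float:
        return float(self.energies[0])

    @property
    def energies_cm(self) -> np.ndarray:
        return (self.energies - self.zpe) * HARTREE_TO_INVCM

    @property
    def n_states(self) -> int:
        return len(self.energies)

    def dominant_configs(self, top_k: int = 3):
        """Per state: the top_k (coefficient, config index) pairs by weight."""
        out = []
        for s in range(self.n_states):
            c = self.coefficients[:, s]
            order = np.argsort(-np.abs(c))[:top_k]
            out.append([(float(c[i]), int(i)) for i in order])
        return out


def assemble_and_solve(nmode: NModeRepresentation, vscf: VSCFResult,
                       space, n_states: int | None = None,
                       e_max_cm: float | None = None,
                       extra_terms: dict | None = None,
                       product_ops: list | None = None,
                       energy_shift: float = 0.0) -> VCISolution:
    """Assemble the VCI matrix in the VSCF modal basis and diagonalize.

    ``space`` is a :class:`VCISpaceSpec` or an explicit configuration array.
    ``extra_terms`` are additional grid-tabulated potential-like terms (the
    Watson mass correction); ``product_ops`` are (coefficient, {mode:
    matrix}) one-mode operator products in the modal basis (the pi-mu-pi
    vibrational angular momentum terms).  Dense diagonalization below 2000
    configurations, iterative (Lanczos) above.
    """
    if isinstance(space, VCISpaceSpec):
        configs = enumerate_space(space)
        spec = space
    else:
        configs = np.asarray(space, dtype=np.int32)
        spec = None
    n_cfg = len(configs)
    f = nmode.n_modes

    # one-mode ingredients in the modal basis
    t_mod, dmats = [], []
    for i in range(f):
        c = vscf.modal_coeffs[i]
        t_mod.append(c.T @ vscf.bases[i].kinetic @ c)
        phi = vscf.modal_values(i)  # (n_modal, n_grid)
        dmats.append(np.einsum("ag,bg,g->abg", phi, phi, nmode.grids[i].weights))

    use_complex = bool(product_ops) and any(
        np.iscomplexobj(m) for _, mats in product_ops for m in mats.values())
    h = np.zeros((n_cfg, n_cfg), dtype=complex if use_complex else float)

    # kinetic energy: one-mode matrix terms
    for i in range(f):
        for idx in _config_groups(configs, (i,)):
            sub = configs[np.ix_(idx, [i])][:, 0]
            h[np.ix_(idx, idx)] += t_mod[i][sub[:, None], sub[None, :]]

    # potential terms (n-mode representation, plus any extra tabulated terms)
    all_terms = dict(nmode.terms)
    if extra_terms:
        for subset, tensor in extra_terms.items():
            key = tuple(sorted(subset))
            all_terms[key] = all_terms.get(key, 0.0) + tensor
    for subset, tensor in all_terms.items():
        vs = _modal_term_tensor(tensor, [dmats[i] for i in subset])
        for idx in _config_groups(configs, subset):
            sub = configs[np.ix_(idx, list(subset))]
            h[np.ix_(idx, idx)] += _term_block(vs, sub)

    # operator products (vibrational angular momentum)
    for coef, mats in (product_ops or []):
        involved = sorted(mats)
        for idx in _config_groups(configs, involved):
            block = np.full((len(idx), len(idx)), coef,
                            dtype=complex if use_complex else float)
            for m in involved:
                sub = configs[np.ix_(idx, [m])][:, 0]
                block = block * mats[m][sub[:, None], sub[None, :]]
            h[np.ix_(idx, idx)] += block

    herm = np.max(np.abs(h - h.conj().T))
    if herm > 1e-9:
        raise RuntimeError(f"non-Hermitian VCI matrix (|H - H^+| = {herm:.2e}); "
                           "this indicates an assembly bug")
    if use_complex:
        h = 0.5 * (h + h.conj().T)

    if n_cfg <= _DENSE_LIMIT or n_states is None:
        evals, evecs = np.linalg.eigh(h)
    else:
        k = min(n_states, n_cfg - 2)
        evals, evecs = scipy.sparse.linalg.eigsh(h, k=k, which="SA")
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]

    if n_states is not None:
        evals, evecs = evals[:n_states], evecs[:, :n_states]
    if e_max_cm is not None:
        keep = (evals - evals[0]) * HARTREE_TO_INVCM <= e_max_cm
        evals, evecs = evals[keep], evecs[:, keep]

    if use_complex:
        # fix arbitrary global phases so leading components are real-positive;
        # with VAM terms the matrix is complex Hermitian and the remaining
        # coefficients may stay genuinely complex
        lead = np.argmax(np.abs(evecs), axis=0)
        phases = np.exp(-1j * np.angle(evecs[lead, np.arange(evecs.shape[1])]))
        evecs = evecs * phases
        if np.max(np.abs(evecs.imag)) < 1e-10:
            evecs = evecs.real

    return VCISolution(energies=np.real(evals) + energy_shift,
                       coefficients=evecs, configs=configs, spec=spec,
                       vscf_energy=vscf.energy)


# ----------------------------------------------------------------------------
# state-character assignment
# ----------------------------------------------------------------------------

def config_label(cfg, mode_numbers=None) -> str:
    """Human-readable configuration label, e.g. 'nu19', '2nu16', 'nu15+nu16'."""
    cfg = np.asarray(cfg)
    excited = np.flatnonzero(cfg)
    if excited.size == 0:
        return "GS"
    parts = []
    for m in excited:
        num = m + 1 if mode_numbers is None else mode_numbers[m]
        q = cfg[m]
        parts.append(f"nu{num}" if q == 1 else f"{q}nu{num}")
    return "+".join(parts)


@dataclass
class StateAssignment:
    """Band character of VCI eigenstates.

    ``states`` holds one record per eigenstate: energy above ZPE (cm^-1),
    dominant configuration labels with coefficients, the single-quantum
    weight |C|^2 on each labeled fundamental, and Fermi-resonance partners
    (other configurations with |coefficient| above the threshold).
    """

    states: list
    band_modes: dict
    threshold: float

    def band_sticks(self, band: str):
        """(energies_cm, |C|^2 weights) of states assigned to a band."""
        e, w = [], []
        for st in self.states:
            weight = st["band_weights"].get(band, 0.0)
            if weight >= self.threshold:
                e.append(st["energy_cm"])
                w.append(weight)
        return np.array(e), np.array(w)


def assign_states(solution: VCISolution, band_modes: dict,
                  threshold: float = 0.1, mode_numbers=None,
                  top_k: int = 3) -> StateAssignment:
    """Project each eigenstate onto single-quantum configurations per band.

    ``band_modes`` maps a band label (e.g. "CH", "OH") to the mode positions
    whose fundamentals define it.  A state is listed under a band if its
    total |C|^2 weight on one-quantum configurations of those modes reaches
    ``threshold``.
    """
    cfgs = solution.configs
    single_quantum = {}
    for band, modes in band_modes.items():
        cols = []
        for m in modes:
            mask = (cfgs[:, m] == 1) & (np.sum(cfgs, axis=1) == 1)
            cols.append(np.flatnonzero(mask))
        single_quantum[band] = np.concatenate(cols) if cols else np.array([], int)

    states = []
    for s in range(solution.n_states):
        c = solution.coefficients[:, s]
        w = np.abs(c) ** 2
        order = np.argsort(-np.abs(c))

        def _coef(value):
            value = complex(value)
            return value.real if abs(value.imag) < 1e-8 else abs(value)

        dominant = [(_coef(c[i]), config_label(cfgs[i], mode_numbers))
                    for i in order[:top_k]]
        partners = [(_coef(c[i]), config_label(cfgs[i], mode_numbers))
                    for i in order if abs(c[i]) >= threshold]
        band_weights = {band: float(np.sum(w[idx]))
                        for band, idx in single_quantum.items()}
        states.append({
            "energy_cm": float(solution.energies_cm[s]),
            "energy_hartree": float(solution.energies[s]),
            "dominant": dominant,
            "partners": partners,
            "band_weights": band_weights,
        })
    return StateAssignment(states=states, band_modes=band_modes,
                           threshold=threshold)
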