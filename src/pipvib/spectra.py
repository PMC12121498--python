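"""Thermally weighted stick spectra and Gaussian band envelopes.

Without a dipole surface there are no true IR intensities; following the
standard power-spectrum surrogate, each eigenstate assigned to a band
receives an arbitrary constant intensity scaled by its conformer's Boltzmann
weight and its squared expansion coefficient on the band's one-quantum
configurations:

    I(E) ~ I_const * wt_conf * |C_band|^2

Sticks are then convolved with unit-area Gaussians to produce a band
envelope; the envelope integral equals the summed stick intensity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .constants import KB_INVCM

__all__ = [
    "ConformerEnsemble", "StickSpectrum", "BroadenedSpectrum",
    "boltzmann_weights", "compose_sticks", "broaden", "band_sum_check",
]

DEFAULT_I_CONSTANT = 0.2   # the conventional arbitrary stick height
DEFAULT_SIGMA_CM = 10.0    # Gaussian broadening width


@dataclass
class ConformerEnsemble:
    """Boltzmann-weighted conformers at temperature T."""

    names: tuple
    relative_energies_cm: np.ndarray
    temperature: float
    weights: np.ndarray

    def weight(self, name: str) -> float:
        return float(self.weights[self.names.index(name)])


def boltzmann_weights(relative_energies_cm, temperature: float = 300.0,
                      names=None) -> ConformerEnsemble:
    """Normalized weights wt_i ~ exp(-dE_i / kB T), dE in cm^-1.

    At 300 K, kB T is about 208.5 cm^-1.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    de = np.asarray(relative_energies_cm, dtype=float)
    if de.size == 0:
        raise ValueError("empty conformer ensemble")
    w = np.exp(-(de - de.min()) / (KB_INVCM * temperature))
    w = w / w.sum()
    names = tuple(names) if names is not None else tuple(
        f"conf{i}" for i in range(de.size))
    return ConformerEnsemble(names=names, relative_energies_cm=de,
                             temperature=temperature, weights=w)


@dataclass
class StickSpectrum:
    """Line positions (cm^-1) and intensities with provenance."""

    positions: np.ndarray
    intensities: np.ndarray
    labels: tuple = ()
    conformers: tuple = ()

    def __post_init__(self):
        order = np.argsort(self.positions)
        self.positions = np.asarray(self.positions, float)[order]
        self.intensities = np.asarray(self.intensities, float)[order]
        if len(self.labels):
            self.labels = tuple(np.asarray(self.labels, object)[order])
        if len(self.conformers):
            self.conformers = tuple(np.asarray(self.conformers, object)[order])
        if np.any(self.intensities < 0):
            raise ValueError("stick intensities must be nonnegative")

    @property
    def total_intensity(self) -> float:
        return float(self.intensities.sum())


def compose_sticks(assignments_per_conformer: dict, ensemble: ConformerEnsemble,
                   band: str, I_constant: float = DEFAULT_I_CONSTANT) -> StickSpectrum:
    """One stick per retained state per conformer: I_const * wt * |C|^2.

    ``assignments_per_conformer`` maps conformer name to a
    :class:`~pipvib.vscf_vci.StateAssignment`; states pass the assignment's
    own band threshold.
    """
    positions, intensities, labels, confs = [], [], [], []
    for name, assignment in assignments_per_conformer.items():
        wt = ensemble.weight(name)
        energies, weights = assignment.band_sticks(band)
        for e, w in zip(energies, weights):
            positions.append(e)
            intensities.append(I_constant * wt * w)
            labels.append(band)
            confs.append(name)
    return StickSpectrum(np.array(positions), np.array(intensities),
                         tuple(labels), tuple(confs))


@dataclass
class BroadenedSpectrum:
    grid: np.ndarray
    envelope: np.ndarray
    sigma: float

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.envelope, self.grid))

    def peak_position(self) -> float:
        return float(self.grid[np.argmax(self.envelope)])


def broaden(sticks: StickSpectrum, sigma: float = DEFAULT_SIGMA_CM,
            grid=None) -> BroadenedSpectrum:
    """Sum of unit-area Gaussians scaled by stick intensities.

    The default grid spans the sticks +- 5 sigma at sigma/10 spacing; a
    warning is raised if a caller-provided grid clips the +-4 sigma support.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if sticks.positions.size == 0:
        raise ValueError("no sticks to broaden")
    if grid is None:
        lo = sticks.positions.min() - 5 * sigma
        hi = sticks.positions.max() + 5 * sigma
        grid = np.arange(lo, hi, sigma / 10.0)
    else:
        grid = np.asarray(grid, dtype=float)
        if (grid[0] > sticks.positions.min() - 4 * sigma
                or grid[-1] < sticks.positions.max() + 4 * sigma):
            import warnings
            warnings.warn("grid does not cover sticks +- 4 sigma; "
                          "envelope integral will lose intensity")
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    env = np.sum(
        sticks.intensities[:, None]
        * norm * np.exp(-0.5 * ((grid[None, :] - sticks.positions[:, None]) / sigma) ** 2),
        axis=0)
    return BroadenedSpectrum(grid=grid, envelope=env, sigma=sigma)


_LABEL_RE = re.compile(r"^(\d*)nu(\w+)$")


def band_sum_check(fundamentals: dict, labels) -> dict:
    """Zero-order energies of combination/overtone labels from fundamentals.

    ``fundamentals`` maps names like "nu15" to energies (cm^-1); ``labels``
    are strings like "nu15+nu16" or "2nu16".  Returns label -> summed energy,
    the zero-order estimate to compare against mixed-state eigenvalues.
    """
    out = {}
    for label in labels:
        total = 0.0
        for part in label.replace(" ", "").split("+"):
            m = _LABEL_RE.match(part)
            if not m:
                raise KeyError(f"cannot parse component {part!r} of {label!r}")
            mult = int(m.group(1) or 1)
            key = f"nu{m.group(2)}"
            if key not in fundamentals:
                raise KeyError(f"unknown fundamental {key!r} in {label!r}")
            total += mult * fundamentals[key]
        out[label] = total
    return out
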