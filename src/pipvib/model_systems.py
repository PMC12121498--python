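"""Analytic model potentials and seeded synthetic training sets.

These are the in-package stand-ins for ab initio data: exact energies and
gradients from known functional forms, with optional Gaussian noise, so every
downstream stage (fitting, normal modes, VSCF/VCI, semiclassical dynamics)
can be exercised and verified against closed forms or dense-grid
diagonalization.

Model potentials over vibrational coordinates are expressed in *mass-scaled*
coordinates (unit mass, hbar = 1), the same convention used by the quantum
and semiclassical machinery; Cartesian models (the bent triatomic) carry
explicit atomic masses.  All quantities are atomic units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AMU_TO_ME, ATOMIC_MASSES_AMU
from .surface import Surface

__all__ = [
    "Morse1D",
    "HarmonicModel",
    "CoupledMorseFermi",
    "TriatomicMorseBend",
    "SyntheticTrainingSet",
    "make_morse_1d",
    "make_harmonic",
    "make_coupled_morse_fermi",
    "make_triatomic",
    "make_random_pip_surface",
    "sample_training_set",
]


def _require_positive(**kwargs):
    for name, val in kwargs.items():
        if not val > 0:
            raise ValueError(f"{name} must be positive, got {val}")


class Morse1D(Surface):
    """Morse oscillator V(r) = D (1 - exp(-a (r - r_e)))^2.

    ``mu`` is the reduced mass in atomic units (electron masses); with the
    default mu = 1 the coordinate is already mass-scaled.  The exact bound
    levels are available in closed form, making this the primary oracle for
    anharmonic level positions:

        E_n = w (n + 1/2) - [w (n + 1/2)]^2 / (4 D),   w = a sqrt(2 D / mu)
    """

    kind = "morse1d"

    def __init__(self, D: float, a: float, mu: float = 1.0, r_e: float = 0.0):
        _require_positive(D=D, a=a, mu=mu)
        self.D, self.a, self.mu, self.r_e = float(D), float(a), float(mu), float(r_e)
        self.n_dof = 1
        self.F_model = 1

    @property
    def parameters(self) -> dict:
        return {"D": self.D, "a": self.a, "mu": self.mu, "r_e": self.r_e}

    @property
    def omega(self) -> float:
        """Harmonic frequency at the minimum (a.u. angular frequency)."""
        return self.a * np.sqrt(2.0 * self.D / self.mu)

    def energy(self, r) -> float:
        y = 1.0 - np.exp(-self.a * (np.asarray(r, dtype=float).ravel()[0] - self.r_e))
        return float(self.D * y * y)

    def gradient(self, r) -> np.ndarray:
        rr = np.asarray(r, dtype=float).ravel()[0]
        e = np.exp(-self.a * (rr - self.r_e))
        return np.array([2.0 * self.D * self.a * e * (1.0 - e)])

    def hessian(self, r, step: float = None) -> np.ndarray:
        rr = np.asarray(r, dtype=float).ravel()[0]
        e = np.exp(-self.a * (rr - self.r_e))
        return np.array([[2.0 * self.D * self.a ** 2 * e * (2.0 * e - 1.0)]])

    def energy_batch(self, r) -> np.ndarray:
        y = 1.0 - np.exp(-self.a * (np.asarray(r, dtype=float).reshape(-1) - self.r_e))
        return self.D * y * y

    def gradient_batch(self, r) -> np.ndarray:
        rr = np.asarray(r, dtype=float).reshape(-1)
        e = np.exp(-self.a * (rr - self.r_e))
        return (2.0 * self.D * self.a * e * (1.0 - e))[:, None]

    def hessian_batch(self, r) -> np.ndarray:
        rr = np.asarray(r, dtype=float).reshape(-1)
        e = np.exp(-self.a * (rr - self.r_e))
        return (2.0 * self.D * self.a ** 2 * e * (2.0 * e - 1.0))[:, None, None]

    # -- closed-form oracle ---------------------------------------------------
    @property
    def n_bound(self) -> int:
        return int(np.floor(2.0 * self.D / self.omega - 0.5)) + 1

    def level(self, n: int) -> float:
        """Exact bound-level energy E_n above the potential minimum."""
        if n < 0 or n >= self.n_bound:
            raise ValueError(f"n = {n} outside the bound spectrum (0..{self.n_bound - 1})")
        s = self.omega * (n + 0.5)
        return s - s * s / (4.0 * self.D)

    def levels(self, n_max: int) -> np.ndarray:
        return np.array([self.level(n) for n in range(n_max + 1)])

    def mass_scaled(self) -> "Morse1D":
        """Equivalent oscillator in the mass-scaled coordinate Q = sqrt(mu) (r - r_e)."""
        return Morse1D(self.D, self.a / np.sqrt(self.mu), 1.0, 0.0)


class HarmonicModel(Surface):
    """Uncoupled harmonic modes, V = 1/2 sum_k w_k^2 Q_k^2 (mass-scaled)."""

    kind = "harmonic"

    def __init__(self, omegas):
        omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
        if np.any(omegas <= 0):
            raise ValueError("harmonic frequencies must be positive")
        self.omegas = omegas
        self.n_dof = self.F_model = omegas.size

    @property
    def parameters(self) -> dict:
        return {"omegas": self.omegas.tolist()}

    def energy(self, q) -> float:
        q = np.asarray(q, dtype=float).ravel()
        return float(0.5 * np.sum(self.omegas ** 2 * q ** 2))

    def gradient(self, q) -> np.ndarray:
        return self.omegas ** 2 * np.asarray(q, dtype=float).ravel()

    def hessian(self, q, step: float = None) -> np.ndarray:
        return np.diag(self.omegas ** 2)

    def energy_batch(self, q) -> np.ndarray:
        q = np.atleast_2d(q)
        return 0.5 * np.sum(self.omegas ** 2 * q ** 2, axis=1)

    def gradient_batch(self, q) -> np.ndarray:
        return self.omegas ** 2 * np.atleast_2d(q)

    def hessian_batch(self, q) -> np.ndarray:
        q = np.atleast_2d(q)
        return np.broadcast_to(np.diag(self.omegas ** 2),
                               (q.shape[0], self.n_dof, self.n_dof)).copy()

    def level(self, quanta) -> float:
        quanta = np.asarray(quanta, dtype=float)
        return float(np.sum(self.omegas * (quanta + 0.5)))


class CoupledMorseFermi(Surface):
    """Two-mode stretch-bend model with a 2:1 Fermi coupling.

    Mass-scaled coordinates: a Morse oscillator in the stretch Q1 (harmonic
    frequency w_s), a harmonic bend Q2 (frequency w_b ~ w_s / 2), plus the
    single cubic coupling lam_c * Q1 * Q2^2 that mixes the stretch
    fundamental |1,0> with the bend overtone |0,2>.
    """

    kind = "coupled_morse_fermi"

    def __init__(self, omega_stretch: float, omega_bend: float, lam_c: float,
                 D: float = 0.05, max_detuning: float = 0.25):
        _require_positive(omega_stretch=omega_stretch, omega_bend=omega_bend, D=D)
        if abs(omega_stretch - 2.0 * omega_bend) > max_detuning * omega_stretch:
            raise ValueError(
                "omega_stretch must be within the stated detuning of 2 * omega_bend"
            )
        self.omega_s = float(omega_stretch)
        self.omega_b = float(omega_bend)
        self.lam_c = float(lam_c)
        self.D = float(D)
        self.alpha = self.omega_s / np.sqrt(2.0 * self.D)  # Morse range in Q1
        self.n_dof = self.F_model = 2
        self._stretch = Morse1D(self.D, self.alpha, 1.0)

    @property
    def parameters(self) -> dict:
        return {"omega_stretch": self.omega_s, "omega_bend": self.omega_b,
                "lam_c": self.lam_c, "D": self.D}

    def energy(self, q) -> float:
        q1, q2 = np.asarray(q, dtype=float).ravel()
        return (self._stretch.energy([q1])
                + 0.5 * self.omega_b ** 2 * q2 ** 2
                + self.lam_c * q1 * q2 ** 2)

    def gradient(self, q) -> np.ndarray:
        q1, q2 = np.asarray(q, dtype=float).ravel()
        g1 = self._stretch.gradient([q1])[0] + self.lam_c * q2 ** 2
        g2 = self.omega_b ** 2 * q2 + 2.0 * self.lam_c * q1 * q2
        return np.array([g1, g2])

    def hessian(self, q, step: float = None) -> np.ndarray:
        q1, q2 = np.asarray(q, dtype=float).ravel()
        h11 = self._stretch.hessian([q1])[0, 0]
        h12 = 2.0 * self.lam_c * q2
        h22 = self.omega_b ** 2 + 2.0 * self.lam_c * q1
        return np.array([[h11, h12], [h12, h22]])

    def energy_batch(self, q) -> np.ndarray:
        q = np.atleast_2d(q)
        return (self._stretch.energy_batch(q[:, 0])
                + 0.5 * self.omega_b ** 2 * q[:, 1] ** 2
                + self.lam_c * q[:, 0] * q[:, 1] ** 2)

    def gradient_batch(self, q) -> np.ndarray:
        q = np.atleast_2d(q)
        g = np.empty_like(q)
        g[:, 0] = self._stretch.gradient_batch(q[:, 0])[:, 0] + self.lam_c * q[:, 1] ** 2
        g[:, 1] = self.omega_b ** 2 * q[:, 1] + 2.0 * self.lam_c * q[:, 0] * q[:, 1]
        return g

    def hessian_batch(self, q) -> np.ndarray:
        q = np.atleast_2d(q)
        h = np.empty((q.shape[0], 2, 2))
        h[:, 0, 0] = self._stretch.hessian_batch(q[:, 0])[:, 0, 0]
        h[:, 0, 1] = h[:, 1, 0] = 2.0 * self.lam_c * q[:, 1]
        h[:, 1, 1] = self.omega_b ** 2 + 2.0 * self.lam_c * q[:, 0]
        return h

    # -- degenerate perturbation theory oracle --------------------------------
    def fermi_coupling_element(self) -> float:
        """<1,0| lam_c Q1 Q2^2 |0,2> in the harmonic product basis."""
        return self.lam_c / (np.sqrt(2.0 * self.omega_s) * np.sqrt(2.0) * self.omega_b)

    def degenerate_pt_doublet(self) -> np.ndarray:
        """2x2 degenerate-PT energies of the |1,0> / |0,2> pair.

        At exact 2:1 resonance the pair splits symmetrically about the common
        zero-order energy by twice the coupling element.
        """
        e10 = self.omega_s * 1.5 + self.omega_b * 0.5
        e02 = self.omega_s * 0.5 + self.omega_b * 2.5
        w = self.fermi_coupling_element()
        h = np.array([[e10, w], [w, e02]])
        return np.linalg.eigvalsh(h)


class MorseBendBend(Surface):
    """Three-mode model: Morse stretch plus two harmonic bends, cubic-coupled.

    V = Morse(Q1) + 1/2 w2^2 Q2^2 + 1/2 w3^2 Q3^2
        + lam12 Q1 Q2^2 + lam13 Q1 Q3^2

    Mass-scaled coordinates; the 2-mode representation of this potential is
    exact (all couplings are pairwise), which makes it a sharp test of the
    VSCF/VCI machinery against three-dimensional grid diagonalization.
    """

    kind = "morse_bend_bend"

    def __init__(self, omega_stretch: float = 0.012, omega_b2: float = 0.006,
                 omega_b3: float = 0.005, lam12: float = 2e-7,
                 lam13: float = 2e-7, D: float = 0.06):
        _require_positive(omega_stretch=omega_stretch, omega_b2=omega_b2,
                          omega_b3=omega_b3, D=D)
        self.omegas = np.array([omega_stretch, omega_b2, omega_b3])
        self.lam12, self.lam13, self.D = lam12, lam13, D
        self._stretch = Morse1D(D, omega_stretch / np.sqrt(2.0 * D), 1.0)
        self.n_dof = self.F_model = 3

    @property
    def parameters(self) -> dict:
        return {"omega_stretch": self.omegas[0], "omega_b2": self.omegas[1],
                "omega_b3": self.omegas[2], "lam12": self.lam12,
                "lam13": self.lam13, "D": self.D}

    def energy_batch(self, q) -> np.ndarray:
        q = np.atleast_2d(q)
        return (self._stretch.energy_batch(q[:, 0])
                + 0.5 * self.omegas[1] ** 2 * q[:, 1] ** 2
                + 0.5 * self.omegas[2] ** 2 * q[:, 2] ** 2
                + self.lam12 * q[:, 0] * q[:, 1] ** 2
                + self.lam13 * q[:, 0] * q[:, 2] ** 2)

    def energy(self, q) -> float:
        return float(self.energy_batch(np.asarray(q, float).ravel()[None])[0])

    def gradient_batch(self, q) -> np.ndarray:
        q = np.atleast_2d(q)
        g = np.empty_like(q)
        g[:, 0] = (self._stretch.gradient_batch(q[:, 0])[:, 0]
                   + self.lam12 * q[:, 1] ** 2 + self.lam13 * q[:, 2] ** 2)
        g[:, 1] = self.omegas[1] ** 2 * q[:, 1] + 2 * self.lam12 * q[:, 0] * q[:, 1]
        g[:, 2] = self.omegas[2] ** 2 * q[:, 2] + 2 * self.lam13 * q[:, 0] * q[:, 2]
        return g

    def gradient(self, q) -> np.ndarray:
        return self.gradient_batch(np.asarray(q, float).ravel()[None])[0]

    def hessian_batch(self, q) -> np.ndarray:
        q = np.atleast_2d(q)
        h = np.zeros((q.shape[0], 3, 3))
        h[:, 0, 0] = self._stretch.hessian_batch(q[:, 0])[:, 0, 0]
        h[:, 1, 1] = self.omegas[1] ** 2 + 2 * self.lam12 * q[:, 0]
        h[:, 2, 2] = self.omegas[2] ** 2 + 2 * self.lam13 * q[:, 0]
        h[:, 0, 1] = h[:, 1, 0] = 2 * self.lam12 * q[:, 1]
        h[:, 0, 2] = h[:, 2, 0] = 2 * self.lam13 * q[:, 2]
        return h

    def hessian(self, q, step: float = None) -> np.ndarray:
        return self.hessian_batch(np.asarray(q, float).ravel()[None])[0]


class DiatomicMorse(Surface):
    """A Cartesian diatomic with a Morse bond, V = D (1 - e^{-a (r - r_e)})^2.

    The harmonic frequency at the minimum is a sqrt(2D/mu) with mu the
    reduced mass -- the closed-form oracle for Cartesian normal-mode
    analysis.  Atom masses from the element symbols.
    """

    kind = "diatomic_morse"

    def __init__(self, D: float, a: float, r_e: float, elements=("H", "H")):
        _require_positive(D=D, a=a, r_e=r_e)
        self.D, self.a, self.r_e = float(D), float(a), float(r_e)
        self.elements = tuple(elements)
        self.n_dof = 6
        self.F_model = 1

    @property
    def parameters(self) -> dict:
        return {"D": self.D, "a": self.a, "r_e": self.r_e}

    @property
    def masses_me(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES_AMU[el] * AMU_TO_ME for el in self.elements])

    @property
    def reduced_mass_me(self) -> float:
        m1, m2 = self.masses_me
        return m1 * m2 / (m1 + m2)

    @property
    def omega(self) -> float:
        return self.a * np.sqrt(2.0 * self.D / self.reduced_mass_me)

    def reference_geometry(self) -> np.ndarray:
        return np.array([[0.0, 0.0, 0.0], [0.0, 0.0, self.r_e]])

    def _oracle(self) -> Morse1D:
        return Morse1D(self.D, self.a, self.reduced_mass_me, self.r_e)

    def level(self, n: int) -> float:
        return self._oracle().level(n)

    def energy(self, x) -> float:
        geom = np.asarray(x, dtype=float).reshape(2, 3)
        r = np.linalg.norm(geom[1] - geom[0])
        y = 1.0 - np.exp(-self.a * (r - self.r_e))
        return float(self.D * y * y)

    def gradient(self, x) -> np.ndarray:
        geom = np.asarray(x, dtype=float).reshape(2, 3)
        d = geom[1] - geom[0]
        r = np.linalg.norm(d)
        e = np.exp(-self.a * (r - self.r_e))
        dVdr = 2.0 * self.D * self.a * e * (1.0 - e)
        u = d / r
        return np.concatenate([-dVdr * u, dVdr * u])


class TriatomicMorseBend(Surface):
    """A synthetic bent triatomic molecule in Cartesian coordinates.

    Two equivalent Morse bonds from the central atom plus a harmonic bend --
    a minimal full-dimensional Cartesian model (water-like by default) for
    exercising normal-mode analysis, the Watson Hamiltonian terms, and the
    complete VSCF/VCI pipeline without any fitted surface.  Atom order:
    central atom first, then the two terminal atoms.
    """

    kind = "triatomic_morse_bend"

    def __init__(self, D: float = 0.18, a: float = 1.2, r0: float = 1.81,
                 f_theta: float = 0.15, theta0_deg: float = 104.5,
                 elements=("O", "H", "H")):
        _require_positive(D=D, a=a, r0=r0, f_theta=f_theta)
        self.D, self.a, self.r0, self.f_theta = D, a, r0, f_theta
        self.theta0 = np.deg2rad(theta0_deg)
        self.elements = tuple(elements)
        self.n_dof = 9
        self.F_model = 3

    @property
    def parameters(self) -> dict:
        return {"D": self.D, "a": self.a, "r0": self.r0,
                "f_theta": self.f_theta, "theta0": self.theta0}

    @property
    def masses_me(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES_AMU[el] * AMU_TO_ME for el in self.elements])

    def reference_geometry(self) -> np.ndarray:
        """The analytic minimum: bonds at r0, bend at theta0 (bohr, (3,3))."""
        half = 0.5 * self.theta0
        return np.array([
            [0.0, 0.0, 0.0],
            [self.r0 * np.sin(half), self.r0 * np.cos(half), 0.0],
            [-self.r0 * np.sin(half), self.r0 * np.cos(half), 0.0],
        ])

    def _internals(self, geom):
        u = geom[1] - geom[0]
        v = geom[2] - geom[0]
        r1, r2 = np.linalg.norm(u), np.linalg.norm(v)
        uh, vh = u / r1, v / r2
        c = np.clip(uh @ vh, -1.0, 1.0)
        return u, v, r1, r2, uh, vh, c

    def energy(self, x) -> float:
        geom = np.asarray(x, dtype=float).reshape(3, 3)
        _, _, r1, r2, _, _, c = self._internals(geom)
        y1 = 1.0 - np.exp(-self.a * (r1 - self.r0))
        y2 = 1.0 - np.exp(-self.a * (r2 - self.r0))
        theta = np.arccos(c)
        return float(self.D * (y1 * y1 + y2 * y2)
                     + 0.5 * self.f_theta * (theta - self.theta0) ** 2)

    def gradient(self, x) -> np.ndarray:
        geom = np.asarray(x, dtype=float).reshape(3, 3)
        _, _, r1, r2, uh, vh, c = self._internals(geom)
        e1 = np.exp(-self.a * (r1 - self.r0))
        e2 = np.exp(-self.a * (r2 - self.r0))
        dVdr1 = 2.0 * self.D * self.a * e1 * (1.0 - e1)
        dVdr2 = 2.0 * self.D * self.a * e2 * (1.0 - e2)
        theta = np.arccos(c)
        s = np.sqrt(max(1.0 - c * c, 1e-14))
        dVdtheta = self.f_theta * (theta - self.theta0)
        g = np.zeros((3, 3))
        g[1] += dVdr1 * uh
        g[2] += dVdr2 * vh
        g[0] -= dVdr1 * uh + dVdr2 * vh
        dth1 = (c * uh - vh) / (s * r1)
        dth2 = (c * vh - uh) / (s * r2)
        g[1] += dVdtheta * dth1
        g[2] += dVdtheta * dth2
        g[0] -= dVdtheta * (dth1 + dth2)
        return g.ravel()


# ----------------------------------------------------------------------------
# factories (the spec-level constructors)
# ----------------------------------------------------------------------------

def make_morse_1d(D: float, a: float, mu: float = 1.0, r_e: float = 0.0) -> Morse1D:
    """Morse oscillator; parameters in atomic units (mass in electron masses)."""
    return Morse1D(D, a, mu, r_e)


def make_harmonic(omegas) -> HarmonicModel:
    return HarmonicModel(omegas)


def make_coupled_morse_fermi(omega_stretch: float = 0.012,
                             omega_bend: float = 0.006,
                             lam_c: float = 5e-7,
                             D: float = 0.06) -> CoupledMorseFermi:
    """Stretch-bend Fermi fixture; defaults give a CH-stretch-scale pair.

    The default stretch (~2635 cm^-1) sits in 2:1 resonance with the bend,
    and the default cubic coupling mixes the stretch fundamental with the
    bend overtone on the ~100 cm^-1 scale seen for CH-stretch Fermi
    resonances.
    """
    return CoupledMorseFermi(omega_stretch, omega_bend, lam_c, D=D)


def make_triatomic(**kwargs) -> TriatomicMorseBend:
    return TriatomicMorseBend(**kwargs)


def make_random_pip_surface(n_atoms: int, partition, max_order: int,
                            coefficient_scale: float, seed: int,
                            lam: float = 2.0):
    """Random PIP surface with seeded Gaussian coefficients (recovery fixture)."""
    from .pip_surface import PIPSurface, generate_basis

    basis = generate_basis(n_atoms, partition, max_order, lam)
    rng = np.random.default_rng(seed)
    coeffs = rng.normal(0.0, 1.0, size=basis.n_p) * coefficient_scale
    return PIPSurface(basis, coeffs, intercept=0.0,
                      provenance={"generator": {"seed": seed,
                                                "scale": coefficient_scale}})


_MODEL_KINDS = {}


def _register(cls):
    _MODEL_KINDS[cls.kind] = cls
    return cls


for _cls in (Morse1D, HarmonicModel, CoupledMorseFermi, MorseBendBend,
             DiatomicMorse, TriatomicMorseBend):
    _register(_cls)


def model_to_dict(model) -> dict:
    """Self-describing archive of an analytic model potential."""
    d = {"format": "pipvib-model-1", "kind": model.kind,
         "parameters": model.parameters}
    if hasattr(model, "elements"):
        d["elements"] = list(model.elements)
    return d


def model_from_dict(data: dict):
    if data.get("format") != "pipvib-model-1":
        raise ValueError("not a pipvib model archive")
    cls = _MODEL_KINDS.get(data.get("kind"))
    if cls is None:
        raise ValueError(f"unknown model kind {data.get('kind')!r}")
    params = dict(data.get("parameters", {}))
    if data.get("elements"):
        params["elements"] = tuple(data["elements"])
    if cls is TriatomicMorseBend and "theta0" in params:
        params["theta0_deg"] = float(np.rad2deg(params.pop("theta0")))
    if cls is HarmonicModel:
        return cls(params["omegas"])
    return cls(**params)


# ----------------------------------------------------------------------------
# synthetic training sets
# ----------------------------------------------------------------------------

@dataclass
class SyntheticTrainingSet:
    """Geometries with energies and gradients from a known generating surface."""

    geometries: np.ndarray  # (n, N, 3) bohr
    energies: np.ndarray    # (n,) hartree
    gradients: np.ndarray   # (n, N, 3) hartree/bohr
    elements: tuple = ()
    noise_sigma: float = 0.0
    seed: int | None = None
    surface_ref: str = ""

    def __post_init__(self):
        n = len(self.energies)
        if not (len(self.geometries) == len(self.gradients) == n):
            raise ValueError("geometry / energy / gradient counts disagree")

    @property
    def n_configs(self) -> int:
        return len(self.energies)

    @property
    def n_observations(self) -> int:
        """Scalar observation count: one energy + 3N gradient components each."""
        return self.n_configs * (1 + 3 * self.geometries.shape[1])

    def write_extxyz(self, path, unit: str = "bohr") -> None:
        from .interface.xyz import write_extxyz
        write_extxyz(path, self, unit=unit)

    @classmethod
    def read_extxyz(cls, path) -> "SyntheticTrainingSet":
        from .interface.xyz import read_extxyz
        return read_extxyz(path)


def sample_training_set(surface: Surface, center_geometry, displacement_sigma: float,
                        n_points: int, noise_sigma: float = 0.0,
                        seed: int | None = None, elements=()) -> SyntheticTrainingSet:
    """Gaussian Cartesian displacements about a center, labeled by the surface.

    Independent Gaussian noise of standard deviation ``noise_sigma`` (hartree
    for energies, hartree/bohr for each gradient component) is added when
    requested; with ``noise_sigma = 0`` the labels are exact surface values.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if displacement_sigma < 0:
        raise ValueError("displacement_sigma must be nonnegative")
    center = np.asarray(center_geometry, dtype=float).reshape(-1, 3)
    rng = np.random.default_rng(seed)
    geoms = center[None] + rng.normal(0.0, displacement_sigma,
                                      size=(n_points, *center.shape))
    energies = np.array([surface.energy(g.ravel()) for g in geoms])
    grads = np.array([surface.gradient(g.ravel()).reshape(center.shape)
                      for g in geoms])
    if noise_sigma > 0:
        energies = energies + rng.normal(0.0, noise_sigma, size=n_points)
        grads = grads + rng.normal(0.0, noise_sigma, size=grads.shape)
    return SyntheticTrainingSet(
        geometries=geoms, energies=energies, gradients=grads,
        elements=tuple(elements), noise_sigma=noise_sigma, seed=seed,
        surface_ref=type(surface).__name__,
    )
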