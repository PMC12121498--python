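# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `pipvib`, in the order the pipeline runs. Internal units
are atomic units throughout (hartree, bohr, electron masses, ħ = 1);
wavenumbers and amu appear only at I/O boundaries (`pipvib.constants`
centralizes the conversions).

## PIP surfaces

**Basis.** For `N` atoms there are `N(N−1)/2` pair Morse variables
`x_ab = exp(−r_ab/λ)`; λ defaults to 2 bohr. A like-atom partition (e.g.
`22222`) induces a permutation group on the pair indices (direct product of
per-block symmetric groups; order 32 for `22222`). The basis enumerates all
exponent vectors of total degree 1..max_order, maps each through every
group element, and groups monomials by their lexicographically smallest
image; each basis function evaluates as the sum over the *distinct*
monomials of its orbit. Summing over group elements instead would multiply
each function by its orbit's stabilizer order — a constant absorbed into
the linear coefficient, so the two conventions fit identically.

**Counting convention.** The degree-0 monomial is excluded from the basis
and carried as an explicit intercept (energies have an arbitrary offset).
For (10 atoms, `22222`, order 4) the enumeration yields 16,980 orbits of
the 211,875 monomials, verified independently by a Burnside-lemma count
(fixed monomials per group element from the cycle structure of the induced
pair permutation); including the intercept the surface carries 16,981
linear coefficients, matching the coefficient count of MSA-style bases for
this system — the customary count includes the constant polynomial.
No "purification" (removal of disconnected products) is applied.

**Fitting.** Each configuration contributes one energy row and `3N` force
rows (negative basis gradients against the negative ab initio gradient).
Per-configuration weights `wt = E0/(E0 + ΔE)` with ΔE the energy above the
training-set minimum multiply both row classes; energy and force classes
carry equal unit weights by default. The solver is SVD-based minimum-norm
least squares (LAPACK gelsd) with a relative singular-value cutoff of
1e-12; a ridge term `η‖c‖²` is available through augmented rows but
defaults to off, since the row count normally far exceeds the coefficient
count. Rank deficiency produces a warning and a flag in the fit report, not
an error. Reported RMSEs come in weighted (Σw r²/Σw) and unweighted
flavors, energies in cm⁻¹ and forces in hartree/bohr.

## Normal modes

Hessians are central finite differences of the analytic gradient (step
1e-3 bohr, symmetrized); frequency changes under step halving are below
0.1 cm⁻¹ on the bundled fixtures. Harmonic analysis mass-weights the
Hessian, builds the six translation/rotation vectors at the reference
geometry, and diagonalizes in the orthonormal complement (an exact Eckart
projection), so exactly `3N−6` vibrational roots emerge; negative
eigenvalues are reported as negative (imaginary) frequencies and can be
masked in table comparisons. The comparison utility always exposes the raw
MAE alongside the integer-rounded value, because published tables
occasionally round inconsistently: for the reference tG+g− column the raw
MAE is 8.58 cm⁻¹, which rounds to 9 rather than the printed 8 — the
discrepancy is surfaced, not hidden.

The `NormalModeModel` defines mass-scaled normal coordinates via
`R(Q) = R_eq + M^{−1/2} L Q` with orthonormal mass-weighted displacement
columns `L`. Because displacements along these columns satisfy the Eckart
conditions exactly, downstream rotational quantities (inertia tensors) are
evaluated in the Eckart frame by construction.

## n-mode representation, VSCF, VCI

**Grids.** Each kept mode gets a Gauss–Hermite grid scaled to its harmonic
frequency (`Q = x/√ω`, effective dQ weights `w e^{x²}/√ω`; default 20
points per mode, raised to 32–60 in oracle comparisons). Intrinsic 1..4-mode
terms are tabulated by inclusion–exclusion; each unique cut is evaluated
once. A free-standing truncated-potential evaluator recomputes the
hierarchy at arbitrary points, which lets tests verify, e.g., that a
potential with only pairwise couplings is reproduced *exactly* at the
2-mode level.

**VSCF.** Modals expand in harmonic-oscillator primitives at the mode
frequency (default 16 primitives, 12 modals); mean fields contract the term
tensors with the other modes' ground densities on the shared grids.
Convergence is 1e-8 hartree on the total energy; 50% density damping
engages after 50 cycles, and non-convergence raises after 200.

**VCI.** Configurations have at most four simultaneously excited modes with
per-class caps on total quanta (the `10 10 10 8` convention: singles
through triples to 10, quadruples to 8). Enumeration is canonical (class,
then total quanta, then lexicographic) and is mirrored by a closed-form
bounded-composition count; for 15 modes with caps 10/10/10/8 and at least
11 modals per mode both give 155,026 configurations — reproducing the
published H-matrix order exactly, which fixes the counting convention
(per-mode quanta limited only by the caps themselves). Matrix elements
factorize into one-mode transition densities contracted with the term
tensors; assembly groups configurations that agree outside a term's mode
support. Dense diagonalization below 2,000 configurations, Lanczos
(ARPACK) above. Assembly asserts Hermiticity to 1e-9 as a bug trap.
Degenerate eigenvalues keep LAPACK's ordering; reported states are sorted
by energy.

**Watson terms.** At J = 0 the Hamiltonian adds the vibrational angular
momentum (VAM) coupling ½ Σ π_a μ_ab π_b and the mass term −⅛ Σ μ_aa. The
mass term is treated as a potential-like function of Q — the inverse
instantaneous inertia tensor in the Eckart frame — expanded to 2-mode level
on the same grids (its constant part shifts all levels uniformly). The VAM
coupling uses the *equilibrium* μ with π built from Coriolis ζ constants,
expanded into products of one-mode Q and P matrices in the modal basis:
since π is itself first order in the displacements, the Q-dependence of μ
inside π·μ·π is a higher-order correction, and freezing μ at equilibrium
keeps the operator algebra to products of one-mode factors. The two
corrections toggle independently so their separate spectral influence is
reportable; on the bundled bent-triatomic fixture the mass term shifts the
ZPE by about −13 cm⁻¹ and the VAM coupling moves fundamentals by 0.01–37
cm⁻¹ — bounded, regression-tracked magnitudes.

**DVR oracle.** Exact levels for ≤3-mode models come from sinc
(Colbert–Miller) DVR on uniform direct-product grids, dense below 5,000
points and sparse Lanczos above. Box placement matters more than density
for Morse-type potentials: walls must exceed the highest level of interest
by several κ-lengths, and the bundled comparisons use boxes validated by
grid-refinement drift below 0.01 cm⁻¹.

## Thermal spectra

Boltzmann weights use electronic (minimum) energies in cm⁻¹ with
k_B·300 K ≈ 208.5 cm⁻¹; adding per-conformer harmonic ZPE is possible
upstream by adjusting the input energies. Stick intensities are
`I_const · wt · |C_band|²` with `I_const = 0.2` by convention — explicitly
arbitrary, since no dipole surface enters. Gaussian broadening (default
σ = 10 cm⁻¹, a package choice) uses unit-area Gaussians so the envelope
integral equals the stick sum (conserved to 0.1% in tests); envelopes are
kept in absolute arbitrary units and never rescaled to experiment.

## AS-SCIVR

**Initial conditions.** Per mode, action (n+½) on the harmonic torus with
an independent uniform phase; one draw per trajectory, seeded.

**Switching.** `H(t) = [1−λ(t)] H_harm + λ(t) H_anh` with
`λ(t) = t/T_AS − sin(2πt/T_AS)/2π` (λ′ vanishing at both ends), integrated
by velocity Verlet with the force evaluated at the current time's λ.
Defaults T_AS = 25,000 a.u., dt = 10 a.u. An optional energy guard flags
dissociating trajectories. On the Morse fixture the switched ensemble's
mean energy lands within ~0.1 cm⁻¹ of the exact ZPE with a spread of
~1–2 cm⁻¹ that decreases as T_AS grows, the adiabatic-invariance signature.

**Propagation and stability.** Velocity Verlet for (p, q) with the exactly
consistent tangent-map update for the four monodromy blocks (the tangent
update uses the same two-Hessian structure as the position/momentum
update), which keeps det M at 1 to machine precision for symmetric
Hessians — the basis of the 1% determinant rejection gate. The classical
action accumulates `∫(½p² − V) dt` by the trapezoid rule. The Herman–Kluk
prefactor determinant `det ½(M_qq + Γ^{−1}M_pp Γ − i M_qp Γ + i Γ^{−1}M_pq)`
with Γ = diag(ω) is tracked continuously: per-step argument increments are
wrapped to (−π, π] and accumulated, and the prefactor phase φ_t is half the
accumulated argument (the square root of the determinant), giving the
analytic slope −Σω/2 on harmonic fixtures.

**Spectral density.** Per accepted trajectory, the windowed time integral
of `e^{i(S_t + Et + φ_t)}⟨Ψ|g_t⟩` on the energy grid (trapezoid in time),
squared and averaged with the (1/2π)^F (1/2πT) prefactors. The reference
state is a coherent state at the equilibrium geometry with
harmonic-approximation momenta matching the run's quanta. The coherent
state overlap uses the closed Gaussian form for a common diagonal Γ,
verified against direct quadrature to 1e-10 (this check caught a phase-sign
error during development, which is exactly its job). The default energy
grid uses the Fourier-limited spacing 2π/T; peak *positions* may be located
on a finer grid since I(E) is a continuous function of E, but their
*uncertainty* remains the 2π/T peak width.

**Accuracy profile.** Harmonic systems are exact up to the integrator's
O(dt²) phase error (≈2 cm⁻¹ at dt = 10 for a 2200 cm⁻¹ mode); the Morse
ZPE peak lands within ~2 cm⁻¹ of the closed form. For the strongly mixed
Fermi fixture the method reproduces the resonance doublet but compresses
its splitting by ~15–20% relative to exact diagonalization, an error that
persists at longer T and smaller dt and therefore reflects the
separable-prefactor time-averaged formulation combined with adiabatic
switching through a resonance zone (adiabatic invariants are not conserved
across resonances), not a numerical artifact. Peak-position scatter across
seeds is ensemble-statistical (~4 cm⁻¹ for 100 trajectories at T = 25,000
a.u. on the coupled fixture, <2 cm⁻¹ at T = 50,000 a.u. where the narrower
Fourier width separates the peak from its neighbors).

## Model systems: what they emulate, and what they do not

The generator suite stands in for ab initio training data and benchmark
spectra: Gaussian-displaced geometries labeled with exact energies and
gradients (optional independent Gaussian noise on each observation),
seeded and bitwise reproducible; Morse oscillators with closed-form levels;
a 2-mode stretch–bend model whose single cubic coupling λ·Q1·Q2² produces
a 2:1 Fermi resonance (default stretch 0.012 a.u. ≈ 2630 cm⁻¹, bend at
half, λ = 5e-7 giving a ~100 cm⁻¹-scale coupling element, CH-stretch-like);
a 3-mode variant with purely pairwise couplings (2-mode representation
exact by construction); and a water-like bent triatomic in Cartesian space
for the full molecular pipeline including rotational (Watson) terms.

These fixtures validate the *algorithms* — they do not certify behavior on
real fitted surfaces: sampled geometries are isotropic Gaussians rather
than dynamics- or reaction-surface-distributed configurations; noise is
i.i.d. rather than systematically structured like basis-set or convergence
error; the cubic Fermi coupling is unbounded far from the minimum (kept
irrelevant by the chosen coupling strength and box sizes, but a reminder
that polynomial couplings must not be trusted asymptotically); and the
triatomic's three modes cannot probe 4-mode-representation truncation
error. Passing tests therefore demonstrate correctness of the machinery
and its convergence behavior at desk scale, not the fidelity of any
particular fitted PES.

## Problem sizes used in the checks

The bundled verification battery runs at desk scale by choice: 100–500
semiclassical trajectories on 1–2-mode fixtures (the production-scale
default of 4,000 remains the CLI default), DVR boxes up to 44³ points,
VCI spaces up to a few hundred configurations for spectra and 155,026 for
the pure enumeration check, and 120-configuration training sets for
coefficient recovery. Each scaled-down setting is paired with a
convergence or self-consistency check (grid refinement, T_AS doubling,
seed stability) so that the reduced size is itself audited.

## Known limitations

- No dipole moment surfaces, hence no true IR intensities anywhere.
- VAM coupling uses equilibrium μ (see above); full 2-mode μ inside
  π·μ·π is not implemented.
- VCI beyond ~10⁴ configurations assembles a dense matrix in memory;
  the iterative eigensolver contract is honored but a matrix-free path is
  not provided.
- J > 0 rovibrational states, 5/6-mode representations, purified or
  fragmented PIP bases, and multiple-coherent-state semiclassics are out
  of scope.
- The AS-SCIVR splitting compression on strong Fermi resonances documented
  above is inherent to the formulation as implemented.
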