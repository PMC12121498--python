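# pipvib

Anharmonic vibrational spectroscopy on machine-learned potential energy
surfaces, in one package: permutationally invariant polynomial (PIP)
regression to ab initio energies and gradients, harmonic normal-mode
analysis, VSCF/VCI quantum vibrational states on an n-mode Watson
Hamiltonian with thermally weighted band envelopes, and adiabatically
switched semiclassical initial value representation (AS-SCIVR) power
spectra.

It is written for molecular spectroscopists who need quantum or
semiclassical anharmonic spectra — fundamentals, overtones, and Fermi
resonances such as the CH-stretch/bend-overtone mixing in ethylene glycol —
beyond what harmonic analysis, classical MD, or ring-polymer methods
resolve. Every algorithm ships with analytic model systems (Morse
oscillators, coupled stretch–bend Fermi fixtures, a bent triatomic), so the
whole stack is testable against closed forms and exact grid diagonalization
without any external dataset.

## The methods

**PIP surfaces.** The potential is a linear expansion in permutationally
invariant polynomials over Morse variables `x_ab = exp(-r_ab / λ)` (λ = 2
bohr by default),

    V(x) = c_0 + Σ_i c_i p_i(x),

where each `p_i` is the sum of a monomial over its orbit under the
permutation group induced by a like-atom partition (e.g. `22222` for
ethylene glycol: the two O, the two hydroxyl H, the two C, and the two H of
each CH2 group interchangeable; group order 32). Coefficients minimize the
joint weighted least-squares loss over energies *and* forces,

    L(c) = Σ_X ( w_X^E |E(c;X) − E_ref(X)|² + w_X^F |F(c;X) − F_ref(X)|² ),

with per-configuration weights `wt = E0 / (E0 + ΔE)` emphasizing low-energy
data (E0 = 0.01 hartree; E0 → ∞ recovers the unweighted fit), solved by
SVD-based minimum-norm least squares with optional ridge regularization.

**VSCF/VCI.** Vibrational states are computed on the Watson Hamiltonian in
mass-scaled normal coordinates at J = 0, with the potential in a
hierarchical n-mode representation (up to 4-mode intrinsic terms on
Gauss–Hermite grids), a two-mode-level treatment of the inverse effective
inertia tensor for the −⅛ Σ μ_αα mass term, and the π·μ·π vibrational
angular momentum coupling built from Coriolis ζ constants (separately
toggleable). VCI diagonalizes in the space of VSCF virtual-state products
with per-excitation-class caps on total quanta (default `10 10 10 8`).

**Spectra.** Lacking a dipole surface, band intensities follow the standard
power-spectrum surrogate `I ∝ I_const · wt_conf · |C_band|²`: Boltzmann
conformer weights times the squared VCI coefficient on one-quantum
configurations of the band, Gaussian-broadened into an envelope.

**AS-SCIVR.** Trajectories start on harmonic tori with quantized actions,
are adiabatically switched into the anharmonic Hamiltonian via
`λ(t) = t/T_AS − sin(2πt/T_AS)/2π` (T_AS = 25,000 a.u., dt = 10 a.u.), then
propagated for another 25,000 a.u. while accumulating the classical action,
the Herman–Kluk prefactor phase from the monodromy blocks, and coherent
state overlaps (Γ = diag(ω)); the time-averaged spectral density

    I(E) = (1/2π)^F Σ_j (1/2πT) | ∫_0^T dt e^{i(S_t + Et + φ_t)} ⟨Ψ|g_t⟩ |²

is accumulated over trajectories that pass a 1% monodromy-determinant
acceptance gate.

## Worked example

Generate a seeded random PIP surface for a 4-atom `22` system, sample a
noise-free training set, and refit:

```bash
pipvib synth --model random-pip --atoms 4 --partition 22 --order 3 \
       --scale 0.01 --seed 7 --out surf.json \
       --sample 100 --center center4.xyz --sigma 0.1 --train-out train.xyz
pipvib fit --train train.xyz --partition 22 --order 3 --E0 1e10 \
       --out fitted.json
```

which prints

```
rows x coefficients : 1300 x 33 (rank 33)
energy RMSE  :      0.000 cm^-1 (unweighted)
             :      0.000 cm^-1 (weighted, E0=1e+10)
force RMSE   :    0.0000000 hartree/bohr (unweighted)
             :    0.0000000 hartree/bohr (weighted)
```

— 100 configurations contribute 1 energy + 12 force rows each (1300
observations) for 32 symmetrized polynomials + intercept, and the noise-free
refit recovers the generating coefficients to machine precision (the test
suite asserts relative error < 1e-8).

For a quantum-level example, the bent-triatomic model runs the full
pipeline — normal modes, 3-mode representation, VSCF/VCI with Watson
corrections:

```bash
pipvib synth --model triatomic --out tri.json
pipvib freq --surface tri.json --geometry tri.xyz --unit bohr --out modes.json
pipvib vci --surface tri.json --modes modes.json --n-modes 3 --caps 6,6,6 \
       --nmax 3 --n-prim 12 --n-modal 8 --states 12 --emax 5000 --out states.json
```

printing harmonic frequencies 1606/3774/3829 cm⁻¹ and anharmonic VCI levels

```
      0.00 cm^-1   +0.9991 GS
   1586.48 cm^-1   +0.9981 nu1          (bend fundamental)
   3160.84 cm^-1   +0.9728 2nu1 -0.2113 nu2   (bend overtone, mixed)
   3594.71 cm^-1   +0.9680 nu2 +0.2110 2nu1   (sym. stretch)
   3638.50 cm^-1   +0.9825 nu3          (asym. stretch)
```

with the stretch fundamentals red-shifted ~180–190 cm⁻¹ from harmonic and a
visible stretch/bend-overtone interaction — the same anharmonic phenomenology
the package is built to resolve on fitted surfaces.

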