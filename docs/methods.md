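# Methods

## Problem and parametrization

A single-determinant excited state is a stationary point of the
mean-field energy with nonaufbau occupations. With a fixed basis, the
orbitals are `C = C0·exp(κ)`, `κ = −κᵀ` real. The energy is invariant
under rotations inside blocks of equal occupation, so the optimization
variables are restricted to the nonredundant pairs `f_i ≠ f_j` (the
invariance is asserted by a property test). The exponential is evaluated
exactly through the Hermitian eigendecomposition of `iκ`; a truncated
power series serves only as a test oracle. After every accepted step the
current orbitals become the new reference (`κ` restarts at zero), so the
gradient formula is always evaluated at `κ = 0`:

    g_ij = 2 (f_j − f_i) H_ij ,      H = Cᵀ F C .

The prefactor and sign are fixed by a central-finite-difference oracle
on the model backend (max deviation < 1e-7 a.u. over random instances),
not by convention.

## Optimizers

Both phases use limited-memory quasi-Newton steps with a fixed maximum
step size instead of a line search; divergence is guarded by the
iteration cap (333 by default).

* **L-BFGS** (two-loop recursion) for minimization: ground state and
  the constrained phase. The initial inverse Hessian is the diagonal
  model `d_ij = 2(ε_i − ε_j)(f_j − f_i)` inverted with |d| floored at
  1e-3 Ha, clamped positive — a minimizer must not follow negative
  curvature. Curvature-violating update pairs are skipped.
* **L-SR1** for the saddle search (release, DO-MOM): the signed
  preconditioner is kept, so negative elements drive uphill steps along
  concave directions. The inverse Hessian is reconstructed densely from
  the update pairs each step (rotation spaces here have tens of
  variables); an update is skipped when `|(s−Hy)ᵀy| < 1e-8‖s−Hy‖‖y‖`.
* The "maximum step size" (0.2 constrained and DO-MOM, 0.1 released) is
  a cap on the max-norm of the κ step with uniform rescaling, keeping
  the direction intact. Memory length 20; all of these are configurable.

Convergence is measured by the squared SCF residual per valence
electron in eV² (1 Ha = 27.211386 eV): 4e-3 for the constrained phase,
4e-8 for full convergence. The Lagrange-multiplier matrix in the
residual is identified with the Fock matrix within equal-occupation
subspaces, which makes the residual exactly the occupied–virtual Fock
coupling norm and ties it algebraically to the gradient,
`r = (eV²/4N)·‖g‖²` — both identities are tested.

## Freeze-and-release driver

The initial guess swaps the hole/particle occupations on ground-state
orbitals; the MOM reference (occupied guess columns) is captured there
and never updated. The freeze phase excludes every rotation pair
touching a hole or particle orbital, in the excited spin channel only,
and minimizes with the reduced Hamiltonian over the relaxed subspace.
Afterward the Hamiltonian is diagonalized within equal-occupation
blocks *restricted to the relaxed orbitals*: frozen columns stay
bit-identical (their reported ε is the diagonal expectation value),
while the refreshed eigenvalues rebuild the diagonal model for the
release phase. Quasi-Newton memory is not carried across the phase
boundary (the variable space changes). Occupations are held fixed in
both FR-DO phases; MOM is active only in the DO-MOM baseline, where the
full pair space is used (occupations may change mid-run, so the
nonredundant set is not stable — equal-occupation directions carry zero
gradient, making this equivalent to the full-κ parametrization). When
MOM changes occupations, the quasi-Newton memory is cleared: the
objective over κ changes discontinuously, and stale curvature pairs
otherwise drive limit cycles. MOM ties (weights equal within 1e-12)
keep the current occupation, preventing oscillation at symmetric mixing.

The guess-time diagonal model uses the *ground-state* canonical orbital
energies — the only eigenvalues available at iteration 0. This is why
the model is always (wrongly) convex along hole/occupied mixing pairs
at the guess: the hole descends from the ground-state HOMO, which lies
above every other occupied orbital. The spin-purification companion run
promotes the electron across spin channels (hole in the opposite
channel), giving an S_z = 1 determinant for `E_s = 2E_m − E_t`.

## Model backend

The test substrate is an unrestricted Pariser–Parr–Pople dimer: two
fragments of a few sites each, nearest-neighbour intra-fragment hopping,
one optional bridge bond, zero-differential-overlap two-electron
integrals with Ohno interpolation `V_pq = 1/√(R_pq² + a_pq²)`,
`a_pq = 2/(U_p+U_q)` (chosen over Mataga–Nishimoto for its clean 1/R
tail). Internal arithmetic is Hartree/Bohr. Two exchange treatments:

* `hf` — nonlocal exchange `K_σ = V ∘ P_σ`. Convex in fractional
  charges; used for the dissociation/oracle fixtures.
* `local` — spin-averaged Slater-type on-site exchange
  `E_x = −Σ_p U_p (n_p/2)^{4/3}`, an orbital-independent local
  potential that is concave in fractional occupation. This emulates the
  two features of semilocal density functionals that drive variational
  collapse of charge-transfer states: occupied and virtual orbitals
  share one potential (so the hole orbital tracks the electrostatics of
  the charged fragment), and fractional delocalization is energetically
  favored (the delocalization error). With Hartree–Fock exchange the
  collapse trap provably cannot form in this model — fractional
  inter-fragment charge is convexly penalized and the virtual hole
  orbital sees the N-electron potential — which is why the collapse
  fixture uses `local`. The optimizer layer is functional-agnostic
  either way.

The ground-state driver starts from a short damped Fock-diagonalization
sweep over the superposition of neutral site densities. A bare
core-Hamiltonian guess can place all charge on the lower-energy
fragment; for decoupled fragments the inter-fragment gradient vanishes
identically (ZDO + t_DA = 0 make the Fock matrix block diagonal), so
direct optimization could never repair the fragment charges afterwards.
The independent fixed-point SCF oracle breaks charge-sloshing limit
cycles by escalating its density damping and requires both ΔE < 1e-12 Ha
and a converged density.

## Fixture generator

`generate_fixture(seed, kind)` defines the study conditions:

* `decoupled` — t_DA = 0, two sites per fragment spaced 2 Bohr
  perpendicular to the axis, U ≈ 1 Ha, site-energy offset ±0.25 Ha with
  ±0.02 per-site detuning (breaks the exact mirror symmetry so
  stationary points are nondegenerate), t_intra ≈ 0.3 Ha — above the
  intra-fragment spin-symmetry-breaking threshold, so the spin-symmetric
  ground state is a true minimum rather than an antiferromagnetic
  saddle. The perpendicular layout keeps inter-fragment distances within
  ~2% of R for R ≥ 10 Bohr, which is what makes the −1 Ha·Bohr slope of
  E_CT vs 1/R physically attainable; the measured slope is −0.978, the
  residual deviation being the Ohno screening length and the finite site
  spread.
* `collapse` — t_DA = 0.06, R ≈ 7–8 Bohr, U 1.2–1.5, local exchange,
  selected by an internal search that *verifies the full collapse
  mechanism* before returning: the occupied/hole rotation scan from the
  guess has a maximum within 15° of zero and a spurious minimum near 45°
  below the guess; the guess-time diagonal model is convex along that
  pair while the post-constrained model is concave; and DO-MOM actually
  converges strictly below the freeze-and-release solution with smaller
  d_CT. The search raises an error rather than silently returning an
  untrapped system.

What the generator does **not** emulate: real electronic structure has
hundreds of basis functions, core states, and geometry-dependent
integrals; saddle orders here are single digits instead of ~10; and the
d_CT contrast between collapsed and target solutions is small (~0.03
Bohr on ~7.5) because in a two-site-per-fragment perpendicular geometry
every inter-fragment density change has d_CT ≈ R — the energy contrast
(~0.18 Ha) carries the discrimination instead. Passing tests demonstrate
the optimization and diagnosis machinery, not chemical accuracy.

## Hessian analysis

The electronic Hessian is built by central finite differences of the
analytic gradient along each rotation direction (step 1e-4 rad,
symmetrized). Away from stationarity the rotating frame introduces
O(step·gradient) asymmetry, which symmetrization suppresses; the
asymmetry is asserted < 1e-5 at stationary states. Model systems are
small, so a dense symmetric eigendecomposition replaces iterative
partial solvers. The saddle order is the count of negative eigenvalues,
optionally filtered to |λ| > 1 eV; the diagonal estimate counts negative
elements of the orbital-energy model. Rotation scans return the energy
along one pair together with the local quadratic model (gradient plus
diagonal curvature), the diagnostic used throughout for the collapse
mechanism.

## Numerical choices and edge cases

* Column signs after diagonalization: largest-magnitude component made
  positive, for reproducible outputs.
* Preconditioner floor 1e-3 Ha; zero diagonal elements (redundant
  directions in the DO-MOM full-pair space) get the positive floor and
  carry zero gradient.
* Degenerate MOM weights: current occupation wins (tie tolerance 1e-12).
* All backends are real; complex orbitals and fractional occupations are
  out of scope.
* Problem sizes: fixtures use 4-site dimers (8–12 rotation variables);
  oracle cross-checks use random systems up to 8 sites. These sizes make
  every dense oracle (power-series exponential, triple-loop
  contractions, finite-difference Hessians, angle scans) exact and fast.

## Known limitations

The model's excitation energies (~5–15 eV) are set by the model
parameters, not calibrated to any molecule. The collapse fixture's
spurious minimum sits slightly below 45° mixing; minima beyond 45° make
MOM flip occupations each iteration and DO-MOM limit-cycle instead of
collapsing — a convergence failure rather than a silent collapse, which
is the other failure mode such calculations show in practice. The
external-geometry path reads XYZ files and maps atoms to model sites;
it is a convenience, not an ab initio interface.
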