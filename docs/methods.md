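# Methods

This note records the models, algorithms and numerical conventions behind
identikit, the design choices made where several constructions were
possible, and what the bundled benchmarks do and do not demonstrate.

## Model class and jet systems

identikit handles ODE models x' = f(x, p, u), y = g(x, p) with f, g vectors
of rational functions, constant parameters p (count m1), known inputs u and
outputs y. Rational right-hand sides are cleared to polynomial form per
equation before any jet expansion; the cleared denominators are retained
and checked for vanishing whenever a point is sampled (valid at generic
complex points, which is the only regime the methods operate in).

The truncated jet system F_r is built by writing states, inputs and outputs
as Taylor series with derivative-normalised coefficients (x_j is the j-th
derivative at t = 0, named `x.j`) and matching coefficients of 1, t, …, t^r.
The expansion uses truncated power-series arithmetic — Leibniz convolution
with binomial weights on polynomial coefficients — rather than symbolic
differentiation of compositions: the cost is quadratic in r per product and
the result is exact. Block G_j holds one polynomial per state (containing
the term −x_{j+1}) and one per output; linear initial-condition constraints
such as x3(0) = 0 are kept as separate extra equations so that F_r remains
a strict prefix of F_{r+1}.

Generic points on F_r = 0 are produced by forward recursion: parameters,
order-0 states (projected onto the initial constraints) and input jets are
drawn at random, after which every higher state jet and every output jet is
the unique solution of a linear equation in its block. Random complex
scalars are a + bi with a, b uniform on [−1, 1], rejecting |z| < 0.1, so
points stay away from coordinate hyperplanes without large dynamic range.
Seeds propagate through a single `numpy.random.Generator`, so every result
is reproducible from one integer seed.

## Rank decisions

All dimension statements reduce to coranks of complex Jacobians at generic
points. Decisions are made from singular values after equilibration
(normalising rows, then columns, by their maximum modulus — rank is
invariant under nonzero diagonal scaling). The default rule keeps a
singular value when it exceeds 1e−8 × σ_max. Two refinements matter in
practice:

* **Ambiguity guard.** When a singular value falls within a factor 100 of
  the cut, the fixed threshold is unreliable. High-order jet systems are
  the offender: their smallest genuine singular values decay toward the cut
  as r grows, while true zeros stay at the numerical floor (≤ 1e−13 of
  σ_max). In the ambiguous case the rank is therefore taken from the
  sharpest spectral gap (ratio > 1e6, opening below 1e−4 × σ_max); a tail
  with no such gap that stays above 1e−10 × σ_max contains no true zeros
  and is counted in full. If neither rule applies and the matrix is small
  (≤ 80 rows/columns), the SVD is recomputed at 40-digit precision.
* **Monotonicity retry.** In the corank-stabilisation loop the reported
  sequence d_r is provably nonincreasing and nonnegative; a row violating
  this is recomputed at up to two fresh random points before being
  accepted, which suppresses the rare unlucky draw at high order.

Coranks are additionally confirmed at a second independent random point in
the coefficient-map route (Method-1 style); disagreement raises rather than
guessing.

## Dimension of unidentifiability

Two routes, which the tests require to agree on every fixture with a known
coefficient map:

* from the coefficient map: ℓ = corank of the Jacobian of c at a random
  complex parameter point (quotient rule for rational entries);
* from jet systems: for r = 0, 1, 2, … seed a generic point on F_r, hold
  input and output jets fixed, and compute d_r = corank₀ JF_r − corank_m1
  JF_r (the dimension of the parameter-space projection of the fiber). The
  loop stops when d_r = 0 or both coranks repeat between consecutive
  orders; one confirmation row beyond the stopping order is computed and
  reported. Fresh random points are used at every order (prefix points
  could be reused; independence was chosen for robustness). The default
  order cap is r = 25, comfortably above the largest stabilisation order
  (r = 16) among the bundled fixtures.

## Path tracking and solving

The tracker follows H(z, t) = 0 from t = 1 to 0 with an RK4 predictor on
the Davidenko ODE dz/dt = −H_z⁻¹ H_t and a Newton corrector (≤ 3 steps,
relative tolerance 1e−9), halving the step on failure and doubling it after
5 consecutive successes (initial 0.05, minimum 1e−8). Endpoints are
polished by Newton at t = 0 and must reach residual 1e−10 relative to the
point norm; paths exceeding |z| = 1e8 are declared divergent (the bound is
raised to 1e13 for jet-side tracking, where coordinates legitimately grow
like eigenvalue^order). There is no endgame for singular endpoints: paths
whose final polish fails are classified singular/divergent and excluded
from solution counts, which is sound here because every counted solution in
the bundled problems is nonsingular.

Square systems are solved from the total-degree start system z_i^{d_i} =
b_i with random b_i and a random unit-modulus gamma factor; all ∏ d_i paths
are tracked, duplicate endpoints are re-tracked at tighter tolerance before
deduplication, and the solution set is checked against a brute-force
univariate-product oracle in the tests. Overdetermined systems are squared
up with generic complex combinations and endpoints filtered on the full
system; inside jet-side fiber sampling, a well-conditioned row subset (QR
with pivoting on the transposed Jacobian) replaces dense randomisation to
preserve sparsity, and equations are rescaled so their largest term at the
seed is of order one. Jet-side tracking additionally works in scaled
coordinates w = z / |z_seed| because jet magnitudes span many orders.

## Identifiability degree

* **Direct solving:** solve c(q) = c(p) at a random p by total-degree
  homotopy and count distinct finite solutions; the base point must be
  recovered among them or the computation aborts.
* **Monodromy:** seed the pseudowitness set W = Graph(c) ∩ (C^m1 × L2) with
  (p, c(p)) for a random codimension-m1 slice L2 through c(p), then run
  random monodromy loops in which the slice constants traverse
  s(t) = 1 − e^{2πi(1−t)} along a random complex direction. New endpoints
  enlarge W; k = #W / #π(W) where π projects to the image coordinates.
  The loop budget is 10 consecutive useless loops (a concrete version of
  "many loops yielding nothing new"), extended while #W fails the
  necessary divisibility #W ≡ 0 mod #π(W).
* **Certification:** completeness of W is certified by the multihomogeneous
  trace test. The last slice hyperplane h_y is dropped to leave a curve
  C = Graph(c) ∩ M2; the curve's points on a generic parameter-space
  hyperplane h_x are found by total-degree solving; and all points of
  C ∩ {h_x · h_y = 0} are tracked to two members of the bilinear family
  h_x · h_y = t. The test passes when the vector sum of the point set moves
  affine-linearly in t (collinearity residual < 1e−6 relative); it reports
  the curve bidegree as a byproduct. A plain linear-trace variant (parallel
  translates of h_y alone) is available but is not the default: for a
  multiprojective curve the affine trace can fail even on a complete set
  because of points at infinity in the chosen pencil, which is exactly why
  the bilinear family is used.
* **Jet-side degree:** at an order r where the model is identifiable, the
  leading output jets are pinned (exactly as many as make the system square
  once the state-fiber dimension has been cut by random linear slices in
  the state jets; the remaining output jets stay unknowns), all solutions
  are enumerated by monodromy over the pinned output coordinates (triangle
  loops with random complex vertices), and each solution is extended by the
  next output jet. Solutions are grouped by their full output — free jets
  plus the extension — and k is the size of the group containing the seed
  solution. Pinning instead of randomised squaring keeps every endpoint a
  genuine solution of the full jet system. The group census is always
  reported and unequal group sizes raise a warning rather than being
  hidden. The enumeration itself stops heuristically (useless loops), but
  `output_line_bidegree` certifies it: the jet solution set over a generic
  output *line* is a curve, and the multihomogeneous trace test on a
  bilinear family — one factor a parameter hyperplane, the other an output
  hyperplane vanishing at the benchmark output — checks completeness and
  reports the curve's bidegree. The trace is summed only over the factor
  coordinates (the parameters in the first factor, and the line coordinate
  s): linearity is a statement about the two slicing factors, and the state
  jets riding along the curve move nonlinearly. The choice of hyperplane
  family is exposed as an argument; no canonical jet-side family is known.
  If groups were not separated at order r+1 the extension depth would need
  to grow; no general stopping depth is known, so the implementation
  exposes it.

## Identifiable functions

Fiber points q on the component V_p through a generic base point p are
sampled by slice moving: a random slice of codimension d (= fiber
dimension) through p is deformed to fresh random slices, Eq-style, with the
fiber equations squared up by generic combinations. Each sample pair (p, q)
imposes the row [f_1(q) − f_1(p), …, f_j(q) − f_j(p)] on the coefficient
vector a of a candidate function Σ a_i f_i in the monomial test space; the
identifiable subspace is the null space of the stacked rows. Pairs are
added until the null-space dimension is stable across two consecutive
additions. Rows that are negligible relative to the matrix maximum are
dropped before per-row normalisation — they are pairs on which every basis
function agrees, and normalising them would amplify noise into spurious
constraints.

Integer-coefficient generators are obtained by reducing the null-space
basis to echelon form over well-conditioned pivot columns, rationalising
each entry with denominators bounded by 1e6, and verifying the candidates
against the constraint rows; recovered generators are re-verified on fresh
samples. python-flint (LLL) is not a dependency; the echelon/rationalise
route plus mpmath-style bounded-denominator reconstruction covers the
integer lattices that arise here, where generators have small coefficients.

The staged search mirrors the practitioner's workflow for building a
transcendence basis of rank-c identifiable functions: at degree d = 1, 2, 3
the monomials of total degree d are scanned for sparse constant
combinations (support 1, then 2, then 3 columns, deciding by the smallest
singular value of the column subset), keeping only candidates that increase
the Jacobian rank of the recovered set, and stopping once rank c = m1 − ℓ
independent functions are known. Scanning by increasing support finds the
sparsest generators first, which is what makes the recovered set match the
published low-degree generators on the 4-compartment benchmark.

Global identifiability requires points on *all* irreducible components of
a fiber. These come from an affine restriction b : C^{m1−d} → C^m1 chosen
so that the restricted map c∘b is identifiable: the restricted fiber is
solved either by total-degree homotopy (small Bézout count) or through the
pseudowitness set of c∘b on a slice through the target value — that slice
section contains the target, so the witness set contains every fiber point
over it. (Monodromy over loops in the restricted base space is *not* used:
the tracked point rides the tautological section p̂(t) and the loop is
trivial by construction.) A function is labelled globally identifiable when
its values agree across all component points; combinations that become
global (sums over conjugate components) are found from a second null space
over the component-value matrix. Component counts come from slice-loop
monodromy on the fiber itself, merging witness-point orbits; the count is
an upper bound that is tight once the loops mix, and is reported as such.

## Benchmarks and their scope

The bundled fixtures are the linear 3-compartment model (7 parameters, 2
dimensions of unidentifiability, three identifiable column sums), its
single-leak restriction (identifiability degree 2), a 3-compartment model
that loses identifiability when x3(0) = 0, a 5-parameter HIV-dynamics model
(jet-side degree 4 with 12 solutions in 3 output classes), a 4-compartment
model (ℓ = 4, six independent identifiable functions up to degree 3, one
fiber component), and a mass-action two-site phosphorylation network (MAPK;
kinase/phosphatase mechanism with 12 species and 22 rate parameters, plus a
32-parameter variant with 10 output-mixing coefficients). The MAPK ODEs are
reconstructed from the standard mass-action mechanism — complexes KS00,
KS01, KS10, FS01, FS10, FS11 formed with binding/unbinding/catalysis rates
a/b/c (kinase) and α/β/γ (phosphatase) — because a typeset flattening of
the species names can conflate the complex KS00 with the product K·S00; the
reconstruction reproduces the published corank tables integer for integer,
which is the strongest available confirmation of the reading.

All fixture inputs are exact and printed in the package; no external data
is used. What the tests demonstrate is agreement of independent numerical
routes on exact benchmark models — they do not address noisy data,
practical (numerical) identifiability, real-parameter restrictions, or
model classes outside rational ODEs (no time-varying parameters, no SDEs,
no numerical integration anywhere). Derivation of input–output equations
by differential elimination is deliberately out of scope: coefficient maps
are supplied as fixtures or by the user, and everything else runs jet-side.

## Known limitations

* Monodromy stopping is heuristic wherever the trace test is not run; the
  useless-loop budget (default 10) trades completeness confidence for time.
* Corank decisions at very high jet order (beyond the stabilisation point)
  can require the retry guard; the reported stabilised dimension is the
  quantity of interest and is stable across seeds in all fixtures.
* The trace test assumes the witness curve section is reduced and the
  family generic; tracking failures yield "inconclusive", never a silent
  pass.
* Component counts from orbit merging are upper bounds (exact in the
  benchmarks, where they are certified by the restricted-map degree).
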