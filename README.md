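# identikit

Structural identifiability analysis for rational ODE models by numerical
algebraic geometry.

## The problem

A dynamical model

```
x'(t) = f(x(t), p, u(t)),      y(t) = g(x(t), p)
```

with rational right-hand sides f, g, unknown constant parameters p, known
input u and measured output y is *structurally identifiable* when perfect
input–output data determines p up to finitely many values. Writing the
coefficients of the model's input–output equations as a rational map
c : C^m1 → C^m2 on the parameters, three questions arise:

* **Is the model identifiable?** The dimension of a generic fiber of c (the
  *dimension of unidentifiability* ℓ) equals the corank of the Jacobian of c
  at a generic complex point; ℓ = 0 means identifiable.
* **If identifiable, how many parameter vectors share the data?** The
  *identifiability degree* k is the generic cardinality of the fiber
  c⁻¹(c(p)); k = 1 is global, k > 1 local identifiability.
* **If unidentifiable, which functions of p are determined?** *Identifiable
  functions* are exactly the functions constant on irreducible components of
  generic fibers; *globally* identifiable functions are constant across all
  components.

identikit answers all three numerically, either from an explicitly known
coefficient map or — when differential elimination is hopeless, as for
larger biochemical networks — directly from the model via truncated
Taylor-jet systems F_r (matching coefficients of 1, t, …, t^r), with:

* Jacobian corank at generic complex points with corank stabilisation over
  the jet order r (the nonincreasing sequence d_r = corank₀ JF_r −
  corank_m1 JF_r converges to ℓ),
* total-degree (Bézout) homotopy continuation with the gamma trick,
* monodromy loops on pseudowitness sets with multihomogeneous trace-test
  certification for the degree k,
* fiber sampling by slice-moving homotopies, null-space interpolation over
  monomial test spaces, and exact integer-coefficient recovery of
  identifiable parameter combinations.

The intended users are modellers in pharmacokinetics, systems biology and
biochemical network analysis who need to know, before fitting, which
parameters or parameter combinations their experiment can possibly
determine.

## Worked example

The classic linear 3-compartment model (drug in blood with two peripheral
compartments, input and measurement in compartment 1, leak rates k0i and
exchange rates kij) ships as the fixture `linear3`:

```
$ identikit dim linear3 --via jets --seed 3
{ ... "dimension": 2, "identifiable": false, "stabilized_at_r": 8,
  "rows": [[0,13,9,2,7], [1,16,8,1,7], [2,19,7,0,7], [3,22,6,0,6],
           [4,25,5,0,5], [5,28,4,0,4], [6,31,3,0,3], [7,34,2,0,2],
           [8,37,2,0,2], [9,40,2,0,2]] ... }
```

Each row is (r, N_r, corank₀, corank₇, d_r): by order r = 8 the sequence d_r
has stabilised at 2, so the 7 rate constants have a 2-dimensional set of
indistinguishable values — the model is unidentifiable. What *can* be
determined:

```
$ identikit functions linear3_c --degree 1 --global --seed 2
{ ... "dimension": 3,
  "functions": ["k01 + k21", "k02 + k12 + k32", "k03 + k13"],
  "labels": ["globally identifiable", "identifiable", "identifiable"],
  "globally_identifiable_combinations":
      ["k01 + k21", "k02 + k03 + k12 + k13 + k32"] ... }
```

The identifiable linear combinations are the three compartment column sums;
`k01 + k21` takes the same value on every irreducible component of the
fiber (globally identifiable), the other two are swapped between components
and only their sum is global.

Restricting the model by k01 = k03 = 0 makes it identifiable, and its
degree comes out by direct solving (12 total-degree paths, 2 finite
solutions) or certified monodromy:

```
$ identikit degree linear3_noleak13_c --method solve --seed 2
{ ... "k": 2 ... }
```

so exactly two parameter vectors produce any generic input–output record —
locally but not globally identifiable.

The same machinery runs jet-side when no input–output equations are
available: `identikit dim mapk_6out --via jets` proves identifiability of a
22-parameter mass-action MAPK two-site phosphorylation network in under a
minute, and `identikit degree hiv --via jets -r 7` enumerates all 12
parameter vectors of a 5-parameter HIV-dynamics model consistent with a
fixed truncated output and groups them into 3 output classes of 4
(identifiability degree 4).

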