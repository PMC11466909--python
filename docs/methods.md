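# Methods

## Scope and model

The package studies mass-action systems `ẋ = Γ(κ ∘ x^A)` on the nonnegative
quadrant with two species, at most bimolecular reactant complexes (quadratic
right-hand sides), four reactions, and product molecularity capped at two
(bimolecular censuses) or three (trimolecular censuses). Within that class it
decides which networks admit fold, Andronov–Hopf, Bogdanov–Takens and Bautin
bifurcations of positive equilibria, and classifies the degenerate (vertical)
variants. Everything is decided exactly; floating point appears only in
numeric cross-checks inside the test-suite.

## Enumeration and dynamical equivalence

The input universe is generated combinatorially — there is no external data.
Reactants range over the six bimolecular complexes `{0, X, Y, 2X, X+Y, 2Y}`,
products over the complexes within the molecularity cap. Two networks are
treated as equivalent when they generate the same *family* of ODE systems up
to swapping the species. For a fixed reactant complex, a set of reactions
contributes the open positive span of its reaction vectors, so the family is
determined by the per-reactant closed convex cones. The fingerprint of a
network is the sorted table (reactant, canonical cone), minimised over the
transposition X↔Y, with cones canonicalised as a primitive ray, a CCW-ordered
extreme-ray pair (sectors and half-planes), a line, or the whole plane.
Class representatives take, for each extreme ray `r` at reactant `c`, the
reaction `c → c + r` (the minimal-molecularity product for that ray); the
censuses never contain full-plane cones, because a reactant carrying three or
more reactions leaves at most two distinct reactant points, which the
collinearity filter removes.

Census patterns: with four distinct reactants the multiplicity pattern is
`(1,1,1,1)`; the Hopf base census also admits `(2,1,1)` (one reactant used
twice). Patterns with at most two distinct reactant points are excluded by
the filters of every census run here; a census with neither the
distinct-reactant nor the non-collinearity filter raises
`NotImplementedError` rather than returning a silently incomplete answer.

## Equilibrium algebra

For a dynamically nontrivial `(2, 4, 2)` network, `ker Γ ∩ ℝ⁴₊` is a
two-dimensional pointed cone; its extreme rays are computed exactly from the
integer nullspace, and the cross-section is `h(α) = (1−α) r₀ + α r₁` on the
open interval `α ∈ (0,1)` (rays ordered lexicographically, so all results
are deterministic). Positive equilibria correspond to
`κ ∘ x^A = λ h(α)`, and the Jacobian there factorises as
`J = λ Γ diag(h(α)) A diag(1/x)`, so that

* `det J = λ² det M(α) / (x₁x₂)` with `M(α) = Γ diag(h(α)) A`,
* `tr J = λ (M₁₁(α)/x₁ + M₂₂(α)/x₂)`.

`M`'s entries are integer affine functions and `det M` an integer quadratic,
so every feasibility decision is a sign question about polynomials of degree
≤ 2: root isolation is closed-form, signs at quadratic surds are evaluated in
`ℚ(√D)`, and open sign conditions are decided by exact sampling at rational
points chosen strictly between all isolated critical roots. The open-domain
semantics (cone boundary and coordinate axes excluded) is enforced throughout.

A subtlety worth recording: purely imaginary eigenvalues arise not only where
`M₁₁M₂₂ < 0` (trace zeroed by the choice of `x`) but also where both diagonal
entries vanish simultaneously — then the trace vanishes for *every* positive
`x`. In the trimolecular census exactly the latter geometry produces 39 of
the 198 Hopf networks; missing it undercounts the Hopf census.

## Fold classification

Fold candidates are det-roots `α*` in `(0,1)` with `(M₁₁, M₂₂) ≠ (0,0)`.
Nondegeneracy is certified at one exact witness (`x₁ = 1`, `x₂` a small
integer making the trace nonzero): the quadratic normal-form coefficient
`⟨p, B(q,q)⟩` over the left/right null vectors of `J` must be nonzero, and
the root must be simple (`det M′(α*) ≠ 0`), which makes the zero eigenvalue
unfold transversally in the rate constants through the chart
`(α, λ, x) ↦ κ`. When every det-root forces `M₁₁ = M₂₂ = 0`, the Jacobian is
nilpotent wherever it is singular (a forced double zero: an incompletely
unfolded codimension-two singularity) — three trimolecular classes are of
this type. Networks admitting no nondegenerate positive equilibrium at all
undergo a vertical fold: at constructed critical rate constants
(`κ = h(α₀)`, making `(1,1)` an equilibrium) the equilibrium set contains a
straight line, detected symbolically by substituting the three candidate line
types through `(1,1)` (through-origin, horizontal, vertical).

Rank-one networks are handled combinatorially: a quadratic rank-one network
admits a nondegenerate fold iff, after deleting trivial species, it has at
most two species and contains three reactions matching (up to positive column
scaling and species swap) the pattern `0→aX, X→0, 2X→bX (b ≥ 3)` or one of
its three liftings along the diagonal direction `(1,1)`.

Origin stability (for the bistability census) is decided uniformly over all
positive κ from the sign-definiteness of `det J(0)` and `tr J(0)` as
polynomials in κ; a zero eigenvalue is resolved only when the center
direction is an invariant axis and the restricted scalar flow has a
sign-definite quadratic coefficient. Anything else returns `undecided`
(never silently stable) — the case does not occur among the 30 bimolecular
fold networks.

## Hopf classification and focal values

The Hopf set of a census network has one of two exact geometries:
*curve* components (open α-intervals with `M₁₁M₂₂ < 0` and `det M > 0`,
trace zeroed by `x₂(α) = −M₂₂/M₁₁`, `x₁ = 1`) and *line* components (one
diagonal entry identically zero, the other with a root `α₀` where
`det M > 0`; the Hopf points are `α = α₀`, `x = (1, t)`, `t > 0`). In both
charts the Jacobian is conjugated by the rational basis `u = (J₁₂, −J₁₁)`,
`w = (0,1)` into `((0,1),(−Δ,0))` form (`J₁₂ ≠ 0` on the whole Hopf set,
since `det J > 0` forces `J₁₂J₂₁ < 0`). Focal values are then closed-form
rational functions of the chart parameter: `η₁, η₂, η₃` come from a
Lyapunov function `V = (Δu² + v²)/2 + V₃ + …` with
`V̇ = η₁(Δu²+v²)² + η₂(Δu²+v²)³ + …`. The generated module
`_focal_formulas.py` stores the closed forms; the test-suite re-derives them
from scratch and also cross-checks `η₁`'s sign against numerical integration
of a weak focus. `η₁ < 0` means the weak focus attracts, i.e. the
bifurcation is supercritical; `ηₖ₊₁` is used only where `η₁ … ηₖ` vanish, so
the well-known basis-dependence of higher focal values away from the
vanishing locus never matters.

The classification decides the sign of `η₁` over each whole component by
isolating the real roots of its numerator (algebraic endpoints are compared
via certified rational enclosures, with exact minimal-polynomial equality
resolution when enclosures keep overlapping). Where `η₁` vanishes
identically, `η₂ ≡ η₃ ≡ 0` is verified symbolically and the Kapteyn–Bautin
criterion certifies a center (vertical Hopf). At isolated `η₁`-roots, `η₂`'s
vanishing is decided by divisibility of its numerator by the root's minimal
polynomial; a nonzero `η₂` is the Bautin case (its sign, `L₂ > 0` for the
unique Bautin network, by adaptive high-precision evaluation of a quantity
already certified nonzero). Transversality holds on curve components because
`∂tr/∂x₁ = −M₁₁/x₁² ≠ 0`, and on line components iff the non-vanishing
diagonal entry has nonzero slope.

For kernel cones of dimension ≥ 3 (e.g. the five-reaction combustion
network) the sign-over-domain analysis is out of scope; focal values are
evaluated exactly at user-supplied rational kernel points instead, and the
test-suite spot-checks supercriticality that way.

## Bogdanov–Takens classification

At a double-zero point (`det M(α*) = 0`, `M₁₁M₂₂ < 0` there, trace zeroed by
`x₂ = −M₂₂/M₁₁`), the field is expanded in the nilpotent basis `q₀ ∈ ker J`,
`J q₁ = q₀`, giving `ξ̇₁ = ξ₂ + ½a₂₀ξ₁² + …`, `ξ̇₂ = ½b₂₀ξ₁² + b₁₁ξ₁ξ₂ + …`.
Only the sign `σ = sign((a₂₀+b₁₁) b₂₀)` and the zero/nonzero pattern are
reported; they are invariant under the scaling freedom of the basis. The
critical `α*` is a quadratic surd at worst, so all coefficients live in
`ℚ(√D)` and are computed there. `a₂₀ + b₁₁ = 0` is the vertical BT case,
where the package instead reports the exact phase-plane structure: a Dulac
monomial `x^p y^q` making the divergence constant, the Hamiltonian of the
rescaled field on the divergence-free parameter subvariety (verified by
`∇H·f ≡ 0`), and the equilibrium-count trichotomy obtained by elimination.
Transversality of the two-parameter unfolding is certified by simplicity of
the det-root, which makes `(tr J, det J)` a submersion in the `(α, x₁)`
chart; the chart `(α, λ, x) ↦ κ` is onto a neighbourhood, so the unfolding
by rate constants is transversal as well.

## Diagonal equivalence and natural coordinates

Diagonal equivalence (`Γ̂ = D₁ Γ D₂` up to species swap and
reactant-preserving reaction permutation) is decided exactly by propagating
the multiplicative system `d₁ᵢ d₂ⱼ = ratioᵢⱼ` over the support graph of `Γ`;
class counting buckets networks by a sign-pattern invariant first. All
bifurcation classifications are invariant across diagonal classes (checked on
the printed pairs), which is the main internal consistency check of the
classifiers.

The natural-coordinates reduction computes `Ḡ = [A|1|U]⁻¹`, verifies the
identity `I − AG = 1v + UW` symbolically, and emits the reduced field
`ẏ = κ^{G+1v} ∘ Γ((κ^W)^U ∘ y^A)` with `n` outer and `m−n−1` inner
parameters — hence the codimension bound `m−2`, which is what rules out
cusp and other codimension-3 bifurcations in the four-reaction class. `U` is
chosen as the integer completion with minimal `|det|` (lexicographic
tie-break); the printed completion of the worked example is kept as a
regression fixture since `U` is not unique.

## What the generator emulates, and what a green test establishes

The enumeration module *is* the data generator: the censuses are the full
combinatorial universe of the stated network class, not a sample, so the
census counters are exact statements about that class. What the green tests
do **not** establish: anything about networks with more species, more
reactions, or higher reactant molecularity; global dynamics (limit-cycle
uniqueness, basins); or stability of non-origin boundary equilibria. Numeric
spot checks (ODE integration, float eigenvalues, finite differences) guard
against sign-convention errors in the exact machinery but carry no proof
weight of their own.

## Numerical and design choices

* Rational sample points between isolated algebraic roots decide all open
  sign conditions; tie cases (sample hitting a root) are impossible by
  construction and guarded by assertions.
* Algebraic numbers of degree ≤ 2 are handled in `ℚ(√D)` without radicals;
  higher-degree roots (from focal-value numerators) are sympy `CRootOf`
  objects with certified rational enclosures.
* `solve_equilibria` uses lex Gröbner bases with shape-lemma back-
  substitution (both variable orders tried), keeping every root exact and
  sign-decidable; one-dimensional solution sets are reported as `continuum`.
* The three-equilibria witness `κ = (1, 1, 51, 200)` for the printed
  high-molecularity example was located by a one-parameter solvability scan
  (`κ^W = h(α)^W` needs three preimages) and is verified at run time by the
  exact solver.
* Classifier "undecidable" outcomes raise (`ArithmeticError`) rather than
  defaulting; none occur across the censuses.
* Per-network decisions are cached in memory (`lru_cache` keyed by the
  network value); the full pipeline takes ~1 minute, so no on-disk cache is
  kept.

## Known limitations

* The dynamical-equivalence census is implemented for four-reaction networks
  on two species; other sizes raise `NotImplementedError`.
* Sign-over-domain focal-value analysis requires a kernel cone of dimension
  ≤ 2 (point evaluation works for any dimension).
* Conservation-law networks (rank < number of species) are outside the
  reduced-Jacobian machinery.
* The per-network Hopf-type table of the reference catalog is only
  checkable in aggregate; individual classifications are validated where the
  type is printed (the Bautin network, the BT rows, the combustion example).
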