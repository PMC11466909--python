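# crnbif — exact bifurcation census of planar quadratic mass-action networks

`crnbif` classifies, by exact symbolic computation, the local bifurcations of
positive equilibria admitted by small chemical reaction networks: two species,
mass-action kinetics, at most bimolecular reactant complexes (so the ODEs are
at most quadratic on the nonnegative quadrant), four reactions, and product
molecularity at most three. It is aimed at researchers in chemical reaction
network theory and mathematical biology who want machine-checked answers to
"which minimal networks can oscillate / be bistable / undergo a
Bogdanov–Takens bifurcation?"

## The mathematics in brief

A network with stoichiometric matrix `Γ` and reactant matrix `Γℓ`
(`A = Γℓᵗ`) defines the mass-action system `ẋ = Γ(κ ∘ x^A)`, `κ > 0`.
For a dynamically nontrivial full-rank planar network, positive equilibria are
parameterised through the cone `ker Γ ∩ ℝ^m₊`: with a cross-section `h(α)` of
the cone, `x` is an equilibrium for `κ = λ h(α)/x^A`, and its Jacobian is

    J = λ Γ diag(h(α)) A diag(1/x).

All eigenvalue questions therefore reduce to sign conditions on the 2×2
*reduced core* `M(α) = Γ diag(h(α)) A`, whose entries are affine and whose
determinant is quadratic in `α`:

* zero eigenvalue: `det M(α) = 0` for some `α` in the open cross-section;
* purely imaginary pair: `det M(α) > 0` with the trace zeroed by `x`
  (diagonal entries of opposite sign, or both zero);
* double zero (Bogdanov–Takens): both at once.

These are decided exactly with rational arithmetic and quadratic-surd sign
evaluation — no floating point enters any decision. Hopf criticality uses
focal values `η₁, η₂, η₃` obtained from a Lyapunov-function construction
(closed formulas in `crnbif._focal_formulas`, re-derived in the test-suite);
`η₁ = η₂ = η₃ = 0` certifies a center for a quadratic field (Kapteyn–Bautin),
i.e. a vertical Andronov–Hopf bifurcation. Bogdanov–Takens points are
classified by the sign `σ = sign((a₂₀+b₁₁)b₂₀)` of the nilpotent normal-form
coefficients, computed exactly in `ℚ` or `ℚ(√D)`.

Networks are enumerated up to *dynamical equivalence* (same family of ODE
systems, up to swapping the two species), fingerprinted by the per-reactant
positive cones of their reaction vectors.

## Worked example

```pycon
>>> from crnbif import parse_network, classify_fold, classify_hopf, bt_normal_form
>>> net = parse_network("2X > 3X; X+Y > 2Y; Y > 0; 0 > Y")
>>> from crnbif.equilibria import reduced_core
>>> reduced_core(net).det        # det M(alpha) = 2 alpha^2 - alpha
(0, -1, 2)
>>> classify_fold(net).fold_nondegenerate
True
>>> classify_hopf(net).kind
'supercritical'
>>> rec = bt_normal_form(net); (rec.sigma, rec.vertical_bt)
(-1, False)
```

`det M(α) = α(2α−1)` vanishes at `α = ½` inside the open cross-section, so
the network admits an equilibrium with a zero eigenvalue; the certified
quadratic normal-form coefficient makes the fold nondegenerate. On
`α ∈ (½, 1)` the diagonal entries of `M` have opposite signs with
`det M > 0`, giving Hopf points whose first focal value is negative
throughout (`supercritical`: a stable limit cycle is born). At `α = ½` the
trace can be zeroed as well, and `σ = −1`: a supercritical Bogdanov–Takens
bifurcation, with the full local bifurcation diagram (fold, Hopf and
homoclinic curves) implied by the normal form.

The same classifiers run over the whole censuses from the command line:

```sh
crnbif census --tracks fold,bimolecular,hopf,bt --out census_out
crnbif verify                  # compares the BT catalog with the printed table
crnbif classify "2X > 3X; X+Y > 2X; X > 0; 0 > Y"
```

`census` prints the named counters (e.g. `Lemma21.total: 5897`,
`Theorem30.supercritical: 135`, `Theorem33.subcritical: 23`) and writes
per-network CSV catalogs.

## Acceptance script

`scripts/acceptance.py` recomputes the headline census counts from scratch —
raw enumeration, dynamical-equivalence reduction, and the exact
eigenvalue-feasibility decisions — and writes them to JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The pipeline is fully deterministic; the seed exists only for reproducibility
of the interface. The run takes about half a minute on one CPU.
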