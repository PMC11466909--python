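"""Kernel cone, reduced Jacobian core, and eigenvalue feasibility decisions."""

from fractions import Fraction

import pytest
import sympy as sp
from hypothesis import given
from hypothesis import strategies as st

from crnbif.core import parse_network
from crnbif.equilibria import (admits_nondegenerate_equilibrium,
                               construct_rate_constants, diag_signs_at_roots,
                               double_zero_feasible, hopf_alpha_intervals,
                               kernel_cone, purely_imaginary_feasible,
                               rank_condition, reduced_core, solve_equilibria,
                               second_eigenvalue_signs,
                               zero_eigenvalue_feasible)

NET1 = parse_network("2X > 3X; X+Y > 2Y; Y > 0; 0 > Y")
LVA = parse_network("2X > 3X; X+Y > 2Y; Y > 0")


def test_kernel_cone_examples():
    cone = kernel_cone(NET1)
    assert cone.rays == ((0, 0, 1, 1), (1, 1, 1, 0))
    assert cone.h_at(Fraction(1, 2)) == [Fraction(1, 2)] * 2 + [1, Fraction(1, 2)]
    assert kernel_cone(LVA).rays == ((1, 1, 1),)
    with pytest.raises(ValueError):
        kernel_cone(parse_network("0 > X"))


def test_reduced_core_printed_example():
    core = reduced_core(NET1)
    # M11 = alpha, M22 = alpha - 1, det M = alpha (2 alpha - 1)
    assert core.m11 == (0, 1)
    assert core.m22 == (-1, 1)
    assert core.det == (0, -1, 2)


def test_rank_condition_examples():
    assert rank_condition(NET1)
    # reactants on a line: 0, X, 2X (plus a repeat)
    collinear = parse_network("0 > Y; X > X+Y; 2X > 3X; X > 2X")
    assert not rank_condition(collinear)


def test_admits_nondegenerate_equilibrium():
    assert admits_nondegenerate_equilibrium(NET1)
    assert admits_nondegenerate_equilibrium(LVA)  # det M = 1 on the single ray


def test_zero_eigenvalue_and_second_signs():
    ok, roots = zero_eigenvalue_feasible(NET1)
    assert ok and len(roots) == 1 and roots[0].value == Fraction(1, 2)
    [(r, s11, s22)] = diag_signs_at_roots(NET1)
    assert (s11, s22) == (1, -1)
    assert second_eigenvalue_signs(NET1) == {"negative", "positive"}
    assert not zero_eigenvalue_feasible(LVA)[0]


def test_purely_imaginary_and_hopf_interval():
    assert purely_imaginary_feasible(NET1)
    assert not purely_imaginary_feasible(LVA)
    # no X+Y reactant -> off-diagonal entries nonnegative, never imaginary
    assert not purely_imaginary_feasible(
        parse_network("2X > 3X; X > 0; Y > 2Y; 0 > Y"))
    [(lo, hi)] = hopf_alpha_intervals(NET1)
    assert lo.value == Fraction(1, 2) and hi == Fraction(1)


def test_double_zero_feasible():
    ok, root = double_zero_feasible(NET1)
    assert ok and root.value == Fraction(1, 2)
    assert not double_zero_feasible(LVA)[0]


def test_jacobian_factorisation_identity():
    """det J = lambda^2 det M(alpha) / (x1 x2), symbolically."""
    a, lam, x1, x2 = sp.symbols("alpha lambda x1 x2", positive=True)
    for net in (NET1, parse_network("2X > 3X; X+Y > 2X; X > 0; 0 > Y")):
        cone = kernel_cone(net)
        h = [c0 + c1 * a for c0, c1 in cone.h_affine()]
        G = sp.Matrix(net.gamma)
        A = sp.Matrix([list(r) for r in net.A])
        J = lam * G * sp.diag(*h) * A * sp.diag(1 / x1, 1 / x2)
        core = reduced_core(net)
        detM = sum(c * a**k for k, c in enumerate(core.det))
        assert sp.simplify(J.det() - lam**2 * detM / (x1 * x2)) == 0


def test_construct_rate_constants_round_trip():
    x = (Fraction(2), Fraction(3))
    kappa = construct_rate_constants(NET1, x, alpha=Fraction(2, 3), lam=Fraction(5))
    field, xs, _ = NET1.mass_action_field(
        kappa=[sp.Rational(k.numerator, k.denominator) for k in kappa])
    vals = {xs[0]: sp.Rational(2), xs[1]: sp.Rational(3)}
    assert all(f.subs(vals) == 0 for f in field)


def test_solve_equilibria_trichotomy_network9():
    net9 = parse_network("2X > 3X; X+Y > 2X; X > 0; 0 > Y")
    # sign of 4 k1 k4 - k3^2 decides 0 / 1 / 2 positive equilibria
    kind, sols = solve_equilibria(net9, [1, 1, 3, 2])   # 8 - 9 < 0
    assert kind == "points" and sorted(s for s, _ in sols) == \
        [(sp.Integer(1), sp.Integer(2)), (sp.Integer(2), sp.Integer(1))]
    assert all(nd for _, nd in sols)
    kind, sols = solve_equilibria(net9, [1, 1, 1, 2])   # 8 - 1 > 0
    assert kind == "points" and sols == []
    kind, sols = solve_equilibria(net9, [1, 1, 2, 1])   # 4 - 4 = 0
    assert kind == "points" and len(sols) == 1 and not sols[0][1]


@given(st.fractions(min_value="1/10", max_value="9/10"),
       st.fractions(min_value="1/4", max_value="4"),
       st.fractions(min_value="1/4", max_value="4"))
def test_feasibility_invariant_under_scaling(alpha, lam, scale):
    """Rate constants built from any (alpha, lambda, x) witness the decisions."""
    x = (scale, 2 * scale)
    kappa = construct_rate_constants(NET1, x, alpha=alpha, lam=lam)
    assert all(k > 0 for k in kappa)
    kind, sols = solve_equilibria(NET1, kappa)
    assert kind == "points"
    assert any(s == (sp.Rational(x[0].numerator, x[0].denominator),
                     sp.Rational(x[1].numerator, x[1].denominator))
               for s, _ in sols)


def test_theorem12_few_reactants_at_most_one_equilibrium(hopf_base_census):
    """<= 3 distinct reactant complexes forbids two nondegenerate equilibria."""
    few = [n for n in hopf_base_census
           if len({r.reactant for r in n.reactions}) <= 3]
    assert few  # the base census does contain repeated-reactant classes
    rng_alpha = [Fraction(1, 3), Fraction(3, 5)]
    for net in few[::7][:20]:
        for a in rng_alpha:
            kappa = construct_rate_constants(net, (Fraction(1), Fraction(2)),
                                             alpha=a)
            kind, sols = solve_equilibria(net, kappa)
            if kind == "continuum":
                continue
            assert sum(1 for _, nd in sols if nd) <= 1, net.serialise()
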