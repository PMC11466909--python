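"""Diagonal equivalence and the natural-coordinates reduction."""

import itertools
from fractions import Fraction

import pytest
import sympy as sp

from crnbif.core import parse_network
from crnbif.equivalence import (count_diagonal_classes, diagonally_equivalent,
                                example10_two_parameter_form,
                                natural_coordinates)
from crnbif.tables import (EXAMPLE10_GBAR, EXAMPLE10_GBAR_INV, EXAMPLE10_U,
                           TABLE3_DIAGONAL_PAIRS, table3_networks)


def _check_witness(net1, net2, w):
    """Verify D1 Gamma D2 (with permutation / species swap) equals Gamma_hat."""
    cand = net2.permute_species((1, 0)) if w.species_swapped else net2
    for i in range(2):
        for j in range(net1.n_reactions):
            lhs = w.d1[i] * Fraction(net1.gamma[i][j]) * w.d2[j]
            assert lhs == cand.gamma[i][w.permutation[j]]


def test_printed_diagonal_pairs_with_witnesses():
    nets = table3_networks()
    for i, j in TABLE3_DIAGONAL_PAIRS:
        ok, w = diagonally_equivalent(nets[i - 1], nets[j - 1])
        assert ok
        _check_witness(nets[i - 1], nets[j - 1], w)


def test_diagonal_equivalence_is_reflexive_symmetric():
    nets = table3_networks()[:6]
    for n in nets:
        assert diagonally_equivalent(n, n)[0]
    for a, b in itertools.combinations(nets, 2):
        assert diagonally_equivalent(a, b)[0] == diagonally_equivalent(b, a)[0]


def test_shape_mismatch_is_inequivalent():
    n3 = parse_network("2X > 3X; X+Y > 2Y; Y > 0")
    n4 = parse_network("2X > 3X; X+Y > 2Y; Y > 0; 0 > Y")
    assert not diagonally_equivalent(n3, n4)[0]


def test_table3_diagonal_class_count():
    assert count_diagonal_classes(table3_networks()) == 28


def test_example10_natural_coordinates_printed_matrices():
    net1 = table3_networks()[0]
    nc = natural_coordinates(net1, U=EXAMPLE10_U)
    assert nc.Gbar == tuple(tuple(sp.Integer(v) for v in row)
                            for row in EXAMPLE10_GBAR)
    M = sp.Matrix(EXAMPLE10_GBAR).inv()
    assert tuple(tuple(M[i, j] for j in range(4)) for i in range(4)) == \
        tuple(tuple(sp.Integer(v) for v in row) for row in EXAMPLE10_GBAR_INV)
    # reduced ODE (inner parameter b1, outer a1, a2):
    X, Y = nc.y
    a1, a2 = nc.outer
    b1, = nc.inner
    assert sp.expand(nc.reduced_field[0] - a1 * (b1**2 * X**2 - b1**2 * X * Y)) == 0
    assert sp.expand(nc.reduced_field[1] - a2 * (b1**2 * X * Y - b1 * Y + b1)) == 0
    assert nc.codimension_bound == 2


def test_example10_two_parameter_form():
    (fx, fy), nc = example10_two_parameter_form()
    X, Y = nc.y
    beta, gamma = sp.symbols("beta gamma", positive=True)
    assert sp.expand(fx - (X**2 - X * Y)) == 0
    assert sp.expand(fy - beta * (gamma * X * Y - Y + 1)) == 0


def test_solvability_recovery():
    """W [A|1] = 0, so multiplying the equilibrium condition by W recovers
    the solvability condition kappa^W = h(alpha)^W."""
    net1 = table3_networks()[0]
    nc = natural_coordinates(net1, U=EXAMPLE10_U)
    W = sp.Matrix([list(r) for r in nc.W])
    A1 = sp.Matrix([list(r) + [1] for r in net1.A])
    assert W * A1 == sp.zeros(1, 3)


def test_natural_coordinates_rejects_rank_deficient():
    collinear = parse_network("0 > Y; X > X+Y; 2X > 3X; X > 2X")
    with pytest.raises(ValueError):
        natural_coordinates(collinear)


def test_classifications_invariant_across_diagonal_pairs():
    """Fold / Hopf / BT classifications agree across the printed pairs."""
    from crnbif.bt import bt_normal_form
    from crnbif.equilibria import (purely_imaginary_feasible,
                                   second_eigenvalue_signs,
                                   zero_eigenvalue_feasible)
    from crnbif.hopf import classify_hopf
    nets = table3_networks()
    for i, j in TABLE3_DIAGONAL_PAIRS:
        a, b = nets[i - 1], nets[j - 1]
        assert zero_eigenvalue_feasible(a)[0] == zero_eigenvalue_feasible(b)[0]
        assert second_eigenvalue_signs(a) == second_eigenvalue_signs(b)
        assert purely_imaginary_feasible(a) == purely_imaginary_feasible(b)
        ca, cb = classify_hopf(a), classify_hopf(b)
        assert ca.kind == cb.kind
        ra, rb = bt_normal_form(a), bt_normal_form(b)
        assert (ra.sigma, ra.vertical_bt) == (rb.sigma, rb.vertical_bt)
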