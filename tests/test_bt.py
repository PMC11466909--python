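"""Bogdanov-Takens normal forms, vertical BT, and the printed catalog."""

from fractions import Fraction

import numpy as np
import pytest
import sympy as sp

from crnbif.bt import (bt_normal_form, bt_point, equilibrium_count_rule_network9,
                       vertical_bt_analysis)
from crnbif.core import parse_network
from crnbif.equilibria import double_zero_feasible
from crnbif.tables import (TABLE3, TABLE3_DIAGONAL_PAIRS, TABLE3_SUBCRITICAL,
                           TABLE3_SUPERCRITICAL, TABLE3_VERTICAL,
                           generalised_lva, table3_networks)


def test_bt_point_network1():
    net1 = table3_networks()[0]
    root, x, h = bt_point(net1)
    assert root.value == Fraction(1, 2)
    assert x == (1, 1)  # M11 = 1/2, M22 = -1/2 -> x2 = 1


def test_no_double_zero_for_generalised_lva():
    assert not double_zero_feasible(generalised_lva(2))[0]
    rec = bt_normal_form(generalised_lva(2))
    assert not rec.double_zero_feasible


@pytest.mark.parametrize("row", [1, 5, 9, 10, 12, 17, 28, 33])
def test_bt_sigma_matches_printed_split(row):
    rec = bt_normal_form(table3_networks()[row - 1])
    assert rec.double_zero_feasible
    if row in TABLE3_SUPERCRITICAL:
        assert rec.sigma == -1 and not rec.vertical_bt
    elif row in TABLE3_VERTICAL:
        assert rec.vertical_bt and rec.sigma is None
    else:
        assert rec.sigma == +1 and not rec.vertical_bt
    if not rec.vertical_bt:
        assert rec.transversal


def test_sigma_invariant_under_diagonal_equivalence():
    nets = table3_networks()
    for i, j in TABLE3_DIAGONAL_PAIRS:
        ri, rj = bt_normal_form(nets[i - 1]), bt_normal_form(nets[j - 1])
        assert ri.sigma == rj.sigma and ri.vertical_bt == rj.vertical_bt


def test_bt_coefficients_against_numeric_oracle():
    """a20, b11, b20 agree with a float computation at the witness (10 digits).

    The numeric route recomputes everything with numpy: equilibrium field from
    float kappa, nilpotent basis from the float Jacobian, and second partial
    derivatives of the transformed field by exact polynomial expansion in
    float arithmetic.
    """
    for row in (1, 9, 20):
        net = parse_network(TABLE3[row - 1], species=["X", "Y"])
        rec = bt_normal_form(net)
        root, x, h = bt_point(net)
        xf = np.array([float(x[0]), float(x[1])])
        hf = np.array([float(v) for v in h])
        A = np.array(net.A, dtype=float)
        G = np.array(net.gamma, dtype=float)
        kf = hf / np.prod(xf ** A, axis=1)

        def field(z):
            return G @ (kf * np.prod(z ** A, axis=1))

        eps = 1e-6
        J = np.zeros((2, 2))
        for j in range(2):
            e = np.zeros(2); e[j] = eps
            J[:, j] = (field(xf + e) - field(xf - e)) / (2 * eps)
        # nilpotent basis: q0 spans ker J, J q1 = q0
        q0 = np.array([J[0, 1], -J[0, 0]])
        col = J[:, 0] if np.linalg.norm(J[:, 0]) > 1e-9 else J[:, 1]
        c = (col @ q0) / (q0 @ q0)
        q1 = (np.array([1.0, 0.0]) if np.linalg.norm(J[:, 0]) > 1e-9
              else np.array([0.0, 1.0])) / c
        S = np.column_stack([q0, q1])
        Sinv = np.linalg.inv(S)

        def Gfield(xi):
            return Sinv @ field(xf + S @ xi)

        d = 1e-4
        a20 = (Gfield([d, 0])[0] + Gfield([-d, 0])[0]) / d**2
        b20 = (Gfield([d, 0])[1] + Gfield([-d, 0])[1]) / d**2
        b11 = (Gfield([d, d])[1] - Gfield([d, -d])[1]
               - Gfield([-d, d])[1] + Gfield([-d, -d])[1]) / (4 * d * d)
        for exact, num in ((rec.a20, a20), (rec.b11, b11), (rec.b20, b20)):
            assert abs(float(exact) - num) < 1e-5 * max(1.0, abs(num))


def test_vertical_bt_hamiltonian_structure():
    net9 = table3_networks()[8]
    rep = vertical_bt_analysis(net9)
    k = sp.symbols("kappa1:5", positive=True)
    assert sp.simplify(rep["dulac_divergence"] - (k[0] - k[1])) == 0
    assert rep["hamiltonian"] is not None
    # conservation at kappa1 = kappa2 = 1, kappa3 = 3, kappa4 = 2, symbolically
    x, y = sp.symbols("x y", positive=True)
    field, xs, kap = net9.mass_action_field(x=(x, y))
    subs = dict(zip(kap, (1, 1, 3, 2)))
    # reorder: in Table 3 order the reactions are (2X>3X, X+Y>2X, 0>Y, X>0)
    H = rep["hamiltonian"].subs(rep["hamiltonian_condition"]).subs(subs)
    f = [fi.subs(subs) for fi in field]
    dH = sp.simplify(sp.diff(H, x) * f[0] + sp.diff(H, y) * f[1])
    assert dH == 0


def test_equilibrium_trichotomy_discriminant():
    disc, net = equilibrium_count_rule_network9()
    k = sp.symbols("kappa1:5", positive=True)
    assert sp.simplify(disc - (k[2]**2 - 4 * k[0] * k[3])) == 0
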