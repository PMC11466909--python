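"""Hopf points, focal values, and Andronov-Hopf classification."""

from fractions import Fraction

import pytest
import sympy as sp

from crnbif import _focal_formulas as ff
from crnbif.core import parse_network
from crnbif.hopf import (classify_hopf, derive_focal_values,
                         focal_value_at_kernel_point, focal_value_at_point,
                         focal_values, hopf_components, hopf_point)
from crnbif.tables import (bautin_network, frank_kamenetsky_salnikov,
                           generalised_lva, table3_networks)

NET1 = parse_network("2X > 3X; X+Y > 2Y; Y > 0; 0 > Y")


def test_generated_formulas_match_fresh_derivation():
    """The stored eta1..eta3 equal an independent re-derivation (symbolically)."""
    etas = derive_focal_values(upto=3)
    syms = sp.symbols("Delta p20 p11 p02 q20 q11 q02")
    for eta, func in zip(etas, (ff.eta1, ff.eta2, ff.eta3)):
        assert sp.cancel(eta - func(*syms)) == 0


def test_focal_value_known_weak_focus():
    """For udot = v, vdot = -u + u^2 - uv the focus is stable (eta1 < 0).

    Oracle: for the classical system xdot = -y + a x^2, ydot = x + b x^2 the
    first focal value has the sign of certain coefficient products; here we
    cross-check eta1 directly by numerical integration of the radius map.
    """
    import numpy as np
    from scipy.integrate import solve_ivp
    vals = dict(Delta=Fraction(1), p20=Fraction(0), p11=Fraction(0),
                p02=Fraction(0), q20=Fraction(1), q11=Fraction(-1),
                q02=Fraction(0))
    eta1 = ff.eta1(**vals)

    def rhs(t, z):
        u, v = z
        return [v, -u + u * u - u * v]

    r0 = 0.05
    sol = solve_ivp(rhs, [0, 2 * np.pi * 40], [r0, 0.0],
                    rtol=1e-11, atol=1e-13, dense_output=True)
    r1 = np.hypot(*sol.y[:, -1])
    assert (eta1 < 0) == (r1 < r0)


def test_hopf_components_and_point_net1():
    comps = hopf_components(NET1)
    assert len(comps) == 1 and comps[0].kind == "curve"
    assert comps[0].lo.value == Fraction(1, 2) and comps[0].hi == 1
    alpha, x, kappa, omega2 = hopf_point(NET1, comps[0], Fraction(3, 4))
    assert alpha == Fraction(3, 4) and omega2 > 0
    # x2 = -M22/M11 = (1 - 3/4)/(3/4) = 1/3
    assert x == (1, Fraction(1, 3))


def test_no_hopf_without_mixed_reactant():
    assert hopf_components(generalised_lva(2)) == []
    with pytest.raises(ValueError):
        classify_hopf(parse_network("2X > 3X; X > 0; Y > 2Y; 0 > Y"))


def test_classify_known_networks():
    assert classify_hopf(NET1).kind == "supercritical"
    c = classify_hopf(bautin_network())
    assert c.kind == "bautin" and c.l2_sign == 1  # subcritical Bautin: L2 > 0
    c9 = classify_hopf(parse_network("2X > 3X; X+Y > 2X; X > 0; 0 > Y"))
    assert c9.kind == "vertical"


def test_focal_values_two_routes_agree():
    """Closed-formula eta1 equals the degree-by-degree derivation numerically."""
    comp = hopf_components(NET1)[0]
    (num, den), = focal_values(NET1, comp, upto=1)
    for a in (Fraction(3, 5), Fraction(7, 10)):
        direct = focal_value_at_point(NET1, comp, a, upto=1)[0]
        aq = sp.Rational(a.numerator, a.denominator)
        assert sp.Rational(direct.numerator, direct.denominator) == \
            num.eval(aq) / den.eval(aq)


def test_fks_network_supercritical_samples():
    """The five-reaction combustion network: L1 < 0 at sampled Hopf points.

    Its kernel cone has three extreme rays, so Hopf witnesses are sampled
    directly from rational kernel points with the trace zeroed by x.
    """
    from crnbif.equilibria import kernel_cone, positive_kernel_rays
    net = frank_kamenetsky_salnikov()
    cone = kernel_cone(net)
    assert cone.dimension >= 3
    found = 0
    for w in [(1, 1, 1), (2, 1, 1), (1, 2, 1), (1, 1, 2), (3, 1, 2)][:5]:
        weights = w + (1,) * (cone.dimension - 3)
        h = cone.point(weights[:cone.dimension])
        # M = Gamma diag(h) A; zero the trace by x2/x1 = -M22/M11 if possible
        import sympy as sp_
        G = sp.Matrix(net.gamma)
        A = sp.Matrix([list(r) for r in net.A])
        M = G * sp.diag(*[sp.Rational(v.numerator, v.denominator) for v in h]) * A
        if M[0, 0] * M[1, 1] >= 0:
            continue
        m11 = Fraction(int(M[0, 0].p), int(M[0, 0].q))
        m22 = Fraction(int(M[1, 1].p), int(M[1, 1].q))
        x2 = -m22 / m11
        eta1 = focal_value_at_kernel_point(net, h, (Fraction(1), x2))
        assert eta1 < 0
        found += 1
    assert found >= 3


def test_vertical_networks_center_certificate(full_report):
    """All vertical networks satisfy eta1 = eta2 = eta3 = 0 identically."""
    verticals = [row["network"] for row in full_report.rows["hopf"]
                 if row["hopf_type"] == "vertical"]
    assert len(verticals) == 17
    for s in verticals[:5]:
        net = parse_network(s, species=["X", "Y"])
        for comp in hopf_components(net):
            vals = focal_values(net, comp, upto=3)
            assert all(num.is_zero for num, _ in vals)
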