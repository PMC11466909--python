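"""Bogdanov-Takens points: double-zero eigenvalues and normal-form data.

A BT point of a planar network is a positive equilibrium whose Jacobian is
nilpotent of index two: ``det M(alpha*) = 0`` with oppositely signed diagonal
entries, and ``x`` chosen to zero the trace.  In a nilpotent basis the field
reads ``xi1' = xi2 + a20/2 xi1^2 + ..., xi2' = b20/2 xi1^2 + b11 xi1 xi2 +
...``; the bifurcation is nondegenerate when ``a20 + b11 != 0`` and
``b20 != 0``, in which case the sign ``sigma = sign((a20 + b11) b20)``
determines the truncated normal form (supercritical for -1, subcritical
for +1).  ``a20 + b11 = 0`` marks the degenerate *vertical* BT case, where an
exact Hamiltonian/Dulac analysis applies instead.

The critical alpha is a root of an integer quadratic, so all coefficients are
computed exactly in Q or in the real quadratic field Q(sqrt(disc)).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import sympy as sp

from ._algebra import QuadExt, poly_deriv, poly_eval
from ._taylor import equilibrium_field, nilpotent_basis_coefficients
from .core import Network, parse_network
from .equilibria import double_zero_feasible, kernel_cone, reduced_core


@dataclass
class BTRecord:
    """Exact Bogdanov-Takens classification data for one network."""

    double_zero_feasible: bool
    a20: object | None = None          # Fraction or QuadExt
    b11: object | None = None
    b20: object | None = None
    sigma: int | None = None           # sign((a20+b11) b20); None if degenerate
    vertical_bt: bool = False          # a20 + b11 = 0
    transversal: bool | None = None
    alpha: object | None = None        # critical cone parameter (root object)
    x: tuple | None = None             # BT equilibrium (x1 = 1 scaling)


def _sign_of(v) -> int:
    if isinstance(v, QuadExt):
        return v.sign()
    return (v > 0) - (v < 0)


def bt_point(net: Network):
    """Exact BT witness: (root, x, h_values) with trace J = 0, J nilpotent."""
    ok, root = double_zero_feasible(net)
    if not ok:
        raise ValueError("network admits no double-zero eigenvalue")
    core = reduced_core(net)
    cone = kernel_cone(net)
    if root.is_rational:
        alpha = root.value
        lift = Fraction
    else:
        alpha = root.as_quadext()
        lift = lambda v: QuadExt(v, 0, root.disc)  # noqa: E731
    m11 = poly_eval([lift(c) for c in core.m11], alpha)
    m22 = poly_eval([lift(c) for c in core.m22], alpha)
    # trace J = M11/x1 + M22/x2 = 0 with x1 = 1
    x = (lift(1), -m22 / m11)
    h = [poly_eval([lift(c0), lift(c1)], alpha) for c0, c1 in cone.h_affine()]
    return root, x, h


def bt_normal_form(net: Network) -> BTRecord:
    """Compute a20, b11, b20, sigma at the BT point, exactly.

    Only signs and zero/nonzero distinctions are reported downstream: they are
    invariant under the scaling freedom in the nilpotent basis.
    Transversality of the two-parameter unfolding holds iff the det-root is
    simple (the unfolding directions alpha and x1 then move (det J, tr J)
    surjectively, and the map kappa -> (alpha, lambda, x) is onto).
    """
    try:
        root, x, h = bt_point(net)
    except ValueError:
        return BTRecord(False)
    comps, _ = equilibrium_field(net, h, x)
    a20, b11, b20 = nilpotent_basis_coefficients(comps)
    s = a20 + b11
    vertical = _sign_of(s) == 0 if not isinstance(s, QuadExt) else s.is_zero()
    sigma = None
    if not vertical and _sign_of(b20) != 0:
        sigma = _sign_of(s) * _sign_of(b20)
    core = reduced_core(net)
    dd = root.sign_of_poly(poly_deriv(core.det))
    return BTRecord(True, a20, b11, b20, sigma, vertical,
                    transversal=(dd != 0), alpha=root, x=x)


# ----------------------------------------------------------------------
# Vertical BT analysis (Hamiltonian / Dulac structure)
# ----------------------------------------------------------------------

def vertical_bt_analysis(net: Network) -> dict:
    """Exact Hamiltonian/Dulac report for vertical-BT candidates.

    Searches for a Dulac function ``x^p y^q`` making the divergence of the
    rescaled field constant; reports that constant, and -- where the constant
    vanishes on a rate-constant subvariety -- a Hamiltonian for the rescaled
    field together with a symbolic conservation check.
    """
    x, y = sp.symbols("x y", positive=True)
    field, xs, kappa = net.mass_action_field(x=(x, y))
    report: dict = {"dulac_divergence": None, "dulac_exponents": None,
                    "hamiltonian": None, "hamiltonian_condition": None}
    for p, q in [(-1, 0), (0, -1), (-1, -1), (0, 0)]:
        B = x**p * y**q
        div = sp.expand(sp.diff(B * field[0], x) + sp.diff(B * field[1], y))
        if div.has(x) or div.has(y):
            continue
        report["dulac_divergence"] = sp.simplify(div)
        report["dulac_exponents"] = (p, q)
        # on the divergence-free subvariety the rescaled field is Hamiltonian
        cond = sp.solve(div, kappa[0], dict=True)
        subs = cond[0] if cond else {}
        g = [sp.simplify(B * f.subs(subs)) for f in field]
        # divergence-free: g = (H_y, -H_x) for some H
        H = -sp.integrate(g[1], x)
        corr = sp.integrate(sp.simplify(g[0] - sp.diff(H, y)), y)
        H = sp.simplify(H + corr)
        check = sp.simplify(sp.diff(H, x) * g[0] + sp.diff(H, y) * g[1])
        if check == 0:
            report["hamiltonian"] = H
            report["hamiltonian_condition"] = subs
        break
    return report


def equilibrium_count_rule_network9():
    """Trichotomy for the vertical-BT network 2X>3X, X+Y>2X, X>0, 0>Y.

    With this reaction order the field is ``xdot = k1 x^2 + k2 x y - k3 x``,
    ``ydot = -k2 x y + k4``.  Returns ``(disc, net)`` where
    ``disc = k3^2 - 4 k1 k4``: the network has 0 / 1 / 2 positive equilibria
    according to ``disc`` negative / zero / positive, derived by exact
    elimination (equivalently, by the sign of ``4 k1 k4 - k3^2``).
    """
    net = parse_network("2X > 3X; X+Y > 2X; X > 0; 0 > Y")
    x, y = sp.symbols("x y", positive=True)
    field, _, kappa = net.mass_action_field(x=(x, y))
    k1, k2, k3, k4 = kappa
    # eliminate y: from ydot = 0, x y = k4/k2; substitute into xdot/x
    poly_x = sp.expand(sp.together(field[0] / x).subs(y, k4 / (k2 * x)) * x)
    disc = sp.discriminant(sp.Poly(poly_x, x))
    return sp.factor(disc), net
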