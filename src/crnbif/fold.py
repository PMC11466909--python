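"""Fold (saddle-node) classification, vertical folds, rank-one folds, and
origin stability.

A fold candidate is a positive equilibrium with a simple zero eigenvalue:
``det M(alpha*) = 0`` at an isolated root with ``(M11, M22) != (0, 0)``.
Nondegeneracy is certified at one exact witness: the quadratic normal-form
coefficient ``<p, B(q, q)>`` (p, q the left/right null vectors of J) is
nonzero, and the zero eigenvalue is unfolded transversally (simple det-root).
If every det-root forces ``M11 = M22 = 0``, the Jacobian there is nilpotent of
index two for every admissible x: the network only admits an incompletely
unfolded double-zero singularity ("forced double zero").
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import sympy as sp

from ._algebra import QuadExt, poly_deriv, poly_eval, poly_is_zero
from ._taylor import equilibrium_field, jacobian
from .core import Network, primitive
from .equilibria import (admits_nondegenerate_equilibrium, diag_signs_at_roots,
                         kernel_cone, reduced_core)


@dataclass
class FoldRecord:
    fold_feasible: bool
    fold_nondegenerate: bool | None
    forced_double_zero: bool
    witness: dict | None = None


def _sign_of(v) -> int:
    if isinstance(v, QuadExt):
        return v.sign()
    return (v > 0) - (v < 0)


def classify_fold(net: Network, verify_witness: bool = True) -> FoldRecord:
    """Decide fold feasibility / nondegeneracy for a planar census network."""
    if net.rank != 2 or net.n_species != 2:
        raise ValueError("fold classification requires a planar full-rank network")
    info = diag_signs_at_roots(net)
    if not info:
        return FoldRecord(False, False, False)
    simple = [(r, s11, s22) for r, s11, s22 in info if (s11, s22) != (0, 0)]
    if not simple:
        return FoldRecord(False, False, True)
    if not verify_witness:
        return FoldRecord(True, None, False)
    root, s11, s22 = simple[0]
    witness = _fold_witness(net, root)
    return FoldRecord(True, witness["nondegenerate"], False, witness)


def _fold_witness(net: Network, root) -> dict:
    """Exact fold witness at a det-root: normal-form coefficient and unfolding."""
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
    # choose positive x with nonzero trace (simple zero eigenvalue)
    x2 = None
    for cand in (1, 2, 3, 5, 7):
        tr = m11 + m22 / lift(cand)
        if _sign_of(tr) != 0:
            x2 = lift(cand)
            break
    if x2 is None:  # m11 = -m22 only happens at isolated x2; unreachable
        raise ArithmeticError("could not find a simple-zero witness")
    x = (lift(1), x2)
    h = [poly_eval([lift(c0), lift(c1)], alpha) for c0, c1 in cone.h_affine()]
    comps, kappa = equilibrium_field(net, h, x)
    (j11, j12), (j21, j22) = jacobian(comps)
    # right/left null vectors of the rank-one J
    q = (j12, -j11) if not (_sign_of(j12) == 0 and _sign_of(j11) == 0) else (j22, -j21)
    p = (-j21, j11) if not (_sign_of(j21) == 0 and _sign_of(j11) == 0) else (j22, -j12)
    Bq = []
    for comp in comps:
        _, _, _, c20, c11, c02 = comp
        Bq.append(c20 * q[0] * q[0] + c11 * q[0] * q[1] + c02 * q[1] * q[1])
    coeff = p[0] * Bq[0] + p[1] * Bq[1]
    transversal = root.sign_of_poly(poly_deriv(core.det)) != 0
    return {
        "alpha": root, "x": x, "kappa": kappa,
        "quadratic_coefficient": coeff,
        "transversal": transversal,
        "nondegenerate": _sign_of(coeff) != 0 and transversal,
    }


# ----------------------------------------------------------------------
# Vertical fold: a line of equilibria at the critical rate constants
# ----------------------------------------------------------------------

def vertical_fold(net: Network) -> str:
    """Classify the equilibrium line of a degenerate census network.

    Precondition: the network is dynamically nontrivial but admits no positive
    nondegenerate equilibrium.  At the critical rate constants the equilibrium
    set contains a straight line through the constructed equilibrium (1, 1):
    returns "through-origin", "horizontal" or "vertical".
    """
    if admits_nondegenerate_equilibrium(net):
        raise ValueError("network admits a nondegenerate equilibrium")
    cone = kernel_cone(net)
    for a0 in (Fraction(1, 3), Fraction(1, 2), Fraction(2, 5)):
        if cone.dimension == 1:
            h = [Fraction(v) for v in cone.rays[0]]
        else:
            h = cone.h_at(a0)
        kappa = h  # x0 = (1,1): x0^A = 1, lambda = 1
        field, (x, y), _ = net.mass_action_field(
            kappa=[sp.Rational(k.numerator, k.denominator) for k in kappa])
        t = sp.Symbol("t", positive=True)
        if all(sp.expand(f.subs({x: t, y: t})) == 0 for f in field):
            return "through-origin"
        if all(sp.expand(f.subs(y, 1)) == 0 for f in field):
            return "horizontal"
        if all(sp.expand(f.subs(x, 1)) == 0 for f in field):
            return "vertical"
        if cone.dimension == 1:
            break
    raise ArithmeticError("no straight equilibrium line found at the witness")


# ----------------------------------------------------------------------
# Rank-one folds (combinatorial characterisation)
# ----------------------------------------------------------------------

def rank_one_fold(net: Network) -> bool:
    """Does a quadratic rank-one network admit a nondegenerate fold?

    Equivalent to admitting multiple positive nondegenerate equilibria, and
    decided combinatorially: after removal of trivial species the network must
    include, on at most two nontrivial species, three reactions simply
    equivalent to 0 -> aX, X -> 0, 2X -> bX (a >= 1, b >= 3), or to one of its
    three two-species liftings along the diagonal direction (1, 1).
    """
    if not net.is_quadratic():
        raise ValueError("requires a quadratic network")
    if net.rank != 1:
        raise ValueError("requires a rank-one network")
    reduced = net
    for idx in sorted(net.trivial_species(), reverse=True):
        reduced = reduced.drop_species(idx)
    n = reduced.n_species
    if n > 2:
        return False

    def has(reactant, direction) -> bool:
        return any(r.reactant.coefficients == reactant
                   and primitive(r.reaction_vector) == direction
                   for r in reduced.reactions)

    if n == 1:
        return has((0,), (1,)) and has((1,), (-1,)) and has((2,), (1,))
    up = lambda c: has(c, (1, 1))  # noqa: E731
    if not has((1, 1), (-1, -1)):
        return False
    if up((2, 0)) and (up((0, 0)) or up((0, 1)) or up((0, 2))):
        return True
    if up((0, 2)) and (up((0, 0)) or up((1, 0)) or up((2, 0))):
        return True
    return False


# ----------------------------------------------------------------------
# Origin stability (for the multistability census)
# ----------------------------------------------------------------------

def origin_stability(net: Network) -> str:
    """Stability of the origin, uniformly over all positive rate constants.

    One of ``not-equilibrium``, ``linearly-stable``,
    ``stable-via-center-manifold``, ``saddle``, ``unstable``, ``undecided``.
    A zero eigenvalue is resolved only when the center direction is an
    invariant axis and the restricted scalar flow has a sign-definite leading
    coefficient; everything else is reported ``undecided``.
    """
    if net.has_reactant(type(net.reactions[0].reactant)((0,) * net.n_species)):
        return "not-equilibrium"
    m = net.n_reactions
    kappa = sp.symbols(f"kappa1:{m + 1}", positive=True)
    col = {0: [sp.Integer(0), sp.Integer(0)], 1: [sp.Integer(0), sp.Integer(0)]}
    for j, r in enumerate(net.reactions):
        rc = r.reactant.coefficients
        if rc == (1, 0):
            col[0][0] += kappa[j] * r.reaction_vector[0]
            col[0][1] += kappa[j] * r.reaction_vector[1]
        elif rc == (0, 1):
            col[1][0] += kappa[j] * r.reaction_vector[0]
            col[1][1] += kappa[j] * r.reaction_vector[1]
    det = sp.expand(col[0][0] * col[1][1] - col[0][1] * col[1][0])
    trace = sp.expand(col[0][0] + col[1][1])
    sdet, strc = _uniform_sign(det, kappa), _uniform_sign(trace, kappa)
    if sdet == -1:
        return "saddle"
    if sdet == 1:
        if strc == -1:
            return "linearly-stable"
        if strc == 1:
            return "unstable"
        return "undecided"
    if sdet is None:
        return "undecided"
    # det == 0: a zero eigenvalue; the other eigenvalue is the trace
    if strc == 1:
        return "unstable"
    if strc != -1:
        return "undecided"
    # kernel of J along a coordinate axis?
    if all(c == 0 for c in col[0]):
        axis = 0
    elif all(c == 0 for c in col[1]):
        axis = 1
    else:
        return "undecided"
    # invariance of the axis and the restricted flow's leading coefficient
    quad = sp.Integer(0)
    for j, r in enumerate(net.reactions):
        rc = r.reactant.coefficients
        if rc[1 - axis] == 0 and rc[axis] >= 1:
            if r.reaction_vector[1 - axis] != 0:
                return "undecided"  # axis not invariant
            if rc[axis] == 2:
                quad += kappa[j] * r.reaction_vector[axis]
    squad = _uniform_sign(sp.expand(quad), kappa)
    if squad == -1:
        return "stable-via-center-manifold"
    if squad == 1:
        return "unstable"
    return "undecided"


def _uniform_sign(expr, kappa):
    """Sign of a polynomial in kappa over the open positive orthant.

    +1 / -1 / 0 when uniform, None when the sign depends on kappa (decided by
    inspecting monomial coefficients; sufficient for these linear/quadratic
    expressions since the monomials are linearly independent on the orthant).
    """
    expr = sp.expand(expr)
    if expr == 0:
        return 0
    poly = sp.Poly(expr, *kappa)
    coeffs = poly.coeffs()
    if all(c > 0 for c in coeffs):
        return 1
    if all(c < 0 for c in coeffs):
        return -1
    return None
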