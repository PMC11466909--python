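"""Exact positive-equilibrium algebra via the kernel cone of Gamma.

For a dynamically nontrivial full-rank planar network, positive equilibria are
parameterised by a cross-section ``h(alpha)`` of the cone
``ker Gamma ∩ R^m_+`` together with a scale ``lambda`` and the state ``x``:
``kappa o x^A = lambda h(alpha)``.  The Jacobian at such an equilibrium is
``J = lambda Gamma D_h(alpha) A D_1/x``, so every eigenvalue-feasibility
question reduces to sign conditions on the 2x2 *reduced core*
``M(alpha) = Gamma diag(h(alpha)) A``, whose entries are affine and whose
determinant is quadratic in ``alpha``.  All decisions here are exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import sympy as sp

from ._algebra import (AlgebraicRoot, dedupe_roots, poly_eval, poly_is_zero,
                       rational_between, roots_in_open_01, sample_points_01)
from .core import Network, primitive


# ----------------------------------------------------------------------
# Kernel cone
# ----------------------------------------------------------------------

def _nullspace(matrix) -> list[tuple[Fraction, ...]]:
    """Basis of the right kernel of an integer matrix (exact)."""
    rows = [list(map(Fraction, row)) for row in matrix]
    m = len(matrix[0]) if matrix else 0
    pivots = []
    r = 0
    for c in range(m):
        pr = next((i for i in range(r, len(rows)) if rows[i][c] != 0), None)
        if pr is None:
            continue
        rows[r], rows[pr] = rows[pr], rows[r]
        pv = rows[r][c]
        rows[r] = [v / pv for v in rows[r]]
        for i in range(len(rows)):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[r])]
        pivots.append(c)
        r += 1
        if r == len(rows):
            break
    free = [c for c in range(m) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * m
        v[fc] = Fraction(1)
        for i, pc in enumerate(pivots):
            v[pc] = -rows[i][fc]
        basis.append(tuple(v))
    return basis


def _rank(matrix) -> int:
    rows = [list(map(Fraction, row)) for row in matrix]
    if not rows:
        return 0
    m = len(rows[0])
    rank = 0
    for c in range(m):
        pr = next((i for i in range(rank, len(rows)) if rows[i][c] != 0), None)
        if pr is None:
            continue
        rows[rank], rows[pr] = rows[pr], rows[rank]
        pv = rows[rank][c]
        for i in range(rank + 1, len(rows)):
            if rows[i][c] != 0:
                f = rows[i][c] / pv
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[rank])]
        rank += 1
    return rank


def positive_kernel_rays(gamma) -> list[tuple[int, ...]]:
    """Primitive extreme rays of ``ker Gamma ∩ R^m_>=0`` (exact)."""
    basis = _nullspace(gamma)
    dim = len(basis)
    if dim == 0:
        return []
    m = len(basis[0])
    rays = set()
    for subset in itertools.combinations(range(m), dim - 1):
        # solve sum_i t_i basis_i with coordinates in `subset` equal to zero
        if dim == 1:
            ker = [(Fraction(1),)]
        else:
            sub = [[basis[i][j] for i in range(dim)] for j in subset]
            ker = _nullspace(sub)
        if len(ker) != 1:
            continue
        t = ker[0]
        v = [sum(t[i] * basis[i][j] for i in range(dim)) for j in range(m)]
        if all(x == 0 for x in v):
            continue
        for sgn in (1, -1):
            w = [sgn * x for x in v]
            if all(x >= 0 for x in w):
                num = [x.numerator * _lcm_den(w) // x.denominator for x in w]
                rays.add(primitive(num))
                break
    return sorted(rays)


def _lcm_den(vals) -> int:
    from math import lcm
    return lcm(*[v.denominator for v in vals]) if vals else 1


@dataclass(frozen=True)
class KernelCone:
    """``ker Gamma ∩ R^m_+`` as primitive extreme rays plus a cross-section.

    For a two-dimensional kernel the cross-section is the open segment
    ``h(alpha) = (1-alpha) r0 + alpha r1``, ``alpha in (0,1)``.
    """

    rays: tuple[tuple[int, ...], ...]

    @property
    def dimension(self) -> int:
        return len(self.rays)

    def h_affine(self) -> list[tuple[int, int]]:
        """Entries of h(alpha) as (constant, slope) integer pairs."""
        if len(self.rays) == 1:
            return [(r, 0) for r in self.rays[0]]
        if len(self.rays) == 2:
            r0, r1 = self.rays
            return [(a, b - a) for a, b in zip(r0, r1)]
        raise NotImplementedError("affine cross-section needs at most two rays")

    def h_at(self, alpha: Fraction) -> list[Fraction]:
        return [poly_eval(c, Fraction(alpha)) for c in self.h_affine()]

    def point(self, weights) -> list[Fraction]:
        """Convex combination of the rays with the given positive weights."""
        s = sum(weights)
        return [sum(Fraction(w, 1) / s * r[j] for w, r in zip(weights, self.rays))
                for j in range(len(self.rays[0]))]


def kernel_cone(net: Network) -> KernelCone:
    rays = positive_kernel_rays(net.gamma)
    if not rays:
        raise ValueError("empty positive kernel: network is dynamically trivial")
    return KernelCone(tuple(rays))


# ----------------------------------------------------------------------
# Reduced Jacobian core M(alpha) = Gamma diag(h(alpha)) A
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ReducedCore:
    """Entries of M(alpha) as integer affine pairs; det as integer quadratic."""

    entries: tuple  # 2x2 of (const, slope)
    det: tuple      # (c0, c1, c2)
    cone: KernelCone

    @property
    def m11(self):
        return self.entries[0][0]

    @property
    def m12(self):
        return self.entries[0][1]

    @property
    def m21(self):
        return self.entries[1][0]

    @property
    def m22(self):
        return self.entries[1][1]

    def entry_at(self, i, j, alpha):
        return poly_eval(self.entries[i][j], alpha)

    def matrix_at(self, alpha):
        return [[poly_eval(self.entries[i][j], alpha) for j in range(2)]
                for i in range(2)]


@lru_cache(maxsize=None)
def reduced_core(net: Network) -> ReducedCore:
    if net.n_species != 2:
        raise ValueError("reduced core is implemented for planar networks")
    cone = kernel_cone(net)
    h = cone.h_affine()
    gamma, A = net.gamma, net.A
    m = net.n_reactions

    def affine_mul_sum(i, l):
        c0 = sum(gamma[i][j] * h[j][0] * A[j][l] for j in range(m))
        c1 = sum(gamma[i][j] * h[j][1] * A[j][l] for j in range(m))
        return (c0, c1)

    entries = tuple(tuple(affine_mul_sum(i, l) for l in range(2)) for i in range(2))
    (a0, a1), (b0, b1) = entries[0]
    (c0, c1), (d0, d1) = entries[1]
    det = (a0 * d0 - b0 * c0,
           a0 * d1 + a1 * d0 - b0 * c1 - b1 * c0,
           a1 * d1 - b1 * c1)
    return ReducedCore(entries, det, cone)


# ----------------------------------------------------------------------
# Feasibility decisions
# ----------------------------------------------------------------------

def rank_condition(net: Network) -> bool:
    """rank [A | 1] = n + 1, necessary for positive nondegenerate equilibria."""
    aug = [list(row) + [1] for row in net.A]
    return _rank(aug) == net.n_species + 1


def admits_nondegenerate_equilibrium(net: Network) -> bool:
    """Exact decision for a full-rank planar network (rank Gamma = n = 2)."""
    if net.rank != net.n_species:
        raise ValueError("requires a full-rank network")
    if not rank_condition(net):
        return False
    core = reduced_core(net)
    if core.cone.dimension == 1:
        return core.det[0] != 0
    return not poly_is_zero(core.det)


def det_roots(net: Network) -> list[AlgebraicRoot]:
    """Roots of det M(alpha) in the open cross-section domain (exact)."""
    core = reduced_core(net)
    if core.cone.dimension == 1:
        return []
    if poly_is_zero(core.det):
        raise ValueError("det M vanishes identically (degenerate network)")
    return roots_in_open_01(core.det)


def zero_eigenvalue_feasible(net: Network):
    """(flag, det-roots): does some positive equilibrium have a zero eigenvalue?"""
    roots = det_roots(net)
    return bool(roots), roots


def diag_signs_at_roots(net: Network):
    """For each det-root: (root, sign M11, sign M22)."""
    core = reduced_core(net)
    return [(r, r.sign_of_poly(core.m11), r.sign_of_poly(core.m22))
            for r in det_roots(net)]


def second_eigenvalue_signs(net: Network) -> set:
    """Achievable signs of the nonzero eigenvalue at zero-eigenvalue equilibria.

    At a det-root the eigenvalues are 0 and trace J = M11/x1 + M22/x2 with x
    free positive, so each sign is achievable iff a diagonal entry has it.
    """
    out = set()
    for _, s11, s22 in diag_signs_at_roots(net):
        if s11 < 0 or s22 < 0:
            out.add("negative")
        if s11 > 0 or s22 > 0:
            out.add("positive")
    return out


def purely_imaginary_feasible(net: Network) -> bool:
    """Does some positive equilibrium have a pair of purely imaginary eigenvalues?

    The trace ``M11(alpha)/x1 + M22(alpha)/x2`` can be zeroed by a choice of
    positive ``x`` iff the diagonal entries have opposite signs, or both
    vanish; purely imaginary eigenvalues additionally need ``det M(alpha) > 0``.
    The open (opposite-sign) case is decided by exact sampling between all
    critical roots; the simultaneous-vanishing case is a rational condition on
    the affine diagonal entries.
    """
    core = reduced_core(net)
    if core.cone.dimension == 1:
        d = core.det[0]
        return d > 0 and (core.m11[0] * core.m22[0] < 0
                          or core.m11[0] == core.m22[0] == 0)
    # open case: M11 M22 < 0 somewhere with det M > 0
    crit = []
    for coeffs in (core.det, core.m11, core.m22):
        if not poly_is_zero(coeffs):
            crit.extend(roots_in_open_01(coeffs))
    for a in sample_points_01(dedupe_roots(crit)):
        if (poly_eval(core.det, a) > 0
                and poly_eval(core.m11, a) * poly_eval(core.m22, a) < 0):
            return True
    # boundary case: M11(alpha) = M22(alpha) = 0 (trace vanishes for every x)
    for a in _common_diag_zeros(core):
        if poly_eval(core.det, a) > 0:
            return True
    return False


def _common_diag_zeros(core: ReducedCore) -> list[Fraction]:
    """Rational alpha in (0,1) where both (affine) diagonal entries vanish.

    If both entries vanish identically, representative sample points with
    det M != 0 resolution are returned instead.
    """
    z11, z22 = poly_is_zero(core.m11), poly_is_zero(core.m22)
    if z11 and z22:
        if poly_is_zero(core.det):
            return []
        roots = roots_in_open_01(core.det)
        return sample_points_01(roots)
    if z11 or z22:
        coeffs = core.m22 if z11 else core.m11
        return [r.value for r in roots_in_open_01(coeffs) if r.is_rational]
    r1 = roots_in_open_01(core.m11)
    r2 = roots_in_open_01(core.m22)
    return [a.value for a in r1 for b in r2 if a.value == b.value]


def double_zero_feasible(net: Network):
    """(flag, root): positive equilibrium with a nilpotent index-two Jacobian.

    Requires det M(alpha) = 0 with oppositely signed diagonal entries, so that
    the trace can also be zeroed by the choice of x while J != 0.
    """
    for root, s11, s22 in diag_signs_at_roots(net):
        if s11 * s22 < 0:
            return True, root
    return False, None


def hopf_alpha_intervals(net: Network):
    """Open alpha-subintervals of (0,1) where det M > 0 and M11 M22 < 0.

    Returned as (lo, hi) pairs of exact algebraic endpoints (AlgebraicRoot or
    Fraction 0/1); used by the focal-value stage.
    """
    core = reduced_core(net)
    if core.cone.dimension == 1:
        return []  # no cross-section parameter: the Hopf set is not a curve
    if core.cone.dimension != 2:
        raise NotImplementedError
    crit = []
    for coeffs in (core.det, core.m11, core.m22):
        if not poly_is_zero(coeffs):
            crit.extend(roots_in_open_01(coeffs))
    crit = dedupe_roots(crit)
    marks: list = [Fraction(0)] + sorted(crit, key=float) + [Fraction(1)]
    intervals = []
    for lo, hi in zip(marks, marks[1:]):
        a = rational_between(lo, hi)
        if (poly_eval(core.det, a) > 0
                and poly_eval(core.m11, a) * poly_eval(core.m22, a) < 0):
            intervals.append((lo, hi))
    return intervals


# ----------------------------------------------------------------------
# Witness construction and equilibrium solving
# ----------------------------------------------------------------------

def construct_rate_constants(net: Network, x, alpha=None, lam=1, h=None):
    """Rate constants kappa = lam * h(alpha) / x^A making x a positive equilibrium."""
    if h is None:
        h = kernel_cone(net).h_at(Fraction(alpha))
    kappa = []
    for j, row in enumerate(net.A):
        mono = Fraction(1)
        for xi, a in zip(x, row):
            mono *= Fraction(xi) ** a
        kappa.append(Fraction(lam) * Fraction(h[j]) / mono)
    if any(k <= 0 for k in kappa):
        raise ValueError("witness outside the open cone / positive orthant")
    return kappa


def solve_equilibria(net: Network, kappa):
    """All positive equilibria for exact rational kappa (n = 2).

    Returns ``("continuum", None)`` if the positive-equilibrium set has a
    one-dimensional component, else ``("points", [(x, nondegenerate), ...])``
    with exact sympy coordinates.
    """
    field, x, _ = net.mass_action_field(kappa=[sp.Rational(k) for k in kappa])
    polys = [sp.Poly(f, *x, domain="QQ") for f in field]
    if all(p.is_zero for p in polys):
        return "continuum", None
    gb = sp.groebner([p for p in polys if not p.is_zero], *x, order="lex")
    if 1 in gb.exprs:
        return "points", []
    if not gb.is_zero_dimensional:
        return "continuum", None
    try:
        sols = _triangular_solve(gb, x)
    except ArithmeticError:
        gb2 = sp.groebner([p for p in polys if not p.is_zero],
                          x[1], x[0], order="lex")
        sols = [(a, b) for b, a in _triangular_solve(gb2, (x[1], x[0]))]
    J = sp.Matrix([[sp.diff(field[i], x[j]) for j in range(2)] for i in range(2)])
    detJ = J.det()
    out = []
    for vals in sols:
        if any(_algebraic_sign(v) is None for v in vals):
            continue  # non-real solution
        if any(_algebraic_sign(v) <= 0 for v in vals):
            continue
        d = detJ.subs(dict(zip(x, vals)))
        nondeg = _algebraic_sign(d) != 0
        out.append((tuple(vals), nondeg))
    return "points", out


def _triangular_solve(gb, x):
    """Solutions of a zero-dimensional lex Groebner basis in two variables.

    Roots are kept as exact algebraic numbers (Rational / CRootOf and rational
    functions thereof), so that signs remain decidable; radical formulas are
    never produced.
    """
    x1, x2 = x
    exprs = list(gb.exprs)
    univ = [e for e in exprs if not e.has(x1)]
    if not univ:
        raise ArithmeticError("unexpected Groebner basis shape")
    g = sp.Poly(sp.gcd_list(univ) if len(univ) > 1 else univ[0], x2)
    lin = [sp.Poly(e, x1).all_coeffs() for e in exprs
           if sp.Poly(e, x1).degree() == 1]
    sols = []
    for r in set(sp.real_roots(g)):
        assigned = None
        for c1, c0 in lin:
            c1r = sp.sympify(c1).subs(x2, r)
            if _algebraic_sign(c1r) in (None, 0):
                continue
            assigned = sp.cancel(-sp.sympify(c0).subs(x2, r) / c1r)
            break
        if assigned is None:
            # the ideal is not in shape position at this root (e.g. two
            # equilibria sharing a coordinate); out of scope for the censuses
            raise ArithmeticError("Groebner basis not in shape position")
        sols.append((assigned, r))
    return sols


def _algebraic_sign(v):
    """Exact sign of an algebraic sympy number; None if not real."""
    if v.is_real is False:
        return None
    if v.is_real is None:
        # decide reality exactly through the minimal polynomial of im(v)
        im = sp.im(v)
        t = sp.Symbol("_t")
        if sp.minimal_polynomial(im, t) != t:
            return None
        v = sp.re(v)
    if v.is_positive:
        return 1
    if v.is_negative:
        return -1
    if v.is_zero:
        return 0
    t = sp.Symbol("_t")
    if sp.minimal_polynomial(v, t) == t:
        return 0
    # nonzero real algebraic number: adaptive evalf gives its sign
    f = v.evalf(50)
    if f > 0:
        return 1
    if f < 0:
        return -1
    return 1 if v.evalf(200) > 0 else -1


def jacobian_at(net: Network, kappa, point):
    """Exact Jacobian matrix of the mass-action field at a point."""
    field, x, _ = net.mass_action_field(kappa=[sp.Rational(k) if not isinstance(k, sp.Expr) else k for k in kappa])
    J = sp.Matrix([[sp.diff(field[i], x[j]) for j in range(2)] for i in range(2)])
    return J.subs(dict(zip(x, point)))
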