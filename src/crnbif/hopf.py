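"""Andronov-Hopf points, exact focal values, and Hopf-type classification.

At a Hopf point the Jacobian ``J = M(alpha) D_{1/x}`` (lambda = 1) is
trace-free with positive determinant.  Two geometries occur in the planar
quadratic censuses:

* *curve* components: ``M11 M22 < 0`` on an open alpha-interval and the trace
  is zeroed by ``x2 = -M22(alpha)/M11(alpha)`` (x1 = 1) -- the Hopf set is a
  curve parameterised by alpha;
* *line* components: one diagonal entry of M vanishes identically and the
  other has a root alpha0 with ``det M(alpha0) > 0`` -- the trace vanishes for
  every positive x, and the Hopf set is the ray ``alpha = alpha0``,
  ``x = (1, t)``, parameterised by t.

On each component the focal values eta1, eta2, eta3 (see
:mod:`crnbif._focal_formulas`) are univariate rational functions of the
parameter, and their signs over the whole component are decided by exact real
root isolation.  The classification follows the sign of eta1, falling back to
eta2 / eta3 exactly where eta1 vanishes; for planar quadratic fields
``eta1 = eta2 = eta3 = 0`` certifies a center (Kapteyn-Bautin), hence a
vertical Andronov-Hopf bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import sympy as sp

from . import _focal_formulas as ff
from ._algebra import AlgebraicRoot, poly_eval, poly_is_zero, roots_in_open_01
from ._taylor import equilibrium_field, rotation_form_coefficients
from .core import Network
from .equilibria import (_common_diag_zeros, hopf_alpha_intervals, kernel_cone,
                         purely_imaginary_feasible, reduced_core)


# ----------------------------------------------------------------------
# Re-derivation of the focal-value formulas (independent in-package oracle)
# ----------------------------------------------------------------------

def derive_focal_values(upto: int = 3):
    """Derive eta1..eta_upto for the generic planar quadratic field.

    Re-runs the Lyapunov-function construction from scratch; the generated
    module :mod:`crnbif._focal_formulas` stores the results of this function
    and is checked against it in the test-suite.
    """
    u, v, D = sp.symbols("u v Delta")
    cs = sp.symbols("p20 p11 p02 q20 q11 q02")
    p20, p11, p02, q20, q11, q02 = cs
    P = p20 * u**2 + p11 * u * v + p02 * v**2
    Q = q20 * u**2 + q11 * u * v + q02 * v**2
    base = D * u**2 + v**2

    def lie(W):
        return sp.expand(sp.diff(W, u) * v - sp.diff(W, v) * D * u)

    def solve_degree(d, rhs, with_eta):
        coeffs = sp.symbols(f"c0:{d + 1}")
        W = sum(c * u ** (d - k) * v**k for k, c in enumerate(coeffs))
        eta = sp.Symbol("eta")
        target = eta * sp.expand(base ** (d // 2)) if with_eta else 0
        eqn = sp.expand(lie(W) + rhs - target)
        eqs = [eqn.coeff(u, d - k).coeff(v, k) for k in range(d + 1)]
        sol = sp.solve(eqs, list(coeffs) + ([eta] if with_eta else []), dict=True)[0]
        Wv = W.subs(sol)
        free = [c for c in coeffs if c in Wv.free_symbols]
        Wv = Wv.subs({c: 0 for c in free})
        ev = sol.get(eta)
        if ev is not None:
            ev = sp.cancel(ev.subs({c: 0 for c in free}))
        return Wv, ev

    V = base / 2
    etas = []
    W = V
    for k in range(1, upto + 1):
        rhs = sp.expand(sp.diff(W, u) * P + sp.diff(W, v) * Q)
        Vodd, _ = solve_degree(2 * k + 1, rhs, False)
        rhs2 = sp.expand(sp.diff(Vodd, u) * P + sp.diff(Vodd, v) * Q)
        Veven, eta = solve_degree(2 * k + 2, rhs2, True)
        etas.append(eta)
        W = Veven
    return etas


# ----------------------------------------------------------------------
# Hopf components
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class HopfComponent:
    """One connected component of the Hopf set, with a rational chart."""

    kind: str                 # "curve" (parameter alpha) or "line" (parameter x2)
    lo: object                # Fraction / AlgebraicRoot; line: Fraction(0)
    hi: object                # line components: None (unbounded)
    alpha0: Fraction | None = None   # line components only


def hopf_components(net: Network) -> list[HopfComponent]:
    core = reduced_core(net)
    if core.cone.dimension == 1:
        d, m11, m22 = core.det[0], core.m11[0], core.m22[0]
        if d > 0 and m11 == m22 == 0:
            return [HopfComponent("line", Fraction(0), None, Fraction(0))]
        if d > 0 and m11 * m22 < 0:
            raise NotImplementedError(
                "isolated Hopf point on a one-dimensional kernel cone")
        return []
    comps = [HopfComponent("curve", lo, hi)
             for lo, hi in hopf_alpha_intervals(net)]
    for a0 in _common_diag_zeros(core):
        if poly_eval(core.det, a0) > 0:
            comps.append(HopfComponent("line", Fraction(0), None, Fraction(a0)))
    return comps


def hopf_point(net: Network, component: HopfComponent, s: Fraction):
    """Exact Hopf witness (alpha, x, kappa, omega^2) at chart parameter ``s``."""
    core = reduced_core(net)
    cone = kernel_cone(net)
    if component.kind == "curve":
        alpha = Fraction(s)
        m11 = poly_eval(core.m11, alpha)
        m22 = poly_eval(core.m22, alpha)
        x = (Fraction(1), Fraction(-m22, m11))
    else:
        alpha = component.alpha0
        x = (Fraction(1), Fraction(s))
    h = cone.h_at(alpha)
    comps, kappa = equilibrium_field(net, [Fraction(v) for v in h],
                                     (Fraction(x[0]), Fraction(x[1])))
    j11, j12 = comps[0][1], comps[0][2]
    j21, j22 = comps[1][1], comps[1][2]
    if j11 + j22 != 0:
        raise ValueError("not a Hopf point: nonzero trace")
    omega2 = j11 * j22 - j12 * j21
    if omega2 <= 0:
        raise ValueError("not a Hopf point: det J <= 0")
    return alpha, x, kappa, omega2


# ----------------------------------------------------------------------
# Focal values
# ----------------------------------------------------------------------

def _component_rotation_coefficients(net: Network, component: HopfComponent, s):
    """(Delta, p20..q02) along the component, in terms of the chart symbol s."""
    core = reduced_core(net)
    cone = kernel_cone(net)
    if component.kind == "curve":
        h = [sp.Integer(c0) + sp.Integer(c1) * s for c0, c1 in cone.h_affine()]
        m11 = sp.Integer(core.m11[0]) + sp.Integer(core.m11[1]) * s
        m22 = sp.Integer(core.m22[0]) + sp.Integer(core.m22[1]) * s
        xstar = (sp.Integer(1), sp.cancel(-m22 / m11))
    else:
        h = [sp.Rational(v) for v in cone.h_at(component.alpha0)]
        xstar = (sp.Integer(1), s)
    comps, _ = equilibrium_field(net, h, xstar)
    return rotation_form_coefficients(comps)


def focal_values(net: Network, component: HopfComponent, upto: int = 1):
    """Focal values eta1..eta_upto as (numerator, denominator) sympy Polys.

    Univariate in the component chart ``s``; eta_{k+1} is meaningful where
    eta_1..eta_k vanish.
    """
    s = sp.Symbol("s")
    coeffs = _component_rotation_coefficients(net, component, s)
    funcs = [ff.eta1, ff.eta2, ff.eta3][:upto]
    out = []
    for f in funcs:
        num, den = sp.fraction(sp.cancel(sp.together(f(*coeffs))))
        out.append((sp.Poly(num, s), sp.Poly(den, s)))
    return out


def focal_value_at_point(net: Network, component: HopfComponent, s: Fraction,
                         upto: int = 3) -> list[Fraction]:
    """eta1..eta_upto at one Hopf point, exactly, via the closed formulas."""
    core = reduced_core(net)
    cone = kernel_cone(net)
    if component.kind == "curve":
        alpha = Fraction(s)
        x2 = Fraction(-poly_eval(core.m22, alpha), poly_eval(core.m11, alpha))
    else:
        alpha = component.alpha0
        x2 = Fraction(s)
    h = [Fraction(v) for v in cone.h_at(alpha)]
    comps, _ = equilibrium_field(net, h, (Fraction(1), x2))
    coeffs = rotation_form_coefficients(comps)
    return [f(*coeffs) for f in [ff.eta1, ff.eta2, ff.eta3][:upto]]


def focal_value_at_kernel_point(net: Network, h_vals, xstar) -> Fraction:
    """eta1 at an explicit Hopf witness given by a positive kernel vector.

    Works for any kernel-cone dimension (used e.g. for five-reaction networks
    whose cone has three extreme rays); requires trace J = 0, det J > 0.
    """
    comps, _ = equilibrium_field(net, [Fraction(v) for v in h_vals],
                                 (Fraction(xstar[0]), Fraction(xstar[1])))
    j11, j22 = comps[0][1], comps[1][2]
    if j11 + j22 != 0:
        raise ValueError("trace J != 0 at the supplied point")
    coeffs = rotation_form_coefficients(comps)
    if coeffs[0] <= 0:
        raise ValueError("det J <= 0 at the supplied point")
    return ff.eta1(*coeffs)


# ----------------------------------------------------------------------
# Exact sign analysis over a component
# ----------------------------------------------------------------------

def _enclosure(x, eps: Fraction):
    """Certified rational enclosure [lo, hi] of an exact real."""
    if isinstance(x, AlgebraicRoot):
        prec = 30
        while True:
            lo, hi = x.bounds(prec)
            if hi - lo <= eps:
                return lo, hi
            prec *= 2
    if isinstance(x, (int, Fraction)):
        return Fraction(x), Fraction(x)
    if isinstance(x, sp.Rational):
        v = Fraction(int(x.p), int(x.q))
        return v, v
    if isinstance(x, sp.polys.rootoftools.ComplexRootOf):
        iv = x.eval_rational(dx=sp.Rational(eps.numerator, eps.denominator) / 2)
        c = Fraction(int(iv.p), int(iv.q))
        return c - eps / 2, c + eps / 2
    if isinstance(x, sp.Expr) and x.is_algebraic:
        conv = _sympy_algebraic_to_root(x)
        if conv is not None:
            return _enclosure(conv, eps)
        # degree > 2: high-precision evalf enclosure (sympy's adaptive evalf)
        digits = max(60, -eps.as_integer_ratio()[1].bit_length() // 3)
        v = Fraction(str(x.evalf(digits)))
        pad = Fraction(1, 10 ** (digits - 10))
        return v - pad, v + pad
    raise TypeError(f"no enclosure for {type(x)}")


def _sympy_algebraic_to_root(x) -> AlgebraicRoot | Fraction | None:
    """Exact conversion of a sympy algebraic number of degree <= 2."""
    if x.is_rational:
        q = sp.Rational(x)
        return Fraction(int(q.p), int(q.q))
    s = sp.Symbol("_t")
    mp = sp.Poly(sp.minimal_polynomial(x, s), s)
    if mp.degree() != 2:
        return None
    a, b, c = (int(v) for v in mp.all_coeffs())
    disc = b * b - 4 * a * c
    side = (x + sp.Rational(b, 2 * a)).is_positive
    if side is None:
        return None
    return AlgebraicRoot(a, b, disc, 1 if side else -1)


def _to_sympy(x):
    if isinstance(x, AlgebraicRoot):
        if x.is_rational:
            return sp.Rational(x.value.numerator, x.value.denominator)
        return (sp.Integer(-x.b) + x.surd_sign * sp.sqrt(x.disc)) / (2 * x.a)
    if isinstance(x, Fraction):
        return sp.Rational(x.numerator, x.denominator)
    return sp.sympify(x)


def _exactly_equal(a, b) -> bool:
    d = sp.simplify(_to_sympy(a) - _to_sympy(b))
    if d.is_zero is not None:
        return bool(d.is_zero)
    return sp.minimal_polynomial(d, sp.Symbol("_t")) == sp.Symbol("_t")


def _strictly_between(x, lo, hi) -> bool:
    """x in the open interval (lo, hi); hi None means +infinity."""
    eps = Fraction(1, 2**20)
    for _ in range(8):
        xl, xu = _enclosure(x, eps)
        ll, lu = _enclosure(lo, eps)
        if hi is None:
            if xl > lu:
                return True
            if xu < ll or _exactly_equal(x, lo):
                return False
        else:
            hl, hu = _enclosure(hi, eps)
            if xl > lu and xu < hl:
                return True
            if xu < ll or xl > hu:
                return False
            if _exactly_equal(x, lo) or _exactly_equal(x, hi):
                return False
        eps /= 2**10
    raise RuntimeError("could not certify interval membership")


def _rational_strictly_between(a, b) -> Fraction:
    """A rational in the open interval (a, b); b None means +infinity."""
    eps = Fraction(1, 2**10)
    for _ in range(12):
        al, au = _enclosure(a, eps)
        if b is None:
            return au + 1
        bl, bu = _enclosure(b, eps)
        if au < bl:
            return (au + bl) / 2
        eps /= 2**6
    raise RuntimeError("could not separate interval endpoints")


@dataclass
class ComponentSignAnalysis:
    component: HopfComponent
    identically_zero: bool
    signs: set = field(default_factory=set)      # signs of eta1 on open pieces
    roots: list = field(default_factory=list)    # interior zeros of eta1


def analyse_eta1(net: Network, component: HopfComponent) -> ComponentSignAnalysis:
    (num, den), = focal_values(net, component, upto=1)
    if num.is_zero:
        return ComponentSignAnalysis(component, True)
    allroots = []
    for r in sp.real_roots(num):  # sorted; repeated with multiplicity
        if not allroots or r != allroots[-1]:
            allroots.append(r)
    interior = [r for r in allroots
                if _strictly_between(r, component.lo, component.hi)]
    marks = [component.lo] + interior + [component.hi]
    ana = ComponentSignAnalysis(component, False, roots=interior)
    for a, b in zip(marks, marks[1:]):
        t = _rational_strictly_between(a, b)
        tq = sp.Rational(t.numerator, t.denominator)
        nv, dv = num.eval(tq), den.eval(tq)
        if dv == 0:
            raise ArithmeticError("focal-value denominator vanished on the domain")
        v = nv / dv
        ana.signs.add(1 if v > 0 else (-1 if v < 0 else 0))
    if 0 in ana.signs:
        raise ArithmeticError("sample point hit a root")
    return ana


def _vanishes_at(num: sp.Poly, root) -> bool:
    """Does the polynomial vanish at an exact algebraic number?

    For an irrational root this is the divisibility of ``num`` by the root's
    minimal polynomial (which is irreducible), an exact test.
    """
    s = sp.Symbol("s")
    if num.is_zero:
        return True
    if isinstance(root, sp.Rational):
        return num.eval(root) == 0
    mp = sp.Poly(sp.minimal_polynomial(root, s), s)
    return sp.div(num, mp, s)[1].is_zero


# ----------------------------------------------------------------------
# Classification
# ----------------------------------------------------------------------

@dataclass
class HopfClassification:
    kind: str                    # supercritical / subcritical / vertical / mixed / bautin
    transversal: bool
    components: list
    eta1_signs: set
    eta1_roots: list
    l2_sign: int | None = None   # Bautin only


def classify_hopf(net: Network) -> HopfClassification:
    """Classify the Andronov-Hopf bifurcations a network admits.

    * ``supercritical`` / ``subcritical``: eta1 < 0 (resp. > 0) on the whole
      Hopf set;
    * ``vertical``: eta1 = eta2 = eta3 = 0 identically (center);
    * ``mixed``: eta1 changes sign, and eta2 = eta3 = 0 wherever eta1 = 0
      (so supercritical, vertical and subcritical bifurcations all occur);
    * ``bautin``: eta1 vanishes somewhere with eta2 != 0 there.
    """
    if not purely_imaginary_feasible(net):
        raise ValueError("network admits no purely imaginary eigenvalues")
    comps = hopf_components(net)
    analyses = [analyse_eta1(net, c) for c in comps]
    transversal = _transversality(net, comps)
    signs = set().union(*(a.signs for a in analyses))
    roots = [(a.component, r) for a in analyses for r in a.roots]
    all_zero = all(a.identically_zero for a in analyses)

    if all_zero:
        for c in comps:
            vals = focal_values(net, c, upto=3)
            if not (vals[1][0].is_zero and vals[2][0].is_zero):
                raise ArithmeticError(
                    "eta1 vanishes identically but eta2/eta3 do not: undecided")
        return HopfClassification("vertical", transversal, comps, {0}, [])

    if any(a.identically_zero for a in analyses):
        raise ArithmeticError("mixed identically-zero and nonzero components")

    if roots:
        l2_signs = []
        for c, r in roots:
            vals = focal_values(net, c, upto=3)
            n2, d2 = vals[1]
            if _vanishes_at(n2, r):
                if not _vanishes_at(vals[2][0], r):
                    raise ArithmeticError("eta2 = 0 but eta3 != 0 at a Hopf point")
                l2_signs.append(0)
            else:
                val = (n2.as_expr() / d2.as_expr()).subs(sp.Symbol("s"), r)
                l2_signs.append(1 if val.evalf(40) > 0 else -1)
        if any(s != 0 for s in l2_signs):
            nz = [s for s in l2_signs if s != 0]
            return HopfClassification("bautin", transversal, comps, signs,
                                      [r for _, r in roots], l2_sign=nz[0])
        return HopfClassification("mixed", transversal, comps, signs,
                                  [r for _, r in roots])

    if signs == {-1}:
        return HopfClassification("supercritical", transversal, comps, signs, [])
    if signs == {1}:
        return HopfClassification("subcritical", transversal, comps, signs, [])
    raise ArithmeticError("eta1 attains both signs without an interior zero")


def _transversality(net: Network, comps) -> bool:
    """Eigenvalues cross the imaginary axis with nonzero speed.

    On curve components the trace moves at rate -M11/x1^2 != 0 under x1.  On
    line components the trace is M22(alpha)/x2 (say), which crosses zero
    transversally in alpha iff M22 has a simple root at alpha0.
    """
    core = reduced_core(net)
    for c in comps:
        if c.kind == "line":
            nz = core.m22 if poly_is_zero(core.m11) else core.m11
            if poly_eval(nz, c.alpha0) != 0:  # pragma: no cover - safety
                raise AssertionError
            if nz[1] == 0:
                return False
    return True
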