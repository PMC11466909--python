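"""Exact scalar arithmetic helpers used by the feasibility decisions.

Everything in the census pipeline reduces to sign questions about integer
polynomials of degree at most two in the kernel-cone parameter ``alpha``.
Those questions are decided here with plain integer / :class:`~fractions.Fraction`
arithmetic plus a small real quadratic-field extension Q(sqrt(D)), so no
floating point enters any classification decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence


def _sign(x) -> int:
    if x > 0:
        return 1
    if x < 0:
        return -1
    return 0


def sign_p_plus_q_sqrtD(p, q, D) -> int:
    """Exact sign of ``p + q*sqrt(D)`` for rational p, q and integer D >= 0."""
    if D < 0:
        raise ValueError("negative radicand")
    if q == 0 or D == 0:
        return _sign(p)
    if p == 0:
        return _sign(q)
    sp, sq = _sign(p), _sign(q)
    if sp == sq:
        return sp
    # opposite signs: compare p^2 with q^2 D
    lhs = p * p
    rhs = q * q * D
    if lhs == rhs:
        return 0
    # |p| dominates -> sign of p, else sign of q
    return sp if lhs > rhs else sq


class QuadExt:
    """Element ``a + b*sqrt(D)`` of the real quadratic field Q(sqrt(D)).

    ``D`` is a fixed positive integer (need not be squarefree).  All operations
    are exact; :meth:`sign` never uses floating point.
    """

    __slots__ = ("a", "b", "D")

    def __init__(self, a, b, D):
        self.a = Fraction(a)
        self.b = Fraction(b)
        self.D = D

    # -- constructors -------------------------------------------------
    @classmethod
    def rational(cls, a, D):
        return cls(a, 0, D)

    def _coerce(self, other):
        if isinstance(other, QuadExt):
            if other.D != self.D:
                if other.b == 0:
                    return QuadExt(other.a, 0, self.D)
                if self.b == 0:
                    raise ValueError("mixed radicands")
                raise ValueError("mixed radicands")
            return other
        return QuadExt(other, 0, self.D)

    # -- ring operations ----------------------------------------------
    def __add__(self, other):
        o = self._coerce(other)
        return QuadExt(self.a + o.a, self.b + o.b, self.D)

    __radd__ = __add__

    def __neg__(self):
        return QuadExt(-self.a, -self.b, self.D)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) - self

    def __mul__(self, other):
        o = self._coerce(other)
        return QuadExt(
            self.a * o.a + self.b * o.b * self.D,
            self.a * o.b + self.b * o.a,
            self.D,
        )

    __rmul__ = __mul__

    def inverse(self):
        n = self.a * self.a - self.b * self.b * self.D
        if n == 0:
            raise ZeroDivisionError("zero element of Q(sqrt(D))")
        return QuadExt(self.a / n, -self.b / n, self.D)

    def __truediv__(self, other):
        return self * self._coerce(other).inverse()

    def __rtruediv__(self, other):
        return self._coerce(other) * self.inverse()

    def __pow__(self, k: int):
        if k < 0:
            return self.inverse() ** (-k)
        out = QuadExt(1, 0, self.D)
        base = self
        while k:
            if k & 1:
                out = out * base
            base = base * base
            k >>= 1
        return out

    # -- order / predicates -------------------------------------------
    def sign(self) -> int:
        return sign_p_plus_q_sqrtD(self.a, self.b, self.D)

    def is_zero(self) -> bool:
        return self.a == 0 and self.b == 0

    def __eq__(self, other):
        o = self._coerce(other)
        return self.a == o.a and self.b == o.b

    def __hash__(self):
        return hash((self.a, self.b, self.D))

    def __lt__(self, other):
        return (self - other).sign() < 0

    def __gt__(self, other):
        return (self - other).sign() > 0

    def __float__(self):
        return float(self.a) + float(self.b) * math.sqrt(self.D)

    def __repr__(self):
        return f"({self.a} + {self.b}*sqrt({self.D}))"


def sqrt_bounds(D: int, prec: int = 30) -> tuple[Fraction, Fraction]:
    """Rational lo < sqrt(D) <= hi with hi - lo <= 2^-prec (D > 0, non-square ok)."""
    scale = 1 << prec
    lo = math.isqrt(D * scale * scale)
    return Fraction(lo, scale), Fraction(lo + 1, scale)


# ----------------------------------------------------------------------
# Polynomials as coefficient tuples, constant term first.
# ----------------------------------------------------------------------

def poly_eval(coeffs: Sequence, x):
    out = 0
    for c in reversed(coeffs):
        out = out * x + c
    return out


def poly_deriv(coeffs: Sequence):
    return tuple(i * c for i, c in enumerate(coeffs))[1:] or (0,)


def poly_is_zero(coeffs: Sequence) -> bool:
    return all(c == 0 for c in coeffs)


@dataclass(frozen=True)
class AlgebraicRoot:
    """A real root of an integer polynomial of degree <= 2.

    Rational roots carry ``value`` (a Fraction, ``surd_sign`` 0); irrational
    roots of ``a x^2 + b x + c`` are ``(-b + s*sqrt(disc)) / (2a)`` with
    ``s = surd_sign`` in {-1, +1}.
    """

    a: int
    b: int
    disc: int
    surd_sign: int
    value: Fraction | None = None
    multiplicity: int = 1

    @property
    def is_rational(self) -> bool:
        return self.surd_sign == 0

    def as_quadext(self) -> QuadExt:
        if self.is_rational:
            return QuadExt(self.value, 0, 1)
        return QuadExt(Fraction(-self.b, 2 * self.a),
                       Fraction(self.surd_sign, 2 * self.a), self.disc)

    def sign_of_poly(self, coeffs: Sequence) -> int:
        """Exact sign of a rational-coefficient polynomial at this root."""
        if self.is_rational:
            return _sign(poly_eval(coeffs, self.value))
        v = poly_eval([QuadExt(c, 0, self.disc) for c in coeffs],
                      self.as_quadext())
        return v.sign()

    def bounds(self, prec: int = 30) -> tuple[Fraction, Fraction]:
        if self.is_rational:
            return self.value, self.value
        lo, hi = sqrt_bounds(self.disc, prec)
        twoa = Fraction(2 * self.a)
        x1 = (-self.b + self.surd_sign * lo) / twoa
        x2 = (-self.b + self.surd_sign * hi) / twoa
        return (x1, x2) if x1 <= x2 else (x2, x1)

    def __float__(self):
        if self.is_rational:
            return float(self.value)
        return float(self.as_quadext())


def quadratic_roots(coeffs: Sequence[int]) -> list[AlgebraicRoot]:
    """All real roots of an integer polynomial of degree <= 2 (ascending)."""
    c0 = int(coeffs[0])
    c1 = int(coeffs[1]) if len(coeffs) > 1 else 0
    c2 = int(coeffs[2]) if len(coeffs) > 2 else 0
    if c2 == 0:
        if c1 == 0:
            return []  # constant (the identically-zero case is handled upstream)
        return [AlgebraicRoot(0, 0, 0, 0, Fraction(-c0, c1))]
    disc = c1 * c1 - 4 * c2 * c0
    if disc < 0:
        return []
    if disc == 0:
        return [AlgebraicRoot(0, 0, 0, 0, Fraction(-c1, 2 * c2), multiplicity=2)]
    s = math.isqrt(disc)
    if s * s == disc:
        r1 = Fraction(-c1 - s, 2 * c2)
        r2 = Fraction(-c1 + s, 2 * c2)
        roots = sorted([r1, r2])
        return [AlgebraicRoot(0, 0, 0, 0, r) for r in roots]
    lo = AlgebraicRoot(c2, c1, disc, -1 if c2 > 0 else 1)
    hi = AlgebraicRoot(c2, c1, disc, 1 if c2 > 0 else -1)
    return [lo, hi]


def roots_in_open_01(coeffs: Sequence[int]) -> list[AlgebraicRoot]:
    """Real roots of an integer deg <= 2 polynomial inside the open unit interval."""
    out = []
    for r in quadratic_roots(coeffs):
        gt0 = r.sign_of_poly((0, 1)) > 0          # r > 0
        lt1 = r.sign_of_poly((-1, 1)) < 0         # r < 1
        if gt0 and lt1:
            out.append(r)
    return out


def roots_equal(r1: AlgebraicRoot, r2: AlgebraicRoot) -> bool:
    """Exact equality of two degree <= 2 algebraic numbers."""
    if r1.is_rational and r2.is_rational:
        return r1.value == r2.value
    if r1.is_rational != r2.is_rational:
        # a rational equals a quadratic surd only if the surd is rational (it is not)
        irr, rat = (r1, r2) if not r1.is_rational else (r2, r1)
        return irr.sign_of_poly((-rat.value, 1)) == 0
    # both irrational: r2 must satisfy r1's quadratic, and lie on the same side
    # of the rational midpoint -b/(2a)
    c = (r1.b * r1.b - r1.disc) // (4 * r1.a)  # c from disc = b^2 - 4ac
    if r2.sign_of_poly((c, r1.b, r1.a)) != 0:
        return False
    side = r2.sign_of_poly((Fraction(r1.b, 2 * r1.a), 1))
    return side == r1.surd_sign


def dedupe_roots(roots: Iterable[AlgebraicRoot]) -> list[AlgebraicRoot]:
    out: list[AlgebraicRoot] = []
    for r in roots:
        if not any(roots_equal(r, s) for s in out):
            out.append(r)
    return out


def _as_bounds(x, prec):
    if isinstance(x, AlgebraicRoot):
        return x.bounds(prec)
    return Fraction(x), Fraction(x)


def rational_between(a, b) -> Fraction:
    """A rational strictly between two distinct reals (Fraction or AlgebraicRoot)."""
    prec = 30
    while prec <= 4000:
        _, ahi = _as_bounds(a, prec)
        blo, _ = _as_bounds(b, prec)
        if ahi < blo:
            return (ahi + blo) / 2
        # handle rational endpoints equal to a bound
        alo, ahi = _as_bounds(a, prec)
        blo, bhi = _as_bounds(b, prec)
        if ahi == alo and blo < ahi < bhi:  # a rational inside b's interval
            prec *= 2
            continue
        prec *= 2
    raise RuntimeError("could not separate the two endpoints")


def sample_points_01(roots: Iterable[AlgebraicRoot]) -> list[Fraction]:
    """Rational points meeting every open subinterval of (0,1) cut by ``roots``.

    The returned points avoid the roots, so strict sign conditions evaluated at
    them decide feasibility of open semialgebraic conditions exactly.
    """
    intervals = []
    prec = 30
    roots = list(roots)
    while True:
        intervals = [r.bounds(prec) for r in roots]
        intervals.sort()
        ok = all(intervals[i][1] < intervals[i + 1][0]
                 for i in range(len(intervals) - 1))
        if ok:
            break
        prec += 30
        if prec > 400:  # distinct deg-2 algebraic numbers separate well before this
            raise RuntimeError("failed to separate roots")
    zero, one = Fraction(0), Fraction(1)
    clipped = [(max(lo, zero), min(hi, one)) for lo, hi in intervals
               if hi > zero and lo < one]
    cuts = sorted({zero, one} | {e for iv in clipped for e in iv})
    samples = []
    for a, b in zip(cuts, cuts[1:]):
        if a >= b:
            continue
        m = (a + b) / 2
        # never sample inside a root's isolating interval
        if any(lo <= m <= hi for lo, hi in clipped):
            continue
        if 0 < m < 1:
            samples.append(m)
    return samples
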