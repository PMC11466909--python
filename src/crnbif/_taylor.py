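"""Quadratic Taylor data of a planar mass-action field at a positive point.

A quadratic polynomial in the displacement ``(xi1, xi2)`` is stored as the
6-tuple ``(c00, c10, c01, c20, c11, c02)``.  All routines are generic in the
coefficient arithmetic: they work for Fractions, quadratic-field elements
(:class:`crnbif._algebra.QuadExt`) and sympy expressions alike.  Since every
reactant complex here is at most bimolecular, the mass-action field *is* its
own quadratic Taylor polynomial, so the expansion is exact.
"""

from __future__ import annotations


def _monomial_taylor(a: int, b: int, x1, x2):
    """Taylor 6-tuple of x1^a x2^b about (x1, x2) with a + b <= 2."""
    if (a, b) == (0, 0):
        return (1, 0, 0, 0, 0, 0)
    if (a, b) == (1, 0):
        return (x1, 1, 0, 0, 0, 0)
    if (a, b) == (0, 1):
        return (x2, 0, 1, 0, 0, 0)
    if (a, b) == (2, 0):
        return (x1 * x1, 2 * x1, 0, 1, 0, 0)
    if (a, b) == (0, 2):
        return (x2 * x2, 0, 2 * x2, 0, 0, 1)
    if (a, b) == (1, 1):
        return (x1 * x2, x2, x1, 0, 1, 0)
    raise ValueError("reactant molecularity above two")


def taylor_field(net, kappa, xstar):
    """Exact Taylor 6-tuples of the two field components about ``xstar``."""
    x1, x2 = xstar
    comps = []
    for i in range(2):
        acc = [0, 0, 0, 0, 0, 0]
        for j, row in enumerate(net.A):
            g = net.gamma[i][j]
            if g == 0:
                continue
            mono = _monomial_taylor(row[0], row[1], x1, x2)
            c = kappa[j] * g
            for k in range(6):
                acc[k] = acc[k] + c * mono[k]
        comps.append(tuple(acc))
    return comps


def equilibrium_field(net, h_vals, xstar, lam=1):
    """Taylor field at the equilibrium defined by kappa = lam h / x^A.

    Returns ``(components, kappa)``; the constant terms of the components are
    zero by construction (Gamma h = 0).
    """
    x1, x2 = xstar
    kappa = []
    for j, row in enumerate(net.A):
        mono = 1
        if row[0]:
            mono = mono * x1 ** row[0]
        if row[1]:
            mono = mono * x2 ** row[1]
        kappa.append(lam * h_vals[j] / mono)
    return taylor_field(net, kappa, xstar), kappa


def jacobian(comps):
    """2x2 Jacobian (linear part) from the two Taylor 6-tuples."""
    return ((comps[0][1], comps[0][2]), (comps[1][1], comps[1][2]))


def subs_linear(comp, T):
    """Compose a Taylor 6-tuple with xi = T zeta (T a 2x2 nested tuple)."""
    c00, c10, c01, c20, c11, c02 = comp
    (t11, t12), (t21, t22) = T
    d10 = c10 * t11 + c01 * t21
    d01 = c10 * t12 + c01 * t22
    d20 = c20 * t11 * t11 + c11 * t11 * t21 + c02 * t21 * t21
    d11 = (c20 * 2 * t11 * t12 + c11 * (t11 * t22 + t12 * t21)
           + c02 * 2 * t21 * t22)
    d02 = c20 * t12 * t12 + c11 * t12 * t22 + c02 * t22 * t22
    return (c00, d10, d01, d20, d11, d02)


def left_mul(Tinv, comps):
    """Apply a 2x2 matrix to the vector of two Taylor 6-tuples."""
    (s11, s12), (s21, s22) = Tinv
    out = []
    for r1, r2 in ((s11, s12), (s21, s22)):
        out.append(tuple(r1 * a + r2 * b for a, b in zip(comps[0], comps[1])))
    return tuple(out)


def rotation_form_coefficients(comps):
    """Transform a trace-free Taylor field into ``((0,1),(-Delta,0))`` form.

    The basis is ``u = (J12, -J11), w = (0, 1)`` (valid whenever J12 != 0,
    which holds at any point with det J > 0 or a nilpotent J with J12 != 0).
    Returns ``(Delta, p20, p11, p02, q20, q11, q02)``.
    """
    (j11, j12), (j21, j22) = jacobian(comps)
    delta = j11 * j22 - j12 * j21
    T = ((j12, 0), (-j11, 1))
    Tinv = ((1 / j12, 0), (j11 / j12, 1))
    G = left_mul(Tinv, tuple(subs_linear(c, T) for c in comps))
    return (delta, G[0][3], G[0][4], G[0][5], G[1][3], G[1][4], G[1][5])


def nilpotent_basis_coefficients(comps):
    """Quadratic coefficients in a nilpotent (Bogdanov-Takens) basis.

    For a field whose Jacobian J is nilpotent of index two, pick
    ``q0`` spanning ker J = im J and ``q1`` with ``J q1 = q0``; in coordinates
    ``x = x* + xi1 q0 + xi2 q1`` the field reads
    ``xi1' = xi2 + a20/2 xi1^2 + ..., xi2' = b20/2 xi1^2 + b11 xi1 xi2 + ...``.
    Returns ``(a20, b11, b20)``.
    """
    (j11, j12), (j21, j22) = jacobian(comps)
    if not _is_zero(j11 + j22):
        raise ValueError("Jacobian is not trace-free")
    if _is_zero(j11) and _is_zero(j12) and _is_zero(j21) and _is_zero(j22):
        raise ValueError("Jacobian vanishes: not nilpotent of index two")
    if not (_is_zero(j12) and _is_zero(j11)):
        q0 = (j12, -j11)
    else:
        q0 = (j22, -j21)
    # find q1 with J q1 = q0 using a nonzero column of J
    col1 = (j11, j21)
    col2 = (j12, j22)
    if not (_is_zero(col1[0]) and _is_zero(col1[1])):
        c = _ratio(col1, q0)
        q1 = (1 / c, 0)
    else:
        c = _ratio(col2, q0)
        q1 = (0, 1 / c)
    S = ((q0[0], q1[0]), (q0[1], q1[1]))
    det = S[0][0] * S[1][1] - S[0][1] * S[1][0]
    Sinv = ((S[1][1] / det, -S[0][1] / det), (-S[1][0] / det, S[0][0] / det))
    G = left_mul(Sinv, tuple(subs_linear(c, S) for c in comps))
    a20 = 2 * G[0][3]
    b20 = 2 * G[1][3]
    b11 = G[1][4]
    return a20, b11, b20


def _is_zero(v) -> bool:
    if hasattr(v, "is_zero"):
        z = v.is_zero
        if callable(z):  # QuadExt
            return z()
        return bool(z)
    return v == 0


def _ratio(col, q0):
    """c with col = c q0 (both nonzero, parallel)."""
    if not _is_zero(q0[0]):
        return col[0] / q0[0]
    return col[1] / q0[1]
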