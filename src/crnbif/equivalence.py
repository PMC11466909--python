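"""Diagonal equivalence and the natural-coordinates reduction.

Two mass-action networks with the same reactant matrix (up to permutations)
are *diagonally equivalent* when ``Gamma_hat = D1 Gamma D2`` for positive
diagonal D1 (species) and D2 (reactions); diagonally equivalent networks are
smoothly equivalent, so every bifurcation classification must agree across a
diagonal class.  The decision below is exact: for each admissible species
transposition and reactant-preserving reaction bijection, the multiplicative
system ``d1_i d2_j = ratio_ij`` is solved by propagation over the bipartite
support graph of Gamma.

The natural-coordinates reduction rewrites an (n, m, n) network as an
(m-2)-parameter family: with ``Gbar = [A|1|U]^{-1}`` partitioned into
``(G; v; W)``, the substitution ``y = kappa^G o x`` turns the field into
``ydot = kappa^{G+1v} o Gamma((kappa^W)^U o y^A)`` with n outer parameters
(diagonal scalings) and m-n-1 inner parameters (which alone move the
equilibrium set).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import sympy as sp

from .core import Network


# ----------------------------------------------------------------------
# Diagonal equivalence
# ----------------------------------------------------------------------

@dataclass
class DiagonalWitness:
    d1: tuple          # positive rationals, one per species
    d2: tuple          # positive rationals, one per reaction
    permutation: tuple # reaction j of net1 maps to permutation[j] of net2
    species_swapped: bool


def _solve_multiplicative(g1, g2, n, m):
    """Solve d1_i d2_j = g2[i][j] / g1[i][j] over positive rationals.

    Entries must have identical zero/sign patterns.  Returns (d1, d2) or None.
    """
    ratio = {}
    for i in range(n):
        for j in range(m):
            a, b = g1[i][j], g2[i][j]
            if (a == 0) != (b == 0):
                return None
            if a != 0:
                r = Fraction(b, a)
                if r <= 0:
                    return None
                ratio[(i, j)] = r
    d1 = [None] * n
    d2 = [None] * m
    # propagate over connected components of the support graph
    for start in range(n):
        if d1[start] is not None or not any((start, j) in ratio for j in range(m)):
            continue
        d1[start] = Fraction(1)
        stack = [("r", start)]
        while stack:
            kind, idx = stack.pop()
            if kind == "r":
                for j in range(m):
                    if (idx, j) in ratio:
                        val = ratio[(idx, j)] / d1[idx]
                        if d2[j] is None:
                            d2[j] = val
                            stack.append(("c", j))
                        elif d2[j] != val:
                            return None
            else:
                for i in range(n):
                    if (i, idx) in ratio:
                        val = ratio[(i, idx)] / d2[idx]
                        if d1[i] is None:
                            d1[i] = val
                            stack.append(("r", i))
                        elif d1[i] != val:
                            return None
    d1 = [v if v is not None else Fraction(1) for v in d1]
    d2 = [v if v is not None else Fraction(1) for v in d2]
    return tuple(d1), tuple(d2)


def _reactant_preserving_bijections(net1: Network, net2: Network):
    """All bijections reactions(net1) -> reactions(net2) matching reactants."""
    groups1: dict = {}
    for j, r in enumerate(net1.reactions):
        groups1.setdefault(r.reactant.coefficients, []).append(j)
    groups2: dict = {}
    for j, r in enumerate(net2.reactions):
        groups2.setdefault(r.reactant.coefficients, []).append(j)
    if set(groups1) != set(groups2):
        return
    if any(len(groups1[c]) != len(groups2[c]) for c in groups1):
        return
    keys = sorted(groups1)
    pools = [list(itertools.permutations(groups2[c])) for c in keys]
    for combo in itertools.product(*pools):
        perm = [None] * net1.n_reactions
        for c, targets in zip(keys, combo):
            for src, dst in zip(groups1[c], targets):
                perm[src] = dst
        yield tuple(perm)


def diagonally_equivalent(net1: Network, net2: Network):
    """Exact decision; returns (flag, DiagonalWitness or None)."""
    if net1.n_species != net2.n_species or net1.n_reactions != net2.n_reactions:
        return False, None
    n, m = net1.n_species, net1.n_reactions
    for swapped in (False, True):
        cand = net2.permute_species((1, 0)) if swapped else net2
        for perm in _reactant_preserving_bijections(net1, cand):
            g1 = net1.gamma
            g2p = [[cand.gamma[i][perm[j]] for j in range(m)] for i in range(n)]
            sol = _solve_multiplicative(g1, g2p, n, m)
            if sol is not None:
                return True, DiagonalWitness(sol[0], sol[1], perm, swapped)
    return False, None


def count_diagonal_classes(nets) -> int:
    """Number of diagonal-equivalence classes among the given networks."""
    return len(diagonal_class_partition(nets))


def diagonal_class_partition(nets) -> list[list[int]]:
    """Partition (as index lists) of the networks under diagonal equivalence."""
    nets = list(nets)
    buckets: dict = {}
    for idx, net in enumerate(nets):
        buckets.setdefault(_diag_invariant(net), []).append(idx)
    parent = list(range(len(nets)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for members in buckets.values():
        for a, b in itertools.combinations(members, 2):
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            if diagonally_equivalent(nets[a], nets[b])[0]:
                parent[rb] = ra
    classes: dict = {}
    for i in range(len(nets)):
        classes.setdefault(find(i), []).append(i)
    return sorted(classes.values())


def _sgn(x):
    return (x > 0) - (x < 0)


def _diag_invariant(net: Network):
    """Hashable invariant of the diagonal class (reactants + sign patterns)."""
    def oriented(swap):
        rows = []
        for r in net.reactions:
            rc = r.reactant.coefficients
            v = r.reaction_vector
            if swap:
                rc, v = rc[::-1], v[::-1]
            rows.append((rc, tuple(_sgn(c) for c in v)))
        return tuple(sorted(rows))
    return min(oriented(False), oriented(True))


# ----------------------------------------------------------------------
# Natural coordinates
# ----------------------------------------------------------------------

@dataclass
class NaturalCoordinates:
    U: tuple
    Gbar: tuple          # [A|1|U]^{-1} as nested tuples of sympy Rationals
    G: tuple             # top n rows
    v: tuple             # row n
    W: tuple             # bottom m-n-1 rows
    reduced_field: tuple # sympy expressions in y and the new parameters
    y: tuple             # state symbols
    outer: tuple         # n outer parameter symbols (kappa^{G+1v})
    inner: tuple         # m-n-1 inner parameter symbols (kappa^W)
    codimension_bound: int


def _augmented(net: Network, U):
    rows = []
    for j, arow in enumerate(net.A):
        rows.append(list(arow) + [1] + [U[j][k] for k in range(len(U[0]))])
    return sp.Matrix(rows)


def default_completion(net: Network) -> tuple:
    """Integer completion U of [A|1] with minimal |det|, lexicographic ties."""
    m, n = net.n_reactions, net.n_species
    k = m - n - 1
    if k != 1:
        raise NotImplementedError("completion search implemented for m = n + 2")
    best = None
    for cand in itertools.product(range(-2, 3), repeat=m):
        U = tuple((c,) for c in cand)
        d = abs(_augmented(net, U).det())
        if d == 0:
            continue
        key = (d, cand)
        if best is None or key < best[0]:
            best = (key, U)
    return best[1]


def natural_coordinates(net: Network, U=None) -> NaturalCoordinates:
    """The reduction of an (n, m, n) network to an (m-2)-parameter family."""
    n, m = net.n_species, net.n_reactions
    if net.rank != n:
        raise ValueError("requires a full-rank network")
    aug1 = sp.Matrix([list(r) + [1] for r in net.A])
    if aug1.rank() != n + 1:
        raise ValueError("rank [A|1] must equal n + 1")
    if U is None:
        U = default_completion(net)
    M = _augmented(net, U)
    if M.det() == 0:
        raise ValueError("U does not complete [A|1] to a nonsingular matrix")
    Gbar = M.inv()
    G = Gbar[:n, :]
    v = Gbar[n, :]
    W = Gbar[n + 1:, :]
    # identity (6):  I - A G = 1 v + U W
    A = sp.Matrix([list(r) for r in net.A])
    lhs = sp.eye(m) - A * G
    rhs = sp.ones(m, 1) * v + sp.Matrix([list(u) for u in U]) * W
    if sp.simplify(lhs - rhs) != sp.zeros(m, m):
        raise ArithmeticError("natural-coordinates identity failed")
    # reduced field  ydot = outer o Gamma((inner)^U o y^A)
    y = sp.symbols(f"Y1:{n + 1}", positive=True)
    outer = sp.symbols(f"a1:{n + 1}", positive=True)
    k = m - n - 1
    inner = sp.symbols(f"b1:{k + 1}", positive=True)
    rates = []
    for j, arow in enumerate(net.A):
        mono = sp.Integer(1)
        for t in range(k):
            mono *= inner[t] ** U[j][t]
        for i in range(n):
            mono *= y[i] ** arow[i]
        rates.append(mono)
    field = tuple(
        sp.expand(outer[i] * sum(net.gamma[i][j] * rates[j] for j in range(m)))
        for i in range(n))
    to_t = lambda mat: tuple(tuple(mat[i, j] for j in range(mat.cols))  # noqa: E731
                             for i in range(mat.rows))
    return NaturalCoordinates(tuple(U), to_t(Gbar), to_t(G), to_t(v), to_t(W),
                              field, y, outer, inner, m - 2)


def example10_two_parameter_form():
    """Reduce the worked example to its printed two-parameter form.

    Verifies symbolically that the reduced field of network
    ``2X>3X; X+Y>2Y; Y>0; 0>Y`` (with the printed completion U) equals, after
    grouping ``beta = a2/(a1 b1)``, ``gamma = b1`` and rescaling time by
    ``a1 b1^2``, the family ``Xdot = X^2 - XY,  Ydot = beta (gamma X Y - Y + 1)``.
    """
    from .tables import EXAMPLE10_U, table3_networks
    net = table3_networks()[0]
    nc = natural_coordinates(net, U=EXAMPLE10_U)
    X, Y = nc.y
    a1, a2 = nc.outer
    b1, = nc.inner
    beta, gamma = sp.symbols("beta gamma", positive=True)
    scaled = [sp.expand(sp.cancel(f / (a1 * b1**2))) for f in nc.reduced_field]
    target = (sp.expand(X**2 - X * Y),
              sp.expand((beta * (gamma * X * Y - Y + 1)).subs(
                  {beta: a2 / (a1 * b1), gamma: b1})))
    if (scaled[0] - target[0] != 0
            or sp.simplify(scaled[1] - target[1]) != 0):
        raise ArithmeticError("two-parameter reduction did not match")
    return (X**2 - X * Y, beta * (gamma * X * Y - Y + 1)), nc
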