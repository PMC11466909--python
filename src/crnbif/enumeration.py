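"""Combinatorial generation of candidate networks modulo dynamical equivalence.

Two mass-action networks on the same species define the same *family* of ODE
systems (are dynamically equivalent) exactly when, for every reactant complex,
the positive span of its reaction vectors agrees.  For planar networks those
positive spans are rays, pointed sectors, lines or the whole plane, and each
has a canonical description by its primitive extreme rays.  The census
routines below enumerate four-reaction networks, fingerprint them by these
per-reactant cones (minimised over the species transposition X <-> Y), and
return one deterministic representative per class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cmp_to_key

from .core import Network, Reaction, SpeciesComplex, primitive


# ----------------------------------------------------------------------
# Complex enumeration
# ----------------------------------------------------------------------

def enumerate_complexes(n_species: int, max_molecularity: int) -> list[SpeciesComplex]:
    """All complexes on ``n_species`` species with molecularity <= bound."""
    out = []
    def rec(prefix, remaining, budget):
        if remaining == 0:
            out.append(SpeciesComplex(tuple(prefix)))
            return
        for c in range(budget + 1):
            rec(prefix + [c], remaining - 1, budget - c)
    rec([], n_species, max_molecularity)
    out.sort()
    return out


def reaction_universe(product_cap: int) -> list[Reaction]:
    """All quadratic reactions on two species with product molecularity <= cap."""
    reactants = [c for c in enumerate_complexes(2, 2)]
    products = [c for c in enumerate_complexes(2, product_cap)]
    return [Reaction(r, p) for r in reactants for p in products if p != r]


# ----------------------------------------------------------------------
# Planar cone canonicalisation
# ----------------------------------------------------------------------

def _cross(a, b):
    return a[0] * b[1] - a[1] * b[0]


def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1]


def _angle_cmp(a, b):
    """Counter-clockwise order starting from the positive x-axis."""
    ha = 0 if (a[1] > 0 or (a[1] == 0 and a[0] > 0)) else 1
    hb = 0 if (b[1] > 0 or (b[1] == 0 and b[0] > 0)) else 1
    if ha != hb:
        return ha - hb
    c = _cross(a, b)
    return 0 if c == 0 else (-1 if c > 0 else 1)


def cone_descriptor(vectors) -> tuple:
    """Canonical form of the closed convex cone positively spanned by ``vectors``.

    Returns ``("ray", r)``, ``("sector", start, end)`` (counter-clockwise from
    start to end, angle < pi for pointed cones, = pi for half-planes),
    ``("line", r)`` or ``("plane",)``.  All rays are primitive integer vectors.
    """
    rays = sorted({primitive(v) for v in vectors})
    if len(rays) == 1:
        return ("ray", rays[0])
    if len(rays) == 2 and rays[0] == tuple(-x for x in rays[1]):
        return ("line", min(rays))
    rays.sort(key=cmp_to_key(_angle_cmp))
    k = len(rays)
    for i in range(k):
        a, b = rays[i], rays[(i + 1) % k]
        c = _cross(a, b)
        if c < 0 or (c == 0 and _dot(a, b) < 0):
            # the cyclic gap from a to b exceeds (or equals) pi:
            # the cone is the sector from b counter-clockwise to a
            return ("sector", b, a)
    return ("plane",)


def _swap2(v):
    return (v[1], v[0])


def equivalence_key(reactant_to_vectors: dict) -> tuple:
    """Dynamical-equivalence fingerprint of a planar network.

    ``reactant_to_vectors`` maps each reactant coefficient pair to the list of
    its reaction vectors.  The fingerprint is the sorted per-reactant cone
    table, minimised over the species transposition.
    """
    def oriented(swap: bool):
        items = []
        for c, vecs in reactant_to_vectors.items():
            if swap:
                c = _swap2(c)
                vecs = [_swap2(v) for v in vecs]
            items.append((c, cone_descriptor(vecs)))
        return tuple(sorted(items))
    return min(oriented(False), oriented(True))


def network_equivalence_key(net: Network) -> tuple:
    if net.n_species != 2:
        raise ValueError("equivalence keys are defined for planar networks")
    table: dict = {}
    for r in net.reactions:
        table.setdefault(r.reactant.coefficients, []).append(r.reaction_vector)
    return equivalence_key(table)


def representative_network(key: tuple) -> Network:
    """Deterministic class representative: minimal-molecularity products.

    For a primitive ray ``r`` at reactant ``c`` the representative reaction is
    ``c -> c + r`` (always a valid complex, and of minimal molecularity for
    that ray).
    """
    reactions = []
    for c, cone in key:
        reactant = SpeciesComplex(c)
        if cone[0] == "ray":
            gens = [cone[1]]
        elif cone[0] == "sector":
            gens = [cone[1], cone[2]]
        elif cone[0] == "line":
            gens = [cone[1], tuple(-x for x in cone[1])]
        else:
            raise NotImplementedError("no canonical representative for a full-plane cone")
        for g in gens:
            product = SpeciesComplex(tuple(a + b for a, b in zip(c, g)))
            reactions.append(Reaction(reactant, product))
    return Network(("X", "Y"), tuple(sorted(reactions)))


# ----------------------------------------------------------------------
# Structural predicates used as census filters
# ----------------------------------------------------------------------

def has_redundant_reaction(net: Network) -> bool:
    """True iff some reaction vector is in the positive span of the other
    reaction vectors sharing its reactant complex."""
    groups: dict = {}
    for r in net.reactions:
        groups.setdefault(r.reactant.coefficients, []).append(r.reaction_vector)
    for vecs in groups.values():
        if len(vecs) < 2:
            continue
        for i, v in enumerate(vecs):
            others = [w for j, w in enumerate(vecs) if j != i]
            if _in_positive_span(v, others):
                return True
    return False


def _in_positive_span(v, gens) -> bool:
    """Is the planar vector v a positive combination of ``gens``?"""
    v = tuple(v)
    for g in gens:  # single generator: positive multiple
        if _cross(v, g) == 0 and _dot(v, g) > 0:
            return True
    for g1, g2 in itertools.combinations(gens, 2):
        d = _cross(g1, g2)
        if d == 0:
            continue
        # solve a*g1 + b*g2 = v
        a = _cross(v, g2)
        b = _cross(g1, v)
        if (a > 0 and b > 0 and d > 0) or (a < 0 and b < 0 and d < 0):
            return True
    return False


def reactants_collinear(net: Network) -> bool:
    """True iff the distinct reactant points are affinely collinear (n = 2)."""
    pts = sorted({r.reactant.coefficients for r in net.reactions})
    if len(pts) <= 2:
        return True
    p0 = pts[0]
    d1 = tuple(a - b for a, b in zip(pts[1], p0))
    return all(_cross(d1, tuple(a - b for a, b in zip(p, p0))) == 0
               for p in pts[2:])


def is_dynamically_nontrivial(net: Network) -> bool:
    """True iff ker(Gamma) meets the open positive orthant."""
    from .equilibria import positive_kernel_rays
    rays = positive_kernel_rays(net.gamma)
    if not rays:
        return False
    m = net.n_reactions
    return all(any(r[j] > 0 for r in rays) for j in range(m))


# ----------------------------------------------------------------------
# Census
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class EnumerationSpec:
    """Configuration of a four-reaction census on two species."""

    n_reactions: int = 4
    max_product_molecularity: int = 3
    require_distinct_reactants: bool = False
    required_reactants: tuple = ()          # SpeciesComplex instances
    required_rays_any: tuple = ()           # ((reactant coeffs, ray), ...) alternatives
    forbid_redundant: bool = False
    forbid_collinear_reactants: bool = False
    require_rank: int | None = 2
    require_dynamically_nontrivial: bool = True
    require_nondegenerate_equilibrium: bool = False


def rays_for_reactant(c: tuple[int, int], product_cap: int) -> list[tuple[int, int]]:
    """Distinct primitive reaction-vector rays available from reactant ``c``."""
    rays = set()
    for p in enumerate_complexes(2, product_cap):
        if p.coefficients != c:
            rays.add(primitive(tuple(a - b for a, b in zip(p.coefficients, c))))
    return sorted(rays)


def census(spec: EnumerationSpec) -> list[Network]:
    """One representative per dynamical-equivalence class passing the filters.

    Deterministic: the output is sorted by the canonical fingerprint.
    """
    if spec.n_reactions != 4:
        raise NotImplementedError("the census is implemented for four reactions")
    reactant_pool = [c.coefficients for c in enumerate_complexes(2, 2)]
    ray_table = {c: rays_for_reactant(c, spec.max_product_molecularity)
                 for c in reactant_pool}

    keys: set[tuple] = set()
    # multiplicity patterns over distinct reactants summing to 4
    if spec.require_distinct_reactants:
        patterns = [(1, 1, 1, 1)]
    elif spec.forbid_collinear_reactants:
        # patterns with <= 2 distinct reactant points are always collinear
        patterns = [(1, 1, 1, 1), (2, 1, 1)]
    else:
        raise NotImplementedError(
            "census without either distinct or non-collinear reactants is out of scope")

    for pattern in patterns:
        k = len(pattern)
        for reactants in itertools.combinations(reactant_pool, k):
            for assignment in set(itertools.permutations(pattern)):
                table_choices = []
                for c, mult in zip(reactants, assignment):
                    table_choices.append(
                        list(itertools.combinations(ray_table[c], mult)))
                for choice in itertools.product(*table_choices):
                    table = {c: list(vecs)
                             for c, vecs in zip(reactants, choice)}
                    keys.add(equivalence_key(table))

    nets = []
    for key in sorted(keys):
        net = representative_network(key)
        if not _passes_filters(net, spec):
            continue
        nets.append(net)
    return nets


def _passes_filters(net: Network, spec: EnumerationSpec) -> bool:
    if spec.required_reactants and not all(net.has_reactant(c)
                                           for c in spec.required_reactants):
        return False
    if spec.required_rays_any:
        def has_ray(c, ray):
            return any(r.reactant.coefficients == c
                       and primitive(r.reaction_vector) == ray
                       for r in net.reactions)
        if not any(has_ray(c, ray) for c, ray in spec.required_rays_any):
            return False
    if spec.forbid_collinear_reactants and reactants_collinear(net):
        return False
    if spec.forbid_redundant and has_redundant_reaction(net):
        return False
    if spec.require_rank is not None and net.rank != spec.require_rank:
        return False
    if spec.require_dynamically_nontrivial and not is_dynamically_nontrivial(net):
        return False
    if spec.require_nondegenerate_equilibrium:
        from .equilibria import admits_nondegenerate_equilibrium
        if not admits_nondegenerate_equilibrium(net):
            return False
    return True


def raw_distinct_reactant_count(product_cap: int) -> int:
    """Brute-force count of raw four-reaction networks with four distinct
    reactants (before any deduplication or filtering): the generator oracle."""
    reactant_pool = [c for c in enumerate_complexes(2, 2)]
    products = enumerate_complexes(2, product_cap)
    count = 0
    for reactants in itertools.combinations(reactant_pool, 4):
        per = [sum(1 for p in products if p != c) for c in reactants]
        n = 1
        for v in per:
            n *= v
        count += n
    return count


# ready-made specs matching the tracks of the analysis ------------------

def spec_trimolecular_distinct() -> EnumerationSpec:
    return EnumerationSpec(max_product_molecularity=3,
                           require_distinct_reactants=True)


def spec_bimolecular_distinct() -> EnumerationSpec:
    return EnumerationSpec(max_product_molecularity=2,
                           require_distinct_reactants=True)


def spec_hopf_base() -> EnumerationSpec:
    return EnumerationSpec(
        max_product_molecularity=3,
        required_reactants=(SpeciesComplex((1, 1)),),
        required_rays_any=(((2, 0), (1, 0)), ((0, 2), (0, 1))),
        forbid_redundant=True,
        forbid_collinear_reactants=True,
        require_nondegenerate_equilibrium=True,
    )
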