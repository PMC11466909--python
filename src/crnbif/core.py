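"""Reaction networks with mass-action kinetics: exact matrices and parsing.

A network on ``n`` species with ``m`` reactions is stored through its reactant
and product stoichiometries.  The stoichiometric matrix is
``Gamma = Gamma_r - Gamma_ell`` (one column per reaction) and the mass-action
vector field is ``xdot = Gamma (kappa o x^A)`` with ``A = Gamma_ell^t``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import cached_property
from math import gcd

import sympy as sp


# ----------------------------------------------------------------------
# Complexes and reactions
# ----------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class SpeciesComplex:
    """Formal nonnegative-integer combination of species, e.g. 2X or X+Y."""

    coefficients: tuple[int, ...]

    def __post_init__(self):
        if any(c < 0 or int(c) != c for c in self.coefficients):
            raise ValueError(f"invalid complex coefficients {self.coefficients}")
        object.__setattr__(self, "coefficients",
                           tuple(int(c) for c in self.coefficients))

    @property
    def molecularity(self) -> int:
        return sum(self.coefficients)

    def is_bimolecular(self) -> bool:
        return self.molecularity <= 2

    def is_trimolecular(self) -> bool:
        return self.molecularity <= 3

    def format(self, species_names) -> str:
        parts = []
        for c, name in zip(self.coefficients, species_names):
            if c == 0:
                continue
            parts.append(name if c == 1 else f"{c}{name}")
        return "+".join(parts) if parts else "0"


@dataclass(frozen=True, order=True)
class Reaction:
    """Ordered pair of distinct complexes (reactant, product)."""

    reactant: SpeciesComplex
    product: SpeciesComplex

    def __post_init__(self):
        if self.reactant == self.product:
            raise ValueError("reactant and product complexes must differ")

    @property
    def reaction_vector(self) -> tuple[int, ...]:
        return tuple(p - r for r, p in
                     zip(self.reactant.coefficients, self.product.coefficients))

    def is_quadratic(self) -> bool:
        return self.reactant.molecularity <= 2

    def is_bimolecular(self) -> bool:
        return self.reactant.molecularity <= 2 and self.product.molecularity <= 2

    def is_trimolecular(self) -> bool:
        return self.reactant.molecularity <= 3 and self.product.molecularity <= 3

    def format(self, species_names) -> str:
        return (f"{self.reactant.format(species_names)} > "
                f"{self.product.format(species_names)}")


def primitive(vec) -> tuple[int, ...]:
    """Divide an integer vector by the gcd of its entries (direction kept)."""
    g = 0
    for v in vec:
        g = gcd(g, abs(int(v)))
    if g == 0:
        raise ValueError("zero vector has no primitive direction")
    return tuple(int(v) // g for v in vec)


# ----------------------------------------------------------------------
# Networks
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Network:
    """An ordered list of reactions on named species."""

    species_names: tuple[str, ...]
    reactions: tuple[Reaction, ...] = field(default=())

    def __post_init__(self):
        n = len(self.species_names)
        for r in self.reactions:
            if len(r.reactant.coefficients) != n:
                raise ValueError("reaction/species dimension mismatch")
        if len(set(self.reactions)) != len(self.reactions):
            raise ValueError("duplicate reactions")

    # -- matrices ------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @cached_property
    def gamma(self) -> tuple[tuple[int, ...], ...]:
        """Stoichiometric matrix, n x m (rows = species)."""
        return tuple(
            tuple(r.reaction_vector[i] for r in self.reactions)
            for i in range(self.n_species)
        )

    @cached_property
    def gamma_ell(self) -> tuple[tuple[int, ...], ...]:
        """Reactant matrix, n x m."""
        return tuple(
            tuple(r.reactant.coefficients[i] for r in self.reactions)
            for i in range(self.n_species)
        )

    @cached_property
    def A(self) -> tuple[tuple[int, ...], ...]:
        """Exponent matrix A = Gamma_ell^t, m x n."""
        return tuple(r.reactant.coefficients for r in self.reactions)

    @cached_property
    def rank(self) -> int:
        return sp.Matrix(self.gamma).rank()

    # -- predicates ------------------------------------------------------
    def is_quadratic(self) -> bool:
        return all(r.is_quadratic() for r in self.reactions)

    def is_bimolecular(self) -> bool:
        return all(r.is_bimolecular() for r in self.reactions)

    def is_trimolecular(self) -> bool:
        return all(r.is_trimolecular() for r in self.reactions)

    def trivial_species(self) -> list[int]:
        """Indices of species with an all-zero row of Gamma."""
        return [i for i, row in enumerate(self.gamma) if all(v == 0 for v in row)]

    def has_reactant(self, cplx: SpeciesComplex) -> bool:
        return any(r.reactant == cplx for r in self.reactions)

    def has_reaction(self, reaction: Reaction) -> bool:
        return reaction in self.reactions

    def reactant_complexes(self) -> list[SpeciesComplex]:
        """Distinct reactant complexes in order of first appearance."""
        seen = []
        for r in self.reactions:
            if r.reactant not in seen:
                seen.append(r.reactant)
        return seen

    # -- transformations -------------------------------------------------
    def permute_species(self, perm) -> "Network":
        """Relabel species: new coordinate i is old coordinate perm[i]."""
        def pc(c):
            return SpeciesComplex(tuple(c.coefficients[p] for p in perm))
        return Network(
            tuple(self.species_names[p] for p in perm),
            tuple(Reaction(pc(r.reactant), pc(r.product)) for r in self.reactions),
        )

    def sorted_reactions(self) -> "Network":
        return Network(self.species_names, tuple(sorted(self.reactions)))

    def drop_species(self, idx: int) -> "Network":
        """Delete species ``idx`` (removing reactions that become trivial)."""
        def dc(c):
            return SpeciesComplex(tuple(v for i, v in enumerate(c.coefficients)
                                        if i != idx))
        names = tuple(nm for i, nm in enumerate(self.species_names) if i != idx)
        keep = []
        for r in self.reactions:
            ra, pr = dc(r.reactant), dc(r.product)
            if ra != pr and Reaction(ra, pr) not in keep:
                keep.append(Reaction(ra, pr))
        return Network(names, tuple(keep))

    # -- symbolic field ----------------------------------------------------
    def mass_action_field(self, kappa=None, x=None):
        """Symbolic mass-action right-hand side ``Gamma (kappa o x^A)``.

        Returns ``(field, x_symbols, kappa_symbols)``; ``field`` is a list of
        sympy polynomial expressions, one per species.
        """
        n, m = self.n_species, self.n_reactions
        if x is None:
            x = sp.symbols(f"x1:{n + 1}", positive=True)
        if kappa is None:
            kappa = sp.symbols(f"kappa1:{m + 1}", positive=True)
        rates = []
        for j, r in enumerate(self.reactions):
            mono = kappa[j]
            for i, a in enumerate(r.reactant.coefficients):
                if a:
                    mono *= x[i] ** a
            rates.append(mono)
        field = [sp.expand(sum(self.gamma[i][j] * rates[j] for j in range(m)))
                 for i in range(n)]
        return field, tuple(x), tuple(kappa)

    # -- serialisation -----------------------------------------------------
    def serialise(self) -> str:
        return "; ".join(r.format(self.species_names) for r in self.reactions)

    def to_json(self) -> str:
        return json.dumps({
            "species": list(self.species_names),
            "reactions": [
                {"reactant": list(r.reactant.coefficients),
                 "product": list(r.product.coefficients)}
                for r in self.reactions
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "Network":
        d = json.loads(text)
        return cls(
            tuple(d["species"]),
            tuple(Reaction(SpeciesComplex(tuple(r["reactant"])),
                           SpeciesComplex(tuple(r["product"])))
                  for r in d["reactions"]),
        )

    def __repr__(self):
        return f"Network({self.serialise()!r})"


# ----------------------------------------------------------------------
# Parsing
# ----------------------------------------------------------------------

_TERM_RE = re.compile(r"^(\d*)([A-Za-z][A-Za-z0-9_]*)$")


def _parse_complex(text: str, species_order: list[str], frozen: bool):
    text = text.strip()
    counts: dict[str, int] = {}
    if text != "0":
        for term in text.split("+"):
            term = term.strip()
            m = _TERM_RE.match(term)
            if not m:
                raise ValueError(f"cannot parse complex term {term!r}")
            coeff = int(m.group(1)) if m.group(1) else 1
            name = m.group(2)
            if name not in species_order:
                if frozen:
                    raise ValueError(f"unknown species {name!r}")
                species_order.append(name)
            counts[name] = counts.get(name, 0) + coeff
    return counts


def parse_network(text: str, species: list[str] | None = None) -> Network:
    """Parse a ';'-separated list of reactions like ``"2X > 3X; X+Y > 2Y"``.

    Species order is first-appearance order unless an explicit ``species``
    list is given.  The empty complex is written ``0``.
    """
    frozen = species is not None
    order: list[str] = list(species) if species else []
    raw = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        sides = chunk.split(">")
        if len(sides) != 2:
            raise ValueError(f"expected exactly one '>' in {chunk!r}")
        raw.append((_parse_complex(sides[0], order, frozen),
                    _parse_complex(sides[1], order, frozen)))
    reactions = []
    for rc, pc in raw:
        reactant = SpeciesComplex(tuple(rc.get(nm, 0) for nm in order))
        product = SpeciesComplex(tuple(pc.get(nm, 0) for nm in order))
        reactions.append(Reaction(reactant, product))
    return Network(tuple(order), tuple(reactions))


def structural_predicates(net: Network) -> dict:
    """Boolean structure flags for a network."""
    return {
        "quadratic": net.is_quadratic(),
        "bimolecular": net.is_bimolecular(),
        "trimolecular": net.is_trimolecular(),
        "has_trivial_species": bool(net.trivial_species()),
    }
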