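"""Enumeration, dynamical-equivalence keys, and structural filters."""

from hypothesis import given
from hypothesis import strategies as st

from crnbif.core import Network, Reaction, SpeciesComplex, parse_network, primitive
from crnbif.enumeration import (cone_descriptor, enumerate_complexes,
                                has_redundant_reaction,
                                is_dynamically_nontrivial,
                                network_equivalence_key,
                                raw_distinct_reactant_count,
                                reactants_collinear, reaction_universe,
                                representative_network)


def test_enumerate_complexes_counts():
    assert len(enumerate_complexes(2, 2)) == 6
    assert len(enumerate_complexes(2, 3)) == 10
    assert [c.coefficients for c in enumerate_complexes(1, 3)] == \
        [(0,), (1,), (2,), (3,)]


def test_raw_universe_sizes():
    assert raw_distinct_reactant_count(3) == 15 * 9**4 == 98415
    assert raw_distinct_reactant_count(2) == 15 * 5**4
    assert len(reaction_universe(3)) == 6 * 9


def test_dynamically_nontrivial_examples():
    net = parse_network("2X > 3X; X+Y > 2Y; Y > 0; 0 > Y")
    assert is_dynamically_nontrivial(net)
    assert not is_dynamically_nontrivial(parse_network("0 > X"))
    # m = rank: kernel is trivial
    assert not is_dynamically_nontrivial(parse_network("0 > X; 0 > Y"))


def test_redundant_reaction_examples():
    assert has_redundant_reaction(parse_network("2X > 3X; 2X > 4X; Y > 0; 0 > Y"))
    net1 = parse_network("2X > 3X; X+Y > 2Y; Y > 0; 0 > Y")
    assert not has_redundant_reaction(net1)
    assert not has_redundant_reaction(parse_network("X+Y > 0; X+Y > 2X; Y > 2Y"))


def test_reactants_collinear_examples():
    assert reactants_collinear(parse_network("2X > 3X; X+Y > 2Y; 2Y > Y"))
    assert not reactants_collinear(
        parse_network("2X > 3X; X+Y > 2Y; Y > 0; 0 > Y"))
    assert reactants_collinear(parse_network("0 > X; X+Y > 2Y"))


def test_cone_descriptor_shapes():
    assert cone_descriptor([(2, 0)]) == ("ray", (1, 0))
    assert cone_descriptor([(1, 0), (3, 0)]) == ("ray", (1, 0))
    assert cone_descriptor([(1, 0), (-2, 0)]) == ("line", (-1, 0))
    kind, a, b = cone_descriptor([(1, 0), (0, 1)])
    assert (kind, a, b) == ("sector", (1, 0), (0, 1))
    assert cone_descriptor([(1, 0), (0, 1), (-1, -1)]) == ("plane",)
    # half-plane
    assert cone_descriptor([(1, 0), (0, 1), (-1, 0)]) == \
        ("sector", (1, 0), (-1, 0))


_reactions = st.sampled_from(reaction_universe(3))


@st.composite
def _networks4(draw):
    rs = draw(st.lists(_reactions, min_size=4, max_size=4, unique=True))
    return Network(("X", "Y"), tuple(rs))


@given(_networks4(), st.permutations(range(4)))
def test_key_invariant_under_permutation_and_swap(net, perm):
    key = network_equivalence_key(net)
    reordered = Network(net.species_names, tuple(net.reactions[p] for p in perm))
    assert network_equivalence_key(reordered) == key
    assert network_equivalence_key(net.permute_species((1, 0))) == key


@given(_networks4())
def test_key_invariant_under_ray_rescaling(net):
    """Replacing a product so the reaction vector doubles keeps the key."""
    key = network_equivalence_key(net)
    for i, r in enumerate(net.reactions):
        doubled = tuple(c + 2 * v for c, v in
                        zip(r.reactant.coefficients, primitive(r.reaction_vector)))
        if any(c < 0 for c in doubled) or sum(doubled) > 3:
            continue
        newr = Reaction(r.reactant, SpeciesComplex(doubled))
        if newr in net.reactions:
            continue
        rs = list(net.reactions)
        rs[i] = newr
        assert network_equivalence_key(Network(net.species_names, tuple(rs))) == key
        break


@given(_networks4())
def test_representative_reproduces_key(net):
    from hypothesis import assume
    key = network_equivalence_key(net)
    assume(all(cone[0] != "plane" for _, cone in key))
    rep = representative_network(key)
    assert network_equivalence_key(rep) == key


def test_census_is_deterministic(trimolecular_census):
    from crnbif.enumeration import census, spec_trimolecular_distinct
    again = census(spec_trimolecular_distinct())
    assert again == trimolecular_census
    # four distinct reactants, quadratic, trimolecular, rank two in every class
    for net in trimolecular_census[:100]:
        assert len({r.reactant for r in net.reactions}) == 4
        assert net.is_quadratic() and net.is_trimolecular()
        assert net.rank == 2
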