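"""Printed reference networks used as inputs and regression fixtures.

TABLE3 lists, in order, the 33 dynamically nonequivalent quadratic
trimolecular (2,4,2) networks admitting a Bogdanov-Takens bifurcation, as the
reference catalog prints them; rows 1-8 are supercritical (sigma = -1), rows
9-10 vertical, rows 11-33 subcritical (sigma = +1).
"""

from .core import parse_network

TABLE3 = [
    "2X > 3X; X+Y > 2Y; Y > 0; 0 > Y",
    "2X > 3X; X+Y > 3Y; Y > 0; 0 > Y",
    "2X > 3X; X+Y > 2Y; Y > 0; X > Y",
    "2X > 3X; X+Y > 3Y; Y > 0; X > Y",
    "2X > 3X; X+Y > 2Y; Y > 0; X > 2Y",
    "2X > 3X; X+Y > 3Y; Y > 0; X > 2Y",
    "2X > 3X; X+Y > 2Y; Y > 0; X > 3Y",
    "2X > 3X; X+Y > 3Y; Y > 0; X > 3Y",
    "2X > 3X; X+Y > 2X; 0 > Y; X > 0",
    "2X > 3X; X+Y > 3X; 0 > Y; X > 0",
    "2X > 3X; X+Y > 2X; 0 > X+2Y; X > 0",
    "2X > 3X; X+Y > 3X; 0 > X+2Y; X > 0",
    "2X > 3X; X+Y > 2X; 0 > X+Y; X > 0",
    "2X > 3X; X+Y > 3X; 0 > X+Y; X > 0",
    "2X > 3X; X+Y > 2X; 0 > 2X+Y; X > 0",
    "2X > 3X; X+Y > 3X; 0 > 2X+Y; X > 0",
    "2X > 3X; X+Y > X; Y > X+2Y; X > Y",
    "2X > 3X; X+Y > X; Y > X+2Y; X > 2Y",
    "2X > 3X; X+Y > X; Y > X+2Y; X > 3Y",
    "2X > 3X; X+Y > 0; Y > 2X; X > 2Y",
    "2X > 3X; X+Y > 0; Y > 3X; X > 2Y",
    "2X > 3X; X+Y > 0; Y > X; X > 3Y",
    "2X > 3X; X+Y > 0; Y > 2X; X > 3Y",
    "2X > 3X; X+Y > 0; Y > 3X; X > 3Y",
    "2X > 3X; X+Y > 0; Y > X; X > X+Y",
    "2X > 3X; X+Y > 0; Y > 2X; X > X+Y",
    "2X > 3X; X+Y > 0; Y > 3X; X > X+Y",
    "2X > 3X; X+Y > Y; 2Y > 0; X > 2X+Y",
    "2X > 3X; X+Y > Y; 2Y > X; X > 2X+Y",
    "2X > 3X; X+Y > Y; 2Y > 2X; X > 2X+Y",
    "2X > 3X; X+Y > Y; 2Y > 3X; X > 2X+Y",
    "2X > 3X; X+Y > Y; 2Y > 2X+Y; X > 2X+Y",
    "2X > 3X; X+Y > 2Y; 2Y > 0; 0 > X+2Y",
]

#: rows (1-based) by BT type
TABLE3_SUPERCRITICAL = list(range(1, 9))
TABLE3_VERTICAL = [9, 10]
TABLE3_SUBCRITICAL = list(range(11, 34))

#: diagonally equivalent pairs among the Table 3 rows (1-based)
TABLE3_DIAGONAL_PAIRS = [(1, 2), (3, 6), (9, 10), (11, 14), (13, 16)]


def table3_networks():
    return [parse_network(s, species=["X", "Y"]) for s in TABLE3]


def generalised_lva(b: int = 2):
    """The generalised Lotka-Volterra-autocatalator 2X>3X, X+Y>bY, Y>0."""
    return parse_network(f"2X > 3X; X+Y > {b}Y; Y > 0", species=["X", "Y"])


def frank_kamenetsky_salnikov():
    """Five-reaction combustion network with an always-supercritical Hopf."""
    return parse_network("2X > 3X; X+Y > 2Y; Y > 0; 0 > Y; X > 2X",
                         species=["X", "Y"])


def three_equilibria_network():
    """A quadratic (2,4,2) network admitting three positive nondegenerate
    equilibria (high product molecularity)."""
    return parse_network("X+Y > X; X > 0; 0 > 5X+Y; 2Y > X+4Y",
                         species=["X", "Y"])


def bautin_network():
    """The unique quadratic trimolecular (2,4,2) network with a Bautin point."""
    return parse_network(TABLE3[11], species=["X", "Y"])


#: The completion matrix U and the resulting Gbar = [A|1|U]^{-1} printed for
#: the worked natural-coordinates example (Table 3 network 1).
EXAMPLE10_U = ((2,), (2,), (1,), (1,))
EXAMPLE10_GBAR = (
    (1, -1, 1, -1),
    (0, 0, 1, -1),
    (1, -2, 2, 0),
    (-1, 2, -2, 1),
)
EXAMPLE10_GBAR_INV = (
    (2, 0, 1, 2),
    (1, 1, 1, 2),
    (0, 1, 1, 1),
    (0, 0, 1, 1),
)
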