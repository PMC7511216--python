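"""Shared toy networks and reference conditions."""

import numpy as np
import pandas as pd
import pytest

from methyloflux.model import (
    FluxVector,
    LabelInput,
    apply_flux_parameters,
    free_flux_basis,
    parse_network,
)
from methyloflux.synthetic import reference_condition

CHAIN = """
MET A 2 source
MET B 2 internal
RXN r1 irr 1 A[ab] -> 1 B[ab]
RXN r2 irr 1 B[ab] -> out
"""

# one split with carbon-order scrambling on the lower branch, one merge
DIAMOND = """
MET S 2 source
MET X 2 internal
MET P 2 internal
RXN up irr 1 S[ab] -> 1 X[ab]
RXN top irr 1 X[ab] -> 1 P[ab]
RXN bot irr 1 X[ab] -> 1 P[ba]
RXN sink irr 1 P[ab] -> out
"""

# cleavage + condensation with a reversible merge
SPLIT_JOIN = """
MET S 4 source
MET X 4 internal
MET P 2 internal
MET Q 2 internal
MET Y 4 internal
RXN up irr 1 S[abcd] -> 1 X[abcd]
RXN split irr 1 X[abcd] -> 1 P[ab] + 1 Q[dc]
RXN join rev 1 P[ab] + 1 Q[cd] -> 1 Y[abcd]
RXN outy irr 1 Y[abcd] -> out
RXN outp irr 1 P[ab] -> out
RXN outq irr 1 Q[ab] -> out
"""

REVERSIBLE_CHAIN = """
MET A 3 source
MET B 3 internal
MET C 3 internal
RXN r1 irr 1 A[abc] -> 1 B[abc]
RXN r2 rev 1 B[abc] -> 1 C[cba]
RXN r3 irr 1 C[abc] -> out
"""

# symmetric intermediate (fumarate-like scrambling)
SYMMETRIC_TOY = """
MET S 4 source
MET F 4 internal
MET M 4 internal
RXN up irr 1 S[abcd] -> 1 F[abcd]
RXN hyd rev 1 F[abcd] -> 1 M[abcd]
RXN sink irr 1 M[abcd] -> out
SYM F
"""

# formaldehyde + pentose condensation and triose cleavage (RuMP-like)
RUMP_TOY = """
MET C1 1 source
MET P5 5 source
MET H6 6 internal
MET T3 3 internal
RXN cond irr 1 C1[a] + 1 P5[bcdef] -> 1 H6[abcdef]
RXN cleave irr 1 H6[abcdef] -> 1 T3[abc] + 1 T3[def]
RXN sink irr 1 T3[abc] -> out
"""


@pytest.fixture(scope="session")
def chain_net():
    return parse_network(CHAIN)


@pytest.fixture(scope="session")
def diamond_net():
    return parse_network(DIAMOND)


@pytest.fixture(scope="session")
def split_join_net():
    return parse_network(SPLIT_JOIN)


@pytest.fixture(scope="session")
def reversible_net():
    return parse_network(REVERSIBLE_CHAIN)


@pytest.fixture(scope="session")
def symmetric_net():
    return parse_network(SYMMETRIC_TOY)


@pytest.fixture(scope="session")
def rump_net():
    return parse_network(RUMP_TOY)


@pytest.fixture(scope="session")
def mannitol_cond():
    return reference_condition("mannitol")


@pytest.fixture(scope="session")
def arabitol_cond():
    return reference_condition("arabitol")


@pytest.fixture(scope="session")
def methanol_cond():
    return reference_condition("methanol")


def oracle_case_suite():
    """Structured toy scenarios for EMU-vs-exhaustive-oracle comparisons:
    condensation, cleavage, reversibility with exchange, symmetry."""
    from methyloflux.model import FluxVector

    def toy_flux(net, **values):
        return FluxVector(
            {r: values.get(r, 0.0) for r in net.reactions},
            {r.id: values.get(f"x_{r.id}", 0.0) for r in net.reactions.values() if r.reversible},
        )

    chain = parse_network(CHAIN)
    diamond = parse_network(DIAMOND)
    split_join = parse_network(SPLIT_JOIN)
    reversible = parse_network(REVERSIBLE_CHAIN)
    symmetric = parse_network(SYMMETRIC_TOY)
    rump = parse_network(RUMP_TOY)
    d_par = free_flux_basis(diamond, [("up", 1.0)])
    return {
        "chain": (chain, toy_flux(chain, r1=1, r2=1),
                  LabelInput({"A": [("10", 0.7), ("01", 0.3)]}, purity=0.99)),
        "diamond": (diamond, apply_flux_parameters(d_par, [0.35]),
                    LabelInput({"S": [("10", 1.0)]}, purity=0.98)),
        "split_join": (split_join,
                       toy_flux(split_join, up=1, split=1, join=0.6, outy=0.6,
                                outp=0.4, outq=0.4, x_join=0.5),
                       LabelInput({"S": [("1010", 0.6), ("0110", 0.4)]}, purity=0.97)),
        "reversible": (reversible, toy_flux(reversible, r1=1, r2=1, r3=1, x_r2=0.8),
                       LabelInput({"A": [("100", 1.0)]}, purity=0.99)),
        "symmetric": (symmetric, toy_flux(symmetric, up=1, hyd=1, sink=1, x_hyd=0.3),
                      LabelInput({"S": [("1100", 1.0)]}, purity=0.99)),
        "rump": (rump, toy_flux(rump, cond=1, cleave=1, sink=2),
                 LabelInput({"C1": [("1", 1.0)], "P5": [("01000", 1.0)]}, purity=0.99)),
    }


def diamond_truth(split=0.3):
    net = parse_network(DIAMOND)
    par = free_flux_basis(net, [("up", 1.0)])
    return net, par, apply_flux_parameters(par, [split])


def diamond_measurements(state, sd=0.005, rng=None):
    """Positional-enrichment measurement table for the diamond P pool."""
    rows = []
    for c in (1, 2):
        v = state.enrichment("P", c)
        if rng is not None:
            v = float(np.clip(v + rng.normal(0.0, sd), 0.0, 1.0))
        rows.append(("P", "enrichment", c, v, sd, True))
    return pd.DataFrame(rows, columns=["species", "kind", "index", "value", "sd", "use"])
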