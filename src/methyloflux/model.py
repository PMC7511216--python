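"""Atom-transition metabolic network models.

A network couples ordinary stoichiometry with carbon atom transitions, the
information needed to simulate isotope labeling.  Metabolites are declared
with a carbon count and a compartment role (``internal``, ``source`` or
``sink``); reactions carry per-carbon atom maps written in letter notation,
e.g. ``FruBP[abcdef] -> DHAP[cba] + GA3P[def]``.

Networks are read and written in a small line-oriented text dialect (and an
equivalent JSON schema)::

    # comment
    MET  Glc6P  6  internal  [pool_size]
    RXN  pgi  rev  1 Fru6P[abcdef] -> 1 Glc6P[abcdef]
    SYM  Fum
    BIO  Pyr  2.833

``MET`` declares a metabolite (id, carbon count, role, optional pool size in
umol/gDCW).  ``RXN`` declares a reaction (id, ``rev``/``irr``, then reactant
and product terms).  The reserved product token ``out`` exports carbon from
the system (used for CO2 venting and biomass drains).  ``SYM`` flags a
rotationally symmetric metabolite (the simulator averages the two carbon
orientations).  ``BIO`` records a biomass precursor demand coefficient
(mmol per gDCW).
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Metabolite",
    "ReactionTerm",
    "Reaction",
    "Network",
    "LabelInput",
    "FluxVector",
    "FluxParameterization",
    "ValidationReport",
    "ParseError",
    "InfeasibleConstraints",
    "parse_network",
    "write_network",
    "network_to_json",
    "network_from_json",
    "validate_network",
    "free_flux_basis",
    "apply_flux_parameters",
    "load_bundled_network",
]

SINK_TOKEN = "out"

ROLES = ("internal", "source", "sink")


class ParseError(ValueError):
    """Raised when model text violates the dialect."""


class InfeasibleConstraints(ValueError):
    """Raised when flux equality constraints contradict the stoichiometry."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    role: str = "internal"
    pool_size: float | None = None  # umol / gDCW, instationary simulation only

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for metabolite {self.id}")
        if self.n_carbons < 0:
            raise ValueError(f"negative carbon count for metabolite {self.id}")


@dataclass(frozen=True)
class ReactionTerm:
    """One occurrence of a metabolite on a reaction side."""

    met: str
    coef: float = 1.0
    atoms: tuple[str, ...] = ()  # one letter per carbon


@dataclass
class Reaction:
    id: str
    reversible: bool
    reactants: list[ReactionTerm]
    products: list[ReactionTerm]  # empty if the reaction exports to `out`
    exports: bool = False  # True when the product side is the reserved sink

    def atom_letters(self, side: str) -> list[str]:
        terms = self.reactants if side == "reactants" else self.products
        return [a for t in terms for a in t.atoms]

    def carbon_balanced(self) -> bool:
        if self.exports:
            return True
        return sorted(self.atom_letters("reactants")) == sorted(self.atom_letters("products"))

    def atom_map(self) -> dict[tuple[int, int], tuple[int, int]]:
        """Resolve letters to index pairs.

        Maps (product occurrence, product carbon position) -> (reactant
        occurrence, reactant carbon position); positions are 0-based.
        """
        source: dict[str, tuple[int, int]] = {}
        for i, term in enumerate(self.reactants):
            for p, letter in enumerate(term.atoms):
                source[letter] = (i, p)
        out: dict[tuple[int, int], tuple[int, int]] = {}
        for j, term in enumerate(self.products):
            for q, letter in enumerate(term.atoms):
                out[(j, q)] = source[letter]
        return out


@dataclass
class Network:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    symmetric: set[str] = field(default_factory=set)
    biomass: dict[str, float] = field(default_factory=dict)  # precursor -> mmol/gDCW
    notes: str = ""

    # -- structural queries -------------------------------------------------

    @property
    def substrates(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.role == "source"]

    @property
    def internal_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.role == "internal"]

    def n_carbons(self, met: str) -> int:
        return self.metabolites[met].n_carbons

    def producers(self, met: str) -> list[tuple[str, str]]:
        """(reaction id, direction) pairs structurally able to produce `met`."""
        hits = []
        for r in self.reactions.values():
            if any(t.met == met for t in r.products):
                hits.append((r.id, "fwd"))
            if r.reversible and any(t.met == met for t in r.reactants):
                hits.append((r.id, "bwd"))
        return hits

    def consumers(self, met: str) -> list[tuple[str, str]]:
        hits = []
        for r in self.reactions.values():
            if any(t.met == met for t in r.reactants):
                hits.append((r.id, "fwd"))
            if r.reversible and any(t.met == met for t in r.products):
                hits.append((r.id, "bwd"))
        return hits

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Net-flux stoichiometric matrix over internal metabolites.

        Returns (S, metabolite ids, reaction ids); S[i, j] is the net
        production of metabolite i by one unit of net flux through reaction j.
        """
        mets = self.internal_metabolites
        rxns = list(self.reactions)
        midx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        for j, rid in enumerate(rxns):
            r = self.reactions[rid]
            for t in r.reactants:
                if t.met in midx:
                    S[midx[t.met], j] -= t.coef
            for t in r.products:
                if t.met in midx:
                    S[midx[t.met], j] += t.coef
        return S, mets, rxns


@dataclass
class LabelInput:
    """Positional isotopomer composition of the fed substrates.

    ``patterns`` maps substrate id to a list of (pattern, molar fraction)
    where a pattern is a string of '0'/'1' over the substrate carbons
    (1-based position i is character i-1), '1' marking a tracer position.
    Tracer positions carry 13C with probability ``purity``.
    """

    patterns: dict[str, list[tuple[str, float]]]
    purity: float = 0.99

    def validate(self, net: Network) -> None:
        for sub, pats in self.patterns.items():
            if sub not in net.metabolites:
                raise ValueError(f"label input references unknown substrate {sub!r}")
            n = net.n_carbons(sub)
            tot = 0.0
            for pat, frac in pats:
                if len(pat) != n or set(pat) - {"0", "1"}:
                    raise ValueError(f"bad pattern {pat!r} for {sub} ({n} carbons)")
                tot += frac
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"pattern fractions for {sub} sum to {tot}, not 1")

    def atom_distribution(self, sub: str, positions: tuple[int, ...]) -> np.ndarray:
        """CID of the fragment of `sub` at 0-based `positions` (tracer space)."""
        out = None
        for pat, frac in self.patterns[sub]:
            cid = np.array([1.0])
            for p in positions:
                one = np.array([1.0 - self.purity, self.purity]) if pat[p] == "1" else np.array([1.0, 0.0])
                cid = np.convolve(cid, one)
            out = frac * cid if out is None else out + frac * cid
        return out


@dataclass
class FluxVector:
    """Net and exchange flux per reaction, mmol / gDCW / h.

    Exchange fluxes are nonnegative and zero for irreversible reactions.
    ``violations`` lists bound problems found when the vector was built
    (reported, never silently clipped).
    """

    net: dict[str, float]
    exch: dict[str, float] = field(default_factory=dict)
    violations: list[str] = field(default_factory=list)

    def forward(self, rid: str) -> float:
        v, e = self.net[rid], self.exch.get(rid, 0.0)
        return max(v, 0.0) + e

    def backward(self, rid: str) -> float:
        v, e = self.net[rid], self.exch.get(rid, 0.0)
        return max(-v, 0.0) + e

    def scaled(self, k: float) -> "FluxVector":
        return FluxVector(
            {r: k * v for r, v in self.net.items()},
            {r: k * e for r, e in self.exch.items()},
        )

    def balance_residual(self, net: Network) -> float:
        """Max relative steady-state imbalance over internal metabolites."""
        S, _, rxns = net.stoichiometric_matrix()
        v = np.array([self.net[r] for r in rxns])
        resid = S @ v
        scale = max(1.0, float(np.max(np.abs(v))) if len(v) else 1.0)
        return float(np.max(np.abs(resid))) / scale if resid.size else 0.0


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:([0-9.]+)\s+)?([A-Za-z0-9_]+)(?:\[([A-Za-z]*)\])?$")


def _parse_term(tok: str, rxn_id: str) -> ReactionTerm:
    m = _TERM_RE.match(tok.strip())
    if not m:
        raise ParseError(f"reaction {rxn_id}: cannot parse term {tok!r}")
    coef = float(m.group(1)) if m.group(1) else 1.0
    atoms = tuple(m.group(3)) if m.group(3) else ()
    return ReactionTerm(met=m.group(2), coef=coef, atoms=atoms)


def _parse_side(text: str, rxn_id: str) -> list[ReactionTerm]:
    return [_parse_term(tok, rxn_id) for tok in text.split("+")]


def parse_network(text: str) -> Network:
    """Parse model text in the documented dialect into a :class:`Network`."""
    mets: dict[str, Metabolite] = {}
    rxns: dict[str, Reaction] = {}
    symmetric: set[str] = set()
    biomass: dict[str, float] = {}
    notes: list[str] = []

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            if raw.strip().startswith("#"):
                notes.append(raw.strip("# ").rstrip())
            continue
        fields = line.split()
        kind = fields[0].upper()
        if kind == "MET":
            if len(fields) not in (4, 5):
                raise ParseError(f"line {lineno}: MET takes id, n_carbons, role[, pool]")
            mid, n, role = fields[1], int(fields[2]), fields[3]
            if mid in mets:
                raise ParseError(f"line {lineno}: duplicate metabolite id {mid!r}")
            if mid == SINK_TOKEN:
                raise ParseError(f"line {lineno}: {SINK_TOKEN!r} is a reserved id")
            pool = float(fields[4]) if len(fields) == 5 else None
            mets[mid] = Metabolite(mid, n, role, pool)
        elif kind == "RXN":
            body = line[len("RXN") :].strip()
            parts = body.split(None, 2)
            if len(parts) < 3 or parts[1] not in ("rev", "irr"):
                raise ParseError(f"line {lineno}: RXN takes id, rev|irr, equation")
            rid, rev_tok, eqn = parts[0], parts[1], parts[2]
            if rid in rxns:
                raise ParseError(f"line {lineno}: duplicate reaction id {rid!r}")
            if "->" not in eqn:
                raise ParseError(f"reaction {rid}: missing '->'")
            lhs, rhs = eqn.split("->", 1)
            reactants = _parse_side(lhs, rid)
            exports = rhs.strip() == SINK_TOKEN
            products = [] if exports else _parse_side(rhs, rid)
            rxns[rid] = Reaction(rid, rev_tok == "rev", reactants, products, exports)
        elif kind == "SYM":
            symmetric.add(fields[1])
        elif kind == "BIO":
            biomass[fields[1]] = float(fields[2])
        else:
            raise ParseError(f"line {lineno}: unknown directive {fields[0]!r}")

    net = Network(mets, rxns, symmetric, biomass, notes="\n".join(notes))
    _check_network(net)
    return net


def _check_network(net: Network) -> None:
    for r in net.reactions.values():
        for t in itertools.chain(r.reactants, r.products):
            if t.met not in net.metabolites:
                raise ParseError(f"reaction {r.id}: undeclared metabolite {t.met!r}")
            n = net.n_carbons(t.met)
            if t.atoms and len(t.atoms) != n:
                raise ParseError(
                    f"reaction {r.id}: {t.met} has {n} carbons but "
                    f"{len(t.atoms)} atom letters"
                )
        letters = r.atom_letters("reactants")
        if len(set(letters)) != len(letters):
            raise ParseError(f"reaction {r.id}: repeated atom letter on reactant side")
        if not r.carbon_balanced():
            raise ParseError(
                f"reaction {r.id}: atom-letter multiset mismatch between sides"
            )
        if r.exports and r.reversible:
            raise ParseError(f"reaction {r.id}: export reactions must be irreversible")
    for s in net.symmetric:
        if s not in net.metabolites:
            raise ParseError(f"SYM references undeclared metabolite {s!r}")
    for b in net.biomass:
        if b not in net.metabolites:
            raise ParseError(f"BIO references undeclared metabolite {b!r}")


def write_network(net: Network) -> str:
    """Serialize a network back to the text dialect (parse-stable)."""
    lines = []
    for m in net.metabolites.values():
        pool = f" {m.pool_size:g}" if m.pool_size is not None else ""
        lines.append(f"MET {m.id} {m.n_carbons} {m.role}{pool}")
    for r in net.reactions.values():

        def side(terms):
            toks = []
            for t in terms:
                coef = f"{t.coef:g} " if t.coef != 1.0 else "1 "
                atoms = f"[{''.join(t.atoms)}]" if t.atoms else ""
                toks.append(f"{coef}{t.met}{atoms}")
            return " + ".join(toks)

        rhs = SINK_TOKEN if r.exports else side(r.products)
        lines.append(f"RXN {r.id} {'rev' if r.reversible else 'irr'} {side(r.reactants)} -> {rhs}")
    for s in sorted(net.symmetric):
        lines.append(f"SYM {s}")
    for b, c in net.biomass.items():
        lines.append(f"BIO {b} {c:g}")
    return "\n".join(lines) + "\n"


def network_to_json(net: Network) -> str:
    obj = {
        "metabolites": [
            {"id": m.id, "n_carbons": m.n_carbons, "role": m.role, "pool_size": m.pool_size}
            for m in net.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "reversible": r.reversible,
                "reactants": [[t.coef, t.met, "".join(t.atoms)] for t in r.reactants],
                "products": [[t.coef, t.met, "".join(t.atoms)] for t in r.products],
                "exports": r.exports,
            }
            for r in net.reactions.values()
        ],
        "symmetric": sorted(net.symmetric),
        "biomass": net.biomass,
        "notes": net.notes,
    }
    return json.dumps(obj, indent=1)


def network_from_json(text: str) -> Network:
    obj = json.loads(text)
    mets = {
        m["id"]: Metabolite(m["id"], m["n_carbons"], m["role"], m.get("pool_size"))
        for m in obj["metabolites"]
    }
    rxns = {}
    for r in obj["reactions"]:
        rxns[r["id"]] = Reaction(
            r["id"],
            r["reversible"],
            [ReactionTerm(met, coef, tuple(atoms)) for coef, met, atoms in r["reactants"]],
            [ReactionTerm(met, coef, tuple(atoms)) for coef, met, atoms in r["products"]],
            r.get("exports", False),
        )
    net = Network(mets, rxns, set(obj.get("symmetric", [])), obj.get("biomass", {}), obj.get("notes", ""))
    _check_network(net)
    return net


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    carbon_balance: dict[str, bool]
    dead_ends: list[str]  # internal metabolites lacking a producer or consumer
    nullspace_dim: int
    ok: bool

    def summary(self) -> str:
        bad = [r for r, b in self.carbon_balance.items() if not b]
        lines = [
            f"reactions: {len(self.carbon_balance)} ({len(bad)} carbon-unbalanced)",
            f"dead-end metabolites: {', '.join(self.dead_ends) or 'none'}",
            f"free net fluxes (nullspace dimension): {self.nullspace_dim}",
            f"status: {'OK' if self.ok else 'FAILED'}",
        ]
        return "\n".join(lines)


def validate_network(net: Network) -> ValidationReport:
    balance = {r.id: r.carbon_balanced() for r in net.reactions.values()}
    dead = []
    for m in net.internal_metabolites:
        if not net.producers(m) or not net.consumers(m):
            dead.append(m)
    S, _, _ = net.stoichiometric_matrix()
    rank = int(np.linalg.matrix_rank(S)) if S.size else 0
    dim = S.shape[1] - rank
    ok = all(balance.values()) and not dead and dim > 0
    return ValidationReport(balance, dead, dim, ok)


# ---------------------------------------------------------------------------
# free-flux parameterization
# ---------------------------------------------------------------------------

Constraint = tuple[str | dict[str, float], float]


@dataclass
class FluxParameterization:
    """Affine map from free net fluxes to the full net-flux vector.

    v_full[order] = offset + basis @ v_free, with `free` naming the free
    net fluxes.  Exchange fluxes of reversible reactions are all free and
    handled separately by :func:`apply_flux_parameters`.
    """

    net: Network
    order: list[str]  # all reaction ids, fixed order
    free: list[str]  # free net flux reaction ids
    basis: np.ndarray  # (n_rxns, n_free)
    offset: np.ndarray  # (n_rxns,)
    free_exchange: list[str]  # reversible reaction ids

    @property
    def n_free(self) -> int:
        return len(self.free)

    def full_net(self, values: np.ndarray) -> dict[str, float]:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.free),):
            raise ValueError(f"expected {len(self.free)} free net flux values, got {values.shape}")
        v = self.offset + self.basis @ values
        return dict(zip(self.order, v))


def _constraint_row(net: Network, c: Constraint, rxns: list[str]) -> tuple[np.ndarray, float]:
    target, value = c
    row = np.zeros(len(rxns))
    coefs = {target: 1.0} if isinstance(target, str) else target
    for rid, coef in coefs.items():
        if rid not in net.reactions:
            raise KeyError(f"constraint references unknown reaction {rid!r}")
        row[rxns.index(rid)] = coef
    return row, float(value)


def free_flux_basis(net: Network, equality_constraints: list[Constraint] | None = None) -> FluxParameterization:
    """Choose a deterministic set of free net fluxes.

    Gaussian elimination runs over columns in lexicographic reaction-id
    order; pivot columns become dependent fluxes, the rest are free.  The
    same network and constraints therefore always yield the same basis.
    """
    S, _, rxns_decl = net.stoichiometric_matrix()
    rows = [S]
    rhs = [np.zeros(S.shape[0])]
    for c in equality_constraints or []:
        row, val = _constraint_row(net, c, rxns_decl)
        rows.append(row[None, :])
        rhs.append(np.array([val]))
    A = np.vstack(rows)
    b = np.concatenate(rhs)

    # column order: lexicographic on reaction id
    order = sorted(range(len(rxns_decl)), key=lambda j: rxns_decl[j])
    A = A[:, order]
    ids = [rxns_decl[j] for j in order]

    A = A.copy()
    b = b.copy()
    m, n = A.shape
    tol = 1e-9 * max(1.0, float(np.max(np.abs(A))))
    pivots: list[tuple[int, int]] = []  # (row, col)
    row = 0
    for col in range(n):
        if row >= m:
            break
        p = row + int(np.argmax(np.abs(A[row:, col])))
        if abs(A[p, col]) <= tol:
            continue
        if p != row:
            A[[row, p]] = A[[p, row]]
            b[[row, p]] = b[[p, row]]
        piv = A[row, col]
        A[row] /= piv
        b[row] /= piv
        for r in range(m):
            if r != row and abs(A[r, col]) > 0:
                f = A[r, col]
                A[r] -= f * A[row]
                b[r] -= f * b[row]
        pivots.append((row, col))
        row += 1

    for r in range(row, m):
        if abs(b[r]) > 1e-6 * max(1.0, abs(b).max()):
            raise InfeasibleConstraints(
                "equality constraints are inconsistent with the stoichiometry"
            )

    pivot_cols = {c for _, c in pivots}
    free_cols = [c for c in range(n) if c not in pivot_cols]
    free_ids = [ids[c] for c in free_cols]

    basis = np.zeros((n, len(free_cols)))
    offset = np.zeros(n)
    for k, c in enumerate(free_cols):
        basis[c, k] = 1.0
    for r, c in pivots:
        offset[c] = b[r]
        for k, fc in enumerate(free_cols):
            basis[c, k] = -A[r, fc]

    # back to declaration order
    inv = np.argsort(order)
    return FluxParameterization(
        net=net,
        order=rxns_decl,
        free=free_ids,
        basis=basis[inv][:, :],
        offset=offset[inv],
        free_exchange=sorted(r.id for r in net.reactions.values() if r.reversible),
    )


def apply_flux_parameters(
    par: FluxParameterization,
    net_values: np.ndarray,
    exch_values: np.ndarray | dict[str, float] | None = None,
) -> FluxVector:
    """Build a steady-state FluxVector from free parameter values.

    Out-of-bound results (negative net flux through an irreversible
    reaction, negative exchange) are recorded in ``violations``.
    """
    netmap = par.full_net(np.asarray(net_values, dtype=float))
    if exch_values is None:
        exch = {r: 0.0 for r in par.free_exchange}
    elif isinstance(exch_values, dict):
        exch = {r: float(exch_values.get(r, 0.0)) for r in par.free_exchange}
    else:
        exch_values = np.asarray(exch_values, dtype=float)
        if exch_values.shape != (len(par.free_exchange),):
            raise ValueError(
                f"expected {len(par.free_exchange)} exchange values, got {exch_values.shape}"
            )
        exch = dict(zip(par.free_exchange, exch_values))

    violations = []
    for rid, v in netmap.items():
        if not par.net.reactions[rid].reversible and v < -1e-9:
            violations.append(f"negative net flux {v:.3g} through irreversible {rid}")
    for rid, e in exch.items():
        if e < 0:
            violations.append(f"negative exchange flux {e:.3g} for {rid}")
    return FluxVector(netmap, exch, violations)


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------


def load_bundled_network(name: str) -> Network:
    """Load one of the bundled B. methanolicus models.

    ``name`` is ``methanol``, ``mannitol`` or ``arabitol``.
    """
    from importlib import resources

    path = resources.files("methyloflux.data").joinpath(f"{name}.net")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"no bundled network named {name!r}") from None
    return parse_network(text)
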