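"""Subline phylogeny from CNA/LOH characters, and event-order logic.

Cell-line sublines accumulate copy-number aberrations (CNA — in principle
reversible by further gain/loss) and regions of loss of heterozygosity
(LOH — irreversible: once a homologue is gone, heterozygosity cannot be
regained).  Shared LOH is therefore strong evidence of common ancestry, and
lineage inference here is small-scale parsimony with asymmetric characters:
reversible characters may change 0->1 and 1->0 at unit cost, irreversible
characters may only change 0->1 (the Camin-Sokal model).

Trees are rooted at the founding clone carrying none of the derived
aberrations (all-zero state), matching the single-origin model of a cell
line established from one patient.  With few taxa all rooted binary
topologies are enumerated exhaustively; ties are reported, never broken.

A second, orthogonal source of ordering information is ploidy logic: in a
near-triploid genome, if one copy of a duplicated homologue is rearranged,
the rearrangement must postdate the doubling of that homologue.  Those
constraints are emitted as a conflict-checked DAG.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .observe import HomologueAssignedKaryotype

__all__ = [
    "CharacterMatrix",
    "Character",
    "LineageTree",
    "parsimony_score",
    "best_tree",
    "enumerate_rooted_trees",
    "event_order_constraints",
    "load_character_matrix",
    "bundled_character_matrix",
]

INF = math.inf

IRREVERSIBLE = "LOH"
REVERSIBLE = "CNA"


@dataclass(frozen=True)
class Character:
    """One aberration scored across taxa; states 0/1 with "?" for unknown."""

    name: str
    char_class: str                      # "LOH" (irreversible) or "CNA"
    states: tuple[str, ...]              # aligned with the matrix's taxa

    def __post_init__(self):
        if self.char_class not in (IRREVERSIBLE, REVERSIBLE):
            raise ValueError(f"character class must be LOH or CNA, "
                             f"got {self.char_class!r}")
        for s in self.states:
            if s not in ("0", "1", "?"):
                raise ValueError(f"bad state {s!r} in character {self.name}")


@dataclass
class CharacterMatrix:
    """Taxa x characters with per-character reversibility class."""

    taxa: tuple[str, ...]
    characters: list[Character]

    def __post_init__(self):
        if len(self.taxa) < 2:
            raise ValueError("need at least two taxa")
        for ch in self.characters:
            if len(ch.states) != len(self.taxa):
                raise ValueError(f"character {ch.name} has "
                                 f"{len(ch.states)} states for "
                                 f"{len(self.taxa)} taxa")
        # a matrix with no varying character is legal (every topology ties);
        # callers can check .informative before tree search
        self.informative = any(len({s for s in ch.states if s != "?"}) > 1
                               for ch in self.characters)

    def state(self, char: Character, taxon: str) -> str:
        return char.states[self.taxa.index(taxon)]


def load_character_matrix(path: str | Path) -> CharacterMatrix:
    """Read a character CSV (columns: character, class, one per taxon)."""
    with open(path) as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].startswith("#")]
    header = rows[0]
    taxa = tuple(header[2:])
    chars = [Character(r[0], r[1], tuple(r[2:])) for r in rows[1:]]
    return CharacterMatrix(taxa, chars)


def bundled_character_matrix() -> CharacterMatrix:
    """The HEL subline aberration matrix shipped with the package."""
    from importlib import resources
    p = resources.files("karyorecon") / "data" / "hel_subline_characters.csv"
    return load_character_matrix(Path(p))


# ---------------------------------------------------------------------------
# trees

@dataclass(frozen=True)
class LineageTree:
    """A rooted binary tree over taxa, with per-edge character changes.

    ``topology`` is a nested tuple of taxon names; ``edge_changes`` maps each
    clade (frozenset of the leaf names below the edge) to the list of
    character-state changes inferred on the edge above it.
    """

    topology: tuple
    cost: float = 0.0
    edge_changes: tuple = ()

    def clades(self) -> list[frozenset]:
        out = []

        def walk(node) -> frozenset:
            if isinstance(node, str):
                s = frozenset([node])
            else:
                s = frozenset().union(*(walk(c) for c in node))
            out.append(s)
            return s

        walk(self.topology)
        return out

    def newick(self) -> str:
        def fmt(node) -> str:
            if isinstance(node, str):
                return node
            return "(" + ",".join(fmt(c) for c in node) + ")"
        return fmt(self.topology) + ";"

    def has_clade(self, *taxa: str) -> bool:
        return frozenset(taxa) in set(self.clades())


def _canon(node):
    """Canonical form of a nested-tuple topology (children sorted)."""
    if isinstance(node, str):
        return node
    kids = sorted((_canon(c) for c in node), key=str)
    return tuple(kids)


def enumerate_rooted_trees(taxa: list[str]) -> list[tuple]:
    """All rooted binary topologies over the taxa ((2n-3)!! of them),
    in deterministic order."""
    taxa = list(taxa)
    trees = [taxa[0]]
    for t in taxa[1:]:
        new = []
        for tree in trees:
            for pos in _insert_positions(tree, t):
                new.append(pos)
        trees = new
    return sorted({_canon(t) for t in trees}, key=str)


def _insert_positions(tree, leaf):
    # attach as sibling of the whole tree (new root)
    yield (tree, leaf)
    if not isinstance(tree, str):
        a, b = tree
        for sub in _insert_positions(a, leaf):
            yield (sub, b)
        for sub in _insert_positions(b, leaf):
            yield (a, sub)


# ---------------------------------------------------------------------------
# parsimony

def _char_cost(tree, matrix: CharacterMatrix, ch: Character):
    """Sankoff minimisation for one character on a rooted tree, root forced
    to state 0 (the founding clone carries no derived aberration).
    Returns (cost, changes) where changes is a list of (clade, '0->1'|'1->0')."""
    irreversible = ch.char_class == IRREVERSIBLE

    def edge_cost(parent: int, child: int) -> float:
        if parent == child:
            return 0.0
        if parent == 1 and child == 0 and irreversible:
            return INF
        return 1.0

    def walk(node):
        """Returns (cost_if_state0, cost_if_state1)."""
        if isinstance(node, str):
            s = matrix.state(ch, node)
            if s == "?":
                return (0.0, 0.0)
            return (0.0, INF) if s == "0" else (INF, 0.0)
        costs = []
        for child in node:
            c0, c1 = walk(child)
            costs.append((
                min(c0 + edge_cost(0, 0), c1 + edge_cost(0, 1)),
                min(c0 + edge_cost(1, 0), c1 + edge_cost(1, 1)),
            ))
        return (sum(c[0] for c in costs), sum(c[1] for c in costs))

    c0, c1 = walk(tree)
    # the founding clone (state 0) sits above the root: a gain on the root
    # edge costs one change
    total_cost = min(c0, c1 + edge_cost(0, 1))
    if not math.isfinite(total_cost):
        return INF, []

    # second pass: reconstruct one optimal labelling (ties -> state 0)
    changes = []

    def down(node, parent_state: int) -> frozenset:
        if isinstance(node, str):
            s = matrix.state(ch, node)
            state = parent_state if s == "?" else int(s)
            if state != parent_state:
                changes.append((frozenset([node]),
                                f"{parent_state}->{state}"))
            return frozenset([node])
        best_state, best_c = None, INF
        for state in (0, 1):
            total = edge_cost(parent_state, state)
            for child in node:
                c0, c1 = walk(child)
                total += min(c0 + edge_cost(state, 0),
                             c1 + edge_cost(state, 1))
            if total < best_c - 1e-12:
                best_state, best_c = state, total
        leaves = frozenset()
        for child in node:
            leaves |= down(child, best_state)
        if best_state != parent_state:
            changes.append((leaves, f"{parent_state}->{best_state}"))
        return leaves

    down(tree, 0)
    return total_cost, changes


def parsimony_score(tree, matrix: CharacterMatrix):
    """Total parsimony cost of a rooted topology under the mixed
    reversible/irreversible model; infinite if an LOH reversal is forced.

    ``tree`` may be a LineageTree or a nested tuple of taxon names.
    """
    topo = tree.topology if isinstance(tree, LineageTree) else tree
    leaves = set()

    def collect(node):
        if isinstance(node, str):
            leaves.add(node)
        else:
            for c in node:
                collect(c)

    collect(topo)
    if leaves != set(matrix.taxa):
        raise ValueError(f"tree taxa {sorted(leaves)} do not match matrix "
                         f"taxa {sorted(matrix.taxa)}")
    total = 0.0
    for ch in matrix.characters:
        c, _ = _char_cost(topo, matrix, ch)
        if not math.isfinite(c):
            return INF
        total += c
    return total


def best_tree(matrix: CharacterMatrix) -> list[LineageTree]:
    """All minimum-cost rooted binary topologies with their per-edge
    changes, by exhaustive enumeration (supported up to 8 taxa)."""
    if len(matrix.taxa) > 8:
        raise ValueError("exhaustive search supported for at most 8 taxa")
    best_cost = INF
    winners: list[LineageTree] = []
    for topo in enumerate_rooted_trees(list(matrix.taxa)):
        cost = parsimony_score(topo, matrix)
        if cost < best_cost - 1e-12:
            best_cost, winners = cost, []
        if abs(cost - best_cost) < 1e-12:
            all_changes = []
            for ch in matrix.characters:
                _, changes = _char_cost(topo, matrix, ch)
                for clade, kind in changes:
                    all_changes.append((clade, ch.name, kind))
            winners.append(LineageTree(topo, cost, tuple(all_changes)))
    return winners


# ---------------------------------------------------------------------------
# event ordering from ploidy logic

def event_order_constraints(hk: HomologueAssignedKaryotype,
                            derivations: dict[str, str] | None = None) -> nx.DiGraph:
    """Partial order over homologue doublings and rearrangements.

    For each chromosome homologue present in >=2 copies of which exactly one
    copy is rearranged, the doubling must precede the rearrangement.  A
    derivative present in >=2 identical copies must have formed before its
    duplication.  ``derivations`` optionally maps a derivative's notation to
    its parent derivative's, adding parent formation < parent duplication <
    child formation.  Returns a DAG; raises if the constraints are cyclic.
    """
    g = nx.DiGraph()
    model = hk.model

    # homologue doubling before rearrangement of one copy
    for c, (na, nb) in sorted(hk.normal_split.items()):
        for label, n_norm in (("A", na), ("B", nb)):
            carriers = [sc for sc in model.structured
                        if any(seg.interval.chrom == c and
                               seg.homologue == label and
                               c in sc.cited
                               for seg in sc.segments)]
            copies = n_norm + len(carriers)
            if copies >= 2 and len(carriers) == 1:
                doubling = ("doubling", c, label)
                rearr = ("rearrangement", carriers[0].notation())
                g.add_edge(doubling, rearr)

    # duplicated derivatives: formation precedes duplication
    seen: dict[tuple, list[str]] = {}
    for sc in model.structured:
        key = (sc.kind, sc.cited,
               tuple(str(s.interval) for s in sc.segments))
        seen.setdefault(key, []).append(sc.notation().lstrip("+"))
    for key, names in sorted(seen.items(), key=str):
        if len(names) >= 2:
            name = sorted(names, key=len)[-1]  # the fully written token
            g.add_edge(("rearrangement", name), ("duplication", name))

    # explicit derivation relationships
    for child, parent in sorted((derivations or {}).items()):
        g.add_edge(("rearrangement", parent), ("duplication", parent))
        g.add_edge(("duplication", parent), ("rearrangement", child))

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"inconsistent event-order constraints: {cycle}")
    return g
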