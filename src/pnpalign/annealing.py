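"""Non-progressive sequence annealing over a column-order graph.

For distantly related families a guide tree misleads more than it helps:
homology is confined to short motifs buried in long divergent stretches.
Sequence annealing instead builds the alignment bottom-up from the most
confident residue pairs.  All cross-sequence residue pairs with posterior
probability above a cutoff are sorted by descending probability and
greedily merged into "same-column" sets.

Every residue starts as its own singleton column node; nodes are connected
by precedence edges (position k of a sequence must precede position k+1).
Inserting a pair (x_i, y_j) merges the two nodes containing the residues,
which is allowed only if

* the merged set would contain at most one residue per sequence, and
* the graph stays acyclic — equivalently, neither node currently reaches
  the other, so no column-order constraint is violated.

Rejection is a normal outcome, checked *before* mutating, so the graph
never needs rollback.  When all pairs are processed, a deterministic
topological sort (Kahn's algorithm with a priority queue keyed by the
smallest (sequence, position) member) emits one alignment column per node.
Residues never merged each occupy their own column, so a family with no
posterior support yields a fully staggered but valid alignment.
"""

from __future__ import annotations

import heapq
from typing import NamedTuple

from .errors import InvariantError
from .posterior import DEFAULT_SPARSITY_CUTOFF, PosteriorSet
from .seqio import GAP, Alignment, Family


class CharRef(NamedTuple):
    """A residue: sequence index within the family, 0-based position."""

    seq: int
    pos: int


class ColumnGraph:
    """Mutable same-column sets with precedence edges.

    Nodes are integer ids; ``members[node]`` maps sequence index -> residue
    position (at most one per sequence).  ``succ``/``pred`` hold the edge
    relation.  ``locate(ref)`` finds the node currently holding a residue.
    """

    def __init__(self, lengths: list[int]):
        self.members: dict[int, dict[int, int]] = {}
        self.succ: dict[int, set[int]] = {}
        self.pred: dict[int, set[int]] = {}
        self._where: dict[CharRef, int] = {}
        nid = 0
        for s, length in enumerate(lengths):
            prev = None
            for p in range(length):
                self.members[nid] = {s: p}
                self.succ[nid] = set()
                self.pred[nid] = set()
                self._where[CharRef(s, p)] = nid
                if prev is not None:
                    self.succ[prev].add(nid)
                    self.pred[nid].add(prev)
                prev = nid
                nid += 1

    def locate(self, ref: CharRef) -> int:
        return self._where[ref]

    def _reaches(self, start: int, goal: int) -> bool:
        stack = [start]
        seen = {start}
        while stack:
            node = stack.pop()
            for nxt in self.succ[node]:
                if nxt == goal:
                    return True
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    def try_insert(self, a: CharRef, b: CharRef) -> bool:
        """Constrain residues a and b to one column; True iff accepted.

        All checks run before any mutation, so a rejected insertion leaves
        the graph exactly as it was.
        """
        u, v = self.locate(a), self.locate(b)
        if u == v:
            return True  # already in the same column
        if self.members[u].keys() & self.members[v].keys():
            return False  # would put two residues of one sequence in a column
        if self._reaches(u, v) or self._reaches(v, u):
            return False  # merging would close a cycle
        # merge v into u
        self.members[u].update(self.members[v])
        for ref in [CharRef(s, p) for s, p in self.members[v].items()]:
            self._where[ref] = u
        for p in self.pred[v]:
            self.succ[p].discard(v)
            self.succ[p].add(u)
            self.pred[u].add(p)
        for s_ in self.succ[v]:
            self.pred[s_].discard(v)
            self.pred[s_].add(u)
            self.succ[u].add(s_)
        del self.members[v], self.succ[v], self.pred[v]
        return True

    def _node_key(self, node: int) -> tuple[int, int]:
        return min(self.members[node].items())

    def topological_columns(self) -> list[dict[int, int]]:
        """Nodes in a deterministic topological order, as member maps."""
        indeg = {n: len(p) for n, p in self.pred.items()}
        ready = [(self._node_key(n), n) for n, d in indeg.items() if d == 0]
        heapq.heapify(ready)
        out = []
        while ready:
            _, node = heapq.heappop(ready)
            out.append(dict(self.members[node]))
            for nxt in self.succ[node]:
                indeg[nxt] -= 1
                if indeg[nxt] == 0:
                    heapq.heappush(ready, (self._node_key(nxt), nxt))
        if len(out) != len(self.members):
            raise InvariantError("column graph contains a cycle")
        return out


class ScoredPair(NamedTuple):
    a: CharRef
    b: CharRef
    probability: float


def sort_pairs(
    posteriors: PosteriorSet, cutoff: float = DEFAULT_SPARSITY_CUTOFF
) -> list[ScoredPair]:
    """All cross-sequence residue pairs with posterior >= cutoff, sorted by
    descending probability; ties broken by (seq, pos, seq, pos) ascending."""
    items: list[tuple[float, int, int, int, int]] = []
    for i, j in posteriors.pairs():
        mat = posteriors.get(i, j)
        for pi, pj in zip(*(mat >= max(cutoff, 1e-300)).nonzero()):
            p = mat[pi, pj]
            if p >= cutoff and p > 0:
                items.append((-p, i, int(pi), j, int(pj)))
    items.sort()
    return [
        ScoredPair(CharRef(i, pi), CharRef(j, pj), -negp)
        for negp, i, pi, j, pj in items
    ]


def anneal(
    family: Family,
    posteriors: PosteriorSet,
    cutoff: float = DEFAULT_SPARSITY_CUTOFF,
) -> Alignment:
    """Greedy sequence annealing; returns a valid alignment of the family."""
    graph = ColumnGraph([len(s) for s in family])
    for pair in sort_pairs(posteriors, cutoff):
        graph.try_insert(pair.a, pair.b)
    return alignment_from_graph(graph, family)


def alignment_from_graph(graph: ColumnGraph, family: Family) -> Alignment:
    """Emit one column per topologically sorted same-column set."""
    columns = graph.topological_columns()
    rows = []
    for s, seq in enumerate(family):
        chars = []
        for col in columns:
            pos = col.get(s)
            chars.append(seq.residues[pos] if pos is not None else GAP)
        rows.append((seq.id, "".join(chars)))
    return Alignment(rows)
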