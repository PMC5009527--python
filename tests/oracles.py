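"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or via a
third-party library, staying independent of the implementation path it
checks.
"""

from __future__ import annotations

import numpy as np


# -- global alignment by exhaustive enumeration ---------------------------


def enumerate_global_alignments(x: str, y: str):
    """Yield every global alignment as a list of (i, j) ops.

    Ops are 0-based index pairs; (i, -1) consumes x[i] against a gap,
    (-1, j) a gap against y[j].
    """

    def rec(i, j, ops):
        if i == len(x) and j == len(y):
            yield list(ops)
            return
        if i < len(x) and j < len(y):
            ops.append((i, j))
            yield from rec(i + 1, j + 1, ops)
            ops.pop()
        if i < len(x):
            ops.append((i, -1))
            yield from rec(i + 1, j, ops)
            ops.pop()
        if j < len(y):
            ops.append((-1, j))
            yield from rec(i, j + 1, ops)
            ops.pop()

    yield from rec(0, 0, [])


def score_alignment(ops, x, y, submat, gap_open, gap_extend):
    """Affine-gap score: a gap run of length k costs open + (k-1)*extend."""
    score = 0.0
    prev_gap = None  # 'x' or 'y' run marker
    for i, j in ops:
        if i >= 0 and j >= 0:
            score += submat[x[i], y[j]]
            prev_gap = None
        else:
            kind = "x" if j < 0 else "y"
            score -= gap_extend if prev_gap == kind else gap_open
            prev_gap = kind
    return score


def optimal_identity_fractions(x, y, submat, gap_open=10.0, gap_extend=1.0):
    """Identity fractions (identities / aligned columns) achievable by
    *any* optimal global alignment, as a set, plus the optimal score."""
    best = None
    fractions = set()
    for ops in enumerate_global_alignments(x, y):
        s = score_alignment(ops, x, y, submat, gap_open, gap_extend)
        matched = [(i, j) for i, j in ops if i >= 0 and j >= 0]
        ident = sum(1 for i, j in matched if x[i] == y[j])
        frac = ident / len(matched) if matched else 0.0
        if best is None or s > best + 1e-9:
            best = s
            fractions = {frac}
        elif abs(s - best) <= 1e-9:
            fractions.add(frac)
    return fractions, best


# -- pair-HMM posterior by exhaustive path enumeration --------------------


def enumerate_pair_posterior(x: str, y: str, model) -> np.ndarray:
    """Posterior match probabilities by summing over every state path."""
    xc, yc = model.encode(x), model.encode(y)
    e_match = model.pair_emission(xc, yc)
    e_x = model.single_emission(xc)
    e_y = model.single_emission(yc)
    lx, ly = len(x), len(y)
    total = 0.0
    post = np.zeros((lx, ly))

    def rec(i, j, state, prob, matches):
        nonlocal total
        if i == lx and j == ly:
            p = prob * model.end[state]
            total += p
            for mi, mj in matches:
                post[mi, mj] += p
            return
        for t in range(model.n_states):
            kind = model.kinds[t]
            tp = model.init[t] if state is None else model.trans[state, t]
            if tp == 0.0:
                continue
            if kind == "M" and i < lx and j < ly:
                matches.append((i, j))
                rec(i + 1, j + 1, t, prob * tp * e_match[i, j], matches)
                matches.pop()
            elif kind == "X" and i < lx:
                rec(i + 1, j, t, prob * tp * e_x[i], matches)
            elif kind == "Y" and j < ly:
                rec(i, j + 1, t, prob * tp * e_y[j], matches)

    rec(0, 0, None, 1.0, [])
    return post / total


# -- agglomerative clustering via scipy -----------------------------------


def scipy_linkage_partitions(dist: np.ndarray, method: str):
    """Merge heights and leaf partitions from scipy's linkage.

    ``method`` is "average" (= size-weighted UPGMA update) or "weighted"
    (= equal-weighted WPGMA update).  Returns a list of
    (height, frozenset of leaf indices) per internal node.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    z = linkage(squareform(dist, checks=False), method=method)
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, h, _) in enumerate(z):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[n + k] = merged
        out.append((float(h), merged))
    return out


# -- annealing consistency via networkx transitive closure ----------------


class NxColumnOracle:
    """Replays pair insertions with networkx doing all graph reasoning."""

    def __init__(self, lengths):
        import networkx as nx

        self.nx = nx
        self.g = nx.DiGraph()
        self.where = {}
        node = 0
        for s, length in enumerate(lengths):
            prev = None
            for p in range(length):
                self.g.add_node(node, members={(s, p)})
                self.where[(s, p)] = node
                if prev is not None:
                    self.g.add_edge(prev, node)
                prev = node
                node += 1

    def try_insert(self, a, b) -> bool:
        u, v = self.where[a], self.where[b]
        if u == v:
            return True
        mu = self.g.nodes[u]["members"]
        mv = self.g.nodes[v]["members"]
        if {s for s, _ in mu} & {s for s, _ in mv}:
            return False
        if self.nx.has_path(self.g, u, v) or self.nx.has_path(self.g, v, u):
            return False
        for ref in mv:
            self.where[ref] = u
        self.g.nodes[u]["members"] = mu | mv
        for p in list(self.g.predecessors(v)):
            if p != u:
                self.g.add_edge(p, u)
        for s_ in list(self.g.successors(v)):
            if s_ != u:
                self.g.add_edge(u, s_)
        self.g.remove_node(v)
        return True

    def is_dag(self) -> bool:
        return self.nx.is_directed_acyclic_graph(self.g)
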