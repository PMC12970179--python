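"""Self-supervised pre-training targets for the text and graph views.

Four label generators:

* :func:`mlm_mask` — masked-language-model positions over a SMILES token
  sequence (default rate 0.15).
* :func:`mask_graph_features` — masked-feature positions drawn jointly over
  node and edge tokens of the molecular graph (default rate 0.85).
* :func:`corrupt_edges` — rewires a fraction of edges to random endpoints
  and labels every edge corrupted/original (default rate 0.15).
* :func:`betti_targets` — per-node topological targets: the Betti numbers
  (beta0, beta1) of the k-hop subgraph around each node.  beta0 counts
  connected components, beta1 counts independent cycles (the cycle rank
  |E| - |V| + beta0).

All plans are deterministic given their seed.  Counts use nearest-integer
rounding of ``rate * n`` with exact ties rounded down and a floor of 0;
rounding ties down keeps the pooled masked/corrupted fraction close to the
nominal rate for small token and edge counts, where rounding ties up would
bias it upward (a 10-edge molecule at rate 0.15 would otherwise always get
2 corrupted edges, i.e. 20%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from mvmol.views import GraphView, TextView

DEFAULT_MLM_RATE = 0.15
DEFAULT_GRAPH_MASK_RATE = 0.85
DEFAULT_EDGE_CORRUPT_RATE = 0.15

#: Betti targets above this value are clipped when used as classification
#: labels; raw values are always retained on the target object.
DEFAULT_BETTI_CLIP = 8


def _round_count(rate: float, n: int) -> int:
    """Nearest-integer rounding of rate * n with ties down, clipped to [0, n]."""
    return min(n, max(0, int(math.ceil(rate * n - 0.5))))


@dataclass(frozen=True)
class MaskingPlan:
    """A reproducible set of token positions to mask."""

    positions: frozenset[int]
    rate: float
    seed: int
    n_tokens: int

    @property
    def n_masked(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class EdgeCorruptionPlan:
    """Per-edge corruption labels and the rewired endpoints.

    ``replacement_endpoints`` maps a corrupted edge index to its new
    (i, j) endpoint pair; ``labels`` is 1 for corrupted edges, 0 for
    originals, aligned with the view's edge order.
    """

    corrupted_edges: frozenset[int]
    replacement_endpoints: dict[int, tuple[int, int]]
    labels: np.ndarray
    rate: float
    seed: int


@dataclass(frozen=True)
class BettiTargets:
    """Per-node (beta0, beta1) of the radius-hop induced subgraph.

    ``values`` is an (n_nodes, 2) integer array; ``clipped`` the same with
    entries capped at ``clip`` for use as classification labels.
    """

    values: np.ndarray
    radius: int
    clip: int = DEFAULT_BETTI_CLIP

    @property
    def clipped(self) -> np.ndarray:
        return np.minimum(self.values, self.clip)


def mlm_mask(
    view: TextView, rate: float = DEFAULT_MLM_RATE, seed: int = 0
) -> MaskingPlan:
    """Choose masked-token positions for masked-language-model pre-training.

    Samples ``round(rate * n_maskable)`` positions uniformly without
    replacement among non-reserved tokens; reserved tokens (pad, mask,
    unknown, begin, end) are never masked.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    reserved = view.vocabulary.reserved_ids
    maskable = [i for i, tid in enumerate(view.token_ids) if tid not in reserved]
    k = _round_count(rate, len(maskable))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(maskable), size=k, replace=False) if k else []
    positions = frozenset(maskable[i] for i in chosen)
    return MaskingPlan(positions=positions, rate=rate, seed=seed, n_tokens=len(view))


def mask_graph_features(
    view: GraphView, rate: float = DEFAULT_GRAPH_MASK_RATE, seed: int = 0
) -> MaskingPlan:
    """Choose graph tokens (atoms and bonds jointly) whose features to mask.

    Token indices 0..|V|-1 address atoms and |V|..|V|+|E|-1 address bonds.
    Masking replaces the categorical feature vector with a sentinel at
    training time; this plan only records positions.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    n = view.n_tokens
    if n == 0:
        raise ValueError("empty token sequence")
    k = _round_count(rate, n)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=k, replace=False) if k else []
    return MaskingPlan(
        positions=frozenset(int(i) for i in chosen), rate=rate, seed=seed, n_tokens=n
    )


def corrupt_edges(
    view: GraphView, rate: float = DEFAULT_EDGE_CORRUPT_RATE, seed: int = 0
) -> EdgeCorruptionPlan:
    """Rewire a fraction of edges and emit corrupted/original labels.

    For each selected edge one endpoint is replaced by a uniformly chosen
    different node, so every corrupted edge differs from its original
    endpoint pair; edge features are left unchanged.  Graphs with fewer
    than two nodes yield an empty plan.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    n_edges = view.n_edges
    labels = np.zeros(n_edges, dtype=np.int64)
    if view.n_atoms < 2 or n_edges == 0:
        return EdgeCorruptionPlan(
            corrupted_edges=frozenset(),
            replacement_endpoints={},
            labels=labels,
            rate=rate,
            seed=seed,
        )
    k = _round_count(rate, n_edges)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_edges, size=k, replace=False) if k else np.array([], dtype=int)
    replacements: dict[int, tuple[int, int]] = {}
    for e in sorted(int(i) for i in chosen):
        i, j = (int(v) for v in view.edges[e])
        which = int(rng.integers(0, 2))  # which endpoint to rewire
        keep, move = (i, j) if which else (j, i)
        candidates = [v for v in range(view.n_atoms) if v != move and v != keep]
        new = int(rng.choice(candidates)) if candidates else move
        pair = (keep, new) if which == 0 else (new, keep)
        if {pair[0], pair[1]} == {i, j}:  # pragma: no cover - excluded above
            continue
        replacements[e] = pair
        labels[e] = 1
    return EdgeCorruptionPlan(
        corrupted_edges=frozenset(replacements),
        replacement_endpoints=replacements,
        labels=labels,
        rate=rate,
        seed=seed,
    )


def _adjacency(view: GraphView) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(view.n_atoms)]
    for i, j in view.edges:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    return adj


def _khop_nodes(adj: list[list[int]], start: int, radius: int) -> set[int]:
    seen = {start}
    frontier = [start]
    for _ in range(radius):
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        if not nxt:
            break
        frontier = nxt
    return seen


def _betti_of_subgraph(nodes: set[int], adj: list[list[int]]) -> tuple[int, int]:
    """(beta0, beta1) of the induced subgraph on ``nodes``.

    beta0 by breadth-first component counting; beta1 from the Euler
    relation beta1 = |E| - |V| + beta0 of a 1-complex.
    """
    n_edges = 0
    unvisited = set(nodes)
    beta0 = 0
    for u in nodes:
        for v in adj[u]:
            if v in nodes and u < v:
                n_edges += 1
    while unvisited:
        beta0 += 1
        stack = [unvisited.pop()]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v in unvisited:
                    unvisited.remove(v)
                    stack.append(v)
    return beta0, n_edges - len(nodes) + beta0


def betti_targets(
    view: GraphView, radius: int = 2, clip: int = DEFAULT_BETTI_CLIP
) -> BettiTargets:
    """Per-node Betti-number targets over radius-hop induced subgraphs.

    For each node v the induced subgraph S_v contains every node within
    ``radius`` hops of v and all edges among them.  The target pair is
    (beta0(S_v), beta1(S_v)).  Since S_v is induced around a single seed
    node it is connected, but beta0 is computed rather than assumed so the
    same routine serves arbitrary node subsets.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    adj = _adjacency(view)
    values = np.empty((view.n_atoms, 2), dtype=np.int64)
    for v in range(view.n_atoms):
        nodes = _khop_nodes(adj, v, radius)
        values[v] = _betti_of_subgraph(nodes, adj)
    return BettiTargets(values=values, radius=radius, clip=clip)


def betti_of_graph(view: GraphView) -> tuple[int, int]:
    """(beta0, beta1) of the full molecular graph."""
    adj = _adjacency(view)
    return _betti_of_subgraph(set(range(view.n_atoms)), adj)
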