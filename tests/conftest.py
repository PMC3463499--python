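"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
shortest paths are recomputed with a hand-rolled BFS, motifs and minimal
hitting sets by exhaustive enumeration, and confusion counts by a naive
per-cell double loop.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np
import pytest

from grnpipe import GeneNetwork, generate_network


# -- fixtures --------------------------------------------------------------


@pytest.fixture(autouse=True)
def _quiet_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def gold_fixture():
    """A 15-gene fully-known gold network with positives and negatives in
    every feature domain (master targets, strict/wide ectoderm and mesoderm)."""
    gt = generate_network(
        15,
        module_sizes={"initiation": 3, "ectoderm": 4, "mesoderm": 3, "mixed": 3, "other": 2},
        density=0.3,
        q=3,
        seed=42,
    )
    net = gt.network
    nodes, mm, adj = net.nodes, net.module_map, net.adjacency
    master = nodes[0]
    ecto = [n for n in nodes if mm[n] == "ectoderm"]
    meso = [n for n in nodes if mm[n] == "mesoderm"]

    def ensure_edge(pairs):
        if not any(adj[net.index(i), net.index(j)] == 1 for i, j in pairs):
            i, j = pairs[0]
            adj[net.index(i), net.index(j)] = 1

    ensure_edge([(i, master) for i in nodes if i != master])
    ensure_edge([(a, b) for a in ecto for b in ecto if a != b])
    ensure_edge([(a, b) for a in meso for b in meso if a != b])
    return net, master


# -- oracles ---------------------------------------------------------------


def bfs_path_lengths(nodes, arcs):
    """Ordered-pair shortest path lengths by plain BFS over an arc set."""
    out = {}
    adjacency = {u: [] for u in nodes}
    for u, v in arcs:
        adjacency[u].append(v)
    for s in nodes:
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for t, d in dist.items():
            if t != s:
                out[(s, t)] = d
    return out


def brute_force_motifs(nodes, arcs):
    """Exhaustive pair/triple enumeration of 2-cycles, FFLs and 3-feedback loops."""
    arcset = set(arcs)
    pos = {n: k for k, n in enumerate(nodes)}
    two = sorted(
        tuple(sorted((a, b)))
        for a, b in itertools.combinations(nodes, 2)
        if (a, b) in arcset and (b, a) in arcset
    )
    ffl, fbl = set(), set()
    for a, b, c in itertools.permutations(nodes, 3):
        if (a, b) in arcset and (b, c) in arcset and (a, c) in arcset:
            ffl.add((a, b, c))
        if (a, b) in arcset and (b, c) in arcset and (c, a) in arcset:
            # one loop per rotation class, anchored at its first-listed node
            fbl.add(min([(a, b, c), (b, c, a), (c, a, b)], key=lambda t: pos[t[0]]))
    return two, sorted(ffl), sorted(fbl)


def brute_force_minimal_hitting_sets(collection, n_vars):
    """All minimal hitting sets by bitmask subset enumeration."""
    masks = [sum(1 << v for v in s) for s in collection]
    hitting = [
        m for m in range(1 << n_vars) if all(m & dm for dm in masks)
    ]
    minimal = []
    for m in sorted(hitting, key=lambda m: bin(m).count("1")):
        if not any((k & m) == k for k in minimal):
            minimal.append(m)
    return sorted(
        frozenset(v for v in range(n_vars) if m & (1 << v)) for m in minimal
    )


def naive_confusion(model: GeneNetwork, gold: GeneNetwork, pairs):
    """Per-cell double loop mirroring the published count definitions."""
    TP = TN = HR = FP = FN = 0
    for i, j in pairs:
        m = model.entry(i, j)
        g = gold.entry(i, j)
        if math.isnan(m) or math.isnan(g):
            continue
        if m == 1 and g in (1, -1):
            TP += 1
        elif m == 1 and g == 0:
            FP += 1
        elif m == -1 and g == 1:
            HR += 1
        elif m == -1 and g == -1:
            TP += 1
        elif m == -1 and g == 0:
            FP += 1
        elif m == 0 and g in (1, -1):
            FN += 1
        elif m == 0 and g == 0:
            TN += 1
    return TP, TN, HR, FP, FN


def random_mixed_network(rng, n, p_unknown=0.2):
    """Random mixed graph with valid symmetric undirected entries."""
    adj = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = rng.random()
            if r < p_unknown:
                adj[i, j] = adj[j, i] = math.nan
            elif r < p_unknown + 0.15:
                adj[i, j] = adj[j, i] = -1
            else:
                adj[i, j] = rng.choice([0, 0, 1])
                adj[j, i] = rng.choice([0, 0, 1])
    nodes = [f"n{k}" for k in range(n)]
    return GeneNetwork(nodes, adj)
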