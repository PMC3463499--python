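"""Synthetic ground truth: networks, discrete dynamics, and evidence tables.

Everything downstream — the evidence rule system, discretization, the
minimal-sets inference, the pipeline combiners and the assessment metrics —
can be exercised against a known answer by generating (i) a random directed
regulatory network with module labels, (ii) time courses of a finite
dynamical system driven by that network (each node updates through a random
q-state lookup table over its parents, states mapped affinely to real
abundances with optional Gaussian noise), and (iii) an evidence table whose
rule-based classification reproduces the network exactly at zero corruption.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .graph import DIRECTED, ABSENT, GeneNetwork, GraphValueError, ProbeMap
from .inference import DiscreteTimeCourse, ExpressionTimeCourse
from .knowledge import EvidenceRecord

DEFAULT_MODULE_SIZES = {
    "initiation": 1,
    "ectoderm": 3,
    "mesoderm": 3,
    "mixed": 2,
    "other": 1,
}


@dataclass
class GroundTruth:
    """A known network plus the update rules that drive its dynamics.

    ``parents[node]`` lists the node indices feeding node's update table;
    ``tables[node]`` maps each combination of parent states (odometer order)
    to the node's next state.  A node with no parents holds a constant.
    """

    network: GeneNetwork
    q: int
    parents: dict[str, tuple[int, ...]]
    tables: dict[str, np.ndarray]
    seed: int | None = None

    @property
    def nodes(self) -> list[str]:
        return self.network.nodes

    def step(self, state: np.ndarray) -> np.ndarray:
        """One synchronous update of the finite dynamical system."""
        nxt = np.empty_like(state)
        for i, node in enumerate(self.nodes):
            ps = self.parents[node]
            table = self.tables[node]
            if ps:
                nxt[i] = table[tuple(state[list(ps)])]
            else:
                nxt[i] = table[()]
        return nxt


def generate_network(
    n: int,
    module_sizes: Mapping[str, int] | None = None,
    density: float = 0.15,
    q: int = 3,
    no_crosstalk: bool = False,
    seed: int | None = None,
    max_parents: int = 12,
) -> GroundTruth:
    """Random ground-truth network with q-state update tables.

    Each ordered off-diagonal pair becomes a directed edge independently
    with probability ``density``; non-edges are explicit 0 (the truth is
    fully known).  Module labels follow ``module_sizes`` in node order.
    With ``no_crosstalk`` the generator never places an ectoderm->mesoderm
    or mesoderm->ectoderm edge, mirroring the tissue constraint the
    inference step can exploit.
    """
    if n < 2:
        raise GraphValueError("need at least 2 nodes")
    if not 0 < density < 1:
        raise GraphValueError("density must lie strictly between 0 and 1")
    if module_sizes is None:
        module_sizes = dict(DEFAULT_MODULE_SIZES)
        # scale the default allotment to n, padding/truncating "other"
        total = sum(module_sizes.values())
        if total != n:
            module_sizes = _fit_module_sizes(n)
    if sum(module_sizes.values()) != n:
        raise GraphValueError(
            f"module sizes {dict(module_sizes)} do not sum to n={n}"
        )
    rng = np.random.default_rng(seed)
    nodes = [f"g{k:02d}" for k in range(n)]
    module_map: dict[str, str] = {}
    cursor = 0
    for module, size in module_sizes.items():
        for _ in range(size):
            module_map[nodes[cursor]] = module
            cursor += 1

    adj = np.zeros((n, n))
    for i in range(n):  # target
        for j in range(n):  # source
            if i == j:
                continue
            mi, mj = module_map[nodes[i]], module_map[nodes[j]]
            if no_crosstalk and {mi, mj} == {"ectoderm", "mesoderm"} and mi != mj:
                continue
            if rng.random() < density:
                adj[i, j] = DIRECTED

    parents: dict[str, tuple[int, ...]] = {}
    tables: dict[str, np.ndarray] = {}
    for i, node in enumerate(nodes):
        ps = tuple(int(j) for j in np.flatnonzero(adj[i] == DIRECTED))
        if len(ps) > max_parents:
            raise GraphValueError(
                f"node {node} has {len(ps)} parents; raise max_parents or lower density"
            )
        parents[node] = ps
        if ps:
            tables[node] = rng.integers(0, q, size=(q,) * len(ps))
        else:
            tables[node] = np.array(rng.integers(0, q))
    net = GeneNetwork(nodes, adj, module_map)
    return GroundTruth(network=net, q=q, parents=parents, tables=tables, seed=seed)


def _fit_module_sizes(n: int) -> dict[str, int]:
    sizes = dict(DEFAULT_MODULE_SIZES)
    total = sum(sizes.values())
    if n >= total:
        sizes["other"] += n - total
        return sizes
    # shrink from the back for very small networks
    for module in ("other", "mixed", "mesoderm", "ectoderm"):
        while sum(sizes.values()) > n and sizes[module] > (0 if module != "ectoderm" else 1):
            sizes[module] -= 1
    sizes = {m: s for m, s in sizes.items() if s > 0}
    if sum(sizes.values()) != n:
        raise GraphValueError(f"cannot fit default modules to n={n}")
    return sizes


def simulate_timecourse(
    gt: GroundTruth,
    T: int = 20,
    n_series: int = 2,
    noise_sd: float = 0.0,
    spacing: float = 1.0,
    offset: float = 1.0,
    seed: int | None = None,
) -> tuple[ExpressionTimeCourse, DiscreteTimeCourse]:
    """Simulate trajectories and map states to real abundances.

    Each series starts from a uniform random initial state and follows the
    synchronous dynamics for ``T`` points.  Abundance = offset + spacing *
    state + N(0, noise_sd).  At zero noise, equal-frequency discretization
    with matching q recovers the simulated state sequence exactly for any
    probe that visits all q states (fewer visited states are recovered up to
    an order-preserving relabeling).  Returns the continuous time course and
    the true discrete one.
    """
    if T < 2:
        raise GraphValueError("need at least 2 time points per series")
    rng = np.random.default_rng(seed)
    n = len(gt.nodes)
    states = np.zeros((n, T * n_series), dtype=int)
    col = 0
    for _ in range(n_series):
        state = rng.integers(0, gt.q, size=n)
        for _t in range(T):
            states[:, col] = state
            state = gt.step(state)
            col += 1
    values = offset + spacing * states.astype(float)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    probe_map = ProbeMap.identity(gt.nodes)
    tc = ExpressionTimeCourse(
        probes=list(gt.nodes),
        values=values,
        series_lengths=[T] * n_series,
        probe_map=probe_map,
    )
    dtc = DiscreteTimeCourse(
        probes=list(gt.nodes),
        values=states,
        series_lengths=[T] * n_series,
        q=gt.q,
        probe_map=probe_map,
    )
    return tc, dtc


def generate_evidence(
    gt: GroundTruth,
    flip_rate: float = 0.0,
    seed: int | None = None,
) -> list[EvidenceRecord]:
    """Evidence table whose rule-based calls reproduce the network.

    Every true edge gets a record satisfying one randomly chosen directed
    clause of the rule system (strong perturbation, perturbation plus
    one-hybrid, repeated directional genetic reports, or perturbation plus a
    single genetic report); every non-edge gets an all-zero record (an
    explicit non-interaction).  With probability ``flip_rate`` a record is
    corrupted into the unknown region (sub-threshold significance with a
    non-zero fold change), erasing the pair's information.
    """
    if not 0 <= flip_rate < 1:
        raise GraphValueError("flip_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    records = []
    nodes = gt.nodes
    adj = gt.network.adjacency
    for i, target in enumerate(nodes):
        for j, source in enumerate(nodes):
            if i == j:
                continue
            if rng.random() < flip_rate:
                records.append(
                    EvidenceRecord(
                        target=target,
                        source=source,
                        sig=float(np.round(rng.uniform(0.1, 1.9), 3)),
                        mag=float(np.round(rng.uniform(0.1, 1.9), 3)),
                        y1h=0,
                        gen=0,
                    )
                )
                continue
            if adj[i, j] == DIRECTED:
                clause = rng.integers(0, 4)
                sig = float(np.round(rng.uniform(2.0, 6.0), 3))
                if clause == 0:
                    rec = EvidenceRecord(target, source, sig=sig, mag=float(np.round(rng.uniform(2.0, 8.0), 3)))
                elif clause == 1:
                    rec = EvidenceRecord(target, source, sig=sig, y1h=1)
                elif clause == 2:
                    rec = EvidenceRecord(target, source, gen=int(rng.integers(2, 4)))
                else:
                    rec = EvidenceRecord(target, source, sig=sig, gen=int(rng.choice([-1, 1])))
                records.append(rec)
            else:
                records.append(EvidenceRecord(target, source))
    return records


def probe_split(
    tc: ExpressionTimeCourse,
    genes_to_split: Mapping[str, int],
    jitter_sd: float = 0.0,
    seed: int | None = None,
) -> ExpressionTimeCourse:
    """Duplicate selected genes' rows into multiple probes with jitter.

    Emulates genes measured by several microarray probes.  The probe map is
    rewritten so the duplicated probes all map back to their gene; with zero
    jitter the duplicates are identical and are maximally coupled by the
    covariance step.
    """
    rng = np.random.default_rng(seed)
    base_map = tc.probe_map or ProbeMap.identity(tc.probes)
    for gene in genes_to_split:
        if gene not in base_map.genes:
            raise GraphValueError(f"gene {gene!r} not in the time course")
        if genes_to_split[gene] < 1:
            raise GraphValueError(f"split count for {gene!r} must be >= 1")
    new_probes: list[str] = []
    new_map: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for i, probe in enumerate(tc.probes):
        gene = base_map.gene_of(probe)
        k = genes_to_split.get(gene, 1)
        if k == 1:
            new_probes.append(probe)
            new_map[probe] = gene
            rows.append(tc.values[i])
        else:
            for rep in range(1, k + 1):
                name = f"{probe}__p{rep}"
                new_probes.append(name)
                new_map[name] = gene
                row = tc.values[i].copy()
                if jitter_sd > 0:
                    row = row + rng.normal(0.0, jitter_sd, size=row.shape)
                rows.append(row)
    return ExpressionTimeCourse(
        probes=new_probes,
        values=np.vstack(rows),
        series_lengths=list(tc.series_lengths),
        probe_map=ProbeMap(new_map),
    )
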