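"""Data-driven network inference from wild-type time-course expression data.

The pipeline combines two complementary methods:

* **COV** — a thresholded sample variance-covariance matrix over all probes.
  Pairs whose covariance reaches the threshold (the median of the whole
  matrix) are coupled by an undirected edge.  Covariance finds many
  relationships but carries no directionality.
* **MSA (Minimal Sets Algorithm)** — an algebraic method over discretized
  time series.  For every target it enumerates *all* subset-minimal sets of
  variables capable of explaining the observed output changes (minimal
  hitting sets of the difference sets between transition pairs with
  different target outputs), then selects one candidate set per target by a
  frequency-based score under a "no cross-talk" preference.  MSA yields few
  but directed edges.

The two adjacency matrices are combined in either order (MSA-COV or
COV-MSA) at probe level and then collapsed to the gene level by the
unanimity rule, yielding the mathematically inferred model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import (
    ABSENT,
    DIRECTED,
    UNDIRECTED,
    GeneNetwork,
    GraphValueError,
    ProbeMap,
    collapse_probes,
)


class InferenceError(ValueError):
    """Raised for invalid inference inputs (e.g. inconsistent transitions)."""


# -- time-course containers ------------------------------------------------


@dataclass
class ExpressionTimeCourse:
    """Real-valued probe x time-point expression matrix.

    ``series_lengths`` partitions the columns into independent time series
    (e.g. two genotypes profiled over the same developmental window);
    transitions are never taken across a series boundary.
    """

    probes: list[str]
    values: np.ndarray  # probes x total time points
    series_lengths: list[int]
    probe_map: ProbeMap | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.probes):
            raise InferenceError("values must be a probes x time matrix")
        if sum(self.series_lengths) != self.values.shape[1]:
            raise InferenceError(
                f"series lengths {self.series_lengths} do not sum to "
                f"{self.values.shape[1]} time points"
            )
        if any(t < 2 for t in self.series_lengths):
            raise InferenceError("every series needs at least 2 time points")
        if np.isnan(self.values).any():
            raise InferenceError("missing values are not supported")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def series_slices(self) -> list[slice]:
        out, start = [], 0
        for t in self.series_lengths:
            out.append(slice(start, start + t))
            start += t
        return out


@dataclass
class DiscreteTimeCourse:
    """Discretized counterpart of :class:`ExpressionTimeCourse`; values in 0..q-1."""

    probes: list[str]
    values: np.ndarray
    series_lengths: list[int]
    q: int
    probe_map: ProbeMap | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        if (self.values < 0).any() or (self.values >= self.q).any():
            raise InferenceError(f"discrete values must lie in 0..{self.q - 1}")

    def series_slices(self) -> list[slice]:
        out, start = [], 0
        for t in self.series_lengths:
            out.append(slice(start, start + t))
            start += t
        return out


@dataclass
class TransitionSet:
    """Consecutive-time input/output pairs pooled across series.

    ``inputs[k]`` is the full state vector at some time t and ``outputs[k]``
    the state vector at t+1 of the same series; ``origins[k]`` records
    (series index, time index within series) for error reporting.
    """

    probes: list[str]
    inputs: np.ndarray  # n_transitions x n_probes
    outputs: np.ndarray  # n_transitions x n_probes
    origins: list[tuple[int, int]]

    @property
    def n_transitions(self) -> int:
        return self.inputs.shape[0]


# -- discretization --------------------------------------------------------


def _equal_frequency(row: np.ndarray, q: int) -> np.ndarray:
    distinct = np.unique(row)
    if len(distinct) <= q:
        # each observed level gets its own state, ordered by value
        return np.searchsorted(distinct, row)
    codes = pd.qcut(row, q, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=int)


def _equal_width(row: np.ndarray, q: int) -> np.ndarray:
    lo, hi = row.min(), row.max()
    if lo == hi:
        return np.zeros_like(row, dtype=int)
    edges = np.linspace(lo, hi, q + 1)
    codes = np.clip(np.digitize(row, edges[1:-1], right=True), 0, q - 1)
    return codes.astype(int)


def _agglomerative(row: np.ndarray, q: int) -> np.ndarray:
    """Single-link merging of adjacent value levels until <= q clusters."""
    distinct = list(np.unique(row))
    clusters = [[v] for v in distinct]
    while len(clusters) > q:
        gaps = [clusters[k + 1][0] - clusters[k][-1] for k in range(len(clusters) - 1)]
        k = int(np.argmin(gaps))
        clusters[k] = clusters[k] + clusters.pop(k + 1)
    level = {v: idx for idx, cluster in enumerate(clusters) for v in cluster}
    return np.array([level[v] for v in row], dtype=int)


_DISCRETIZERS: dict[str, Callable[[np.ndarray, int], np.ndarray]] = {
    "equal-frequency": _equal_frequency,
    "equal-width": _equal_width,
    "agglomerative": _agglomerative,
}


def discretize(
    tc: ExpressionTimeCourse,
    q: int = 7,
    method: str = "equal-frequency",
    joint_series: bool = True,
) -> DiscreteTimeCourse:
    """Discretize each probe independently into at most ``q`` states.

    ``joint_series=True`` (default) pools all series of a probe into one
    binning; ``False`` bins each series separately.  A probe with fewer
    distinct values than ``q`` uses fewer states (with a warning), and a
    constant probe maps to the single state 0.  Deterministic for a fixed
    input and method.
    """
    if q < 2:
        raise InferenceError("q must be at least 2")
    try:
        fn = _DISCRETIZERS[method]
    except KeyError:
        raise InferenceError(f"unknown discretization method {method!r}") from None
    out = np.zeros_like(tc.values, dtype=int)
    blocks = [slice(None)] if joint_series else tc.series_slices()
    short = []
    for i, probe in enumerate(tc.probes):
        for block in blocks:
            row = tc.values[i, block]
            if len(np.unique(row)) < q:
                short.append(probe)
            out[i, block] = fn(row, q)
    if short:
        warnings.warn(
            f"{len(set(short))} probe(s) have fewer distinct values than q; "
            f"fewer states used: {sorted(set(short))[:5]}..."
        )
    return DiscreteTimeCourse(
        probes=list(tc.probes),
        values=out,
        series_lengths=list(tc.series_lengths),
        q=q,
        probe_map=tc.probe_map,
    )


def extract_transitions(dtc: DiscreteTimeCourse) -> TransitionSet:
    """Collect consecutive-pair transitions within each series.

    A series of T points contributes T-1 transitions; the end of one series
    never feeds into the start of the next.
    """
    inputs, outputs, origins = [], [], []
    for s_idx, block in enumerate(dtc.series_slices()):
        states = dtc.values[:, block]
        for t in range(states.shape[1] - 1):
            inputs.append(states[:, t])
            outputs.append(states[:, t + 1])
            origins.append((s_idx, t))
    return TransitionSet(
        probes=list(dtc.probes),
        inputs=np.array(inputs, dtype=int),
        outputs=np.array(outputs, dtype=int),
        origins=origins,
    )


# -- minimal sets ----------------------------------------------------------


def _minimize_family(sets: Sequence[frozenset]) -> list[frozenset]:
    """Keep only the subset-minimal members (an antichain)."""
    out: list[frozenset] = []
    for s in sorted(set(sets), key=lambda s: (len(s), sorted(s))):
        if not any(t <= s for t in out):
            out.append(s)
    return out


def minimal_hitting_sets(collection: Sequence[frozenset]) -> list[frozenset]:
    """All subset-minimal hitting sets of a collection of non-empty sets.

    Incremental construction: maintain the minimal hitting sets of the
    first k sets; to absorb set D, keep members that already hit D and
    extend each member that misses D by every element of D, minimizing
    after each step.  An empty collection is hit by the empty set.
    """
    sets = _minimize_family([frozenset(s) for s in collection])
    if any(not s for s in sets):
        raise InferenceError("cannot hit an empty set")
    family: list[frozenset] = [frozenset()]
    for d in sets:
        hit = [h for h in family if h & d]
        extended = [h | {v} for h in family if not h & d for v in sorted(d)]
        family = _minimize_family(hit + extended)
    return sorted(family, key=lambda s: (len(s), sorted(s)))


@dataclass
class MinimalSetFamily:
    """All minimal candidate regulator sets for one target probe.

    The family is an antichain of variable-index sets, each of which
    intersects ("hits") every difference set between transition pairs with
    different target outputs.  ``variable_frequency[v]`` is the fraction of
    family members containing variable v; ``set_scores`` are the normalized
    products of member frequencies (a reconstruction of a frequency-based
    model score; see the scoring notes in the docs).
    """

    target: int
    sets: list[frozenset]
    variable_frequency: dict[int, float] = field(default_factory=dict)
    set_scores: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sets:
            raise InferenceError(f"empty minimal-set family for target {self.target}")
        if not self.variable_frequency:
            self._score()

    def _score(self) -> None:
        m = len(self.sets)
        freq: dict[int, float] = {}
        for s in self.sets:
            for v in s:
                freq[v] = freq.get(v, 0.0) + 1.0 / m
        raw = {
            s: float(np.prod([freq[v] for v in s])) if s else 1.0 for s in self.sets
        }
        total = sum(raw.values())
        self.variable_frequency = freq
        self.set_scores = {s: r / total for s, r in raw.items()}

    def best(
        self,
        candidates: Sequence[frozenset] | None = None,
        rng: np.random.Generator | None = None,
    ) -> frozenset:
        """Highest-scoring candidate; ties prefer smaller sets.

        Residual ties mean the data cannot distinguish the candidates at
        all; they are resolved uniformly at random from ``rng`` (so errors
        are not systematically biased toward any variable) or, without an
        rng, by lexicographic variable order.
        """
        pool = list(candidates) if candidates is not None else list(self.sets)
        best_key = max((self.set_scores[s], -len(s)) for s in pool)
        tied = sorted(
            (s for s in pool if (self.set_scores[s], -len(s)) == best_key),
            key=lambda s: sorted(s),
        )
        if len(tied) == 1 or rng is None:
            return tied[0]
        return tied[int(rng.integers(len(tied)))]


def minimal_sets(ts: TransitionSet, target: int | str, lenient: bool = False) -> MinimalSetFamily:
    """Minimal candidate regulator sets for ``target`` from transition data.

    For every pair of transitions whose target outputs differ, the
    difference set is the set of variables at which the two input states
    differ; the family is the antichain of minimal hitting sets of all
    difference sets.  A constant target output yields the family {{}} —
    a constant function depends on no variable.

    Two identical input states with different target outputs make the data
    inconsistent (an empty difference set cannot be hit).  By default this
    is an error naming the colliding transitions; with ``lenient=True`` the
    later conflicting transition is dropped with a warning.
    """
    if isinstance(target, str):
        target = ts.probes.index(target)
    inputs, outputs, origins = ts.inputs, ts.outputs[:, target], list(ts.origins)

    keep = list(range(len(origins)))
    if lenient:
        kept: list[int] = []
        for k in range(len(origins)):
            clash = next(
                (
                    p
                    for p in kept
                    if outputs[p] != outputs[k] and (inputs[p] == inputs[k]).all()
                ),
                None,
            )
            if clash is None:
                kept.append(k)
            else:
                warnings.warn(
                    f"target {ts.probes[target]}: dropping transition at "
                    f"(series, t)={origins[k]} conflicting with {origins[clash]}"
                )
        keep = kept

    diff_sets: list[frozenset] = []
    for a_pos in range(len(keep)):
        for b_pos in range(a_pos + 1, len(keep)):
            a, b = keep[a_pos], keep[b_pos]
            if outputs[a] == outputs[b]:
                continue
            diff = frozenset(np.flatnonzero(inputs[a] != inputs[b]).tolist())
            if not diff:
                raise InferenceError(
                    f"inconsistent transitions for target {ts.probes[target]!r}: "
                    f"identical inputs at (series, t)={origins[a]} and "
                    f"{origins[b]} with different outputs"
                )
            diff_sets.append(diff)
    family = minimal_hitting_sets(diff_sets)
    return MinimalSetFamily(target=target, sets=family)


def select_model(
    families: Sequence[MinimalSetFamily],
    probes: Sequence[str],
    module_map: Mapping[str, str] | None = None,
    crosstalk_policy: str = "prefer-no-crosstalk",
    rng: np.random.Generator | None = None,
) -> tuple[GeneNetwork, dict]:
    """Choose one minimal set per target and assemble the MSA adjacency.

    Under ``prefer-no-crosstalk`` (default), candidate sets that place an
    ectoderm variable in a mesoderm target's regulator set (or vice versa)
    are discarded — unless *every* candidate violates the constraint, in
    which case the unfiltered family is kept with a warning ("wherever
    possible").  Among survivors the highest-scoring set wins; ties prefer
    smaller sets, then the lexicographically first.  Returns the probe-level
    {+1, 0} network and a provenance dict of families/choices/discards.
    """
    if crosstalk_policy not in ("prefer-no-crosstalk", "off"):
        raise InferenceError(f"unknown crosstalk policy {crosstalk_policy!r}")
    n = len(probes)
    adj = np.zeros((n, n))
    provenance: dict = {"targets": {}}

    def _module(idx: int) -> str | None:
        return module_map.get(probes[idx]) if module_map else None

    for fam in families:
        target_module = _module(fam.target)
        discarded: list[frozenset] = []
        candidates = list(fam.sets)
        if crosstalk_policy == "prefer-no-crosstalk" and target_module in (
            "ectoderm",
            "mesoderm",
        ):
            other = "mesoderm" if target_module == "ectoderm" else "ectoderm"
            ok = [s for s in candidates if not any(_module(v) == other for v in s)]
            discarded = [s for s in candidates if s not in ok]
            if ok:
                candidates = ok
            else:
                warnings.warn(
                    f"target {probes[fam.target]}: all candidate sets violate "
                    f"no-crosstalk; constraint relaxed"
                )
        chosen = fam.best(candidates, rng=rng)
        for v in chosen:
            adj[fam.target, v] = DIRECTED
        provenance["targets"][probes[fam.target]] = {
            "family": [sorted(probes[v] for v in s) for s in fam.sets],
            "scores": {
                ",".join(sorted(probes[v] for v in s)): round(score, 6)
                for s, score in fam.set_scores.items()
            },
            "chosen": sorted(probes[v] for v in chosen),
            "discarded_by_crosstalk": [sorted(probes[v] for v in s) for s in discarded],
        }
    return GeneNetwork(list(probes), adj, dict(module_map) if module_map else None), provenance


# -- covariance ------------------------------------------------------------


def covariance_adjacency(
    tc: ExpressionTimeCourse,
    absolute: bool = False,
) -> tuple[GeneNetwork, float]:
    """Undirected coupling network from the thresholded covariance matrix.

    The sample variance-covariance matrix (n-1 divisor) is computed over all
    time points pooled across series; the threshold is the median of the
    entire matrix, diagonal included.  Entries >= threshold become -1
    (undirected interaction), the rest 0.  With ``absolute=True`` the
    comparison uses covariance magnitudes.  Returns the probe-level network
    (the diagonal may carry -1 self entries; downstream combiners discard
    them) and the threshold used.
    """
    if tc.values.shape[1] < 2:
        raise InferenceError("need at least 2 time points for covariance")
    cov = np.cov(tc.values)
    cov = np.atleast_2d(cov)
    mat = np.abs(cov) if absolute else cov
    threshold = float(np.median(mat))
    adj = np.where(mat >= threshold, UNDIRECTED, ABSENT)
    return GeneNetwork(list(tc.probes), adj, validate=False), threshold


# -- pipeline combiners ----------------------------------------------------


def _check_same_universe(a: GeneNetwork, b: GeneNetwork) -> None:
    if a.nodes != b.nodes:
        raise InferenceError("networks are over different probe universes")


def combine_msa_cov(
    msa: GeneNetwork,
    cov: GeneNetwork,
    probe_map: ProbeMap | None = None,
    collapse: bool = True,
) -> GeneNetwork:
    """MSA-COV order: keep MSA's directed edges, add COV's undirected ones.

    Probe-level entry: +1 if msa(i,j)=1; -1 if i != j, cov(i,j)=-1 and
    neither msa direction is set; 0 otherwise.  Undirected self-loops are
    discarded (self-regulation cannot be determined from covariance).  The
    result is then collapsed to the gene level by unanimity.
    """
    _check_same_universe(msa, cov)
    n = msa.n_nodes
    adj = np.zeros((n, n))
    m, c = msa.adjacency, cov.adjacency
    for i in range(n):
        for j in range(n):
            if m[i, j] == DIRECTED:
                adj[i, j] = DIRECTED
            elif i != j and c[i, j] == UNDIRECTED and m[i, j] == 0 and m[j, i] == 0:
                adj[i, j] = UNDIRECTED
    net = GeneNetwork(msa.nodes, adj, msa.module_map)
    if collapse:
        if probe_map is None:
            probe_map = ProbeMap.identity(msa.nodes)
        net = collapse_probes(net, probe_map)
    return net


def combine_cov_msa(
    cov: GeneNetwork,
    msa: GeneNetwork,
    probe_map: ProbeMap | None = None,
    collapse: bool = True,
) -> GeneNetwork:
    """COV-MSA order: COV decides which pairs interact, MSA orients them.

    Probe-level entry: +1 if cov(i,j)=-1 and msa(i,j)=1; -1 if i != j,
    cov(i,j)=-1 and neither msa direction is set; 0 when cov(i,j)=0 (COV
    vetoes even an MSA edge) or when only the reverse MSA direction exists.
    Self-loops and gene-level collapse handled as in :func:`combine_msa_cov`.
    """
    _check_same_universe(cov, msa)
    n = cov.n_nodes
    adj = np.zeros((n, n))
    m, c = msa.adjacency, cov.adjacency
    for i in range(n):
        for j in range(n):
            if c[i, j] == UNDIRECTED and m[i, j] == DIRECTED:
                adj[i, j] = DIRECTED
            elif i != j and c[i, j] == UNDIRECTED and m[i, j] == 0 and m[j, i] == 0:
                adj[i, j] = UNDIRECTED
    net = GeneNetwork(cov.nodes, adj, msa.module_map)
    if collapse:
        if probe_map is None:
            probe_map = ProbeMap.identity(cov.nodes)
        net = collapse_probes(net, probe_map)
    return net


PIPELINE_ORDERS = ("msa-cov", "cov-msa")


def run_pipeline(
    tc: ExpressionTimeCourse,
    q: int = 7,
    order: str = "msa-cov",
    module_map: Mapping[str, str] | None = None,
    discretization: str = "equal-frequency",
    crosstalk_policy: str = "prefer-no-crosstalk",
    lenient: bool = False,
    joint_series: bool = True,
    absolute_covariance: bool = False,
    seed: int | None = 0,
) -> tuple[GeneNetwork, dict]:
    """Full inference pipeline: discretize, MSA, COV, combine, collapse.

    ``module_map`` maps genes (or probes) to modules; probes inherit the
    module of their gene for the no-crosstalk filter.  ``seed`` drives only
    the resolution of exact score ties in model selection; the pipeline is
    deterministic for identical inputs and seed.  Returns the
    gene-level mixed network plus a provenance record (parameters, the COV
    threshold, every target's minimal-set family with scores, the chosen and
    discarded sets).
    """
    order = order.lower()
    if order not in PIPELINE_ORDERS:
        raise InferenceError(f"unknown pipeline order {order!r}")
    probe_map = tc.probe_map or ProbeMap.identity(tc.probes)
    probe_modules = None
    if module_map is not None:
        probe_modules = {
            p: module_map.get(probe_map.gene_of(p), module_map.get(p))
            for p in tc.probes
        }

    dtc = discretize(tc, q=q, method=discretization, joint_series=joint_series)
    ts = extract_transitions(dtc)
    families = [minimal_sets(ts, k, lenient=lenient) for k in range(tc.n_probes)]
    rng = np.random.default_rng(seed) if seed is not None else None
    msa_net, msa_prov = select_model(
        families, tc.probes, probe_modules, crosstalk_policy=crosstalk_policy, rng=rng
    )
    cov_net, threshold = covariance_adjacency(tc, absolute=absolute_covariance)

    if order == "msa-cov":
        combined = combine_msa_cov(msa_net, cov_net, probe_map)
    else:
        combined = combine_cov_msa(cov_net, msa_net, probe_map)
    if module_map is not None:
        combined.module_map = {g: module_map.get(g) for g in combined.nodes}

    provenance = {
        "order": order,
        "seed": seed,
        "q": q,
        "discretization": discretization,
        "joint_series": joint_series,
        "crosstalk_policy": crosstalk_policy,
        "covariance_threshold": threshold,
        "n_transitions": ts.n_transitions,
        "msa": msa_prov,
        "directed_edges": sorted(combined.directed_edges()),
        "undirected_edges": sorted(combined.undirected_edges()),
    }
    return combined, provenance


# -- time-course I/O -------------------------------------------------------


def write_timecourse(tc: ExpressionTimeCourse, path: str | Path) -> None:
    """TSV with probes as rows; the first column holds probe identifiers."""
    cols = [f"t{k}" for k in range(tc.values.shape[1])]
    df = pd.DataFrame(tc.values, index=tc.probes, columns=cols)
    df.to_csv(path, sep="\t", index_label="probe")


def read_timecourse(
    path: str | Path,
    series_lengths: Sequence[int],
    probe_map: ProbeMap | None = None,
) -> ExpressionTimeCourse:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTimeCourse(
        probes=[str(p) for p in df.index],
        values=df.to_numpy(dtype=float),
        series_lengths=list(series_lengths),
        probe_map=probe_map,
    )
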