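"""Knowledge-driven network construction.

Two kinds of knowledge models are built here:

* a **gold standard network (GSN)** assembled from a per-pair evidence table
  (perturbation significance, fold change, yeast one-hybrid hits, genetic
  interactions) via a fixed rule system requiring two independent lines of
  evidence for a directed edge;
* a **wild-type-model-style network** encoded from a curated directed edge
  list with temporal-phase and tissue ("no cross-talk") blocking constraints
  that turn structurally impossible pairs into explicit non-interactions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .graph import (
    ABSENT,
    DIRECTED,
    UNDIRECTED,
    UNKNOWN,
    GeneNetwork,
    GraphValueError,
    is_unknown,
)


@dataclass(frozen=True)
class EvidenceRecord:
    """Evidence for one ordered gene pair: does ``source`` regulate ``target``?

    Attributes
    ----------
    sig:
        Z-score significance of the transcript-abundance change in the
        perturbation experiment (>= 0).
    mag:
        Fold-change magnitude of the transcript-abundance change (>= 0).
    y1h:
        Number of yeast one-hybrid (DNA-binding) interactions observed (>= 0).
    gen:
        Signed count of genetic-interaction reports: positive values count
        directional expression-change reports, negative values count
        non-directional synthetic-interaction reports.
    """

    target: str
    source: str
    sig: float = 0.0
    mag: float = 0.0
    y1h: int = 0
    gen: int = 0

    def __post_init__(self):
        if self.sig < 0 or self.mag < 0:
            raise GraphValueError(
                f"sig/mag must be non-negative for pair ({self.target}, {self.source})"
            )
        if self.y1h < 0:
            raise GraphValueError(
                f"y1h must be non-negative for pair ({self.target}, {self.source})"
            )


def classify_evidence(rec: EvidenceRecord, y1h_exact: bool = False) -> float:
    """Apply the edge-assignment rules to one evidence record.

    Returns +1 (directed edge), -1 (undirected edge), 0 (non-interaction) or
    NaN (unknown).  Rules are evaluated in priority order — a record
    satisfying both the directed and the undirected predicate (e.g. three
    directional genetic reports) is called directed, since directional
    evidence is strictly more informative:

    * ``+1`` if (sig >= 2 and mag >= 2) or (sig >= 2 and y1h hit) or
      (gen >= 2) or (sig >= 2 and \\|gen\\| = 1)
    * ``-1`` if \\|gen\\| >= 2
    * ``0``  if mag = 0 and sig = 0 and y1h = 0
    * unknown otherwise

    ``y1h_exact=True`` reads the one-hybrid clause as "exactly one hit";
    the default accepts one or more.
    """
    y1h_hit = rec.y1h == 1 if y1h_exact else rec.y1h >= 1
    if (
        (rec.sig >= 2 and rec.mag >= 2)
        or (rec.sig >= 2 and y1h_hit)
        or (rec.gen >= 2)
        or (rec.sig >= 2 and abs(rec.gen) == 1)
    ):
        return DIRECTED
    if abs(rec.gen) >= 2:
        return UNDIRECTED
    if rec.mag == 0 and rec.sig == 0 and rec.y1h == 0:
        return ABSENT
    return UNKNOWN


def build_gsn(
    records: Iterable[EvidenceRecord],
    genes: Sequence[str] | None = None,
    module_map: Mapping[str, str] | None = None,
    y1h_exact: bool = False,
) -> GeneNetwork:
    """Build a gold standard network from an evidence table.

    Each ordered pair with a record gets the rule-based call; pairs without
    a record stay unknown (absence of evidence is not evidence of absence —
    an explicit all-zero record is required for a 0).  Undirected calls are
    symmetrized.  When the reverse pair of an undirected call carries a
    directed call, the directed edge wins and the undirected mark is dropped
    with a warning.  The diagonal is forced to 0: the perturbation design
    cannot detect auto-regulation, so the network contains no self-loops.
    """
    records = list(records)
    if genes is None:
        seen: dict[str, None] = {}
        for rec in records:
            seen.setdefault(rec.target)
            seen.setdefault(rec.source)
        genes = list(seen)
    index = {g: k for k, g in enumerate(genes)}
    if len(index) != len(genes):
        raise GraphValueError("gene identifiers are not unique")
    n = len(genes)
    raw = np.full((n, n), UNKNOWN)
    have = np.zeros((n, n), dtype=bool)
    for rec in records:
        for name in (rec.target, rec.source):
            if name not in index:
                raise GraphValueError(f"record references unknown gene {name!r}")
        i, j = index[rec.target], index[rec.source]
        if have[i, j]:
            raise GraphValueError(
                f"duplicate evidence records for ordered pair ({rec.target}, {rec.source})"
            )
        have[i, j] = True
        raw[i, j] = classify_evidence(rec, y1h_exact=y1h_exact)

    adj = raw.copy()
    for i in range(n):
        for j in range(i + 1, n):
            a, b = raw[i, j], raw[j, i]
            if a == UNDIRECTED and b == DIRECTED:
                warnings.warn(
                    f"pair ({genes[i]}, {genes[j]}): undirected call dropped in "
                    f"favor of the reverse directed edge"
                )
                adj[i, j] = UNKNOWN
            elif b == UNDIRECTED and a == DIRECTED:
                warnings.warn(
                    f"pair ({genes[j]}, {genes[i]}): undirected call dropped in "
                    f"favor of the reverse directed edge"
                )
                adj[j, i] = UNKNOWN
            elif a == UNDIRECTED or b == UNDIRECTED:
                adj[i, j] = UNDIRECTED
                adj[j, i] = UNDIRECTED
    np.fill_diagonal(adj, ABSENT)
    return GeneNetwork(genes, adj, module_map)


def non_interactions(net: GeneNetwork) -> list[tuple[str, str]]:
    """Ordered off-diagonal (target, source) pairs with an explicit 0 entry.

    These are evidenced non-interactions, distinct from unknown pairs.
    """
    out = []
    for i, target in enumerate(net.nodes):
        for j, source in enumerate(net.nodes):
            if i != j and net.adjacency[i, j] == ABSENT:
                out.append((target, source))
    return out


# -- wild-type-model-style encoding ---------------------------------------


@dataclass
class KnowledgeEdgeSpec:
    """A curated directed edge list plus blocking annotations.

    ``edges`` are (source, target) pairs.  ``phase_map`` assigns each gene an
    ordinal expression-time phase; a gene may influence genes of its own or a
    later phase only.  ``tissue_map`` marks transcription-factor genes as
    ``ectoderm-TF`` or ``mesoderm-TF`` (anything else is unconstrained);
    TFs of one tissue are blocked from regulating TFs of the other.
    """

    edges: list[tuple[str, str]]
    phase_map: dict[str, int]
    tissue_map: dict[str, str]

    def __post_init__(self):
        for src, tgt in self.edges:
            for g in (src, tgt):
                if g not in self.phase_map:
                    raise GraphValueError(f"gene {g!r} in edge list missing from phase map")

    @classmethod
    def from_file(cls, path: str | Path) -> "KnowledgeEdgeSpec":
        data = yaml.safe_load(Path(path).read_text())
        edges = [(str(s), str(t)) for s, t in data["edges"]]
        return cls(
            edges=edges,
            phase_map={str(k): int(v) for k, v in data.get("phases", {}).items()},
            tissue_map={str(k): str(v) for k, v in data.get("tissues", {}).items()},
        )

    def to_file(self, path: str | Path) -> None:
        data = {
            "edges": [list(e) for e in self.edges],
            "phases": dict(self.phase_map),
            "tissues": dict(self.tissue_map),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def encode_knowledge_model(
    spec: KnowledgeEdgeSpec,
    genes: Sequence[str] | None = None,
    module_map: Mapping[str, str] | None = None,
) -> GeneNetwork:
    """Encode a curated edge list as a directed network with blocked pairs.

    Listed edges become +1.  A pair (target i, source j) becomes an explicit
    0 when phase(j) > phase(i) (a later-phase gene cannot influence an
    earlier-phase one) or when source and target are TFs of opposite tissues
    (no cross-talk).  All remaining pairs stay unknown.  An edge that is both
    listed and blocked is a contradiction and is rejected.
    """
    if genes is None:
        genes = list(spec.phase_map)
    index = {g: k for k, g in enumerate(genes)}
    n = len(genes)
    adj = np.full((n, n), UNKNOWN)

    def _blocked(target: str, source: str) -> bool:
        pi = spec.phase_map.get(target)
        pj = spec.phase_map.get(source)
        if pi is not None and pj is not None and pj > pi:
            return True
        ti = spec.tissue_map.get(target)
        tj = spec.tissue_map.get(source)
        return {ti, tj} == {"ectoderm-TF", "mesoderm-TF"}

    for i, target in enumerate(genes):
        for j, source in enumerate(genes):
            if i != j and _blocked(target, source):
                adj[i, j] = ABSENT
    for src, tgt in spec.edges:
        for g in (src, tgt):
            if g not in index:
                raise GraphValueError(f"edge gene {g!r} not in gene list")
        if _blocked(tgt, src):
            raise GraphValueError(
                f"edge {src} -> {tgt} is asserted but blocked by phase/tissue constraints"
            )
        adj[index[tgt], index[src]] = DIRECTED
    np.fill_diagonal(adj, ABSENT)
    return GeneNetwork(genes, adj, module_map)


# -- evidence-table I/O ----------------------------------------------------

_EVIDENCE_COLUMNS = ("target", "source", "sig", "mag", "y1h", "gen")


def read_evidence_table(path: str | Path, sheet: str | None = None) -> list[EvidenceRecord]:
    """Read an evidence table from TSV/CSV (or a spreadsheet tab).

    Expected columns: target, source, sig, mag, y1h and either a signed
    ``gen`` column or the split pair ``gen_directional`` /
    ``gen_nondirectional`` (at most one of the two may be non-zero per row).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet or 0)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("target", "source"):
        if col not in df.columns:
            raise GraphValueError(f"evidence table {path} missing column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if "gen" in df.columns:
            gen = int(d.get("gen") or 0)
        else:
            pos = int(d.get("gen_directional") or 0)
            neg = int(d.get("gen_nondirectional") or 0)
            if pos and neg:
                raise GraphValueError(
                    f"row ({d['target']}, {d['source']}): both directional and "
                    f"non-directional genetic counts are non-zero"
                )
            gen = pos if pos else -neg
        records.append(
            EvidenceRecord(
                target=str(d["target"]),
                source=str(d["source"]),
                sig=float(d.get("sig") or 0.0),
                mag=float(d.get("mag") or 0.0),
                y1h=int(d.get("y1h") or 0),
                gen=gen,
            )
        )
    return records


def write_evidence_table(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.target, r.source, r.sig, r.mag, r.y1h, r.gen)
            for r in records
        ],
        columns=list(_EVIDENCE_COLUMNS),
    )
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df.to_csv(path, sep=sep, index=False)
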