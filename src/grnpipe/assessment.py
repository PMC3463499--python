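"""Model assessment against a gold standard network.

Mixed graphs need a confusion scheme beyond the usual four cells: a model's
undirected edge whose gold-standard counterpart is directed is *half right*
(HR) — the interaction is real but the model did not commit to a direction.
HR predictions carry weight 0.5 in modified recall and precision:

    TPR = (TP + 0.5 HR) / (TP + 0.5 HR + FN + 0.5 HR)
    PPV = (TP + 0.5 HR) / (TP + 0.5 HR + FP)
    FPR = FP / (FP + TN)

Because each model contributes a single (recall, precision) and (FPR, TPR)
point per feature subnetwork rather than a curve, performance is summarized
by the signed Euclidean distance of each point from its random-guess line
(the ROC diagonal y = x, and the PR anti-diagonal y = 1 - x), positive above
the line and negative below.  The total distance sums these over six feature
domains (overall, master-regulator targets, and strict/wide ectoderm and
mesoderm subnetworks) in both spaces; a perfect model scores 12/sqrt(2)
(about 8.49), a random one 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .graph import ABSENT, DIRECTED, UNDIRECTED, GeneNetwork, GraphValueError, is_unknown

SQRT2 = math.sqrt(2.0)

#: default handling of the two model=-1 combinations the core scheme leaves
#: open: an undirected model edge over an undirected gold edge asserts the
#: same (direction-free) interaction, hence TP; an undirected model edge over
#: a gold non-interaction is a wrong assertion, hence FP.
RESIDUAL_POLICIES = ("tp-fp", "hr-halffp")


@dataclass
class ConfusionSummary:
    """Counts over the scoreable ordered pairs of one domain.

    Floats rather than ints so that fractional residual policies (e.g. a
    half false positive) remain representable.
    """

    TP: float = 0.0
    TN: float = 0.0
    HR: float = 0.0
    FP: float = 0.0
    FN: float = 0.0

    @property
    def total(self) -> float:
        return self.TP + self.TN + self.HR + self.FP + self.FN

    @property
    def predictions(self) -> float:
        """Number of predictions made: TP + TN + HR + FP (FN are misses)."""
        return self.TP + self.TN + self.HR + self.FP

    @property
    def correct(self) -> float:
        """Number of correct predictions: TP + TN + 0.5 HR."""
        return self.TP + self.TN + 0.5 * self.HR


@dataclass
class AssessmentPoint:
    """Rates and signed distances for one feature domain.

    A rate with a zero denominator is ``None`` (undefined), never coerced;
    distances over undefined rates are ``None`` as well.
    """

    tpr: float | None
    ppv: float | None
    fpr: float | None
    pr_distance: float | None = None
    roc_distance: float | None = None


@dataclass
class PairDomain:
    """A named set of ordered off-diagonal (target, source) pairs."""

    label: str
    pairs: set

    def __len__(self) -> int:
        return len(self.pairs)


def roc_distance(fpr: float | None, tpr: float | None) -> float | None:
    """Signed distance of an ROC point from the diagonal y = x.

    sqrt(2) * (TPR - FPR) / 2; positive above the diagonal (better than a
    random guess), negative below.  Maximum sqrt(2)/2 at (0, 1).
    """
    if fpr is None or tpr is None:
        return None
    return SQRT2 * (tpr - fpr) / 2.0


def pr_distance(recall: float | None, precision: float | None) -> float | None:
    """Signed distance of a PR point from the anti-diagonal y = 1 - x.

    sqrt(2) * (recall - 1 + precision) / 2; positive above the line,
    negative below.  Maximum sqrt(2)/2 at (1, 1).
    """
    if recall is None or precision is None:
        return None
    return SQRT2 * (recall - 1.0 + precision) / 2.0


def classifier_point(cs: ConfusionSummary) -> AssessmentPoint:
    """Modified rates plus their signed distances for one confusion summary."""
    tp_w = cs.TP + 0.5 * cs.HR
    tpr_den = cs.TP + cs.HR + cs.FN
    ppv_den = tp_w + cs.FP
    fpr_den = cs.FP + cs.TN
    tpr = tp_w / tpr_den if tpr_den > 0 else None
    ppv = tp_w / ppv_den if ppv_den > 0 else None
    fpr = cs.FP / fpr_den if fpr_den > 0 else None
    return AssessmentPoint(
        tpr=tpr,
        ppv=ppv,
        fpr=fpr,
        pr_distance=pr_distance(tpr, ppv),
        roc_distance=roc_distance(fpr, tpr),
    )


# -- pair domains ----------------------------------------------------------


def feature_domains(
    nodes: Sequence[str],
    module_map: Mapping[str, str],
    master: str,
) -> list[PairDomain]:
    """The six assessed feature domains over ordered off-diagonal pairs.

    * ``Overall`` — every ordered pair;
    * ``P`` — the master regulator's candidate targets: pairs (i, master);
    * ``E(s)``/``M(s)`` — strict module subnetworks, both endpoints inside
      the ectoderm/mesoderm module;
    * ``E(w)``/``M(w)`` — modules in the whole network, at least one
      endpoint inside.
    """
    if master not in nodes:
        raise GraphValueError(f"master regulator {master!r} not among nodes")
    all_pairs = {(i, j) for i in nodes for j in nodes if i != j}
    domains = [PairDomain("Overall", all_pairs)]
    domains.append(PairDomain("P", {(i, master) for i in nodes if i != master}))
    for label, module in (("E", "ectoderm"), ("M", "mesoderm")):
        members = {g for g in nodes if module_map.get(g) == module}
        strict = {(i, j) for (i, j) in all_pairs if i in members and j in members}
        wide = {(i, j) for (i, j) in all_pairs if i in members or j in members}
        domains.append(PairDomain(f"{label}(s)", strict))
        domains.append(PairDomain(f"{label}(w)", wide))
    return domains


# -- confusion counting ----------------------------------------------------

_PRIORITY = (DIRECTED, UNDIRECTED, ABSENT)


def _merge_cells(a: float, b: float) -> float:
    """Collapse the two cells of an unordered pair by information priority."""
    for value in _PRIORITY:
        if a == value or b == value:
            return value
    return math.nan


def confusion_counts(
    model: GeneNetwork,
    gold: GeneNetwork,
    domain: PairDomain | None = None,
    residual_policy: str = "tp-fp",
    pair_mode: str = "ordered",
) -> ConfusionSummary:
    """Count TP/TN/HR/FP/FN over a pair domain.

    Core scheme per ordered pair (skipping any pair unknown in either
    matrix):

    * TP — model and gold both +1, or model +1 over gold -1;
    * TN — both 0;
    * HR — model -1 over gold +1 (half right);
    * FP — model +1 over gold 0;
    * FN — model 0 over gold +1 or -1.

    The two residual combinations are policy-controlled: under ``tp-fp``
    (default) model -1 over gold -1 is TP and model -1 over gold 0 is FP;
    under ``hr-halffp`` they count as HR and half an FP respectively.

    ``pair_mode="unordered"`` scores each unordered pair once, after merging
    its two cells by priority (+1 over -1 over 0 over unknown) in both
    matrices.
    """
    if model.nodes != gold.nodes:
        raise GraphValueError("model and gold networks are over different node sets")
    if residual_policy not in RESIDUAL_POLICIES:
        raise GraphValueError(f"unknown residual policy {residual_policy!r}")
    if pair_mode not in ("ordered", "unordered"):
        raise GraphValueError(f"unknown pair mode {pair_mode!r}")
    nodes = model.nodes
    if domain is None:
        pairs = {(i, j) for i in nodes for j in nodes if i != j}
    else:
        pairs = domain.pairs

    cs = ConfusionSummary()

    def _count(m: float, g: float) -> None:
        if is_unknown(m) or is_unknown(g):
            return
        if m == DIRECTED:
            if g in (DIRECTED, UNDIRECTED):
                cs.TP += 1
            else:
                cs.FP += 1
        elif m == UNDIRECTED:
            if g == DIRECTED:
                cs.HR += 1
            elif g == UNDIRECTED:
                if residual_policy == "tp-fp":
                    cs.TP += 1
                else:
                    cs.HR += 1
            else:
                cs.FP += 1 if residual_policy == "tp-fp" else 0.5
        else:  # m == ABSENT
            if g in (DIRECTED, UNDIRECTED):
                cs.FN += 1
            else:
                cs.TN += 1

    if pair_mode == "ordered":
        for i, j in pairs:
            _count(model.entry(i, j), gold.entry(i, j))
    else:
        seen = set()
        for i, j in pairs:
            key = frozenset((i, j))
            if key in seen:
                continue
            seen.add(key)
            m = _merge_cells(model.entry(i, j), model.entry(j, i))
            g = _merge_cells(gold.entry(i, j), gold.entry(j, i))
            _count(m, g)
    return cs


# -- full assessment -------------------------------------------------------


@dataclass
class AssessmentReport:
    """Per-feature confusion summaries and points plus global totals."""

    features: dict[str, tuple[ConfusionSummary, AssessmentPoint]]
    prediction_count: float
    correct_count: float
    total_distance: float
    undefined_features: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def percent_correct(self) -> float | None:
        if self.prediction_count == 0:
            return None
        return 100.0 * self.correct_count / self.prediction_count

    def to_dict(self) -> dict:
        def _round(x):
            return None if x is None else round(x, 6)

        return {
            "schema": "grnpipe-assessment/1",
            "config": self.config,
            "features": {
                label: {
                    "TP": cs.TP,
                    "TN": cs.TN,
                    "HR": cs.HR,
                    "FP": cs.FP,
                    "FN": cs.FN,
                    "scoreable_pairs": cs.total,
                    "tpr": _round(pt.tpr),
                    "ppv": _round(pt.ppv),
                    "fpr": _round(pt.fpr),
                    "pr_distance": _round(pt.pr_distance),
                    "roc_distance": _round(pt.roc_distance),
                }
                for label, (cs, pt) in self.features.items()
            },
            "prediction_count": self.prediction_count,
            "correct_count": self.correct_count,
            "percent_correct": _round(self.percent_correct),
            "total_distance": round(self.total_distance, 6),
            "undefined_features": self.undefined_features,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def assess_model(
    model: GeneNetwork,
    gold: GeneNetwork,
    module_map: Mapping[str, str] | None = None,
    master: str | None = None,
    residual_policy: str = "tp-fp",
    pair_mode: str = "ordered",
) -> AssessmentReport:
    """Assess a model against the gold standard over the six feature domains.

    Prediction and correct counts are taken over the Overall domain.  The
    total distance sums PR and ROC distances across all six features; a
    feature with an undefined rate contributes 0 there and is listed in
    ``undefined_features``.
    """
    if module_map is None:
        module_map = gold.module_map or model.module_map or {}
    if master is None:
        raise GraphValueError("a master regulator must be designated")
    domains = feature_domains(gold.nodes, module_map, master)
    features: dict[str, tuple[ConfusionSummary, AssessmentPoint]] = {}
    total = 0.0
    undefined = []
    for dom in domains:
        cs = confusion_counts(
            model, gold, dom, residual_policy=residual_policy, pair_mode=pair_mode
        )
        pt = classifier_point(cs)
        features[dom.label] = (cs, pt)
        if pt.pr_distance is None or pt.roc_distance is None:
            undefined.append(dom.label)
        total += (pt.pr_distance or 0.0) + (pt.roc_distance or 0.0)
    overall = features["Overall"][0]
    return AssessmentReport(
        features=features,
        prediction_count=overall.predictions,
        correct_count=overall.correct,
        total_distance=total,
        undefined_features=undefined,
        config={
            "residual_policy": residual_policy,
            "pair_mode": pair_mode,
            "master": master,
        },
    )


def plot_assessment(
    reports: Mapping[str, AssessmentReport],
    path: str | Path,
) -> None:
    """Scatter the per-feature PR and ROC points of one or more models."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_pr, ax_roc) = plt.subplots(1, 2, figsize=(9, 4))
    ax_pr.plot([0, 1], [1, 0], "k--", lw=0.8)
    ax_roc.plot([0, 1], [0, 1], "k--", lw=0.8)
    markers = ["s", "^", "o", "D", "v", "*"]
    for k, (name, report) in enumerate(reports.items()):
        marker = markers[k % len(markers)]
        for label, (_, pt) in report.features.items():
            if pt.tpr is not None and pt.ppv is not None:
                ax_pr.scatter(pt.tpr, pt.ppv, marker=marker, label=f"{name} {label}", s=25)
            if pt.fpr is not None and pt.tpr is not None:
                ax_roc.scatter(pt.fpr, pt.tpr, marker=marker, s=25)
    ax_pr.set_xlabel("recall")
    ax_pr.set_ylabel("precision")
    ax_roc.set_xlabel("FPR")
    ax_roc.set_ylabel("TPR")
    for ax in (ax_pr, ax_roc):
        ax.set_xlim(-0.05, 1.05)
        ax.set_ylim(-0.05, 1.05)
    ax_pr.legend(fontsize=5, loc="lower left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
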