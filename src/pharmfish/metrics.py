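"""Validation statistics: rank-sum AUC, its standard error and effective
degrees of freedom, ROC curves, the Power Metric, contingency metrics
(F-score / MCC / enrichment factor), threshold sweeps and the AUC filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from pharmfish.datasets import ACTIVE, INACTIVE
from pharmfish.errors import DegenerateDataError


@dataclass(frozen=True)
class ScoredLabels:
    scores: tuple
    labels: tuple

    def __post_init__(self):
        scores = tuple(float(s) for s in self.scores)
        labels = tuple(self.labels)
        if len(scores) != len(labels):
            raise ValueError("scores and labels must be parallel")
        for lab in labels:
            if lab not in (ACTIVE, INACTIVE):
                raise ValueError(f"bad label {lab!r}")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    @property
    def n_active(self) -> int:
        return sum(1 for lab in self.labels if lab == ACTIVE)

    @property
    def n_inactive(self) -> int:
        return sum(1 for lab in self.labels if lab == INACTIVE)


def auc_rank_sum(data: ScoredLabels) -> float:
    """Mann-Whitney AUC from the rank sum of the actives.

    Ties between actives and inactives get midranks, i.e. each tied
    active/inactive pair contributes 1/2 — equivalent to
    P(score_a > score_i) + P(score_a = score_i)/2.
    """
    na, ni = data.n_active, data.n_inactive
    if na == 0 or ni == 0:
        raise DegenerateDataError("AUC needs at least one compound per class")
    ranks = rankdata(data.scores)  # midranks for ties
    rank_sum = sum(r for r, lab in zip(ranks, data.labels) if lab == ACTIVE)
    return (rank_sum - na * (na + 1) / 2) / (na * ni)


def _auc_variance_components(w: float, na: int, ni: int) -> tuple:
    """The two addends of the Hanley-style SE^2 approximation."""
    v_a = w * w * (1 - w) / ((1 + w) * na)
    v_i = w * (1 - w) ** 2 / ((2 - w) ** 2 * ni)
    return v_a, v_i


def auc_se(w: float, na: int, ni: int) -> float:
    """Approximate standard error of an observed AUC for a 'typical' ROC."""
    if not 0 <= w <= 1:
        raise ValueError(f"AUC out of range: {w}")
    if na < 2 or ni < 2:
        raise DegenerateDataError("AUC SE needs Na >= 2 and Ni >= 2")
    v_a, v_i = _auc_variance_components(w, na, ni)
    return math.sqrt(v_a + v_i)


def auc_dof(w: float, na: int, ni: int) -> float:
    """Welch-Satterthwaite effective dof pairing v_a with Na-1, v_i with Ni-1."""
    if not 0 <= w <= 1:
        raise ValueError(f"AUC out of range: {w}")
    if na < 2 or ni < 2:
        raise DegenerateDataError("effective dof needs Na >= 2 and Ni >= 2")
    v_a, v_i = _auc_variance_components(w, na, ni)
    if v_a == 0 and v_i == 0:
        return float(na + ni - 2)  # degenerate w in {0,1}: no variance to weigh
    return (v_a + v_i) ** 2 / (v_a**2 / (na - 1) + v_i**2 / (ni - 1))


def roc_curve(data: ScoredLabels) -> list:
    """ROC vertices as (threshold, TPR, FPR), thresholds descending.

    One vertex per distinct score (tied compounds enter together), starting
    from (inf, 0, 0).
    """
    na, ni = data.n_active, data.n_inactive
    if na == 0 or ni == 0:
        raise DegenerateDataError("ROC needs at least one compound per class")
    order = sorted(zip(data.scores, data.labels), key=lambda t: -t[0])
    vertices = [(math.inf, 0.0, 0.0)]
    tp = fp = 0
    idx = 0
    while idx < len(order):
        threshold = order[idx][0]
        while idx < len(order) and order[idx][0] == threshold:
            if order[idx][1] == ACTIVE:
                tp += 1
            else:
                fp += 1
            idx += 1
        vertices.append((threshold, tp / na, fp / ni))
    return vertices


def power_metric(data: ScoredLabels, chi: float = 0.5) -> float:
    """TPR / (TPR + FPR) at the operating point where TPR + FPR = chi.

    The ROC polyline is walked from the top of the ranking; TPR and FPR
    are linearly interpolated to the crossing, so the metric equals
    TPR(chi) / chi.  1.0 means the top of the list is all active.
    """
    if not 0 < chi < 2:
        raise ValueError("chi must be in (0, 2)")
    vertices = roc_curve(data)
    prev_tpr = prev_fpr = 0.0
    for _thr, tpr, fpr in vertices[1:]:
        total = tpr + fpr
        if total >= chi:
            prev_total = prev_tpr + prev_fpr
            frac = (chi - prev_total) / (total - prev_total)
            tpr_at = prev_tpr + frac * (tpr - prev_tpr)
            return tpr_at / chi
        prev_tpr, prev_fpr = tpr, fpr
    return prev_tpr / chi  # unreachable for chi < 2


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    tn: int
    fn: int
    # (actives_in_collection, collection_size) for the enrichment factor;
    # defaults to this table's own prevalence
    prevalence_override: tuple | None = None

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def prevalence(self) -> float:
        if self.prevalence_override is not None:
            na_total, n_total = self.prevalence_override
            return na_total / n_total
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.fn) / total if total else float("nan")


@dataclass(frozen=True)
class ContingencyMetrics:
    """F-score, MCC and enrichment factor; None marks an undefined metric."""

    f_score: float | None
    mcc: float | None
    ef: float | None


def contingency_metrics(table: ContingencyTable) -> ContingencyMetrics:
    tp, fp, tn, fn = table.tp, table.fp, table.tn, table.fn

    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    if precision is None or recall is None or precision + recall == 0:
        f_score = None
    else:
        f_score = 2 * precision * recall / (precision + recall)

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None

    prevalence = table.prevalence
    if precision is None or not prevalence or math.isnan(prevalence):
        ef = None
    else:
        ef = precision / prevalence
    return ContingencyMetrics(f_score, mcc, ef)


def table_from_calls(calls: Mapping, labels: Mapping,
                     prevalence_override: tuple | None = None) -> ContingencyTable:
    """Confusion counts from {id: bool active-call} vs {id: label}."""
    tp = fp = tn = fn = 0
    for cid, is_active_call in calls.items():
        truly_active = labels[cid] == ACTIVE
        if is_active_call:
            tp += truly_active
            fp += not truly_active
        else:
            fn += truly_active
            tn += not truly_active
    return ContingencyTable(tp, fp, tn, fn, prevalence_override)


DEFAULT_THRESHOLD_GRID = tuple(round(-1.0 + 0.05 * k, 2) for k in range(41))


def sweep_threshold(papi_values: Sequence[float], labels: Sequence[str],
                    metric: str = "mcc",
                    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID) -> tuple:
    """Best classification cutoff on Pa-Pi by F-score, MCC or EF.

    Returns (best_threshold, best_metric_value); ties go to the smallest
    threshold; grid points where the metric is undefined are skipped.
    """
    if metric not in ("f", "mcc", "ef"):
        raise ValueError("metric must be one of: f, mcc, ef")
    label_set = set(labels)
    if label_set != {ACTIVE, INACTIVE}:
        raise DegenerateDataError("threshold sweep needs both classes present")
    attr = {"f": "f_score", "mcc": "mcc", "ef": "ef"}[metric]
    best_threshold, best_value = None, -math.inf
    for threshold in grid:
        calls = {i: v >= threshold for i, v in enumerate(papi_values)}
        m = contingency_metrics(table_from_calls(calls, dict(enumerate(labels))))
        value = getattr(m, attr)
        if value is not None and value > best_value:
            best_threshold, best_value = threshold, value
    if best_threshold is None:
        raise DegenerateDataError("metric undefined on the whole grid")
    return best_threshold, best_value


def filter_models(model_aucs: Mapping) -> dict:
    """Keep models whose validation AUC is STRICTLY greater than 0.5."""
    return {model_id: auc for model_id, auc in model_aucs.items() if auc > 0.5}


def write_roc_tsv(path, data: ScoredLabels) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["threshold", "tpr", "fpr"])
        for threshold, tpr, fpr in roc_curve(data):
            writer.writerow([repr(threshold), repr(tpr), repr(fpr)])
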