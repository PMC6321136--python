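"""Grouping bioassay models into activity classes, scoring and ranking.

The class score counts (compound, model) pairs called active among a
class's member models, normalized by the number of query compounds and by
the square root of the class's model count — the sqrt balances classes
with many models against classes with few.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from pharmfish.datasets import ACTIVE
from pharmfish.errors import DegenerateDataError
from pharmfish.metrics import ScoredLabels, auc_dof, auc_rank_sum, auc_se

PROBABLE_ACTIVE, PROBABLE_INACTIVE, EXCLUDED = (
    "probable_active", "probable_inactive", "excluded")


@dataclass(frozen=True)
class ActivityClass:
    class_id: str
    model_ids: frozenset  # dataset_ids of member models

    def __post_init__(self):
        object.__setattr__(self, "model_ids", frozenset(self.model_ids))
        if not self.model_ids:
            raise DegenerateDataError(f"class {self.class_id!r} has no models")

    @property
    def n_models(self) -> int:
        return len(self.model_ids)


@dataclass(frozen=True)
class ClassScore:
    class_id: str
    n_hits: int
    score: float
    rank: int | None = None


def class_score(calls: Mapping, activity_class: ActivityClass,
                n_compounds: int) -> ClassScore:
    """Normalized hit score for one class.

    calls maps (compound_id, dataset_id) -> call; every active call whose
    dataset belongs to the class counts one hit (a compound active in k of
    the class's models contributes k).  score = hits / (n_compounds *
    sqrt(n_models)).
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    hits = sum(1 for (_cid, dsid), call in calls.items()
               if dsid in activity_class.model_ids and call == ACTIVE)
    value = hits / (n_compounds * math.sqrt(activity_class.n_models))
    return ClassScore(activity_class.class_id, hits, value)


def score_classes(calls: Mapping, classes: Sequence[ActivityClass],
                  n_compounds: int) -> list:
    """Score every class and assign dense ranks 1..n (best score first).

    Score ties are broken by class_id so the ranking is a deterministic
    permutation.
    """
    scored = [class_score(calls, c, n_compounds) for c in classes]
    scored.sort(key=lambda s: (-s.score, s.class_id))
    return [ClassScore(s.class_id, s.n_hits, s.score, rank=i + 1)
            for i, s in enumerate(scored)]


def label_classes(outcome_counts: Mapping) -> dict:
    """Predominance labels from per-class (n_active, n_inactive) outcome counts."""
    labels = {}
    for class_id, (n_active, n_inactive) in outcome_counts.items():
        if n_active < 0 or n_inactive < 0:
            raise ValueError("outcome counts must be >= 0")
        if n_active > n_inactive:
            labels[class_id] = PROBABLE_ACTIVE
        elif n_inactive > n_active:
            labels[class_id] = PROBABLE_INACTIVE
        else:
            labels[class_id] = EXCLUDED
    return labels


def class_roc(class_scores: Sequence[ClassScore], class_labels: Mapping) -> dict:
    """Rank-sum AUC over class scores with probable_active as the positive
    label; excluded classes are left out.  Returns AUC with its standard
    error and effective dof when both classes have >= 2 members.
    """
    scores, labels = [], []
    for cs in class_scores:
        label = class_labels.get(cs.class_id)
        if label == PROBABLE_ACTIVE:
            scores.append(cs.score)
            labels.append("active")
        elif label == PROBABLE_INACTIVE:
            scores.append(cs.score)
            labels.append("inactive")
    data = ScoredLabels(tuple(scores), tuple(labels))
    auc = auc_rank_sum(data)
    result = {"auc": auc, "n_active": data.n_active, "n_inactive": data.n_inactive,
              "se": None, "dof": None}
    if data.n_active >= 2 and data.n_inactive >= 2:
        result["se"] = auc_se(auc, data.n_active, data.n_inactive)
        result["dof"] = auc_dof(auc, data.n_active, data.n_inactive)
    return result


def combine_rankings(rank_svm: Mapping, rank_nb: Mapping) -> list:
    """Final ordered class list from two per-method rankings.

    Sort key: (best rank across methods, average rank, class_id).
    """
    if set(rank_svm) != set(rank_nb):
        missing = set(rank_svm) ^ set(rank_nb)
        raise ValueError(f"rankings cover different classes: {sorted(missing)[:5]}")
    keyed = [
        (min(rank_svm[c], rank_nb[c]), (rank_svm[c] + rank_nb[c]) / 2, c)
        for c in rank_svm
    ]
    keyed.sort()
    return [c for _best, _avg, c in keyed]


def write_ranked_classes_tsv(path, ordered_class_ids: Sequence[str],
                             scores_svm: Mapping, scores_nb: Mapping) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rank", "class_id", "score_svm", "score_nb"])
        for i, class_id in enumerate(ordered_class_ids, start=1):
            writer.writerow([i, class_id,
                             repr(scores_svm[class_id].score),
                             repr(scores_nb[class_id].score)])
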