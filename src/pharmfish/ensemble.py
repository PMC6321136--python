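"""Ensembles of linear-SVM and Bernoulli naive-Bayes members over sparse
fingerprint keys, with out-of-sample (OOF) score collection.

Each ensemble member is fitted on one repeat of the stratified 70/30
split; the raw scores of that repeat's validation compounds are pooled per
compound and averaged, giving the reference score distribution used for
Pa/Pi calibration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from pharmfish.datasets import ACTIVE, ActivityDataset, SplitPlan, stratified_split
from pharmfish.datasets import _deserialize_key, _serialize_key
from pharmfish.errors import DegenerateDataError
from pharmfish.metrics import ScoredLabels, power_metric

# exponentially growing cost grid 2^-12 ... 2^6 (19 values)
COST_GRID = tuple(2.0**e for e in range(-12, 7))

SVM_LINEAR, NAIVE_BAYES = "svm_linear", "naive_bayes"


def _sorted_vocab(fingerprints: Sequence) -> tuple:
    vocab = set()
    for fp in fingerprints:
        vocab |= set(_keys_of(fp))
    return tuple(sorted(vocab))


def _keys_of(fp):
    return fp.keys if hasattr(fp, "keys") and not isinstance(fp, (set, frozenset)) else fp


def _to_matrix(fingerprints: Sequence, vocab_index: Mapping) -> np.ndarray:
    x = np.zeros((len(fingerprints), len(vocab_index)), dtype=np.float64)
    for row, fp in enumerate(fingerprints):
        for key in _keys_of(fp):
            col = vocab_index.get(key)
            if col is not None:
                x[row, col] = 1.0
    return x


@dataclass(frozen=True)
class MemberModel:
    """One fitted classifier: a linear score over present fingerprint keys.

    For SVM the score is the signed decision value w.x + b.  For naive
    Bayes it is the log posterior odds log P(active|x) - log P(inactive|x),
    which is ``bias`` (the empty-fingerprint log odds, absence terms
    included) plus the per-key log-likelihood-ratio weights of the present
    keys.
    """

    method: str
    repeat_index: int
    vocab: tuple
    weights: np.ndarray
    bias: float
    selected_cost: float | None = None

    def score_keys(self, keys) -> float:
        index = self._index()
        total = self.bias
        for key in _keys_of(keys):
            col = index.get(key)
            if col is not None:
                total += self.weights[col]
        return float(total)

    def _index(self) -> dict:
        cached = getattr(self, "_cached_index", None)
        if cached is None:
            cached = {key: i for i, key in enumerate(self.vocab)}
            object.__setattr__(self, "_cached_index", cached)
        return cached


def _fit_svm(x: np.ndarray, y: np.ndarray, cost: float) -> tuple:
    svc = SVC(kernel="linear", C=cost)
    svc.fit(x, y)
    w = np.asarray(svc.coef_).ravel().copy()
    b = float(svc.intercept_[0])
    return w, b


def _fit_nb(x: np.ndarray, y: np.ndarray, alpha: float = 1.0) -> tuple:
    """Bernoulli NB with Laplace smoothing over the training vocabulary."""
    n_a = int(y.sum())
    n_i = int(len(y) - n_a)
    theta_a = (x[y == 1].sum(axis=0) + alpha) / (n_a + 2 * alpha)
    theta_i = (x[y == 0].sum(axis=0) + alpha) / (n_i + 2 * alpha)
    w = np.log(theta_a / theta_i) - np.log((1 - theta_a) / (1 - theta_i))
    bias = math.log(n_a / n_i) + float(np.log((1 - theta_a) / (1 - theta_i)).sum())
    return w, bias


def select_cost(train_fingerprints: Sequence, train_labels: Sequence[str],
                seed: int = 0, grid: Sequence[float] = COST_GRID,
                n_folds: int = 5, chi: float = 0.5) -> float:
    """SVM cost maximizing the mean CV Power Metric at the chi quota.

    Stratified folds; ties broken toward the smaller cost.
    """
    y = np.asarray([1 if lab == ACTIVE else 0 for lab in train_labels])
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise DegenerateDataError("cost selection needs >=2 compounds per class")
    key_sets = [frozenset(_keys_of(fp)) for fp in train_fingerprints]
    if len(set(key_sets)) == 1:
        raise DegenerateDataError("degenerate feature matrix: all fingerprints identical")
    vocab = _sorted_vocab(train_fingerprints)
    index = {key: i for i, key in enumerate(vocab)}
    x = _to_matrix(train_fingerprints, index)

    n_folds = min(n_folds, int(y.sum()), int(len(y) - y.sum()))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(x, y))
    labels_arr = np.asarray(train_labels)

    best_cost, best_pm = None, -math.inf
    for cost in grid:
        pms = []
        for train_idx, val_idx in folds:
            w, b = _fit_svm(x[train_idx], y[train_idx], cost)
            scores = x[val_idx] @ w + b
            pms.append(power_metric(
                ScoredLabels(tuple(scores), tuple(labels_arr[val_idx])), chi=chi))
        mean_pm = float(np.mean(pms))
        if mean_pm > best_pm:
            best_cost, best_pm = cost, mean_pm
    return best_cost


@dataclass(frozen=True)
class EnsembleModel:
    """>= 30 member classifiers plus pooled OOF reference scores."""

    dataset_id: str
    method: str
    members: tuple
    oof_scores: dict   # compound_id -> tuple of raw validation scores
    labels: dict       # compound_id -> label
    selected_cost: float | None = None

    def __post_init__(self):
        for cid, scores in self.oof_scores.items():
            if not scores:
                raise DegenerateDataError(f"compound {cid!r} has no OOF score")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def oof_mean(self) -> dict:
        return {cid: float(np.mean(s)) for cid, s in self.oof_scores.items()}

    @property
    def oof_sd(self) -> dict:
        return {cid: float(np.std(s, ddof=1)) if len(s) > 1 else 0.0
                for cid, s in self.oof_scores.items()}

    def reference_scores(self) -> tuple:
        """(active oof means, inactive oof means) — the Pa/Pi reference."""
        means = self.oof_mean
        actives = tuple(means[c] for c, lab in self.labels.items() if lab == ACTIVE)
        inactives = tuple(means[c] for c, lab in self.labels.items() if lab != ACTIVE)
        return actives, inactives

    def validation_auc(self):
        from pharmfish.metrics import auc_rank_sum

        means = self.oof_mean
        ids = sorted(means)
        return auc_rank_sum(ScoredLabels(
            tuple(means[c] for c in ids), tuple(self.labels[c] for c in ids)))


def train_ensemble(dataset: ActivityDataset, fingerprints: Mapping,
                   method: str = SVM_LINEAR,
                   split_plan: SplitPlan | None = None,
                   seed: int = 0, n_repeats: int = 30,
                   cost: float | None = None,
                   nb_alpha: float = 1.0) -> EnsembleModel:
    """Fit one member per stratified repeat and pool validation scores.

    The SVM cost is selected once on the full dataset by 5-fold CV Power
    Metric unless given explicitly.  Each member's vocabulary is restricted
    to the keys seen in its own training split.
    """
    missing = [c for c in dataset.compound_ids if c not in fingerprints]
    if missing:
        raise KeyError(f"missing fingerprints for: {missing[:5]}")
    if split_plan is None:
        split_plan = stratified_split(dataset, seed=seed, n_repeats=n_repeats)

    if method == SVM_LINEAR and cost is None:
        cost = select_cost(
            [fingerprints[c] for c in dataset.compound_ids],
            [lab for _, lab in dataset.records], seed=seed)

    labels = dataset.labels()
    members = []
    oof: dict = {cid: [] for cid in dataset.compound_ids}
    for r in range(split_plan.n_repeats):
        train_ids = [c for c in dataset.compound_ids if c in split_plan.assignments[r]]
        val_ids = [c for c in dataset.compound_ids if c not in split_plan.assignments[r]]
        vocab = _sorted_vocab([fingerprints[c] for c in train_ids])
        index = {key: i for i, key in enumerate(vocab)}
        x = _to_matrix([fingerprints[c] for c in train_ids], index)
        y = np.asarray([1 if labels[c] == ACTIVE else 0 for c in train_ids])
        if method == SVM_LINEAR:
            w, b = _fit_svm(x, y, cost)
        elif method == NAIVE_BAYES:
            w, b = _fit_nb(x, y, alpha=nb_alpha)
        else:
            raise ValueError(f"unknown method {method!r}")
        member = MemberModel(method, r, vocab, w, b,
                             selected_cost=cost if method == SVM_LINEAR else None)
        members.append(member)
        for cid in val_ids:
            oof[cid].append(member.score_keys(fingerprints[cid]))
    return EnsembleModel(
        dataset_id=dataset.dataset_id, method=method, members=tuple(members),
        oof_scores={cid: tuple(scores) for cid, scores in oof.items()},
        labels=labels, selected_cost=cost if method == SVM_LINEAR else None)


def score(ensemble: EnsembleModel, fingerprint) -> tuple:
    """(mean, SD, N) of the raw member scores for one fingerprint."""
    values = np.asarray([m.score_keys(fingerprint) for m in ensemble.members])
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return float(values.mean()), sd, len(values)


# --------------------------------------------------------------------------
# Persistence: a single JSON bundle (text-only, schema-versioned)
# --------------------------------------------------------------------------

BUNDLE_SCHEMA = 1


def save_ensemble(path, ensemble: EnsembleModel) -> None:
    bundle = {
        "schema_version": BUNDLE_SCHEMA,
        "dataset_id": ensemble.dataset_id,
        "method": ensemble.method,
        "selected_cost": ensemble.selected_cost,
        "labels": ensemble.labels,
        "oof_scores": {c: list(s) for c, s in ensemble.oof_scores.items()},
        "members": [
            {
                "repeat_index": m.repeat_index,
                "vocab": [_serialize_key(k) for k in m.vocab],
                "weights": [float(v) for v in m.weights],
                "bias": m.bias,
                "selected_cost": m.selected_cost,
            }
            for m in ensemble.members
        ],
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def load_ensemble(path) -> EnsembleModel:
    with open(path) as fh:
        bundle = json.load(fh)
    if bundle.get("schema_version") != BUNDLE_SCHEMA:
        raise ValueError(f"unsupported model bundle schema in {path}")
    members = tuple(
        MemberModel(
            method=bundle["method"],
            repeat_index=m["repeat_index"],
            vocab=tuple(_deserialize_key(k) for k in m["vocab"]),
            weights=np.asarray(m["weights"]),
            bias=m["bias"],
            selected_cost=m["selected_cost"],
        )
        for m in bundle["members"]
    )
    return EnsembleModel(
        dataset_id=bundle["dataset_id"], method=bundle["method"], members=members,
        oof_scores={c: tuple(s) for c, s in bundle["oof_scores"].items()},
        labels=bundle["labels"], selected_cost=bundle["selected_cost"])
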