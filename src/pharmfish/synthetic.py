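"""Seeded fixture generators with the statistical structure the framework
assumes: planted-signal binary fingerprints, typed point clouds for the
geometry stage, and whole activity-class collections for end-to-end
ranking-recovery experiments.  Synthetic fingerprints use plain integer
bits so ML and calibration tests do not depend on chemistry rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from pharmfish.datasets import ACTIVE, INACTIVE, ActivityDataset
from pharmfish.pharmacophore import PPP_TYPES, PharmacophorePoint


@dataclass(frozen=True)
class FingerprintGeneratorSpec:
    n_active: int = 50
    n_inactive: int = 50
    n_bits: int = 120
    n_signal_bits: int = 20
    p_signal_active: float = 0.9
    p_signal_inactive: float = 0.1
    p_background: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_signal_active, self.p_signal_inactive, self.p_background):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_signal_bits > self.n_bits:
            raise ValueError("n_signal_bits must be <= n_bits")
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("both classes need at least one compound")


def _draw_fingerprint(rng: np.random.Generator, signal_bits: Sequence[int],
                      background_bits: Sequence[int], p_signal: float,
                      p_background: float) -> frozenset:
    keys = {b for b in signal_bits if rng.random() < p_signal}
    keys |= {b for b in background_bits if rng.random() < p_background}
    return frozenset(keys)


def gen_fingerprint_dataset(spec: FingerprintGeneratorSpec,
                            dataset_id: str = "synthetic",
                            id_prefix: str = "cpd") -> tuple:
    """(fingerprints, ActivityDataset) with planted signal bits.

    Signal bits are indices [0, n_signal_bits); actives carry each with
    p_signal_active, inactives with p_signal_inactive; everyone carries
    the remaining background bits with p_background.
    """
    rng = np.random.default_rng(spec.seed)
    signal = range(spec.n_signal_bits)
    background = range(spec.n_signal_bits, spec.n_bits)
    fingerprints: dict = {}
    records = []
    for i in range(spec.n_active):
        cid = f"{id_prefix}_a{i:04d}"
        fingerprints[cid] = _draw_fingerprint(
            rng, signal, background, spec.p_signal_active, spec.p_background)
        records.append((cid, ACTIVE))
    for i in range(spec.n_inactive):
        cid = f"{id_prefix}_i{i:04d}"
        fingerprints[cid] = _draw_fingerprint(
            rng, signal, background, spec.p_signal_inactive, spec.p_background)
        records.append((cid, INACTIVE))
    return fingerprints, ActivityDataset(dataset_id, tuple(records))


def gen_point_cloud_molecule(n_points: int,
                             type_distribution: Mapping | None = None,
                             box_size: float = 10.0, seed: int = 0) -> list:
    """Typed PPPs uniform in a cube — geometry-stage fixtures."""
    rng = np.random.default_rng(seed)
    if type_distribution is None:
        type_distribution = {t: 1.0 for t in PPP_TYPES}
    types = sorted(type_distribution)
    weights = np.asarray([type_distribution[t] for t in types], dtype=float)
    weights /= weights.sum()
    points = []
    for i in range(n_points):
        ppp_type = types[rng.choice(len(types), p=weights)]
        position = tuple(rng.uniform(0.0, box_size, size=3))
        points.append(PharmacophorePoint(position, ppp_type, frozenset({i})))
    return points


@dataclass(frozen=True)
class ClassCollectionSpec:
    n_classes: int = 20
    models_per_class: tuple = (1, 3)   # inclusive range
    fraction_planted_active: float = 0.25
    n_query: int = 15
    n_background_bits: int = 100
    # n_bits is ignored here: the collection lays out one global bit space
    model_spec: FingerprintGeneratorSpec = field(
        default_factory=lambda: FingerprintGeneratorSpec(
            n_active=30, n_inactive=30, n_bits=15, n_signal_bits=15))
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0 <= self.fraction_planted_active <= 1:
            raise ValueError("fraction_planted_active must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticCollection:
    datasets: dict        # dataset_id -> ActivityDataset
    fingerprints: dict    # dataset_id -> {compound_id: frozenset}
    class_map: dict       # dataset_id -> class_id
    classes: dict         # class_id -> frozenset of dataset_ids
    truth: dict           # class_id -> probable_active / probable_inactive
    query_fingerprints: dict  # compound_id -> frozenset


def gen_class_collection(spec: ClassCollectionSpec | None = None) -> SyntheticCollection:
    """A collection of labelled datasets grouped into activity classes.

    Planted-active classes share their signal-bit block with the query
    compounds, so queries look active to those classes' models and
    inactive elsewhere; truth labels are emitted for recovery tests.
    """
    from pharmfish.activity_classes import PROBABLE_ACTIVE, PROBABLE_INACTIVE

    spec = spec or ClassCollectionSpec()
    rng = np.random.default_rng(spec.seed)
    n_signal = spec.model_spec.n_signal_bits
    # bit layout: query/planted block, one block per null class, background
    query_bits = tuple(range(n_signal))
    n_planted = max(1, round(spec.fraction_planted_active * spec.n_classes))

    datasets, fingerprints, class_map, classes, truth = {}, {}, {}, {}, {}
    next_block = n_signal
    for c in range(spec.n_classes):
        class_id = f"class{c:03d}"
        planted = c < n_planted
        truth[class_id] = PROBABLE_ACTIVE if planted else PROBABLE_INACTIVE
        if planted:
            signal_bits = query_bits
        else:
            signal_bits = tuple(range(next_block, next_block + n_signal))
            next_block += n_signal
        lo, hi = spec.models_per_class
        n_models = int(rng.integers(lo, hi + 1))
        members = set()
        for m in range(n_models):
            dataset_id = f"{class_id}_ds{m}"
            members.add(dataset_id)
            class_map[dataset_id] = class_id
            background = tuple(range(next_block_total(spec, n_signal),
                                     next_block_total(spec, n_signal)
                                     + spec.n_background_bits))
            fps, ds = _gen_planted_dataset(
                rng, dataset_id, spec.model_spec, signal_bits, background)
            datasets[dataset_id] = ds
            fingerprints[dataset_id] = fps
        classes[class_id] = frozenset(members)

    background = tuple(range(next_block_total(spec, n_signal),
                             next_block_total(spec, n_signal)
                             + spec.n_background_bits))
    query_fps = {
        f"query{i:03d}": _draw_fingerprint(
            rng, query_bits, background,
            spec.model_spec.p_signal_active, spec.model_spec.p_background)
        for i in range(spec.n_query)
    }
    return SyntheticCollection(datasets, fingerprints, class_map, classes,
                               truth, query_fps)


def next_block_total(spec: ClassCollectionSpec, n_signal: int) -> int:
    """First background bit index: after the query block and all null blocks."""
    n_planted = max(1, round(spec.fraction_planted_active * spec.n_classes))
    return n_signal * (1 + spec.n_classes - n_planted)


def _gen_planted_dataset(rng, dataset_id, model_spec, signal_bits, background):
    fingerprints, records = {}, []
    for i in range(model_spec.n_active):
        cid = f"{dataset_id}_a{i:03d}"
        fingerprints[cid] = _draw_fingerprint(
            rng, signal_bits, background,
            model_spec.p_signal_active, model_spec.p_background)
        records.append((cid, ACTIVE))
    for i in range(model_spec.n_inactive):
        cid = f"{dataset_id}_i{i:03d}"
        fingerprints[cid] = _draw_fingerprint(
            rng, signal_bits, background,
            model_spec.p_signal_inactive, model_spec.p_background)
        records.append((cid, INACTIVE))
    return fingerprints, ActivityDataset(dataset_id, tuple(records))


def run_class_recovery(collection: SyntheticCollection, method: str = "naive_bayes",
                       threshold: float | None = None, seed: int = 0,
                       n_repeats: int = 30) -> dict:
    """End-to-end: train one ensemble per dataset, predict the queries,
    score and rank the classes, return class_roc output plus the ranking.
    """
    from pharmfish.activity_classes import ActivityClass, class_roc, score_classes
    from pharmfish.calibration import predict
    from pharmfish.ensemble import train_ensemble

    if threshold is None:
        threshold = 0.30 if method == "naive_bayes" else 0.25
    calls = {}
    for dataset_id in sorted(collection.datasets):
        ensemble = train_ensemble(
            collection.datasets[dataset_id], collection.fingerprints[dataset_id],
            method=method, seed=seed, n_repeats=n_repeats)
        for cid in sorted(collection.query_fingerprints):
            pred = predict(ensemble, collection.query_fingerprints[cid],
                           compound_id=cid, threshold=threshold)
            calls[(cid, dataset_id)] = pred.call
    classes = [ActivityClass(cid, members)
               for cid, members in sorted(collection.classes.items())]
    scored = score_classes(calls, classes, n_compounds=len(collection.query_fingerprints))
    roc = class_roc(scored, collection.truth)
    roc["ranking"] = [s.class_id for s in scored]
    roc["scores"] = {s.class_id: s.score for s in scored}
    return roc
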