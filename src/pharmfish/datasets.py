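"""Labelled bioassay datasets, stratified resampling, and tabular IO."""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from pharmfish.errors import DegenerateDataError, SchemaError
from pharmfish.pharmacophore import ModalFingerprint, TripletKey

ACTIVE, INACTIVE = "active", "inactive"

# accepted label spellings after strip/casefold
_LABEL_NORMALIZATION = {
    "active": ACTIVE, "1": ACTIVE, "true": ACTIVE,
    "inactive": INACTIVE, "0": INACTIVE, "false": INACTIVE,
}


def normalize_label(token: str) -> str:
    label = _LABEL_NORMALIZATION.get(token.strip().casefold())
    if label is None:
        raise SchemaError(f"unknown activity label {token!r}")
    return label


@dataclass(frozen=True)
class ActivityDataset:
    """One bioassay's compounds with binary activity labels."""

    dataset_id: str
    records: tuple  # of (compound_id, label)

    def __post_init__(self):
        records = tuple((cid, lab) for cid, lab in self.records)
        ids = [cid for cid, _ in records]
        dupes = sorted({cid for cid in ids if ids.count(cid) > 1})
        if dupes:
            raise SchemaError(f"duplicate compound_ids in {self.dataset_id!r}: {dupes}")
        for _cid, lab in records:
            if lab not in (ACTIVE, INACTIVE):
                raise SchemaError(f"label must be active/inactive, got {lab!r}")
        object.__setattr__(self, "records", records)

    @property
    def n_active(self) -> int:
        return sum(1 for _, lab in self.records if lab == ACTIVE)

    @property
    def n_inactive(self) -> int:
        return sum(1 for _, lab in self.records if lab == INACTIVE)

    @property
    def compound_ids(self) -> tuple:
        return tuple(cid for cid, _ in self.records)

    def labels(self) -> dict:
        return dict(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SplitPlan:
    """Repeated stratified 70/30 train/validation assignments.

    assignments[r] is a frozenset of the compound_ids in repeat r's
    training set; the complement is that repeat's validation set.
    """

    seed: int
    n_repeats: int
    train_fraction: float
    assignments: tuple  # of frozenset[compound_id]

    def validation_ids(self, dataset: ActivityDataset, repeat: int) -> tuple:
        train = self.assignments[repeat]
        return tuple(cid for cid in dataset.compound_ids if cid not in train)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _draw_plan(dataset: ActivityDataset, seed: int, n_repeats: int,
               train_fraction: float) -> SplitPlan:
    actives = [cid for cid, lab in dataset.records if lab == ACTIVE]
    inactives = [cid for cid, lab in dataset.records if lab == INACTIVE]
    n_train_a = _round_half_up(train_fraction * len(actives))
    n_train_i = _round_half_up(train_fraction * len(inactives))
    # every repeat must leave at least one compound of each class out
    n_train_a = min(n_train_a, len(actives) - 1)
    n_train_i = min(n_train_i, len(inactives) - 1)
    assignments = []
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        train = set(rng.permutation(actives)[:n_train_a])
        train |= set(rng.permutation(inactives)[:n_train_i])
        assignments.append(frozenset(train))
    return SplitPlan(seed, n_repeats, train_fraction, tuple(assignments))


def stratified_split(dataset: ActivityDataset, seed: int = 0, n_repeats: int = 30,
                     train_fraction: float = 0.70, max_redraws: int = 5,
                     require_coverage: bool = True) -> SplitPlan:
    """Repeated stratified random partition into 70% train / 30% validation.

    Per class the training count is round-half-up(train_fraction * class
    size), capped so each class keeps at least one validation compound.
    If some compound never lands in a validation set across all repeats the
    whole plan is re-drawn with an incremented seed (calibration needs
    out-of-sample scores for every training compound); pass
    require_coverage=False for standalone few-repeat plans.
    """
    if dataset.n_active < 2 or dataset.n_inactive < 2:
        raise DegenerateDataError(
            f"dataset {dataset.dataset_id!r} needs >=2 compounds per class "
            f"(got Na={dataset.n_active}, Ni={dataset.n_inactive})")
    if not require_coverage:
        return _draw_plan(dataset, seed, n_repeats, train_fraction)
    for attempt in range(max_redraws + 1):
        plan = _draw_plan(dataset, seed + attempt, n_repeats, train_fraction)
        in_validation = set()
        for r in range(n_repeats):
            in_validation.update(plan.validation_ids(dataset, r))
        if in_validation == set(dataset.compound_ids):
            return plan
    raise DegenerateDataError(
        f"could not cover every compound in a validation set after "
        f"{max_redraws + 1} plan draws for dataset {dataset.dataset_id!r}")


# --------------------------------------------------------------------------
# Tabular artifacts (all TSV with headers)
# --------------------------------------------------------------------------

def read_activity_tsv(path, dataset_id: str | None = None) -> ActivityDataset:
    """Read `compound_id<TAB>label` with header; labels are normalized."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise SchemaError(f"{path}: missing header (compound_id, label)")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise SchemaError(f"{path}:{lineno}: expected 2 columns")
            try:
                label = normalize_label(row[1])
            except SchemaError as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
            records.append((row[0].strip(), label))
    return ActivityDataset(dataset_id or str(path), tuple(records))


def write_activity_tsv(path, dataset: ActivityDataset) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["compound_id", "label"])
        writer.writerows(dataset.records)


def write_fingerprint_tsv(path, fingerprints: Mapping) -> None:
    """`compound_id<TAB>key1;key2;...`, keys and rows deterministically sorted."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["compound_id", "keys"])
        for cid in sorted(fingerprints):
            fp = fingerprints[cid]
            keys = fp.keys if isinstance(fp, ModalFingerprint) else fp
            writer.writerow([cid, ";".join(sorted(_serialize_key(k) for k in keys))])


def read_fingerprint_tsv(path) -> dict:
    fingerprints: dict = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[0] != "compound_id":
            raise SchemaError(f"{path}: missing fingerprint header")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            cid = row[0].strip()
            if cid in fingerprints:
                raise SchemaError(f"{path}:{lineno}: duplicate compound_id {cid!r}")
            blob = row[1] if len(row) > 1 else ""
            keys = frozenset(_deserialize_key(tok) for tok in blob.split(";") if tok)
            fingerprints[cid] = ModalFingerprint(cid, keys)
    return fingerprints


def _serialize_key(key) -> str:
    if isinstance(key, TripletKey):
        return key.serialize()
    return f"#{int(key)}"  # synthetic integer bit


def _deserialize_key(token: str):
    if token.startswith("#"):
        return int(token[1:])
    return TripletKey.deserialize(token)


def read_class_map_tsv(path) -> dict:
    """dataset_id -> class_id map; a dataset may appear under several classes."""
    mapping: dict = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise SchemaError(f"{path}: missing header (dataset_id, class_id)")
        for row in reader:
            if not row or len(row) < 2:
                continue
            mapping.setdefault(row[0].strip(), set()).add(row[1].strip())
    return {k: frozenset(v) for k, v in mapping.items()}


def write_class_map_tsv(path, mapping: Mapping) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["dataset_id", "class_id"])
        for dataset_id in sorted(mapping):
            classes = mapping[dataset_id]
            if isinstance(classes, str):
                classes = [classes]
            for class_id in sorted(classes):
                writer.writerow([dataset_id, class_id])


def read_pubchem_csv(path, dataset_id: str | None = None) -> ActivityDataset:
    """Optional importer for PubChem Bioassay exports.

    Keeps rows whose PUBCHEM_ACTIVITY_OUTCOME is Active/Inactive; every
    other outcome (Inconclusive, Unspecified, ...) is dropped.
    """
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "PUBCHEM_CID" not in reader.fieldnames:
            raise SchemaError(f"{path}: not a PubChem bioassay CSV")
        for row in reader:
            outcome = (row.get("PUBCHEM_ACTIVITY_OUTCOME") or "").strip().casefold()
            if outcome in ("active", "inactive"):
                records.append((row["PUBCHEM_CID"].strip(), outcome))
    return ActivityDataset(dataset_id or str(path), tuple(records))
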