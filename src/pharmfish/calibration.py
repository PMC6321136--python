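"""Rank-based Pa/Pi probability calibration with confidence limits.

A query's raw ensemble score is compared with the out-of-sample reference
score distributions of the training actives and inactives.  Pa is the
fraction of reference actives scoring worse, Pi the fraction of reference
inactives scoring better (ties count 1/2).  The member-score t-interval is
propagated through the same mapping to give upper/lower Pa-Pi limits; a
non-positive lower limit vetoes an active call (applicability-domain
filter: the ensemble disagrees too much to trust the mean).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import t as t_dist

from pharmfish.datasets import ACTIVE, INACTIVE
from pharmfish.ensemble import EnsembleModel
from pharmfish.errors import DegenerateDataError

DEFAULT_THRESHOLD = 0.15


@dataclass(frozen=True)
class Prediction:
    """Calibrated activity prediction for one compound against one model."""

    compound_id: str
    dataset_id: str
    method: str
    raw_mean: float
    raw_sd: float
    n_models: int
    pa_mean: float
    pi_mean: float
    papi_mean: float
    papi_upper: float
    papi_lower: float
    call: str
    empty_fingerprint: bool = False
    low_confidence: bool = False

    def __post_init__(self):
        if not (0 <= self.pa_mean <= 1 and 0 <= self.pi_mean <= 1):
            raise ValueError("Pa and Pi must lie in [0, 1]")
        if not self.papi_lower <= self.papi_mean <= self.papi_upper:
            raise ValueError("Pa-Pi limits must bracket the mean")
        if self.call not in (ACTIVE, INACTIVE):
            raise ValueError(f"bad call {self.call!r}")
        if self.call == ACTIVE and self.papi_lower <= 0:
            raise ValueError("active call requires a positive Pa-Pi lower limit")


def _fraction_with_half_ties(reference: Sequence[float], s: float, below: bool) -> float:
    ref = np.asarray(reference, dtype=float)
    if below:
        return float(((ref < s).sum() + 0.5 * (ref == s).sum()) / len(ref))
    return float(((ref > s).sum() + 0.5 * (ref == s).sum()) / len(ref))


def pa_pi(score: float, reference_actives: Sequence[float],
          reference_inactives: Sequence[float]) -> tuple:
    """(Pa, Pi) of a raw score against the reference distributions.

    Pa = fraction of reference actives with a worse (lower) score;
    Pi = fraction of reference inactives with a better (higher) score;
    ties contribute 1/2 in both.
    """
    if not math.isfinite(score):
        raise ValueError(f"non-finite score {score!r}")
    if not len(reference_actives) or not len(reference_inactives):
        raise DegenerateDataError("empty reference class for Pa/Pi")
    pa = _fraction_with_half_ties(reference_actives, score, below=True)
    pi = _fraction_with_half_ties(reference_inactives, score, below=False)
    return pa, pi


def score_limits(member_scores: Sequence[float],
                 confidence: float = 0.95) -> tuple:
    """(mean, lower, upper): mean +/- t(1-(1-conf)/2, N-1) * SD/sqrt(N)."""
    values = np.asarray(member_scores, dtype=float)
    n = len(values)
    if n < 2:
        raise DegenerateDataError("score limits need at least 2 member scores")
    mean = float(values.mean())
    sem = float(values.std(ddof=1)) / math.sqrt(n)
    half = float(t_dist.ppf(0.5 + confidence / 2, n - 1)) * sem
    return mean, mean - half, mean + half


def decide_call(papi_mean: float, papi_lower: float,
                threshold: float = DEFAULT_THRESHOLD) -> str:
    """Active iff Pa-Pi mean >= threshold (inclusive) AND the lower limit
    is strictly positive; a non-positive lower limit always vetoes."""
    return ACTIVE if (papi_mean >= threshold and papi_lower > 0) else INACTIVE


def predict(ensemble: EnsembleModel, fingerprint, compound_id: str = "",
            threshold: float = DEFAULT_THRESHOLD,
            confidence: float = 0.95) -> Prediction:
    """Score, calibrate and call one compound against one ensemble.

    Pa-Pi mean comes from the mean member score; the upper limit maps the
    upper score limit (highest Pa minus lowest Pi) and the lower limit the
    lower score limit.  Call is active iff papi_mean >= threshold AND
    papi_lower > 0.  With a single member the limits are undefined and the
    compound is flagged low-confidence and called inactive.
    """
    if not -1 <= threshold <= 1:
        raise ValueError("threshold must be in [-1, 1]")
    keys = fingerprint.keys if hasattr(fingerprint, "keys") and not isinstance(
        fingerprint, (set, frozenset)) else fingerprint
    empty = len(keys) == 0
    values = [m.score_keys(fingerprint) for m in ensemble.members]
    ref_a, ref_i = ensemble.reference_scores()

    if len(values) < 2:
        mean = float(values[0])
        pa, pi = pa_pi(mean, ref_a, ref_i)
        return Prediction(
            compound_id=compound_id, dataset_id=ensemble.dataset_id,
            method=ensemble.method, raw_mean=mean, raw_sd=0.0, n_models=1,
            pa_mean=pa, pi_mean=pi, papi_mean=pa - pi,
            papi_upper=pa - pi, papi_lower=min(pa - pi, 0.0),
            call=INACTIVE, empty_fingerprint=empty, low_confidence=True)

    mean, lower, upper = score_limits(values, confidence=confidence)
    sd = float(np.std(values, ddof=1))
    pa, pi = pa_pi(mean, ref_a, ref_i)
    pa_hi, pi_hi = pa_pi(upper, ref_a, ref_i)
    pa_lo, pi_lo = pa_pi(lower, ref_a, ref_i)
    papi_mean = pa - pi
    papi_upper = pa_hi - pi_hi   # higher Pa minus lowest Pi
    papi_lower = pa_lo - pi_lo   # lower Pa minus highest Pi
    call = decide_call(papi_mean, papi_lower, threshold)
    return Prediction(
        compound_id=compound_id, dataset_id=ensemble.dataset_id,
        method=ensemble.method, raw_mean=mean, raw_sd=sd, n_models=len(values),
        pa_mean=pa, pi_mean=pi, papi_mean=papi_mean,
        papi_upper=papi_upper, papi_lower=papi_lower, call=call,
        empty_fingerprint=empty)


def combine_methods(pred_svm: Prediction, pred_nb: Prediction) -> Prediction:
    """OR-combination: active if either method predicted active."""
    if (pred_svm.compound_id != pred_nb.compound_id
            or pred_svm.dataset_id != pred_nb.dataset_id):
        raise ValueError("cannot combine predictions of different compounds/datasets")
    preds = (pred_svm, pred_nb)
    active = [p for p in preds if p.call == ACTIVE]
    # carry the fields of the stronger (or only) active prediction
    carrier = max(active, key=lambda p: p.papi_mean) if active else max(
        preds, key=lambda p: p.papi_mean)
    call = ACTIVE if active else INACTIVE
    return Prediction(
        compound_id=carrier.compound_id, dataset_id=carrier.dataset_id,
        method="both", raw_mean=carrier.raw_mean, raw_sd=carrier.raw_sd,
        n_models=carrier.n_models, pa_mean=carrier.pa_mean,
        pi_mean=carrier.pi_mean, papi_mean=carrier.papi_mean,
        papi_upper=carrier.papi_upper, papi_lower=carrier.papi_lower,
        call=call, empty_fingerprint=carrier.empty_fingerprint,
        low_confidence=carrier.low_confidence)


PREDICTION_COLUMNS = ("compound_id", "dataset_id", "method", "raw_mean",
                      "papi_mean", "papi_lower", "papi_upper", "call")


def write_predictions_tsv(path, predictions: Sequence[Prediction]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PREDICTION_COLUMNS)
        for p in predictions:
            writer.writerow([p.compound_id, p.dataset_id, p.method,
                             repr(p.raw_mean), repr(p.papi_mean),
                             repr(p.papi_lower), repr(p.papi_upper), p.call])
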