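"""Evaluate a scoring model on feature vectors.

The linear predictor is ``L = intercept + sum_j beta_j * count_j`` with the
summation in fixed covariate order so results are bit-stable, and the
probability is the logistic transform ``p = exp(L) / (1 + exp(L))``
computed in its numerically stable branch form (no overflow for large
``|L|``).  A patient is classified as having physician-documented insomnia
when ``p`` reaches the model's probability threshold; ties at the threshold
classify positive (the conservative-toward-sensitivity convention, which is
configurable only by nudging the threshold itself).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

from .emr_model import FeatureVector, ModelSpec, ScoreResult

__all__ = [
    "linear_predictor",
    "probability",
    "classify",
    "score_corpus",
    "stable_logistic",
]


def linear_predictor(fv: FeatureVector, model: ModelSpec) -> float:
    """The log-odds L of physician-documented insomnia for one patient."""
    total = model.intercept
    for name, coef in model.ordered_coefficients():
        total += coef * getattr(fv, name)
    return total


def stable_logistic(x: float) -> float:
    """exp(x)/(1+exp(x)) without overflow for large |x|."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def probability(fv: FeatureVector, model: ModelSpec) -> float:
    """The modeled probability of physician-documented insomnia."""
    return stable_logistic(linear_predictor(fv, model))


def classify(fv: FeatureVector, model: ModelSpec,
             patient_id: str = "") -> ScoreResult:
    """Score one patient and threshold the probability.

    Requires the model to carry a threshold (run threshold selection first
    for a freshly fit model).
    """
    if model.threshold is None:
        raise ValueError("model has no threshold; run select_threshold or "
                         "load a thresholded model")
    L = linear_predictor(fv, model)
    p = stable_logistic(L)
    return ScoreResult(patient_id=patient_id, linear_predictor=L,
                       probability=p,
                       classified_insomnia=p >= model.threshold)


def score_corpus(features: Mapping[str, FeatureVector],
                 model: ModelSpec) -> list[ScoreResult]:
    """Score every patient, ordered by patient id for determinism."""
    if not features:
        raise ValueError("no feature vectors to score")
    return [classify(features[pid], model, patient_id=pid)
            for pid in sorted(features)]


def positives(results: Sequence[ScoreResult]) -> list[ScoreResult]:
    """The classified-positive subset, preserving order."""
    return [r for r in results if r.classified_insomnia]
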