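"""Model development protocol: adaptive-LASSO logistic regression over
variable subsets, specificity-anchored threshold calibration, bootstrap
AUROC confidence intervals, and a permutation overfitting check.

The adaptive LASSO is the two-stage estimator: a pilot (unpenalized, or
ridge-stabilized under separation) logistic fit produces coefficients
``b0``; the second stage solves an L1-penalized logistic regression with
per-covariate penalty weights ``1/|b0_j|**gamma`` (gamma defaults to 1),
implemented by rescaling each column by ``|b0_j|**gamma`` and penalizing
uniformly.  Penalty strength is chosen by k-fold cross-validated deviance
over a geometric path.  Covariates with zero second-stage coefficient are
dropped, and the returned model's coefficients come from an unpenalized
("relaxed") refit on the selected support — so the reported coefficients
are maximum-likelihood estimates on the selected variables rather than
shrunken values, matching how clinical scoring equations are reported.

Counts enter the model untransformed and unstandardized; the adaptive
penalty weights absorb scale differences.  AUROC uses the rank-statistic
(Mann-Whitney) form with half credit for ties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .emr_model import FEATURE_NAMES, FeatureVector, ModelSpec
from .scoring import stable_logistic

__all__ = [
    "TrainConfig",
    "SUBSET_COVARIATES",
    "auroc",
    "split_train_validation",
    "fit_adaptive_lasso",
    "refit_standard_errors",
    "ThresholdSelection",
    "threshold_from_probabilities",
    "select_threshold",
    "AurocCI",
    "bootstrap_auroc_ci",
    "OverfitReport",
    "overfitting_check",
    "SubsetResult",
    "compare_subsets",
    "design_matrix",
    "model_probabilities",
]

# Covariates available to each variable-subset configuration.
SUBSET_COVARIATES: dict[str, tuple[str, ...]] = {
    "icd_only": ("n_insomnia_codes",),
    "structured_only": ("n_insomnia_codes", "n_anxdep_codes",
                        "n_insomnia_rx", "n_joint_codes", "n_emr_facts"),
    "unstructured_only": ("n_sleep_notes", "n_psych_notes"),
    "combined": FEATURE_NAMES,
}

_POSITIVE = "insomnia"


@dataclass(frozen=True)
class TrainConfig:
    """Protocol parameters.

    ``train_fraction`` 2/3 and ``target_specificity`` 0.97 are the
    protocol's published anchors; ``bootstrap_reps`` 1000 and
    ``overfit_permutations`` 100 are the published replication counts.
    ``adaptive_gamma``, the cross-validation fold count and the penalty
    path are the literature-standard defaults for the adaptive LASSO.
    """

    variable_subset: str = "combined"
    train_fraction: float = 2.0 / 3.0
    target_specificity: float = 0.97
    bootstrap_reps: int = 1000
    overfit_permutations: int = 100
    adaptive_gamma: float = 1.0
    penalty_selection: str = "bic"  # "bic" or "cv" (k-fold deviance)
    cv_folds: int = 5
    n_lambda: int = 30
    lambda_min_ratio: float = 1e-4
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variable_subset not in SUBSET_COVARIATES:
            raise ValueError(f"unknown variable_subset "
                             f"{self.variable_subset!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0.0 <= self.target_specificity <= 1.0:
            raise ValueError("target_specificity must lie in [0, 1]")
        for name in ("bootstrap_reps", "overfit_permutations", "cv_folds",
                     "n_lambda"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.adaptive_gamma <= 0:
            raise ValueError("adaptive_gamma must be positive")
        if self.penalty_selection not in ("bic", "cv"):
            raise ValueError("penalty_selection must be 'bic' or 'cv'")


def _binary_labels(labels: Mapping[str, str],
                   ids: Sequence[str]) -> np.ndarray:
    return np.array([1 if labels[i] == _POSITIVE else 0 for i in ids],
                    dtype=np.int64)


def design_matrix(features: Mapping[str, FeatureVector],
                  ids: Sequence[str],
                  covariates: Sequence[str]) -> np.ndarray:
    """Rows in ``ids`` order, columns in ``covariates`` order."""
    return np.array([[getattr(features[i], c) for c in covariates]
                     for i in ids], dtype=float)


def model_probabilities(model: ModelSpec,
                        features: Mapping[str, FeatureVector],
                        ids: Sequence[str]) -> np.ndarray:
    """Model probability for each patient, in ``ids`` order."""
    out = np.empty(len(ids))
    coefs = model.ordered_coefficients()
    for k, pid in enumerate(ids):
        fv = features[pid]
        L = model.intercept + sum(c * getattr(fv, n) for n, c in coefs)
        out[k] = stable_logistic(L)
    return out


def auroc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(score_case > score_control) with half credit
    for ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def split_train_validation(labels: Mapping[str, str], fraction: float,
                           seed: int) -> tuple[list[str], list[str]]:
    """Stratified-by-label random split: per stratum, floor(fraction * n)
    ids go to training.  Deterministic under seed; exact partition."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    classes = set(labels.values())
    if len(classes) < 2:
        raise ValueError("split requires both label classes present")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    val: list[str] = []
    for cls in sorted(classes):
        ids = sorted(i for i, s in labels.items() if s == cls)
        perm = rng.permutation(len(ids))
        n_train = int(math.floor(fraction * len(ids)))
        train.extend(ids[j] for j in perm[:n_train])
        val.extend(ids[j] for j in perm[n_train:])
    return sorted(train), sorted(val)


def _pilot_fit(X: np.ndarray, y: np.ndarray,
               max_iter: int) -> np.ndarray:
    """Unpenalized logistic pilot; ridge-stabilized fallback when the
    likelihood is monotone (separation) or the fit diverges."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(penalty=None, solver="lbfgs",
                                 max_iter=max_iter)
        clf.fit(X, y)
    coefs = clf.coef_.ravel()
    if not np.all(np.isfinite(coefs)) or np.max(np.abs(coefs)) > 30.0:
        warnings.warn("separation detected in pilot logistic fit; "
                      "falling back to a ridge-stabilized pilot")
        clf = LogisticRegression(penalty="l2", C=1.0, solver="lbfgs",
                                 max_iter=max_iter)
        clf.fit(X, y)
        coefs = clf.coef_.ravel()
    return coefs


def fit_adaptive_lasso(features: Mapping[str, FeatureVector],
                       labels: Mapping[str, str],
                       config: TrainConfig,
                       ids: Sequence[str] | None = None) -> ModelSpec:
    """Two-stage adaptive-LASSO logistic fit on the configured variable
    subset.  The returned model has no threshold; run
    :func:`select_threshold` on held-out data to calibrate one.
    """
    ids = sorted(ids) if ids is not None else sorted(features)
    if len(ids) < 10:
        raise ValueError("need at least 10 labeled rows to fit")
    covariates = list(SUBSET_COVARIATES[config.variable_subset])
    X = design_matrix(features, ids, covariates)
    y = _binary_labels(labels, ids)
    if y.min() == y.max():
        raise ValueError("labels are single-class; cannot fit")

    pilot = _pilot_fit(X, y, config.max_iter)
    w = np.abs(pilot) ** config.adaptive_gamma
    live = np.flatnonzero(w > 1e-10)
    if live.size == 0:
        warnings.warn("pilot fit found no usable covariates; returning an "
                      "intercept-only model")
        return _relaxed_refit(X[:, :0], y, [], config)

    Xw = X[:, live] * w[live]
    # inverse penalty strengths, weakest penalty last
    Cs = np.geomspace(config.lambda_min_ratio, 1.0, config.n_lambda) * 1e3
    if config.penalty_selection == "bic":
        chosen_C = _select_C_bic(Xw, y, Cs, config)
    else:
        chosen_C = _select_C_cv(Xw, y, Cs, config)
    beta_scaled = _l1_fit(Xw, y, chosen_C, config.max_iter)
    support = live[np.flatnonzero(np.abs(beta_scaled) > 1e-10)]
    selected = [covariates[j] for j in support]
    return _relaxed_refit(X[:, support], y, selected, config)


def _l1_fit(Xw: np.ndarray, y: np.ndarray, C: float,
            max_iter: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(penalty="l1", C=C, solver="liblinear",
                                 max_iter=max_iter)
        clf.fit(Xw, y)
    return clf.coef_.ravel()


def _select_C_bic(Xw: np.ndarray, y: np.ndarray, Cs: np.ndarray,
                  config: TrainConfig) -> float:
    """Penalty strength minimizing BIC = deviance + df*ln(n) along the
    path (df = selected covariates + intercept); ties go to the stronger
    penalty.  BIC is the selection-consistent choice for the adaptive
    LASSO."""
    n = len(y)
    best_bic, best_C = math.inf, Cs[0]
    for C in Cs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LogisticRegression(penalty="l1", C=C, solver="liblinear",
                                     max_iter=config.max_iter)
            clf.fit(Xw, y)
        beta = clf.coef_.ravel()
        p = np.clip(clf.predict_proba(Xw)[:, 1], 1e-12, 1 - 1e-12)
        deviance = -2.0 * float(np.sum(y * np.log(p)
                                       + (1 - y) * np.log(1 - p)))
        df = int(np.sum(np.abs(beta) > 1e-10)) + 1
        bic = deviance + df * math.log(n)
        if bic < best_bic - 1e-9:
            best_bic, best_C = bic, float(C)
    return best_C


def _select_C_cv(Xw: np.ndarray, y: np.ndarray, Cs: np.ndarray,
                 config: TrainConfig) -> float:
    """Penalty strength minimizing k-fold cross-validated deviance."""
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                         random_state=config.seed % (2**31))
    losses = np.zeros((config.cv_folds, len(Cs)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f, (tr, te) in enumerate(cv.split(Xw, y)):
            for j, C in enumerate(Cs):
                clf = LogisticRegression(penalty="l1", C=C,
                                         solver="liblinear",
                                         max_iter=config.max_iter)
                clf.fit(Xw[tr], y[tr])
                losses[f, j] = log_loss(y[te],
                                        clf.predict_proba(Xw[te])[:, 1],
                                        labels=[0, 1])
    return float(Cs[int(losses.mean(axis=0).argmin())])


def _relaxed_refit(Xs: np.ndarray, y: np.ndarray, selected: list[str],
                   config: TrainConfig) -> ModelSpec:
    """Unpenalized logistic refit on the selected support (the reported
    coefficients are MLEs, not shrunken values)."""
    if Xs.shape[1] == 0:
        p = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        return ModelSpec(intercept=math.log(p / (1 - p)), coefficients={},
                         variable_subset=config.variable_subset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(penalty=None, solver="lbfgs",
                                 max_iter=config.max_iter)
        clf.fit(Xs, y)
    coefs = dict(zip(selected, clf.coef_.ravel().tolist()))
    return ModelSpec(intercept=float(clf.intercept_[0]), coefficients=coefs,
                     variable_subset=config.variable_subset)


def refit_standard_errors(features: Mapping[str, FeatureVector],
                          labels: Mapping[str, str],
                          model: ModelSpec,
                          ids: Sequence[str] | None = None
                          ) -> dict[str, float]:
    """Wald standard errors of the model's coefficients (and intercept,
    keyed ``"intercept"``) from the observed information matrix evaluated
    at the model's coefficients on the given data."""
    ids = sorted(ids) if ids is not None else sorted(features)
    covariates = [n for n, _ in model.ordered_coefficients()]
    X = design_matrix(features, ids, covariates)
    Xd = np.column_stack([np.ones(len(ids)), X])
    beta = np.array([model.intercept]
                    + [model.coefficients[c] for c in covariates])
    eta = Xd @ beta
    p = np.array([stable_logistic(v) for v in eta])
    W = p * (1 - p)
    info = Xd.T @ (Xd * W[:, None])
    cov = np.linalg.pinv(info)
    ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return {"intercept": float(ses[0]),
            **{c: float(ses[k + 1]) for k, c in enumerate(covariates)}}


# ---------------------------------------------------------------------------
# Threshold selection


@dataclass(frozen=True)
class ThresholdSelection:
    """A thresholded model plus the operating point achieved on the
    threshold-selection (validation) data."""

    model: ModelSpec
    achieved_specificity: float
    achieved_sensitivity: float | None
    n_negatives: int


def threshold_from_probabilities(probs: np.ndarray, y: np.ndarray,
                                 target_specificity: float) -> float:
    """Smallest candidate cut point achieving the target specificity on
    the negatives.  Candidates are the observed probabilities; a tie at
    the cut classifies positive, so specificity at t is the fraction of
    negatives strictly below t.  Falls back (with a warning) to a cut just
    above the largest negative probability when the negatives are too few
    to resolve the target (fewer than ``1/(1-target)``)."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    neg = probs[y == 0]
    if neg.size == 0:
        raise ValueError("threshold selection requires validation negatives")
    if target_specificity > 0 and neg.size < 1.0 / max(1e-12,
                                                       1 - target_specificity):
        warnings.warn(
            f"{neg.size} negatives cannot resolve specificity "
            f"{target_specificity}; using a cut just above the largest "
            f"negative probability")
        return float(np.nextafter(neg.max(), 1.0))
    for t in np.unique(probs):
        if np.mean(neg < t) >= target_specificity:
            return float(t)
    return float(np.nextafter(neg.max(), 1.0))


def select_threshold(model: ModelSpec,
                     features: Mapping[str, FeatureVector],
                     labels: Mapping[str, str],
                     target_specificity: float = 0.97,
                     ids: Sequence[str] | None = None) -> ThresholdSelection:
    """Pick the smallest probability cut point whose specificity on the
    validation negatives reaches the target.

    Candidate cut points are the observed validation probabilities (a tie
    at the threshold classifies positive, so specificity at cut point t is
    the fraction of negatives scoring strictly below t).  With fewer than
    ``1/(1-target)`` negatives the target is unresolvable; the cut point
    is then placed just above the largest negative probability (warns).
    """
    ids = sorted(ids) if ids is not None else sorted(features)
    probs = model_probabilities(model, features, ids)
    y = _binary_labels(labels, ids)
    neg = probs[y == 0]
    pos = probs[y == 1]
    threshold = threshold_from_probabilities(probs, y, target_specificity)
    achieved_spec = float(np.mean(neg < threshold))
    achieved_sens = float(np.mean(pos >= threshold)) if pos.size else None
    return ThresholdSelection(
        model=replace(model, threshold=threshold),
        achieved_specificity=achieved_spec,
        achieved_sensitivity=achieved_sens,
        n_negatives=int(neg.size))


# ---------------------------------------------------------------------------
# Bootstrap AUROC


@dataclass(frozen=True)
class AurocCI:
    auroc: float
    ci_low: float
    ci_high: float
    reps: int


def bootstrap_auroc_ci(model: ModelSpec,
                       features: Mapping[str, FeatureVector],
                       labels: Mapping[str, str],
                       reps: int = 1000, seed: int = 0,
                       ids: Sequence[str] | None = None) -> AurocCI:
    """Point AUROC on the full validation set plus percentile 2.5/97.5
    bounds over patient-resampled bootstrap replicates.

    Replicates that draw a single class are redrawn.  The percentile
    bounds are widened, if necessary, to bracket the point estimate.
    """
    ids = sorted(ids) if ids is not None else sorted(features)
    probs = model_probabilities(model, features, ids)
    y = _binary_labels(labels, ids)
    point = auroc(probs, y)
    rng = np.random.default_rng(seed)
    n = len(ids)
    stats = np.empty(reps)
    for r in range(reps):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap "
                               "replicate")
        stats[r] = auroc(probs[idx], yb)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return AurocCI(auroc=point, ci_low=float(min(lo, point)),
                   ci_high=float(max(hi, point)), reps=reps)


# ---------------------------------------------------------------------------
# Overfitting check


@dataclass(frozen=True)
class OverfitReport:
    mean_auroc: float
    standard_error: float | None
    aurocs: tuple[float, ...]
    external_auroc: float | None = None

    @property
    def gap(self) -> float | None:
        if self.external_auroc is None:
            return None
        return abs(self.mean_auroc - self.external_auroc)


def overfitting_check(features: Mapping[str, FeatureVector],
                      labels: Mapping[str, str],
                      config: TrainConfig,
                      ids: Sequence[str] | None = None,
                      external_auroc: float | None = None) -> OverfitReport:
    """Repeated sub-splits of the training set: refit on the
    sub-derivation part, score the held-out sub-validation part, and
    average the AUROCs.  A mean close to the external-validation AUROC
    indicates no overfitting."""
    ids = sorted(ids) if ids is not None else sorted(features)
    sub_labels = {i: labels[i] for i in ids}
    rng = np.random.default_rng(config.seed)
    perm_seeds = rng.integers(0, 2**31 - 1, size=config.overfit_permutations)
    aurocs = []
    for s in perm_seeds:
        tr, va = split_train_validation(sub_labels, config.train_fraction,
                                        int(s))
        sub_model = fit_adaptive_lasso(features, labels,
                                       replace(config, seed=int(s)), ids=tr)
        probs = model_probabilities(sub_model, features, va)
        aurocs.append(auroc(probs, _binary_labels(labels, va)))
    arr = np.array(aurocs)
    se = (float(arr.std(ddof=1) / math.sqrt(len(arr)))
          if len(arr) > 1 else None)
    return OverfitReport(mean_auroc=float(arr.mean()), standard_error=se,
                         aurocs=tuple(arr.tolist()),
                         external_auroc=external_auroc)


# ---------------------------------------------------------------------------
# Variable-subset comparison


@dataclass(frozen=True)
class SubsetResult:
    subset: str
    auroc: float
    ci_low: float
    ci_high: float
    threshold: float
    achieved_specificity: float
    achieved_sensitivity: float | None
    model: ModelSpec


def compare_subsets(features: Mapping[str, FeatureVector],
                    labels: Mapping[str, str],
                    config: TrainConfig,
                    subsets: Sequence[str] = ("combined", "structured_only",
                                              "unstructured_only",
                                              "icd_only")) -> list[SubsetResult]:
    """Run the full fit + threshold + bootstrap protocol once per variable
    subset on identical train/validation splits."""
    labeled = {i: s for i, s in labels.items() if i in features}
    train_ids, val_ids = split_train_validation(
        labeled, config.train_fraction, config.seed)
    rows: list[SubsetResult] = []
    for subset in subsets:
        cfg = replace(config, variable_subset=subset)
        model = fit_adaptive_lasso(features, labels, cfg, ids=train_ids)
        sel = select_threshold(model, features, labels,
                               cfg.target_specificity, ids=val_ids)
        ci = bootstrap_auroc_ci(sel.model, features, labels,
                                reps=cfg.bootstrap_reps, seed=cfg.seed,
                                ids=val_ids)
        rows.append(SubsetResult(
            subset=subset, auroc=ci.auroc, ci_low=ci.ci_low,
            ci_high=ci.ci_high, threshold=sel.model.threshold,
            achieved_specificity=sel.achieved_specificity,
            achieved_sensitivity=sel.achieved_sensitivity,
            model=sel.model))
    return rows
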