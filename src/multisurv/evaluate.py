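"""Balanced nested cross-validation of a random-forest survival classifier.

The outer stratified 10-fold loop estimates generalization AUC; inside each
outer training fold the classes are balanced by down-sampling the majority
class (minority kept whole, majority subsampled to a fraction), and an inner
leave-one-out loop tunes the forest's variables-per-split parameter by pooling
all leave-one-out probability predictions and computing one AUC per candidate.
The winner is refit on the balanced training portion and applied to the
untouched outer test fold; outer predictions are pooled per repeat into a
ROC/AUC, and the whole procedure is repeated with fresh RNG substreams.
Monte-Carlo SHAP values (permutation-sampling estimator) attribute outer-fold
predictions to features; positive SHAP pushes toward the nonsurvivor class.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from multisurv.formats import FeatureMatrix
from multisurv.labels import LabelSet

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class NestedCvConfig:
    outer_folds: int = 10
    tune_grid_size: int = 10
    minority_multiplier: float = 1.0
    majority_fraction: float = 0.3
    repeats: int = 100
    shap_nsim: int = 10
    n_trees: int = 500
    inner_n_trees: int | None = None  # forest size for inner-loop tuning fits
    compute_shap: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.majority_fraction <= 1:
            raise ValueError("majority_fraction must be in (0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclasses.dataclass
class NestedCvResult:
    predictions: pd.DataFrame  # repeat, sample_id, prob_nonsurvivor, label
    auc_per_repeat: list[float]
    chosen_params: pd.DataFrame  # repeat, fold, max_features
    shap: pd.DataFrame | None  # samples x features, averaged over repeats

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_repeat))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.auc_per_repeat, ddof=1)) if len(self.auc_per_repeat) > 1 else 0.0


def balance_downsample(
    samples: np.ndarray,
    labels: np.ndarray,
    minority_multiplier: float = 1.0,
    majority_fraction: float = 0.3,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Down-sample the majority class (and optionally resample the minority).

    The minority class is kept in full when ``minority_multiplier == 1`` and
    resampled with replacement to ``round(multiplier * n_minor)`` otherwise;
    the majority class is subsampled without replacement to
    ``ceil(fraction * n_major)``.  Returns indices into ``samples``.
    """
    rng = rng or np.random.default_rng()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("balancing requires exactly two classes")
    minor_cls = classes[counts.argmin()]
    minor_idx = np.flatnonzero(labels == minor_cls)
    major_idx = np.flatnonzero(labels != minor_cls)
    n_major = int(np.ceil(majority_fraction * len(major_idx)))
    if n_major < 1:
        raise ValueError("majority_fraction leaves no majority samples")
    if minority_multiplier == 1.0:
        keep_minor = minor_idx
    else:
        n_minor = max(1, round(minority_multiplier * len(minor_idx)))
        keep_minor = rng.choice(minor_idx, size=n_minor, replace=True)
    keep_major = rng.choice(major_idx, size=n_major, replace=False)
    out = np.concatenate([keep_minor, keep_major])
    rng.shuffle(out)
    return out


def pooled_roc_auc(y_true: np.ndarray, scores: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC via the rank (Mann-Whitney) statistic with midranks."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(y_true, scores)
    auc = float(roc_auc_score(y_true, scores))
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return roc, auc


def _mtry_grid(n_features: int, size: int) -> list[int]:
    """Candidate variables-per-split values: sqrt-anchored, evenly spread in [2, p]."""
    if n_features <= 2:
        return [max(1, n_features)]
    grid = set(np.round(np.linspace(2, n_features, size)).astype(int))
    grid.add(max(1, int(round(np.sqrt(n_features)))))
    return sorted(g for g in grid if 1 <= g <= n_features)


def _fit_rf(X, y, mtry, n_trees, rs):
    return RandomForestClassifier(n_estimators=n_trees, max_features=mtry,
                                  n_jobs=1, random_state=rs).fit(X, y)


def _inner_loocv_auc(X, y, mtry, n_trees, rs) -> float:
    """AUC of pooled leave-one-out probability predictions at one mtry."""
    probs = np.empty(len(y))
    mask = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        mask[i] = False
        clf = _fit_rf(X[mask], y[mask], mtry, n_trees, rs)
        probs[i] = clf.predict_proba(X[i:i + 1])[0, clf.classes_.tolist().index(1)]
        mask[i] = True
    if len(np.unique(y)) < 2:
        return 0.5
    return roc_auc_score(y, probs)


def nested_cv_evaluate(
    matrix: FeatureMatrix,
    labels: LabelSet,
    config: NestedCvConfig,
) -> NestedCvResult:
    """Run the full balanced nested cross-validation (see module docstring)."""
    y_all = labels.binary()
    keep = [s for s in matrix.sample_ids if s in y_all.index]
    dropped = matrix.values.shape[0] - len(keep)
    if dropped:
        logger.info("dropped %d samples without labels", dropped)
    X_df = matrix.values.loc[keep]
    incomplete = X_df.isna().mean(axis=1) > 0.5
    if incomplete.any():
        logger.info("dropped %d samples missing most features", int(incomplete.sum()))
        X_df = X_df.loc[~incomplete]
    X = X_df.to_numpy(dtype=float)
    y = y_all.loc[X_df.index].to_numpy()
    samples = np.array(X_df.index)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")

    master = np.random.SeedSequence(config.seed)
    repeat_seeds = master.spawn(config.repeats)
    grid = _mtry_grid(X.shape[1], config.tune_grid_size)

    pred_rows, aucs, param_rows = [], [], []
    shap_sum = np.zeros_like(X, dtype=float)
    shap_count = np.zeros(len(y))
    for rep, seq in enumerate(repeat_seeds):
        rng = np.random.default_rng(seq)
        cv = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                             random_state=int(rng.integers(2**31)))
        probs = np.empty(len(y))
        ok = True
        for fold, (tr, te) in enumerate(cv.split(X, y)):
            bal_local = balance_downsample(tr, y[tr], config.minority_multiplier,
                                           config.majority_fraction, rng)
            bal = tr[bal_local]
            if len(np.unique(y[bal])) < 2:
                logger.warning("repeat %d fold %d single-class after balancing; "
                               "repeat aborted", rep, fold)
                ok = False
                break
            inner_rs = int(rng.integers(2**31))
            inner_trees = config.inner_n_trees or config.n_trees
            best_mtry, best_auc = grid[0], -np.inf
            for mtry in grid:
                mtry_eff = min(mtry, X.shape[1])
                auc = _inner_loocv_auc(X[bal], y[bal], mtry_eff, inner_trees, inner_rs)
                if auc > best_auc:
                    best_mtry, best_auc = mtry_eff, auc
            clf = _fit_rf(X[bal], y[bal], best_mtry, config.n_trees,
                          int(rng.integers(2**31)))
            pos = clf.classes_.tolist().index(1)
            probs[te] = clf.predict_proba(X[te])[:, pos]
            param_rows.append({"repeat": rep, "fold": fold, "max_features": best_mtry})
            if config.compute_shap and config.shap_nsim > 0:
                phi = shap_values(clf, pd.DataFrame(X[te], columns=X_df.columns),
                                  nsim=config.shap_nsim, rng=rng,
                                  background=X[bal])
                shap_sum[te] += phi.to_numpy()
                shap_count[te] += 1
        if not ok:
            continue
        _, auc = pooled_roc_auc(y, probs)
        aucs.append(auc)
        pred_rows.append(pd.DataFrame({"repeat": rep, "sample_id": samples,
                                       "prob_nonsurvivor": probs, "label": y}))
    if not aucs:
        raise RuntimeError("every repeat aborted; check class sizes and balancing")
    shap = None
    if config.compute_shap and config.shap_nsim > 0 and shap_count.all():
        shap = pd.DataFrame(shap_sum / shap_count[:, None], index=X_df.index,
                            columns=X_df.columns)
    return NestedCvResult(
        predictions=pd.concat(pred_rows, ignore_index=True),
        auc_per_repeat=aucs,
        chosen_params=pd.DataFrame(param_rows),
        shap=shap,
    )


def shap_values(
    model,
    matrix: pd.DataFrame,
    nsim: int = 10,
    rng: np.random.Generator | None = None,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Monte-Carlo SHAP values by permutation sampling.

    For each explained sample and each of ``nsim`` simulations, a random
    feature permutation and a random background sample are drawn; walking the
    permutation, features are switched one by one from the background value to
    the explained sample's value, and each feature is credited with the change
    in predicted nonsurvivor probability its switch causes.  The average over
    simulations estimates the Shapley value.  Positive values push the
    prediction toward the positive (nonsurvivor) class.
    """
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    rng = rng or np.random.default_rng()
    X = matrix.to_numpy(dtype=float)
    bg = X if background is None else np.asarray(background, dtype=float)
    n, p = X.shape
    pos = model.classes_.tolist().index(1)

    def f(data: np.ndarray) -> np.ndarray:
        return model.predict_proba(data)[:, pos]

    phi = np.zeros((n, p))
    for _ in range(nsim):
        perm = rng.permutation(p)
        current = bg[rng.integers(len(bg), size=n)].copy()
        prev = f(current)
        for j in perm:
            current[:, j] = X[:, j]
            cur = f(current)
            phi[:, j] += cur - prev
            prev = cur
    return pd.DataFrame(phi / nsim, index=matrix.index, columns=matrix.columns)
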