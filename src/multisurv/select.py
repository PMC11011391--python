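"""Feature filtering and selection.

Two screening filters (zero variance, greedy correlation pruning at |r| > 0.9)
precede two selection engines:

* ``lasso_auc_profile`` — an L1-penalized logistic-regression path; at each of
  ~100 log-spaced penalties it records the number of nonzero coefficients on
  the full data and the stratified k-fold cross-validated AUC, profiling how
  predictive a feature family is as a function of how many features it is
  allowed (the per-omics comparison tool).
* ``boruta_rank`` — shadow-feature selection: each undecided feature gets a
  permuted copy, a random forest is fit on real + shadow columns, and a
  feature scores a "hit" when its importance Z-score beats the best shadow.
  Two-sided binomial tests on hit counts (Bonferroni over undecided features)
  confirm or reject features; the loop stops when all are decided or at
  ``max_runs``, leaving the rest tentative.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from multisurv.formats import FeatureMatrix
from multisurv.labels import LabelSet

logger = logging.getLogger(__name__)

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"


def zero_variance_filter(matrix: FeatureMatrix) -> FeatureMatrix:
    """Remove features with identical values across all samples."""
    values = matrix.values
    keep = [c for c in values.columns if values[c].nunique(dropna=False) > 1]
    return matrix.subset(keep)


def correlation_filter(matrix: FeatureMatrix, cutoff: float = 0.9
                       ) -> tuple[FeatureMatrix, list[str]]:
    """Greedy pruning of feature pairs with |Pearson r| > cutoff.

    Pairs are processed in descending |r|; from each offending pair the member
    with the larger mean absolute correlation against all remaining features
    is removed (ties: the later column).  Repeats until no pair exceeds the
    cutoff.  Run :func:`zero_variance_filter` first — constant columns have
    undefined correlations.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    corr = matrix.values.corr().abs().to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    alive = list(range(corr.shape[0]))
    removed_idx: list[int] = []
    while alive:
        sub = corr[np.ix_(alive, alive)]
        iu = np.triu_indices(len(alive), 1)
        if iu[0].size == 0 or sub[iu].max() <= cutoff:
            break
        k = int(sub[iu].argmax())  # first maximal pair in (i, j), i < j order
        i_loc, j_loc = int(iu[0][k]), int(iu[1][k])
        mean_i = sub[i_loc].sum() / (len(alive) - 1)
        mean_j = sub[j_loc].sum() / (len(alive) - 1)
        if mean_i > mean_j:
            drop_loc = i_loc
        elif mean_j > mean_i:
            drop_loc = j_loc
        else:  # tie: remove the later column id
            drop_loc = max(i_loc, j_loc)
        removed_idx.append(alive.pop(drop_loc))
    cols = list(matrix.values.columns)
    removed = [cols[i] for i in removed_idx]  # in removal order
    kept = [cols[i] for i in range(len(cols)) if i not in set(removed_idx)]
    return matrix.subset(kept), removed


# ---------------------------------------------------------------------------
# Lasso AUC profile
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LassoProfile:
    points: pd.DataFrame  # penalty, n_nonzero, mean_cv_auc, sd_cv_auc
    selected_features: list[list[str]]

    @property
    def mean_auc(self) -> float:
        """Mean cross-validated AUC across the profile's path points."""
        return float(self.points["mean_cv_auc"].mean())

    def to_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False)


def _align(matrix: FeatureMatrix, labels: LabelSet) -> tuple[pd.DataFrame, np.ndarray]:
    y_all = labels.binary()
    samples = [s for s in matrix.sample_ids if s in y_all.index]
    X = matrix.values.loc[samples]
    y = y_all.loc[samples].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    return X, y


def lasso_auc_profile(
    matrix: FeatureMatrix,
    labels: LabelSet,
    n_folds: int = 10,
    max_features: int = 100,
    n_penalties: int = 100,
    penalty_min_ratio: float = 0.01,
    seed: int = 0,
) -> LassoProfile:
    """Cross-validated AUC along an L1-logistic penalty path.

    Features are standardized; the path runs over ``n_penalties`` log-spaced
    penalty values from the data-derived maximal penalty (at which all
    coefficients are zero) down by ``penalty_min_ratio``.  Recording stops
    once the full-data fit selects more than ``max_features`` features.  Fold
    assignment is stratified and shared across the whole path.
    """
    X_df, y = _align(matrix, labels)
    X = X_df.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    n = len(y)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    if lam_max == 0:
        raise ValueError("all features are uncorrelated constants")
    lams = np.geomspace(lam_max, lam_max * penalty_min_ratio, n_penalties)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))

    rows, selected = [], []
    for lam in lams:
        C = 1.0 / (n * lam)
        full = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                  max_iter=2000, random_state=0).fit(X, y)
        nz = np.flatnonzero(np.abs(full.coef_[0]) > 1e-12)
        if len(nz) > max_features:
            break
        fold_aucs = []
        for tr, te in folds:
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                     max_iter=2000, random_state=0).fit(X[tr], y[tr])
            probs = clf.predict_proba(X[te])[:, 1]
            if len(np.unique(y[te])) == 2:
                fold_aucs.append(roc_auc_score(y[te], probs))
        rows.append({
            "penalty": lam,
            "n_nonzero": len(nz),
            "mean_cv_auc": float(np.mean(fold_aucs)),
            "sd_cv_auc": float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0,
        })
        selected.append([X_df.columns[i] for i in nz])
    return LassoProfile(points=pd.DataFrame(rows), selected_features=selected)


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BorutaResult:
    decision: pd.Series  # feature -> Confirmed / Tentative / Rejected
    importance_history: pd.DataFrame  # runs x features (NaN once inactive)
    hit_counts: pd.Series
    runs_performed: int

    @property
    def confirmed(self) -> list[str]:
        return list(self.decision.index[self.decision == CONFIRMED])

    @property
    def tentative(self) -> list[str]:
        return list(self.decision.index[self.decision == TENTATIVE])

    @property
    def rejected(self) -> list[str]:
        return list(self.decision.index[self.decision == REJECTED])

    def ranking(self) -> pd.Series:
        """Confirmed features ordered by decreasing mean importance score."""
        means = self.importance_history[self.confirmed].mean(axis=0)
        return means.sort_values(ascending=False)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"decision": self.decision, "hits": self.hit_counts,
                           "mean_importance": self.importance_history.mean(axis=0)})
        df.to_csv(path, sep="\t", index_label="feature_id")


def _impurity_z(rf: RandomForestClassifier, n_features: int) -> np.ndarray:
    per_tree = np.array([t.feature_importances_ for t in rf.estimators_])
    mean = per_tree.mean(axis=0)
    sd = per_tree.std(axis=0, ddof=1)
    z = np.zeros(n_features)
    ok = sd > 0
    z[ok] = mean[ok] / sd[ok]
    return z


def _permutation_z(rf, X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                   n_repeats: int = 5) -> np.ndarray:
    from sklearn.inspection import permutation_importance

    res = permutation_importance(rf, X, y, n_repeats=n_repeats, scoring="accuracy",
                                 random_state=int(rng.integers(2**31)))
    z = np.zeros(X.shape[1])
    ok = res.importances_std > 0
    z[ok] = res.importances_mean[ok] / res.importances_std[ok]
    return z


def boruta_rank(
    matrix: FeatureMatrix,
    labels: LabelSet,
    max_runs: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
    n_trees: int = 500,
    importance: str = "impurity_z",
    min_shadows: int = 5,
) -> BorutaResult:
    """Shadow-feature selection of the combined feature matrix.

    Per run, every active (confirmed or undecided) feature gets a permuted
    shadow copy (padded to at least ``min_shadows``); a random forest is fit
    on real + shadow columns and per-feature importance Z-scores are computed
    (``importance="impurity_z"``: mean/sd of per-tree impurity importances;
    ``"permutation_z"``: mean/sd of permutation-importance repeats).  An
    undecided feature scores a hit when its Z exceeds the best shadow Z; after
    each run two-sided binomial tests (p=0.5, Bonferroni over undecided
    features) confirm or reject.  Features still undecided at the end are
    tentative.
    """
    if max_runs < 10:
        raise ValueError("max_runs must be >= 10")
    if importance not in ("impurity_z", "permutation_z"):
        raise ValueError(f"unknown importance {importance!r}")
    X_df, y = (matrix.values, None)
    features = list(X_df.columns)
    if not features:
        return BorutaResult(decision=pd.Series(dtype=object),
                            importance_history=pd.DataFrame(),
                            hit_counts=pd.Series(dtype=int), runs_performed=0)
    X_df, y = _align(matrix, labels)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    X = X_df.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    decision = pd.Series(TENTATIVE, index=features, dtype=object)
    hits = pd.Series(0, index=features, dtype=int)
    history: list[pd.Series] = []
    undecided = list(features)

    run = 0
    while undecided and run < max_runs:
        run += 1
        active = [f for f in features if decision[f] != REJECTED]
        cols = [features.index(f) for f in active]
        X_act = X[:, cols]
        n_shadow = max(len(active), min_shadows)
        shadow_src = rng.choice(len(active), size=n_shadow, replace=n_shadow > len(active)) \
            if n_shadow > len(active) else np.arange(len(active))
        shadows = X_act[:, shadow_src].copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        X_run = np.hstack([X_act, shadows])
        rf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", n_jobs=1,
            random_state=int(rng.integers(2**31)),
        ).fit(X_run, y)
        if importance == "impurity_z":
            z = _impurity_z(rf, X_run.shape[1])
        else:
            z = _permutation_z(rf, X_run, y, rng)
        z_real, z_shadow = z[:len(active)], z[len(active):]
        shadow_max = z_shadow.max()
        row = pd.Series(np.nan, index=features)
        row[active] = z_real
        history.append(row)
        for f, zf in zip(active, z_real):
            if decision[f] == TENTATIVE and zf > shadow_max:
                hits[f] += 1
        # binomial decisions over currently undecided features
        m = len(undecided)
        still = []
        for f in undecided:
            k = int(hits[f])
            p_two = min(1.0, 2 * min(stats.binom.cdf(k, run, 0.5),
                                     stats.binom.sf(k - 1, run, 0.5)))
            if p_two * m < alpha:
                decision[f] = CONFIRMED if k > run / 2 else REJECTED
            else:
                still.append(f)
        undecided = still

    importance_history = pd.DataFrame(history, index=pd.RangeIndex(1, run + 1, name="run"),
                                      columns=features)
    logger.info("Boruta finished after %d runs: %d confirmed, %d tentative, %d rejected",
                run, (decision == CONFIRMED).sum(), (decision == TENTATIVE).sum(),
                (decision == REJECTED).sum())
    return BorutaResult(decision=decision, importance_history=importance_history,
                        hit_counts=hits, runs_performed=run)
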