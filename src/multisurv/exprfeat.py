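"""Count-matrix processing and PCA feature extraction.

Raw read-count matrices (mRNA or miRNA, features x samples) are filtered for a
minimum read count and depth-normalized with the median-of-ratios size-factor
estimator: the size factor of sample j is the median, over features with a
positive geometric mean across samples, of count_fj / geomean_f; normalized
values are counts divided by the sample's factor.  Methylation beta values
need no processing and pass through as raw features.  PCA condenses any dense
feature matrix to at most n_samples - 1 score features.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from multisurv.formats import FeatureMatrix


class NormalizationError(ValueError):
    pass


def filter_min_count(counts: pd.DataFrame, min_reads: int = 10) -> pd.DataFrame:
    """Drop features whose count is below ``min_reads`` in every sample."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = counts.max(axis=1) >= min_reads
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (features x samples input)."""
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_x = np.log(x)
    log_geomean = log_x.mean(axis=1)
    usable = np.isfinite(log_geomean)  # features with no zero count
    if not usable.any():
        raise NormalizationError("no feature has a positive geometric mean across samples")
    ratios = log_x[usable] - log_geomean[usable, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def size_factor_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Return (normalized matrix, per-sample size factors)."""
    factors = size_factors(counts)
    return counts / factors, factors


@dataclasses.dataclass
class PcaModel:
    loadings: pd.DataFrame  # features x k, orthonormal columns
    centers: pd.Series  # per-feature means
    explained_variance_ratio: np.ndarray

    def transform(self, matrix: FeatureMatrix) -> pd.DataFrame:
        centered = matrix.values[self.loadings.index] - self.centers
        return centered @ self.loadings


def pca_features(matrix: FeatureMatrix, k: int) -> tuple[FeatureMatrix, PcaModel]:
    """Project a complete feature matrix onto its first ``k`` principal components.

    Components are ordered by decreasing explained variance; signs are fixed so
    the largest-magnitude loading of each component is positive.
    """
    values = matrix.values
    if values.isna().any().any():
        raise ValueError("PCA requires a complete matrix (no missing values)")
    n, p = values.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {k}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(values.to_numpy())
    loadings = pca.components_.T  # p x k
    # deterministic sign: largest-|loading| entry positive per component
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    scores *= flip
    loadings = loadings * flip
    omics = matrix.provenance["omics"].iloc[0] if len(matrix.provenance) else "mrna"
    names = [f"{omics}_PC{i + 1}" for i in range(k)]
    out = FeatureMatrix(pd.DataFrame(scores, index=values.index, columns=names),
                        omics=omics, method="pca")
    model = PcaModel(
        loadings=pd.DataFrame(loadings, index=values.columns, columns=names),
        centers=pd.Series(pca.mean_, index=values.columns),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
    return out, model
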