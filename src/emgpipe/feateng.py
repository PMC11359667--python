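"""Feature engineering: column z-scoring, correlation audit, PCA projection
retaining a cumulative-explained-variance target, and one-hot label encoding.

The transforms store their fitted parameters so held-out rows can be
projected without leakage; the audit is report-only (redundancy is resolved
by PCA downstream, not by dropping columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import ConfigurationError, DegenerateInputError, ShapeError
from .features import FeatureMatrix


@dataclass
class ZscoreParams:
    """Per-column mean and sample SD (denominator N-1) fitted on training rows."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != self.mean.size:
            raise ShapeError(f"expected {self.mean.size} columns, got {values.shape[-1]}")
        return (values - self.mean) / self.sd


def zscore_fit_transform(features: FeatureMatrix | np.ndarray) -> tuple[np.ndarray, ZscoreParams]:
    """Standardize every column to mean 0 / SD 1; errors name any constant column."""
    if isinstance(features, FeatureMatrix):
        values, columns = features.values, features.columns
    else:
        values = np.asarray(features, dtype=float)
        columns = [f"col{i}" for i in range(values.shape[1])]
    if values.shape[0] < 2:
        raise ShapeError("z-scoring needs at least 2 rows")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        names = ", ".join(columns[i] for i in dead[:5])
        raise DegenerateInputError(f"constant column(s) cannot be z-scored: {names}")
    params = ZscoreParams(mean=mean, sd=sd)
    return params.transform(values), params


def correlation_audit(
    standardized: np.ndarray, threshold: float = 0.90
) -> list[tuple[int, int, float]]:
    """All unordered column pairs with \\|Pearson r\\| >= threshold, sorted by \\|r\\| descending."""
    z = np.asarray(standardized, dtype=float)
    if z.shape[0] < 2:
        raise ShapeError("correlation audit needs at least 2 rows")
    r = np.clip(np.corrcoef(z, rowvar=False), -1.0, 1.0)
    pairs = []
    for i in range(r.shape[0]):
        for j in range(i + 1, r.shape[0]):
            # tiny slack so exact duplicates survive a threshold of 1.0
            if abs(r[i, j]) >= threshold - 1e-12:
                pairs.append((i, j, float(r[i, j])))
    pairs.sort(key=lambda p: -abs(p[2]))
    return pairs


@dataclass
class EngineeredDataset:
    """PCA-projected matrix plus every fitted parameter needed to transform
    held-out rows: the training column mean, the retained orthonormal basis
    and the per-component explained-variance ratios."""

    projected: np.ndarray
    basis: np.ndarray  # k x n_features, rows orthonormal
    center: np.ndarray  # training mean removed before projection
    explained_variance_ratio: np.ndarray  # all components, nonincreasing
    k: int
    cumulative_variance: float
    labels: np.ndarray | None = None
    onehot: np.ndarray | None = None

    def transform(self, standardized: np.ndarray) -> np.ndarray:
        z = np.asarray(standardized, dtype=float)
        return (z - self.center) @ self.basis.T


def pca_fit_transform(
    standardized: np.ndarray,
    retention: float = 0.999,
    labels: np.ndarray | None = None,
) -> EngineeredDataset:
    """Project onto the smallest number of principal components whose
    cumulative explained-variance ratio reaches ``retention``.

    Components are eigenvectors of the sample covariance ordered by
    eigenvalue; the fitted mean and basis apply to held-out rows via
    :meth:`EngineeredDataset.transform`.
    """
    if not 0.0 < retention <= 1.0:
        raise ConfigurationError(f"retention must be in (0, 1], got {retention}")
    z = np.asarray(standardized, dtype=float)
    if z.shape[0] < 2:
        raise ShapeError("PCA needs at least 2 rows")

    pca = PCA(svd_solver="full")
    pca.fit(z)
    evr = pca.explained_variance_ratio_
    cumulative = np.cumsum(evr)
    # float-tolerant: rank-deficient data reaches 1.0 only to machine precision
    k = int(np.searchsorted(cumulative, retention - 1e-10, side="left")) + 1
    k = min(k, evr.size)

    basis = pca.components_[:k]
    ds = EngineeredDataset(
        projected=np.empty(0),
        basis=basis,
        center=pca.mean_,
        explained_variance_ratio=evr,
        k=k,
        cumulative_variance=float(cumulative[k - 1]),
        labels=None if labels is None else np.asarray(labels),
    )
    ds.projected = ds.transform(z)
    if labels is not None:
        ds.onehot = onehot(ds.labels)
    return ds


def onehot(labels: np.ndarray, n_classes: int = 7) -> np.ndarray:
    """0/1 encoding of class ids 1..n_classes; each row sums to exactly 1."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 1 or labels.max() > n_classes):
        raise ConfigurationError(f"labels must lie in 1..{n_classes}")
    out = np.zeros((labels.size, n_classes), dtype=int)
    out[np.arange(labels.size), labels - 1] = 1
    return out
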