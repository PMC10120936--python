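"""Feature screening by pre/post Gaussian overlap, and redundancy checks
with bias-corrected distance correlation.

Candidate acoustic features are screened by fitting a Gaussian to the
pre-surgery and post-surgery value distributions of each feature and
computing the overlapping coefficient of the two densities: a small overlap
means the feature separates the two states well.  Redundancy among retained
features is quantified with the bias-corrected (U-centered) distance
correlation of Székely and Rizzo, which detects general (not just linear)
dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "OverlapResult",
    "gaussian_overlap",
    "rank_features",
    "distance_correlation",
    "correlation_matrix",
    "OverlapFeatureSelector",
]


@dataclass(frozen=True)
class OverlapResult:
    feature_name: str
    mu_pre: float
    sigma_pre: float
    mu_post: float
    sigma_post: float
    overlap: float


def gaussian_overlap(
    pre_values: np.ndarray,
    post_values: np.ndarray,
    feature_name: str = "",
) -> OverlapResult:
    """Overlapping coefficient of Gaussians fitted to the two groups.

    Each group is summarized by its sample mean and SD; the overlap is
    ``integral of min(f_pre, f_post)`` in [0, 1] (1 = identical densities).
    The equal-variance case has the closed form ``2*Phi(-|mu1-mu2|/(2*sigma))``;
    otherwise adaptive quadrature over the joint mu +/- 8 sigma envelope is
    used (error well below 1e-8).
    """
    a = np.asarray(pre_values, dtype=np.float64)
    b = np.asarray(post_values, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 values per group")
    mu1, s1 = float(a.mean()), float(a.std(ddof=1))
    mu2, s2 = float(b.mean()), float(b.std(ddof=1))
    if s1 <= 0 or s2 <= 0:
        raise ValueError(f"degenerate variance for feature {feature_name!r}")

    if np.isclose(s1, s2, rtol=1e-9, atol=0.0):
        ovl = float(2 * norm.cdf(-abs(mu1 - mu2) / (2 * s1)))
    else:
        lo = min(mu1 - 8 * s1, mu2 - 8 * s2)
        hi = max(mu1 + 8 * s1, mu2 + 8 * s2)
        ovl, _ = integrate.quad(
            lambda x: min(norm.pdf(x, mu1, s1), norm.pdf(x, mu2, s2)),
            lo,
            hi,
            limit=400,
        )
        ovl = float(min(max(ovl, 0.0), 1.0))
    return OverlapResult(feature_name, mu1, s1, mu2, s2, ovl)


def rank_features(
    feature_table: pd.DataFrame,
    pre_mask: np.ndarray,
    post_mask: np.ndarray,
    features: list[str] | None = None,
    k: int | None = None,
    max_overlap: float | None = None,
) -> list[OverlapResult]:
    """Rank features by ascending pre/post overlap (most discriminative first).

    ``k`` truncates to the top-k; ``max_overlap`` keeps only features below
    an overlap ceiling.  Both may be combined.
    """
    pre_mask = np.asarray(pre_mask, dtype=bool)
    post_mask = np.asarray(post_mask, dtype=bool)
    if not pre_mask.any() or not post_mask.any():
        raise ValueError("both phases must be present in the table")
    if features is None:
        features = [
            c for c in feature_table.columns
            if pd.api.types.is_numeric_dtype(feature_table[c])
        ]
    results = [
        gaussian_overlap(
            feature_table.loc[pre_mask, f].to_numpy(),
            feature_table.loc[post_mask, f].to_numpy(),
            feature_name=f,
        )
        for f in features
    ]
    results.sort(key=lambda r: r.overlap)
    if max_overlap is not None:
        results = [r for r in results if r.overlap <= max_overlap]
    if k is not None:
        results = results[:k]
    return results


# ---------------------------------------------------------------------------
# Distance correlation (Székely–Rizzo)


def _dist_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    return np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))


def _u_center(d: np.ndarray) -> np.ndarray:
    """U-centering of a distance matrix (bias-corrected estimator)."""
    n = d.shape[0]
    row = d.sum(axis=1, keepdims=True)
    col = d.sum(axis=0, keepdims=True)
    total = d.sum()
    u = d - row / (n - 2) - col / (n - 2) + total / ((n - 1) * (n - 2))
    np.fill_diagonal(u, 0.0)
    return u


def _d_center(d: np.ndarray) -> np.ndarray:
    """Ordinary double centering (biased estimator)."""
    return d - d.mean(axis=1, keepdims=True) - d.mean(axis=0, keepdims=True) + d.mean()


def distance_correlation(
    x: np.ndarray, y: np.ndarray, bias_corrected: bool = True
) -> float:
    """Distance correlation between two samples.

    With ``bias_corrected=True`` (default) the U-centered statistic of
    Székely and Rizzo is returned; it may be slightly negative and needs
    n >= 4.  The biased variant uses ordinary double centering and lies in
    [0, 1].  Constant inputs have zero distance variance and raise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape[0] != y.shape[0]:
        raise ValueError("samples must have equal length")
    n = x.shape[0]
    dx, dy = _dist_matrix(x), _dist_matrix(y)
    if dx.max() == 0 or dy.max() == 0:
        raise ValueError("constant input: distance variance is zero")
    if bias_corrected:
        if n < 4:
            raise ValueError("bias-corrected variant needs n >= 4")
        ux, uy = _u_center(dx), _u_center(dy)
        denom = n * (n - 3)
        dcov2 = (ux * uy).sum() / denom
        vx = (ux * ux).sum() / denom
        vy = (uy * uy).sum() / denom
        if vx <= 0 or vy <= 0:
            raise ValueError("zero distance variance after U-centering")
        return float(dcov2 / np.sqrt(vx * vy))
    ax, ay = _d_center(dx), _d_center(dy)
    dcov2 = (ax * ay).mean()
    vx = (ax * ax).mean()
    vy = (ay * ay).mean()
    if vx <= 0 or vy <= 0:
        raise ValueError("zero distance variance")
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(vx * vy)))


def correlation_matrix(
    feature_table: pd.DataFrame,
    features: list[str],
    bias_corrected: bool = True,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise distance correlations (diagonal = 1)."""
    if len(features) < 2:
        raise ValueError("need >= 2 features")
    m = len(features)
    out = np.eye(m)
    cols = {f: feature_table[f].to_numpy(dtype=np.float64) for f in features}
    for i in range(m):
        for j in range(i + 1, m):
            r = distance_correlation(cols[features[i]], cols[features[j]],
                                     bias_corrected)
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=features, columns=features)


# ---------------------------------------------------------------------------
# sklearn-style selector


class OverlapFeatureSelector:
    """Select the k features whose pre/post Gaussian overlap is smallest.

    ``fit(X, y)`` takes a feature matrix and a binary phase label vector
    (1 = post-surgery); ``transform`` keeps the selected columns.  Mirrors
    the screening that reduced a large candidate set to the retained
    features.
    """

    def __init__(self, k: int = 4, max_overlap: float | None = None,
                 feature_names: list[str] | None = None):
        self.k = k
        self.max_overlap = max_overlap
        self.feature_names = feature_names

    def get_params(self, deep: bool = True) -> dict:
        return {
            "k": self.k,
            "max_overlap": self.max_overlap,
            "feature_names": self.feature_names,
        }

    def set_params(self, **params) -> "OverlapFeatureSelector":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "OverlapFeatureSelector":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(bool)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        names = self.feature_names or [f"x{i}" for i in range(X.shape[1])]
        table = pd.DataFrame(X, columns=names)
        self.overlaps_ = rank_features(
            table, ~y, y, features=names, k=self.k, max_overlap=self.max_overlap
        )
        selected = {r.feature_name for r in self.overlaps_}
        self.support_ = np.array([n in selected for n in names])
        self.feature_names_out_ = [n for n in names if n in selected]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return X[:, self.support_]

    def fit_transform(self, X, y) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_support(self) -> np.ndarray:
        return self.support_
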