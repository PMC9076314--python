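"""Uncorrelated linear discriminant analysis (ULDA), min-max normalization,
scatter-plot export, and the RES cluster-separability index.

ULDA reduces a K-class feature space to at most K−1 dimensions whose
transformed training features are mutually uncorrelated with respect to the
total scatter matrix: ``Gᵀ·S_t·G = I``.  It is computed by simultaneous
diagonalization — whiten with the total scatter via SVD, then SVD the
whitened between-class scatter — which stays well-posed when the
within-class scatter is singular (small folds, collinear features).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = [
    "UldaProjection",
    "ulda_fit",
    "ulda_transform",
    "minmax_normalize",
    "res_index",
    "ScatterData",
    "export_scatter",
]

_RANK_TOL = 1e-10  # singular values below tol * max are treated as zero


@dataclass(frozen=True)
class UldaProjection:
    """Fitted ULDA reduction: ``z = Gᵀ (x − μ_train)``."""

    projection: np.ndarray   # (n_features_in, r)
    mean: np.ndarray         # training global mean
    classes: tuple
    columns: tuple[str, ...]

    @property
    def n_components(self) -> int:
        return self.projection.shape[1]


def ulda_fit(train: FeatureMatrix) -> UldaProjection:
    """Fit ULDA on a training feature matrix.

    Maximizes between-class scatter subject to ``Gᵀ S_t G = I`` where
    ``S_t = Σ_j (x_j − μ)(x_j − μ)ᵀ`` is the total scatter of the training
    rows.  The output dimensionality equals the rank of the whitened
    between-class scatter, at most ``n_classes − 1``.
    """
    X = np.asarray(train.values, dtype=float)
    y = np.asarray(train.labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("ULDA needs at least 2 classes")
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training samples")

    mu = X.mean(axis=0)
    Ht = (X - mu).T                                   # total scatter factor
    # between-class scatter factor: sqrt(n_k) (mu_k - mu)
    Hb = np.column_stack(
        [np.sqrt(np.sum(y == c)) * (X[y == c].mean(axis=0) - mu) for c in classes]
    )

    U, s, _ = np.linalg.svd(Ht, full_matrices=False)
    t = int(np.sum(s > _RANK_TOL * s[0])) if s.size and s[0] > 0 else 0
    if t == 0:
        raise ValueError("total scatter is zero: constant feature matrix")
    U1, s1 = U[:, :t], s[:t]

    B = (U1 / s1).T @ Hb                              # whitened between factor
    P, sb, _ = np.linalg.svd(B, full_matrices=False)
    q = int(np.sum(sb > _RANK_TOL * sb[0])) if sb.size and sb[0] > 0 else 0
    q = min(q, len(classes) - 1)
    if q == 0:
        raise ValueError("between-class scatter is zero: identical class means")

    G = (U1 / s1) @ P[:, :q]
    return UldaProjection(
        projection=G, mean=mu, classes=tuple(classes), columns=tuple(train.columns)
    )


def ulda_transform(proj: UldaProjection, features: FeatureMatrix) -> FeatureMatrix:
    """Apply a training-fitted projection to (train or held-out) features."""
    if tuple(features.columns) != proj.columns:
        raise ValueError("feature columns do not match the fitted projection")
    Z = (features.values - proj.mean) @ proj.projection
    return FeatureMatrix(
        values=Z,
        columns=[f"ULDA{i + 1}" for i in range(proj.n_components)],
        labels=features.labels,
        trial_index=features.trial_index,
        window_index=features.window_index,
        spec_name=f"{features.spec_name}/ulda",
    )


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Per-feature affine map to [0, 1]: ``(x − min) / (max − min)``.

    Raises on constant columns (zero range).
    """
    values = np.asarray(values, dtype=float)
    arr = values if values.ndim == 2 else values[:, None]
    lo, hi = arr.min(axis=0), arr.max(axis=0)
    if np.any(hi <= lo):
        bad = int(np.flatnonzero(hi <= lo)[0])
        raise ValueError(f"feature column {bad} is constant; min-max undefined")
    out = (arr - lo) / (hi - lo)
    return out if values.ndim == 2 else out[:, 0]


def res_index(points: np.ndarray, labels: np.ndarray) -> float:
    """RES index: mean pairwise Euclidean distance between class means over
    the mean within-class per-feature standard deviation.

    Defined for exactly two feature columns.  With K classes and class means
    ``(m1k, m2k)``::

        ED̄ = (2 / (K(K−1))) · Σ_{p<q} sqrt((m1p−m1q)² + (m2p−m2q)²)
        σ̄  = (1 / (2K)) · Σ_i Σ_k s_ik        (sample SD, N−1 denominator)
        RES = ED̄ / σ̄

    Higher is better-separated; the score is classifier-independent and
    invariant to rigid translation and global scaling of the embedding.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("res_index is defined for exactly 2 feature columns")
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    K = len(classes)
    if K < 2:
        raise ValueError("res_index needs at least 2 classes")
    means = np.empty((K, 2))
    sds = np.empty((K, 2))
    for k, c in enumerate(classes):
        pts = P[y == c]
        if pts.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 points")
        means[k] = pts.mean(axis=0)
        sds[k] = pts.std(axis=0, ddof=1)
    dists = [
        float(np.linalg.norm(means[p] - means[q]))
        for p in range(K - 1)
        for q in range(p + 1, K)
    ]
    ed_bar = 2.0 / (K * (K - 1)) * float(np.sum(dists))
    sigma_bar = float(np.sum(sds)) / (2 * K)
    if sigma_bar == 0:
        raise ValueError("degenerate clusters: zero mean within-class SD")
    return ed_bar / sigma_bar


@dataclass(frozen=True)
class ScatterData:
    """First two ULDA features per window, min-max normalized to [0, 1]."""

    points: np.ndarray   # (n, 2)
    labels: np.ndarray
    res: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"f1": self.points[:, 0], "f2": self.points[:, 1], "label": self.labels}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def export_scatter(features: FeatureMatrix, paper_mode: bool = False) -> ScatterData:
    """Fit ULDA on the whole feature matrix and export the first two reduced
    features, min-max normalized, plus the RES index of the raw embedding.

    ``paper_mode=True`` keeps every 4th window per trial (the conventional
    5-points-per-trial scatter for 250 ms windows on 5 s trials: 5 points x
    6 trials x 10 movements = 300); otherwise all windows are kept.
    """
    proj = ulda_fit(features)
    if proj.n_components < 2:
        raise ValueError("scatter export needs at least 2 ULDA dimensions")
    reduced = ulda_transform(proj, features)
    pts = reduced.values[:, :2]
    labels = reduced.labels
    if paper_mode:
        keep = reduced.window_index % 4 == 0
        pts, labels = pts[keep], labels[keep]
    res = res_index(pts, labels)
    return ScatterData(points=minmax_normalize(pts), labels=labels, res=res)
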