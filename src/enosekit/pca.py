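"""Principal component analysis for unsupervised pattern recognition.

Columns are always mean-centered; by default they are also scaled to unit
variance (correlation-matrix PCA), the appropriate choice when variables
carry different units.  The decomposition is by singular values, with the
sign of each component fixed so that its largest-magnitude loading is
positive, making scores reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCAResult", "fit_pca", "separation_score"]


@dataclass
class PCAResult:
    """Scores, loadings and explained variance of a PCA fit."""

    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # variables x components
    explained_variance_ratio: np.ndarray
    scaled: bool
    column_means: np.ndarray
    column_scales: np.ndarray

    @property
    def cumulative_3pc(self) -> float:
        """Fraction of variance carried by the first three components."""
        k = min(3, len(self.explained_variance_ratio))
        return float(np.sum(self.explained_variance_ratio[:k]))


def fit_pca(table: pd.DataFrame, scale: bool = True) -> PCAResult:
    """Fit PCA on a samples x variables table.

    Parameters
    ----------
    table : DataFrame
        Numeric matrix, no missing values, >= 2 samples.
    scale : bool
        Divide each centered column by its sample SD (default).  A constant
        column is an error in this mode.
    """
    X = table.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 variable")
    if np.isnan(X).any():
        raise ValueError("missing values are not supported")
    means = X.mean(axis=0)
    Xc = X - means
    if scale:
        scales = X.std(axis=0, ddof=1)
        if np.any(scales == 0):
            bad = table.columns[int(np.argmax(scales == 0))]
            raise ValueError(f"constant column {bad!r} cannot be autoscaled")
    else:
        scales = np.ones(X.shape[1])
    Xs = Xc / scales
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(U * s, index=table.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=table.columns, columns=comp_names)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=ratio,
        scaled=scale,
        column_means=means,
        column_scales=scales,
    )


def separation_score(result: PCAResult, labels: pd.Series) -> float:
    """Leave-one-out nearest-centroid accuracy in the 3-PC score space.

    Quantifies how well two groups split in the leading score space: each
    sample is assigned to the nearer of the two class centroids computed
    from all other samples.  Returns a fraction in [0, 1].
    """
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("two label values required")
    k = min(3, result.scores.shape[1])
    S = result.scores.iloc[:, :k].to_numpy()
    y = labels.loc[result.scores.index].to_numpy()
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        dists = []
        for g in groups:
            sel = mask & (y == g)
            if not sel.any():
                raise ValueError("a class vanished in a leave-one-out fold")
            centroid = S[sel].mean(axis=0)
            dists.append(np.linalg.norm(S[i] - centroid))
        predicted = groups[int(np.argmin(dists))]
        correct += int(predicted == y[i])
    return correct / n
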