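"""Principal component analysis with a deterministic sign convention.

Shared by composition-based contig binning and the protein-family site
comparison so both honour one contract: variance fractions are
non-negative, non-increasing and sum to at most 1, and component signs are
fixed so that each component's largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["PcaResult", "pca"]


@dataclass
class PcaResult:
    """Scores are observations x components; loadings features x components."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    ids: list[str]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.ids, columns=cols)


def pca(
    data: pd.DataFrame | np.ndarray,
    center: bool = True,
    scale: bool = False,
) -> PcaResult:
    """PCA of observations (rows) x features (columns).

    ``scale`` divides each feature by its standard deviation (constant
    features are left unscaled). Inputs with zero total variance yield
    all-zero scores and variance fractions rather than an error.
    """
    if isinstance(data, pd.DataFrame):
        ids = [str(i) for i in data.index]
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    if X.shape[0] < 3:
        raise ValueError("PCA requires at least 3 observations")
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd

    n_comp = min(X.shape)
    Xc = X - X.mean(axis=0) if center else X
    total_var = (Xc * Xc).sum()
    if total_var <= 1e-300:
        return PcaResult(
            scores=np.zeros((X.shape[0], n_comp)),
            loadings=np.zeros((X.shape[1], n_comp)),
            explained_variance_ratio=np.zeros(n_comp),
            ids=ids,
        )
    if center:
        model = PCA(n_components=n_comp, svd_solver="full")
        scores = model.fit_transform(X)
        loadings = model.components_.T  # features x components
        ratio = model.explained_variance_ratio_
    else:
        # uncentered variant: plain SVD of the data matrix
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        scores = u * s
        loadings = vt.T
        ratio = s**2 / (s**2).sum()

    # deterministic signs: largest-magnitude loading of each component > 0
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        pivot = int(np.argmax(np.abs(col)))
        if col[pivot] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]
    return PcaResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=ratio, ids=ids)
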