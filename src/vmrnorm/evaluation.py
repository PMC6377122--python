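"""Normalization-quality evaluation by PCA and t-SNE embeddings.

A good normalization should (i) preserve the intrinsic variability of the
data — checked by comparing the PCA variance structure before and after —
and (ii) reveal grouping structure (e.g. developmental stages) that
nuisance variation was masking — visualised with t-SNE.

Each larva contributes one feature vector: its per-second activity over a
short window around the light change (default ``t in {-1..3}``, five
seconds spanning two pre-change and three post-change bins; trials are
averaged). PCA runs on the column-centered, un-scaled matrix — all columns
share Burst Duration units. t-SNE delegates to scikit-learn with a fixed
seed; only determinism given the seed and parameter pass-through are
contractual, since t-SNE geometry is not comparable across implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .plate_data import subset_window

__all__ = [
    "EmbeddingResult",
    "DEFAULT_EVAL_WINDOW",
    "build_feature_matrix",
    "pca_embed",
    "tsne_embed",
]

#: Window around the light change used for embedding features.
DEFAULT_EVAL_WINDOW = (-1, 3)


@dataclass
class EmbeddingResult:
    """2-D embedding of per-larva window traces."""

    coordinates: pd.DataFrame  # index (larva_id, stage_dpf), columns dim1/dim2
    method: str
    variance_explained: tuple = ()  # per-component fractions; PCA only
    parameters: dict = field(default_factory=dict)
    components: np.ndarray | None = None  # PCA loadings, rows orthonormal

    def to_frame(self) -> pd.DataFrame:
        out = self.coordinates.reset_index()
        out["method"] = self.method
        return out


def build_feature_matrix(table: pd.DataFrame,
                         window=DEFAULT_EVAL_WINDOW) -> pd.DataFrame:
    """One row per larva, one column per second of the window.

    Trials are averaged so each larva appears once. Larvae missing any
    second of the window are dropped (count recorded in
    ``df.attrs['n_dropped']``). Row order is deterministic (sorted by
    larva_id) and independent of the input record order. The row index
    carries the stage label: ``(larva_id, stage_dpf)``.
    """
    t_min, t_max = window
    sub = subset_window(table, t_min, t_max)
    seconds = list(range(t_min, t_max + 1))
    wide = (sub.groupby(["larva_id", "stage_dpf", "t"])["activity"].mean()
            .unstack("t"))
    missing = [s for s in seconds if s not in wide.columns]
    if missing:
        raise ValueError(f"no records at second(s) {missing} in window {window}")
    wide = wide[seconds]
    complete = wide.dropna().sort_index()
    complete.attrs["n_dropped"] = int(len(wide) - len(complete))
    return complete


def pca_embed(matrix: pd.DataFrame) -> EmbeddingResult:
    """First two principal components of the column-centered matrix.

    Variance-explained fractions come from the eigenvalues of the sample
    covariance (equivalently the squared singular values over n - 1).
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError(f"PCA needs >= 3 rows, got {X.shape[0]}")
    if np.allclose(X, X.mean(axis=0), atol=0):
        raise ValueError("matrix is constant: zero total variance")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    out = pd.DataFrame(coords, index=matrix.index, columns=["dim1", "dim2"])
    return EmbeddingResult(
        coordinates=out,
        method="pca",
        variance_explained=tuple(float(v) for v in
                                 pca.explained_variance_ratio_),
        parameters={"n_components": 2},
        components=pca.components_,
    )


def tsne_embed(matrix: pd.DataFrame, perplexity: float = 30.0,
               seed: int = 0, n_iter: int = 1000) -> EmbeddingResult:
    """2-D t-SNE embedding, deterministic for a given (matrix, perplexity, seed)."""
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    bound = (n - 1) / 3
    if perplexity >= bound:
        raise ValueError(
            f"perplexity {perplexity} too large for n={n}; "
            f"require perplexity < (n - 1) / 3 = {bound:g}")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca", max_iter=n_iter, n_jobs=1)
    coords = tsne.fit_transform(X)
    out = pd.DataFrame(coords, index=matrix.index, columns=["dim1", "dim2"])
    return EmbeddingResult(
        coordinates=out,
        method="tsne",
        parameters={"perplexity": float(perplexity), "seed": int(seed),
                    "iterations": int(n_iter)},
    )
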