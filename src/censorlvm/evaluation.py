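"""Embedding quality metrics and substitution baselines.

The nearest-neighbour error counts, over all cells, how often a cell's
closest other cell in the embedding carries a different label — a simple,
interpretable score for how well a 2D map separates known cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from . import cgplvm
from .data_io import CtMatrix
from .preprocessing import housekeeping_means, substitute_censored


@dataclass
class EvaluationReport:
    nn_error_count: int
    n_cells: int
    per_label_errors: dict = field(default_factory=dict)
    method: str = ""

    @property
    def error_rate(self) -> float:
        return self.nn_error_count / self.n_cells

    def to_dict(self) -> dict:
        return {
            "nn_error_count": self.nn_error_count,
            "n_cells": self.n_cells,
            "error_rate": self.error_rate,
            "per_label_errors": self.per_label_errors,
            "method": self.method,
        }


def nn_error(coords: np.ndarray, labels, method: str = "") -> EvaluationReport:
    """Leave-one-out nearest-neighbour label mismatch count.

    Euclidean distance; the query cell is excluded from its own
    neighbourhood; equidistant neighbours are broken deterministically in
    favour of the lowest index.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    N = coords.shape[0]
    if N < 2:
        raise ValueError("need at least two cells")
    unlabeled = [i for i, l in enumerate(labels)
                 if l is None or (isinstance(l, float) and np.isnan(l)) or str(l) == ""]
    if unlabeled:
        raise ValueError(f"unlabeled cells at indices {unlabeled}")
    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)
    nn = np.argmin(D, axis=1)  # argmin takes the lowest index on ties
    errors = labels[nn] != labels
    per_label = {}
    for lab in np.unique(labels):
        sel = labels == lab
        per_label[str(lab)] = int(errors[sel].sum())
    return EvaluationReport(
        nn_error_count=int(errors.sum()), n_cells=N,
        per_label_errors=per_label, method=method,
    )


def baseline_embed(
    ct: CtMatrix,
    method: str = "pca",
    b_sub: float | None = None,
    q: int = 2,
    seed: int = 0,
    ct_max: float = 40.0,
    settings: cgplvm.OptimizerSettings | None = None,
) -> np.ndarray:
    """Substitution baseline: replace non-detects, normalize, embed.

    ``method="pca"`` performs classical PCA of the substituted, normalized,
    centered matrix; ``method="substituted-gplvm"`` fits a Gaussian-noise
    GPLVM with a shared RBF kernel to the same matrix.  Missing entries are
    imputed with the column mean for the baseline (standard PCA cannot skip
    them).
    """
    sub_values = substitute_censored(ct, b_sub)
    hk_mean, keep = housekeeping_means(ct)
    sel = np.where(keep)[0]
    gene_sel = np.array([j for j in range(ct.n_genes)
                         if ct.gene_ids[j] not in ct.housekeeping], dtype=int)
    Y = -(sub_values[np.ix_(sel, gene_sel)] - hk_mean[sel, None])  # expression orientation
    miss = ct.missing[np.ix_(sel, gene_sel)]
    if np.any(miss):
        col = np.where(miss, np.nan, Y)
        col = np.nanmean(col, axis=0)
        Y = np.where(miss, np.broadcast_to(col, Y.shape), Y)
    Yc = Y - Y.mean(axis=0)
    if Yc.shape[1] < q:
        raise ValueError("q exceeds the number of genes after normalization")
    if np.allclose(Yc, 0.0):
        raise ValueError("matrix is constant after substitution")
    if method == "pca":
        return PCA(n_components=q, random_state=seed).fit_transform(Yc)
    if method == "substituted-gplvm":
        noise = cgplvm.cn.NoiseAssignment(
            kind=np.where(miss, cgplvm.cn.MISSING, cgplvm.cn.GAUSSIAN),
            y=Yc, b1=np.zeros_like(Yc), b2=np.ones_like(Yc),
        )
        model = cgplvm.fit(
            noise,
            cgplvm.ModelSpec(q=q, kernel="rbf", noise="gaussian", seed=seed,
                             center=False),
            settings or cgplvm.OptimizerSettings(outer_max=5, inner_iters=40),
        )
        return model.X
    raise ValueError(f"unknown baseline method {method!r}")
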