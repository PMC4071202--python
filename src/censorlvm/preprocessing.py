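"""Housekeeping normalization with per-cell censoring-threshold propagation.

Cell-wise normalization subtracts the mean housekeeping-gene Ct of each cell
from all of that cell's Ct values, removing cell-size / efficiency effects.
Crucially, the detection limit is an instrument property in *raw* Ct, so
after normalization the censoring threshold differs across cells: for cell
``n`` the normalized threshold is ``LOD_d - hk_mean(n)``, and the ceiling
implied by the maximal measurable 40 Ct is ``ct_max - hk_mean(n)``.

NormalizedExpression stays in normalized-Ct orientation (lower = more
expression).  The model layer works on the sign-flipped values (larger =
more expression), under which a qPCR non-detect is *left*-censored at
``-(LOD_d - hk_mean(n))`` — or interval-censored between the flipped
ceiling and threshold when the interval noise model is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import censor_noise as cn
from .data_io import CtMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizedExpression:
    """Per-cell normalized expression with per-entry censoring bounds.

    ``values`` are normalized Ct (raw Ct minus the cell's mean housekeeping
    Ct); ``lower_bound``/``upper_bound`` are the per-entry normalized
    censoring threshold and the ceiling from the maximal measurable Ct.
    """

    values: np.ndarray  # (N, D) normalized Ct
    censored: np.ndarray
    missing: np.ndarray
    lower_bound: np.ndarray  # (N, D) normalized LOD
    upper_bound: np.ndarray  # (N, D) normalized ceiling
    gene_ids: list[str]
    cell_ids: list[str]
    cell_labels: np.ndarray | None = None
    hk_mean: np.ndarray | None = None  # (N,) per-cell housekeeping mean

    def __post_init__(self) -> None:
        if np.any(self.lower_bound >= self.upper_bound):
            raise ValueError("lower_bound must be < upper_bound everywhere")
        detected = ~(self.censored | self.missing)
        if np.any(self.values[detected] >= self.lower_bound[detected]):
            raise ValueError("detected entries must lie below the censoring threshold")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def housekeeping_means(ct: CtMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mean housekeeping Ct and the mask of normalizable cells.

    Cells with partly censored/missing housekeeping entries fall back to the
    mean of their remaining usable housekeeping genes (logged); cells with
    none usable are flagged for dropping.
    """
    if not ct.housekeeping:
        raise ValueError("housekeeping gene set is empty")
    hk_idx = ct.hk_index()
    usable = ~(ct.censored | ct.missing)[:, hk_idx]
    n_usable = usable.sum(axis=1)
    partial = (n_usable > 0) & (n_usable < len(hk_idx))
    if np.any(partial):
        logger.warning(
            "%d cells have censored/missing housekeeping entries; "
            "using the mean of their remaining housekeeping genes",
            int(partial.sum()),
        )
    keep_cells = n_usable > 0
    if not np.all(keep_cells):
        dropped = [ct.cell_ids[i] for i in np.where(~keep_cells)[0]]
        logger.warning("dropping %d cells with no usable housekeeping gene: %s",
                       len(dropped), dropped[:5])
    hk_vals = np.where(usable, ct.values[:, hk_idx], 0.0)
    hk_mean = hk_vals.sum(axis=1) / np.maximum(n_usable, 1)
    hk_mean[~keep_cells] = np.nan
    return hk_mean, keep_cells


def normalize_housekeeping(
    ct: CtMatrix,
    ct_max: float = 40.0,
    keep_housekeeping: bool = False,
) -> NormalizedExpression:
    """Per-cell housekeeping normalization of a Ct matrix.

    A cell whose housekeeping genes are partly censored/missing is
    normalized with the mean of its remaining usable housekeeping genes (a
    warning is logged); a cell with no usable housekeeping gene is dropped.
    Housekeeping columns are dropped from the output by default — they are
    approximately constant after normalization.
    """
    hk_mean, keep_cells = housekeeping_means(ct)
    sel = np.where(keep_cells)[0]
    gene_sel = np.arange(ct.n_genes)
    if not keep_housekeeping:
        gene_sel = np.array([j for j in gene_sel if ct.gene_ids[j] not in ct.housekeeping],
                            dtype=int)
    values = ct.values[np.ix_(sel, gene_sel)] - hk_mean[sel, None]
    lower = ct.lod[gene_sel][None, :] - hk_mean[sel, None]
    upper = np.full_like(lower, ct_max) - hk_mean[sel, None]
    return NormalizedExpression(
        values=values,
        censored=ct.censored[np.ix_(sel, gene_sel)],
        missing=ct.missing[np.ix_(sel, gene_sel)],
        lower_bound=lower,
        upper_bound=upper,
        gene_ids=[ct.gene_ids[j] for j in gene_sel],
        cell_ids=[ct.cell_ids[i] for i in sel],
        cell_labels=None if ct.cell_labels is None else ct.cell_labels[sel],
        hk_mean=hk_mean[sel],
    )


def substitute_censored(ct: CtMatrix, b_sub: float | None = None) -> np.ndarray:
    """Replace censored Ct entries with a fixed value (default: the LOD).

    This is the conventional work-around the probabilistic model replaces;
    the resulting dense matrix feeds standard PCA/ICA/t-SNE baselines.
    Missing entries are left as NaN.
    """
    values = ct.values.copy()
    if b_sub is None:
        sub = np.broadcast_to(ct.lod[None, :], values.shape)
    else:
        if np.any(b_sub < ct.lod):
            raise ValueError("b_sub must be >= LOD")
        sub = np.full_like(values, float(b_sub))
        detected = ~(ct.censored | ct.missing)
        for j in range(ct.n_genes):
            col = values[detected[:, j], j]
            if col.size and b_sub < col.max():
                logger.warning(
                    "b_sub=%g is below the largest detected Ct of gene %s "
                    "(%g); substitution interleaves with detected values",
                    b_sub, ct.gene_ids[j], col.max(),
                )
    values[ct.censored] = sub[ct.censored]
    values[ct.missing] = np.nan
    return values


def model_noise_assignment(
    ne: NormalizedExpression,
    noise: str = "censored",
    lam: float = 10.0,
    beta: float = 1.0,
) -> cn.NoiseAssignment:
    """Build the model-orientation noise assignment for normalized qPCR data.

    Flips to expression orientation (``f = -normalized Ct``) and tags
    entries: detected -> gaussian, absent -> missing, non-detects ->
    left-censored at the flipped threshold (``noise="censored"``) or
    interval-censored between the flipped ceiling and threshold
    (``noise="censored-interval"``).  ``noise="gaussian"`` treats every
    non-missing entry as an exact observation (substitution-style fits).
    """
    if noise not in ("gaussian", "censored", "censored-interval"):
        raise ValueError(f"unknown noise model {noise!r}")
    N, D = ne.shape
    y = -ne.values
    kind = np.full((N, D), cn.GAUSSIAN, dtype=int)
    kind[ne.missing] = cn.MISSING
    b1 = np.zeros((N, D))
    b2 = np.ones((N, D))
    if noise == "gaussian":
        # substitution-style: censored entries become exact observations at
        # the normalized threshold (their stored values are placeholders)
        y = np.where(ne.censored, -ne.lower_bound, y)
    elif noise == "censored":
        kind[ne.censored] = cn.CENSORED_LEFT
        b1 = -ne.lower_bound
    else:  # censored-interval: floor from the Ct ceiling, roof from the LOD
        kind[ne.censored] = cn.CENSORED_INTERVAL
        b1 = -ne.upper_bound
        b2 = -ne.lower_bound
    y = np.where(np.isfinite(y), y, 0.0)
    return cn.NoiseAssignment(kind=kind, y=y, b1=b1, b2=b2, beta=beta, lam=lam)
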