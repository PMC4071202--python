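"""Posterior prediction, censored-residual diagnostics and uncertainty maps.

The fitted model defines an explicit generative mapping from latent space
back to expression space: for any latent point x* each output dimension has
a GP posterior mean and variance, computed from that dimension's kernel and
its ADF site pseudo-observations.  Two diagnostics build on this:

* censored residuals — how far the posterior means of censored entries
  reach beyond their detection bounds (a censoring-aware fit should place a
  large fraction beyond the bound; a substitution fit pins them below it);
* the 2D uncertainty map — background shading proportional to the log
  product of per-dimension posterior variances, darker = more uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from . import censor_noise as cn
from .cgplvm import FittedModel
from .kernels import add_jitter, cross_kernel, shared_matrix


@dataclass
class PosteriorPrediction:
    """Per-dimension posterior moments at query latent points."""

    x_star: np.ndarray  # (M, Q)
    mean: np.ndarray  # (M, D)
    variance: np.ndarray  # (M, D)


def predict(model: FittedModel, x_star: np.ndarray) -> PosteriorPrediction:
    """GP posterior per output dimension at latent points ``x_star``.

    Uses each dimension's training kernel (shared terms plus its censored
    diagonal) with the ADF site parameters as heteroscedastic
    pseudo-observations; cross-covariances exclude white and censor-white
    terms, so moments are for the noise-free latent function.
    """
    if model.X is None:
        raise ValueError("model is not fitted")
    x_star = np.atleast_2d(np.asarray(x_star, dtype=float))
    N, D = model.noise.shape
    kspec = model.kernel
    X = model.X
    Ksh = shared_matrix(kspec, X)
    Kstar_all, kss = cross_kernel(kspec, X, x_star)
    gaussian = model.noise.kind == cn.GAUSSIAN
    M = x_star.shape[0]
    mean = np.zeros((M, D))
    var = np.tile(np.maximum(kss, 1e-12)[:, None], (1, D))
    for d in range(D):
        tau = model.sites_tau[:, d].copy()
        m = model.sites_m[:, d].copy()
        gd = gaussian[:, d]
        tau[gd] = model.noise.beta
        m[gd] = model.noise.y[gd, d]
        act = tau > 0
        na = int(act.sum())
        if na == 0:
            continue
        Kd = Ksh[np.ix_(act, act)].copy()
        if kspec.censor_masks is not None:
            Kd[np.diag_indices(na)] += kspec.censor_var * kspec.censor_masks[d, act]
        A = add_jitter(Kd)
        A[np.diag_indices(na)] += 1.0 / tau[act]
        c, low = cho_factor(A, lower=True)
        Ks = Kstar_all[:, act]
        mean[:, d] = Ks @ cho_solve((c, low), m[act])
        V = cho_solve((c, low), Ks.T)
        var[:, d] = np.maximum(kss - np.sum(Ks * V.T, axis=1), 1e-12)
    return PosteriorPrediction(x_star=x_star, mean=mean, variance=var)


def censored_residuals(
    model: FittedModel,
    data=None,
    mask: np.ndarray | None = None,
    bound: np.ndarray | None = None,
    side: str | None = None,
):
    """Signed residuals of censored entries beyond their detection bounds.

    For each censored entry the residual is the posterior mean at that
    cell's fitted latent position minus the bound, signed so that positive
    means *beyond the bound on the censored side* (e.g. mapped past the
    normalized LOD).  By default the entries and bounds come from the
    model's own noise assignment; pass ``data`` (a NormalizedExpression) or
    explicit ``mask``/``bound``/``side`` to diagnose a model that was fitted
    ignoring the censoring (the substitution baseline).

    Returns ``(residuals, fraction_beyond)``; with no censored entries the
    residual vector is empty and the fraction NaN.
    """
    pred = predict(model, model.X)
    F = pred.mean  # model orientation
    if data is not None:
        mask = data.censored
        bound = model.bounds_to_model(data.lower_bound)
        side = "left" if model.orientation_sign < 0 else "right"
    if mask is None:
        kind = model.noise.kind
        res = []
        for n, d in zip(*np.nonzero(model.noise.censored)):
            k = kind[n, d]
            if k == cn.CENSORED_RIGHT:
                res.append(F[n, d] - model.noise.b1[n, d])
            elif k == cn.CENSORED_LEFT:
                res.append(model.noise.b1[n, d] - F[n, d])
            else:  # interval: measured from the detection-side bound b2
                res.append(model.noise.b2[n, d] - F[n, d])
        res = np.asarray(res, dtype=float)
    else:
        mask = np.asarray(mask, dtype=bool)
        b = np.broadcast_to(np.asarray(bound, dtype=float), mask.shape)
        sgn = 1.0 if side == "right" else -1.0
        res = sgn * (F[mask] - b[mask])
    frac = float(np.mean(res > 0)) if res.size else float("nan")
    return res, frac


@dataclass
class UncertaintyMap:
    """Normalized 2D uncertainty field; intensity 1 = most uncertain (darkest)."""

    xs: np.ndarray  # (R,)
    ys: np.ndarray  # (R,)
    intensity: np.ndarray  # (R, R), in [0, 1]
    log_var_product: np.ndarray  # (R, R) raw sum of log posterior variances


def uncertainty_map(model: FittedModel, resolution: int = 80, pad: float = 0.1,
                    grid: tuple[np.ndarray, np.ndarray] | None = None) -> UncertaintyMap:
    """Per-pixel uncertainty of the latent-to-data mapping on a 2D lattice.

    The scalar per pixel is the log of the product of per-dimension
    posterior variances (the model is a product of independent GPs, so the
    product is its joint predictive spread), min-max normalized to [0, 1]
    per image.  Requires a 2D latent space.
    """
    if model.X.shape[1] != 2:
        raise ValueError("uncertainty_map requires a 2D latent space")
    if grid is None:
        lo = model.X.min(axis=0)
        hi = model.X.max(axis=0)
        span = np.maximum(hi - lo, 1e-6)
        lo = lo - pad * span
        hi = hi + pad * span
        xs = np.linspace(lo[0], hi[0], resolution)
        ys = np.linspace(lo[1], hi[1], resolution)
    else:
        xs, ys = (np.asarray(g, dtype=float) for g in grid)
    XX, YY = np.meshgrid(xs, ys)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    pred = predict(model, pts)
    logv = np.sum(np.log(pred.variance), axis=1).reshape(len(ys), len(xs))
    rng = logv.max() - logv.min()
    intensity = (logv - logv.min()) / (rng if rng > 0 else 1.0)
    return UncertaintyMap(xs=xs, ys=ys, intensity=intensity, log_var_product=logv)


def render_map(umap: UncertaintyMap, X: np.ndarray | None = None,
               labels: np.ndarray | None = None, path=None, ax=None):
    """Scatter of latent points over the grayscale uncertainty background."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 5))
    else:
        fig = ax.figure
    ax.imshow(
        umap.intensity, origin="lower", cmap="gray_r",
        extent=(umap.xs[0], umap.xs[-1], umap.ys[0], umap.ys[-1]),
        aspect="auto", vmin=0.0, vmax=1.0,
    )
    if X is not None:
        if labels is None:
            ax.scatter(X[:, 0], X[:, 1], s=12, c="tab:blue")
        else:
            for lab in np.unique(labels):
                sel = labels == lab
                ax.scatter(X[sel, 0], X[sel, 1], s=12, label=str(lab))
            ax.legend(fontsize=8, markerscale=1.5)
    ax.set_xlabel("latent dim 1")
    ax.set_ylabel("latent dim 2")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
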