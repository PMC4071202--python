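"""Censored-data dual PCA / GPLVM: model assembly and optimization.

The model is a product of D Gaussian processes over shared latent
coordinates X (one GP per output dimension), with per-entry likelihoods
from :mod:`censorlvm.censor_noise`.  With a linear kernel, Gaussian noise
and centered data this is exactly dual probabilistic PCA — the fitted
latent subspace coincides with classical PCA scores — and the censoring
extension replaces the Gaussian factor of each non-detect with a probit.

Fitting alternates two steps:

1. *Assimilation*: a single ADF sweep computes a Gaussian posterior over
   latent function values and the approximate log marginal likelihood.
2. *Optimization*: holding the non-Gaussian site approximations fixed, the
   marginal likelihood is a closed-form Gaussian of the site
   pseudo-observations, differentiable in X and all hyperparameters; a
   scaled-conjugate-gradient block maximizes it jointly.

The probit steepness can be learnt through the white-noise kernel trick: a
steep base slope plus a learnable diagonal variance on censored entries is
an equivalent, smoothly parameterized description of a shallower slope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from . import censor_noise as cn
from ._scg import scg_minimize
from .kernels import KernelSpec, add_jitter, backprop_X, kernel_gradients, shared_matrix
from .preprocessing import NormalizedExpression, model_noise_assignment

logger = logging.getLogger(__name__)

STEEP_LAMBDA = 100.0  # base probit slope when the slope is learnt


@dataclass
class ModelSpec:
    """Model configuration.

    ``noise`` is one of ``"gaussian"``, ``"censored"`` (one-sided) or
    ``"censored-interval"`` (adds the measurement-ceiling bound).
    ``lambda_mode`` is ``"learn"``, ``"fixed:<value>"`` or a number.
    ``center=None`` auto-selects: on for the linear kernel (required for
    the PCA equivalence), off otherwise.
    """

    q: int = 2
    kernel: str = "linear"
    noise: str = "censored"
    lambda_mode: str | float = "fixed:10"
    learn_beta: bool = True
    beta0: float | None = None
    center: bool | None = None
    init: str = "substituted-pca"
    seed: int = 0

    def fixed_lambda(self) -> float | None:
        if self.lambda_mode == "learn":
            return None
        if isinstance(self.lambda_mode, str):
            if not self.lambda_mode.startswith("fixed:"):
                raise ValueError(f"bad lambda_mode {self.lambda_mode!r}")
            return float(self.lambda_mode.split(":", 1)[1])
        return float(self.lambda_mode)


@dataclass
class OptimizerSettings:
    optimizer: str = "scg"  # or "lbfgs"
    outer_max: int = 100
    inner_iters: int = 50
    tol: float = 1e-5


@dataclass
class FittedModel:
    """Optimized latent coordinates, hyperparameters and ADF state."""

    X: np.ndarray
    kernel: KernelSpec
    noise: cn.NoiseAssignment
    sites_m: np.ndarray
    sites_tau: np.ndarray
    trace: list
    converged: bool
    spec: ModelSpec
    adf: cn.ADFState | None = None
    orientation_sign: float = 1.0
    center_offsets: np.ndarray | None = None
    gene_ids: list | None = None
    cell_ids: list | None = None
    cell_labels: np.ndarray | None = None

    @property
    def log_marginal(self) -> float:
        return self.trace[-1] if self.trace else np.nan

    @property
    def effective_lambda(self) -> float:
        """Probit slope implied by the base slope and any censored-diagonal variance."""
        if self.kernel.censor_masks is not None:
            return cn.effective_lambda(self.noise.lam, self.kernel.censor_var)
        return self.noise.lam

    def to_data_orientation(self, values_model: np.ndarray) -> np.ndarray:
        """Map model-orientation function values back to the input orientation."""
        v = np.asarray(values_model, dtype=float)
        if self.center_offsets is not None:
            v = v + self.center_offsets
        return self.orientation_sign * v

    def bounds_to_model(self, bounds_data: np.ndarray) -> np.ndarray:
        """Map input-orientation bounds into centered model orientation."""
        b = self.orientation_sign * np.asarray(bounds_data, dtype=float)
        if self.center_offsets is not None:
            b = b - self.center_offsets
        return b

    # -- serialization (JSON metadata + array payloads as lists) --

    def save(self, path) -> None:
        payload = {
            "X": self.X.tolist(),
            "kernel": {
                "terms": list(self.kernel.terms),
                "rbf_alpha": self.kernel.rbf_alpha,
                "rbf_gamma": self.kernel.rbf_gamma,
                "bias_var": self.kernel.bias_var,
                "white_var": self.kernel.white_var,
                "censor_var": self.kernel.censor_var,
                "censor_masks": None if self.kernel.censor_masks is None
                else self.kernel.censor_masks.tolist(),
            },
            "noise": {
                "kind": self.noise.kind.tolist(),
                "y": self.noise.y.tolist(),
                "b1": self.noise.b1.tolist(),
                "b2": self.noise.b2.tolist(),
                "beta": self.noise.beta,
                "lam": self.noise.lam,
            },
            "sites_m": self.sites_m.tolist(),
            "sites_tau": self.sites_tau.tolist(),
            "trace": list(map(float, self.trace)),
            "converged": self.converged,
            "spec": self.spec.__dict__,
            "orientation_sign": self.orientation_sign,
            "center_offsets": None if self.center_offsets is None
            else self.center_offsets.tolist(),
            "gene_ids": self.gene_ids,
            "cell_ids": self.cell_ids,
            "cell_labels": None if self.cell_labels is None else list(map(str, self.cell_labels)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            p = json.load(fh)
        k = p["kernel"]
        kernel = KernelSpec(
            terms=tuple(k["terms"]), rbf_alpha=k["rbf_alpha"], rbf_gamma=k["rbf_gamma"],
            bias_var=k["bias_var"], white_var=k["white_var"], censor_var=k["censor_var"],
            censor_masks=None if k["censor_masks"] is None else np.array(k["censor_masks"]),
        )
        nz = p["noise"]
        noise = cn.NoiseAssignment(
            kind=np.array(nz["kind"]), y=np.array(nz["y"]),
            b1=np.array(nz["b1"]), b2=np.array(nz["b2"]),
            beta=nz["beta"], lam=nz["lam"],
        )
        return cls(
            X=np.array(p["X"]), kernel=kernel, noise=noise,
            sites_m=np.array(p["sites_m"]), sites_tau=np.array(p["sites_tau"]),
            trace=p["trace"], converged=p["converged"], spec=ModelSpec(**p["spec"]),
            orientation_sign=p["orientation_sign"],
            center_offsets=None if p["center_offsets"] is None else np.array(p["center_offsets"]),
            gene_ids=p["gene_ids"], cell_ids=p["cell_ids"],
            cell_labels=None if p["cell_labels"] is None else np.array(p["cell_labels"]),
        )


def substituted_matrix(noise: cn.NoiseAssignment) -> np.ndarray:
    """Dense model-orientation matrix with censored entries at their bounds.

    Gaussian entries keep their values; one-sided censored entries are set
    to the bound, interval entries to the detection-side bound b2; missing
    entries get their column mean.
    """
    Y = noise.y.copy()
    one_sided = np.isin(noise.kind, (cn.CENSORED_RIGHT, cn.CENSORED_LEFT))
    Y[one_sided] = noise.b1[one_sided]
    iv = noise.kind == cn.CENSORED_INTERVAL
    Y[iv] = noise.b2[iv]
    miss = noise.kind == cn.MISSING
    if np.any(miss):
        col_mean = np.where(miss, np.nan, Y)
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(col_mean, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        Y[miss] = np.broadcast_to(col_mean, Y.shape)[miss]
    return Y


def init_latents(data, q: int, method: str = "substituted-pca", seed: int = 0) -> np.ndarray:
    """Initial latent coordinates: PCA of the bound-substituted matrix, or random."""
    noise = data if isinstance(data, cn.NoiseAssignment) else model_noise_assignment(data)
    N, D = noise.shape
    if q > D:
        raise ValueError(f"latent dimension q={q} exceeds data dimension D={D}")
    if method == "random":
        rng = np.random.default_rng(seed)
        return rng.standard_normal((N, q))
    if method != "substituted-pca":
        raise ValueError(f"unknown init method {method!r}")
    Y = substituted_matrix(noise)
    Yc = Y - Y.mean(axis=0)
    U, S, _ = np.linalg.svd(Yc, full_matrices=False)
    X0 = U[:, :q] * S[:q]
    sd = X0.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return X0 / sd


def objective_and_gradients(
    X: np.ndarray,
    kspec: KernelSpec,
    noise: cn.NoiseAssignment,
    beta: float,
    sites_m: np.ndarray,
    sites_tau: np.ndarray,
    learn_beta: bool = True,
):
    """Negative fixed-site log marginal and its gradients.

    With the non-Gaussian site approximations (pseudo-observations
    ``sites_m`` with precisions ``sites_tau``) held fixed, each dimension's
    marginal is the Gaussian ``N(m_d; 0, K_d + diag(1/tau_d))`` over active
    entries (Gaussian entries always use the current ``beta``, for which the
    site approximation is exact; zero-precision entries drop out).  Returns
    ``(nll, dnll_dX, dnll_dlogparams, dnll_dlogbeta)``.
    """
    if not np.isfinite(beta) or beta <= 0:
        raise FloatingPointError(f"invalid gaussian precision beta={beta}")
    N, D = noise.shape
    Ksh = shared_matrix(kspec, X)
    masks = kspec.censor_masks
    gaussian = noise.kind == cn.GAUSSIAN
    G_sum = np.zeros((N, N))
    dlog_censor = 0.0
    dlog_beta = 0.0
    nll = 0.0
    for d in range(D):
        tau = sites_tau[:, d].copy()
        m = sites_m[:, d].copy()
        gd = gaussian[:, d]
        tau[gd] = beta
        m[gd] = noise.y[gd, d]
        act = tau > 0
        na = int(act.sum())
        if na == 0:
            continue
        Kd = Ksh[np.ix_(act, act)].copy()
        if masks is not None:
            Kd[np.diag_indices(na)] += kspec.censor_var * masks[d, act]
        A = add_jitter(Kd)
        A[np.diag_indices(na)] += 1.0 / tau[act]
        try:
            c, low = cho_factor(A, lower=True)
        except np.linalg.LinAlgError as err:
            raise FloatingPointError(
                f"Cholesky failure in dimension {d} (na={na})"
            ) from err
        ma = m[act]
        alpha = cho_solve((c, low), ma)
        nll += 0.5 * ma @ alpha + np.sum(np.log(np.diag(c))) + 0.5 * na * np.log(2 * np.pi)
        Ainv = cho_solve((c, low), np.eye(na))
        Gd = 0.5 * (np.outer(alpha, alpha) - Ainv)  # d logL / dA
        Gfull = np.zeros((N, N))
        Gfull[np.ix_(act, act)] = Gd
        G_sum += Gfull
        diagG = np.diag(Gfull)
        if masks is not None:
            dlog_censor += kspec.censor_var * float(np.sum(diagG * masks[d] * act))
        if learn_beta:
            dlog_beta += float(np.sum(diagG[gd & act]) * (-1.0 / beta))
    dX = -backprop_X(kspec, X, G_sum)
    dparams: dict[str, float] = {}
    grads = kernel_gradients(kspec, X, dim=None).dparam
    for name in kspec.learnable:
        if name == "censor_var":
            dparams[name] = -dlog_censor
        else:
            dparams[name] = -float(np.sum(G_sum * grads[name]))
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite objective")
    return nll, dX, dparams, (-dlog_beta if learn_beta else 0.0)


def _dim_kernels(kspec: KernelSpec, X: np.ndarray, D: int) -> np.ndarray:
    Ksh = shared_matrix(kspec, X)
    if kspec.censor_masks is None:
        return np.broadcast_to(Ksh, (D,) + Ksh.shape)
    Ks = np.repeat(Ksh[None], D, axis=0)
    for d in range(D):
        Ks[d][np.diag_indices(X.shape[0])] += kspec.censor_var * kspec.censor_masks[d]
    return Ks


def _resolve_data(data, spec: ModelSpec):
    """Normalize the input into a model-orientation NoiseAssignment + metadata."""
    meta = {"sign": 1.0, "gene_ids": None, "cell_ids": None, "cell_labels": None}
    if isinstance(data, NormalizedExpression):
        lam = spec.fixed_lambda()
        noise = model_noise_assignment(
            data, noise=spec.noise, lam=STEEP_LAMBDA if lam is None else lam)
        meta.update(sign=-1.0, gene_ids=data.gene_ids, cell_ids=data.cell_ids,
                    cell_labels=data.cell_labels)
    elif isinstance(data, cn.NoiseAssignment):
        noise = replace(data)
        lam = spec.fixed_lambda()
        noise.lam = STEEP_LAMBDA if lam is None else lam
    else:
        raise TypeError(f"cannot fit data of type {type(data).__name__}")
    return noise, meta


def fit(data, spec: ModelSpec = None, settings: OptimizerSettings = None,
        **spec_kwargs) -> FittedModel:
    """Fit the censored-data latent variable model.

    ``data`` is a :class:`NormalizedExpression` (qPCR pipeline) or a
    :class:`NoiseAssignment` already in model orientation.  Alternates ADF
    assimilation with scaled-conjugate-gradient blocks over the latent
    coordinates and hyperparameters until the relative change in the
    approximate log marginal falls below ``settings.tol``; the
    best-objective state is returned.
    """
    if spec is None:
        spec = ModelSpec(**spec_kwargs)
    elif spec_kwargs:
        spec = replace(spec, **spec_kwargs)
    if settings is None:
        settings = OptimizerSettings()
    noise, meta = _resolve_data(data, spec)
    N, D = noise.shape
    gaussian = noise.kind == cn.GAUSSIAN

    terms = tuple(t.strip() for t in spec.kernel.split("+"))
    center = spec.center
    if center is None:
        center = "linear" in terms
    offsets = None
    if center:
        with np.errstate(invalid="ignore"):
            offsets = np.where(gaussian, noise.y, np.nan)
            offsets = np.nanmean(offsets, axis=0)
        offsets = np.where(np.isfinite(offsets), offsets, 0.0)
        noise.y = noise.y - offsets
        noise.b1 = noise.b1 - offsets
        noise.b2 = noise.b2 - offsets

    X = init_latents(noise, spec.q, spec.init, spec.seed)

    y_obs = noise.y[gaussian]
    y_var = float(np.var(y_obs)) if y_obs.size else 1.0
    y_var = max(y_var, 1e-8)
    learn_lambda = spec.fixed_lambda() is None and bool(np.any(noise.censored))
    kspec = KernelSpec(
        terms=terms,
        rbf_alpha=y_var,
        rbf_gamma=1.0 / max(np.median(_pdist2(X)), 1e-8) if "rbf" in terms else 1.0,
        censor_masks=noise.censor_masks() if learn_lambda else None,
        censor_var=max(1.0 / 10.0**2 - 1.0 / STEEP_LAMBDA**2, 1e-6),
        learn_censor_var=learn_lambda,
    )
    beta = spec.beta0 if spec.beta0 is not None else 1.0 / (0.1 * y_var)
    learn_beta = spec.learn_beta and bool(np.any(gaussian))

    def pack(X, kspec, beta):
        parts = [X.ravel(), kspec.get_log_params()]
        if learn_beta:
            parts.append(np.array([np.log(beta)]))
        return np.concatenate(parts)

    def unpack(theta):
        Xn = theta[: N * spec.q].reshape(N, spec.q)
        nk = len(kspec.learnable)
        ks = kspec.with_log_params(theta[N * spec.q: N * spec.q + nk])
        b = float(np.exp(theta[-1])) if learn_beta else beta
        return Xn, ks, b

    noise.beta = beta
    state = cn.assimilate(noise, _dim_kernels(kspec, X, D))
    best = dict(obj=state.log_marginal, X=X.copy(), kspec=kspec, beta=beta, state=state)
    trace = [state.log_marginal]
    converged = False
    prev = state.log_marginal
    for outer in range(settings.outer_max):
        sm, st = state.site_m, state.site_tau

        def fun_grad(theta):
            # wild trial steps (overflowing/vanishing log hyperparameters,
            # failed factorizations) are rejected, not fatal
            try:
                with np.errstate(over="ignore"):
                    Xn, ks, b = unpack(theta)
                f, dX, dp, dlb = objective_and_gradients(
                    Xn, ks, noise, b, sm, st, learn_beta=learn_beta)
            except (FloatingPointError, ValueError, OverflowError,
                    np.linalg.LinAlgError):
                return np.inf, np.full_like(theta, np.nan)
            g = [dX.ravel(), np.array([dp[n] for n in ks.learnable])]
            if learn_beta:
                g.append(np.array([dlb]))
            return f, np.concatenate(g)

        theta0 = pack(X, kspec, beta)
        if settings.optimizer == "scg":
            res = scg_minimize(fun_grad, theta0, max_iter=settings.inner_iters)
            theta = res.x
        elif settings.optimizer == "lbfgs":
            res = minimize(fun_grad, theta0, jac=True, method="L-BFGS-B",
                           options={"maxiter": settings.inner_iters})
            theta = res.x
        else:
            raise ValueError(f"unknown optimizer {settings.optimizer!r}")
        X, kspec, beta = unpack(theta)
        noise.beta = beta
        state = cn.assimilate(noise, _dim_kernels(kspec, X, D))
        obj = state.log_marginal
        trace.append(obj)
        if not np.isfinite(obj):
            raise FloatingPointError("approximate log marginal diverged")
        if obj > best["obj"]:
            best = dict(obj=obj, X=X.copy(), kspec=kspec, beta=beta, state=state)
        if abs(obj - prev) < settings.tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = obj
    if not converged:
        logger.warning("fit did not converge in %d outer iterations", settings.outer_max)

    noise.beta = best["beta"]
    state = best["state"]
    return FittedModel(
        X=best["X"], kernel=best["kspec"], noise=noise,
        sites_m=state.site_m, sites_tau=state.site_tau,
        trace=trace + [best["obj"]], converged=converged, spec=spec, adf=state,
        orientation_sign=meta["sign"], center_offsets=offsets,
        gene_ids=meta["gene_ids"], cell_ids=meta["cell_ids"],
        cell_labels=meta["cell_labels"],
    )


def _pdist2(X: np.ndarray) -> np.ndarray:
    d2 = (np.sum(X**2, 1)[:, None] + np.sum(X**2, 1)[None, :] - 2 * X @ X.T)
    iu = np.triu_indices(X.shape[0], k=1)
    return np.maximum(d2[iu], 0.0)
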