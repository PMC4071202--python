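"""Covariance functions for the latent variable model.

A kernel is a sum of *shared* terms (linear, RBF, bias, white) evaluated on
the latent coordinates, plus an optional *censor-white* term: extra diagonal
variance added only at censored training points, with a different 0/1 mask
per output dimension.  The censor-white term is how the probit slope is
learnt — adding diagonal variance v at a censored site is equivalent to
flattening the probit slope of that site's likelihood (see
:mod:`censorlvm.censor_noise`) — and it is an observation artifact, so it
never contributes to cross-covariances with test points.

All shared terms are computed once and reused across output dimensions;
only the diagonal correction differs between dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VALID_TERMS = ("linear", "rbf", "bias", "white")


@dataclass
class KernelSpec:
    """Kernel composition and hyperparameters.

    Parameters
    ----------
    terms
        Shared terms, any of ``"linear"``, ``"rbf"``, ``"bias"``, ``"white"``.
    rbf_alpha, rbf_gamma
        RBF signal variance and inverse squared length-scale:
        ``k(x, x') = alpha * exp(-gamma/2 * ||x - x'||^2)``.
    bias_var, white_var
        Variance of the constant (bias) and shared white-noise terms.
    censor_masks
        Optional ``(D, N)`` 0/1 array; row ``d`` marks the censored training
        points of output dimension ``d``.
    censor_var
        Diagonal variance added at censored points (the white-noise encoding
        of the learnable probit slope).
    learn_censor_var
        Whether ``censor_var`` is a free hyperparameter during fitting.
    """

    terms: tuple[str, ...] = ("linear",)
    rbf_alpha: float = 1.0
    rbf_gamma: float = 1.0
    bias_var: float = 1.0
    white_var: float = 1e-2
    censor_masks: np.ndarray | None = None
    censor_var: float = 1e-2
    learn_censor_var: bool = False
    learnable: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if isinstance(self.terms, str):
            self.terms = tuple(t.strip() for t in self.terms.split("+"))
        for t in self.terms:
            if t not in VALID_TERMS:
                raise ValueError(f"unknown kernel term {t!r}")
        if self.learnable is None:
            names = []
            if "rbf" in self.terms:
                names += ["rbf_alpha", "rbf_gamma"]
            if "bias" in self.terms:
                names += ["bias_var"]
            if "white" in self.terms:
                names += ["white_var"]
            if self.learn_censor_var and self.censor_masks is not None:
                names += ["censor_var"]
            self.learnable = tuple(names)
        self._check_positive()

    def _check_positive(self) -> None:
        for name in ("rbf_alpha", "rbf_gamma", "bias_var", "white_var", "censor_var"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"hyperparameter {name} must be finite and > 0, got {v}")

    # -- hyperparameter vector interface (log space enforces positivity) --

    def get_log_params(self) -> np.ndarray:
        return np.log([getattr(self, n) for n in self.learnable])

    def with_log_params(self, log_params: np.ndarray) -> "KernelSpec":
        updates = {n: float(np.exp(v)) for n, v in zip(self.learnable, log_params)}
        return replace(self, **updates)


def _sqdist(X: np.ndarray, Z: np.ndarray | None = None) -> np.ndarray:
    Z = X if Z is None else Z
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Z**2, axis=1)[None, :]
        - 2.0 * X @ Z.T
    )
    return np.maximum(d2, 0.0)


def shared_matrix(spec: KernelSpec, X: np.ndarray) -> np.ndarray:
    """Sum of the shared terms on the training latents (N x N)."""
    N = X.shape[0]
    K = np.zeros((N, N))
    if "linear" in spec.terms:
        K += X @ X.T
    if "rbf" in spec.terms:
        K += spec.rbf_alpha * np.exp(-0.5 * spec.rbf_gamma * _sqdist(X))
    if "bias" in spec.terms:
        K += spec.bias_var
    if "white" in spec.terms:
        K += spec.white_var * np.eye(N)
    return K


def kernel_matrix(spec: KernelSpec, X: np.ndarray, dim: int | None = None) -> np.ndarray:
    """Full training covariance for output dimension ``dim``.

    With no censor-white term (or ``dim=None``) every dimension shares one
    matrix; otherwise the censored diagonal of dimension ``dim`` receives an
    extra ``censor_var``.
    """
    if not np.all(np.isfinite(X)):
        raise ValueError("latent coordinates must be finite")
    K = shared_matrix(spec, X)
    if dim is not None and spec.censor_masks is not None:
        K = K + np.diag(spec.censor_var * spec.censor_masks[dim])
    return K


def cross_kernel(
    spec: KernelSpec, X: np.ndarray, x_star: np.ndarray, dim: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Covariance between test points and training points.

    Returns ``(K_star, k_ss)`` where ``K_star`` is ``(M, N)`` and ``k_ss`` the
    ``(M,)`` prior variances at the test points.  White and censor-white terms
    model observation artifacts at training points and are excluded, so the
    result is the noise-free function-space covariance.  ``dim`` is accepted
    for interface symmetry; the cross-covariance is dimension-independent.
    """
    x_star = np.atleast_2d(x_star)
    if x_star.shape[1] != X.shape[1]:
        raise ValueError(
            f"test points have dimension {x_star.shape[1]}, expected {X.shape[1]}"
        )
    M = x_star.shape[0]
    Ks = np.zeros((M, X.shape[0]))
    kss = np.zeros(M)
    if "linear" in spec.terms:
        Ks += x_star @ X.T
        kss += np.sum(x_star**2, axis=1)
    if "rbf" in spec.terms:
        Ks += spec.rbf_alpha * np.exp(-0.5 * spec.rbf_gamma * _sqdist(x_star, X))
        kss += spec.rbf_alpha
    if "bias" in spec.terms:
        Ks += spec.bias_var
        kss += spec.bias_var
    return Ks, kss


@dataclass
class KernelGradients:
    """Analytic gradients of one dimension's kernel matrix.

    ``dparam[name]`` is dK/d(log name) (log-space, matching the positivity
    parameterization used by the optimizer).  ``dX()`` materializes the full
    (N, Q, N, N) tensor dK/dX — only sensible for small N; the fitting path
    uses :func:`backprop_X` instead.
    """

    spec: KernelSpec
    X: np.ndarray
    dim: int | None
    dparam: dict[str, np.ndarray]

    def dX(self) -> np.ndarray:
        N, Q = self.X.shape
        out = np.zeros((N, Q, N, N))
        eye = np.eye(N)
        if "linear" in self.spec.terms:
            for n in range(N):
                for q in range(Q):
                    E = np.outer(eye[n], self.X[:, q])
                    out[n, q] += E + E.T
        if "rbf" in self.spec.terms:
            Krbf = self.spec.rbf_alpha * np.exp(
                -0.5 * self.spec.rbf_gamma * _sqdist(self.X)
            )
            g = self.spec.rbf_gamma
            for n in range(N):
                for q in range(Q):
                    diff = self.X[n, q] - self.X[:, q]
                    col = -g * Krbf[n] * diff  # col[n] = 0: K(x, x) is flat
                    out[n, q, n, :] += col
                    out[n, q, :, n] += col
        return out


def kernel_gradients(spec: KernelSpec, X: np.ndarray, dim: int | None = None) -> KernelGradients:
    """Gradients of ``kernel_matrix(spec, X, dim)`` w.r.t. log hyperparameters."""
    N = X.shape[0]
    dparam: dict[str, np.ndarray] = {}
    if "rbf" in spec.terms:
        d2 = _sqdist(X)
        Krbf = spec.rbf_alpha * np.exp(-0.5 * spec.rbf_gamma * d2)
        dparam["rbf_alpha"] = Krbf
        dparam["rbf_gamma"] = Krbf * (-0.5 * spec.rbf_gamma * d2)
    if "bias" in spec.terms:
        dparam["bias_var"] = np.full((N, N), spec.bias_var)
    if "white" in spec.terms:
        dparam["white_var"] = spec.white_var * np.eye(N)
    if spec.censor_masks is not None and dim is not None:
        dparam["censor_var"] = np.diag(spec.censor_var * spec.censor_masks[dim])
    return KernelGradients(spec=spec, X=X, dim=dim, dparam=dparam)


def backprop_X(spec: KernelSpec, X: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Chain a symmetric gradient matrix ``G = dL/dK`` back to ``dL/dX``.

    ``G`` must already be summed over output dimensions (shared terms are
    identical across dimensions, and the censor-white term does not depend
    on X).
    """
    G = 0.5 * (G + G.T)
    dX = np.zeros_like(X)
    if "linear" in spec.terms:
        dX += 2.0 * G @ X
    if "rbf" in spec.terms:
        Krbf = spec.rbf_alpha * np.exp(-0.5 * spec.rbf_gamma * _sqdist(X))
        W = 2.0 * G * Krbf  # (G + G^T) ∘ K
        np.fill_diagonal(W, 0.0)
        dX += -spec.rbf_gamma * (W.sum(axis=1)[:, None] * X - W @ X)
    return dX


def add_jitter(K: np.ndarray, rel: float = 1e-6) -> np.ndarray:
    """Fixed relative jitter on the diagonal before factorization."""
    return K + rel * max(np.mean(np.diag(K)), 1e-12) * np.eye(K.shape[0])
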