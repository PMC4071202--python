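"""Censoring noise models and the assumed-density-filtering approximation.

The latent variable model places a GP prior over latent function values
``f_{:,d}`` for every output dimension ``d`` and attaches one likelihood
factor per matrix entry:

* ``gaussian`` — ``p(y | f) = N(y; f, 1/beta)`` for detected values;
* ``missing``  — a constant factor (the entry carries no information);
* ``censored_right`` at bound ``b`` — ``p(censored | f) = Phi(lam (f - b))``:
  the probability that an observation generated around ``f`` falls beyond
  the bound, a probit with steepness ``lam``;
* ``censored_left`` — the mirrored probit ``Phi(lam (b - f))``;
* ``censored_interval`` between ``b1 < b2`` —
  ``Phi(lam (f - b1)) - Phi(lam (f - b2))``.

Because the probit factors are non-Gaussian, the posterior over F is
approximated by a Gaussian via assumed density filtering (ADF): one sweep
over the entries, each factor moment-matched against the running Gaussian.
For a probit factor the partition function is available in closed form,

    Z = Phi( +/- (mu - b) / sqrt(v + 1/lam^2) ),

which also exposes the slope/variance equivalence used to learn ``lam``:
extra diagonal kernel variance ``v_c`` at a censored site combines with a
steep base slope ``lam0`` into an effective slope
``1 / sqrt(1/lam0^2 + v_c)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import log_ndtr, ndtr

from .kernels import add_jitter

logger = logging.getLogger(__name__)

# entry tags
GAUSSIAN = 0
MISSING = 1
CENSORED_RIGHT = 2
CENSORED_LEFT = 3
CENSORED_INTERVAL = 4

_TAG_NAMES = {
    GAUSSIAN: "gaussian",
    MISSING: "missing",
    CENSORED_RIGHT: "censored_right",
    CENSORED_LEFT: "censored_left",
    CENSORED_INTERVAL: "censored_interval",
}


@dataclass
class NoiseAssignment:
    """Per-entry noise tags for an N x D data matrix.

    ``y`` holds observed values (used only at ``gaussian`` entries), ``b1``
    and ``b2`` per-entry censoring bounds: the single bound for one-sided
    tags lives in ``b1``; interval tags use both with ``b1 < b2``.  ``beta``
    is the Gaussian observation precision and ``lam`` the probit steepness,
    both shared across entries.
    """

    kind: np.ndarray  # (N, D) int
    y: np.ndarray  # (N, D) float
    b1: np.ndarray  # (N, D) float
    b2: np.ndarray  # (N, D) float
    beta: float = 1.0
    lam: float = 10.0

    def __post_init__(self) -> None:
        self.kind = np.asarray(self.kind, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        self.b1 = np.broadcast_to(np.asarray(self.b1, dtype=float), self.kind.shape).copy()
        self.b2 = np.broadcast_to(np.asarray(self.b2, dtype=float), self.kind.shape).copy()
        if self.lam <= 0:
            raise ValueError("probit steepness lam must be > 0")
        if self.beta <= 0:
            raise ValueError("gaussian precision beta must be > 0")
        iv = self.kind == CENSORED_INTERVAL
        if np.any(self.b1[iv] >= self.b2[iv]):
            raise ValueError("interval censoring requires b1 < b2")
        bad = ~np.isin(self.kind, list(_TAG_NAMES))
        if np.any(bad):
            raise ValueError(f"unknown noise tags {np.unique(self.kind[bad])}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.kind.shape

    @property
    def censored(self) -> np.ndarray:
        """Boolean mask of censored entries (any censoring flavour)."""
        return np.isin(self.kind, (CENSORED_RIGHT, CENSORED_LEFT, CENSORED_INTERVAL))

    @property
    def missing(self) -> np.ndarray:
        return self.kind == MISSING

    def censor_masks(self) -> np.ndarray:
        """(D, N) 0/1 masks I_c per output dimension, for the censor-white kernel."""
        return self.censored.T.astype(float).copy()


def censor_likelihood(f: np.ndarray | float, kind: int, lam: float,
                      b1: float = 0.0, b2: float = 0.0, y: float = 0.0,
                      beta: float = 1.0) -> np.ndarray | float:
    """Likelihood of one entry's observation event given latent value ``f``."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    f = np.asarray(f, dtype=float)
    if kind == GAUSSIAN:
        return np.sqrt(beta / (2 * np.pi)) * np.exp(-0.5 * beta * (f - y) ** 2)
    if kind == MISSING:
        return np.ones_like(f)
    if kind == CENSORED_RIGHT:
        return ndtr(lam * (f - b1))
    if kind == CENSORED_LEFT:
        return ndtr(lam * (b1 - f))
    if kind == CENSORED_INTERVAL:
        return ndtr(lam * (f - b1)) - ndtr(lam * (f - b2))
    raise ValueError(f"unknown tag {kind}")


def _phi_ratio(z: np.ndarray) -> np.ndarray:
    """phi(z) / Phi(z), stable in the lower tail."""
    z = np.asarray(z, dtype=float)
    log_pdf = -0.5 * z**2 - 0.5 * np.log(2 * np.pi)
    return np.exp(log_pdf - log_ndtr(z))


def log_partition(mu: float, v: float, kind: int, lam: float,
                  b1: float = 0.0, b2: float = 0.0, y: float = 0.0,
                  beta: float = 1.0) -> tuple[float, float, float]:
    """Log partition function of one tilted site and its mu-derivatives.

    ``Z(mu, v) = ∫ p(obs | f) N(f; mu, v) df`` for a cavity/running marginal
    ``N(mu, v)``.  Returns ``(log Z, d log Z / d mu, d^2 log Z / d mu^2)``.
    One-sided probit sites are the closed-form normal CDF of
    ``±(mu - b) / s`` with ``s = sqrt(v + 1/lam^2)``; interval sites the
    difference of two such terms; Gaussian sites a Gaussian convolution;
    missing sites have ``Z = 1``.
    """
    if v <= 0:
        raise ValueError("cavity variance must be > 0")
    if kind == MISSING:
        return 0.0, 0.0, 0.0
    if kind == GAUSSIAN:
        s2 = v + 1.0 / beta
        r = y - mu
        logZ = -0.5 * (np.log(2 * np.pi * s2) + r * r / s2)
        return logZ, r / s2, -1.0 / s2
    if lam <= 0:
        raise ValueError("lam must be > 0")
    s = np.sqrt(v + 1.0 / (lam * lam))
    if kind in (CENSORED_RIGHT, CENSORED_LEFT):
        sign = 1.0 if kind == CENSORED_RIGHT else -1.0
        z = sign * (mu - b1) / s
        u = _phi_ratio(z)
        logZ = float(log_ndtr(z))
        g1 = sign * u / s
        g2 = -u * (z + u) / (s * s)
        return logZ, float(g1), float(g2)
    if kind == CENSORED_INTERVAL:
        z1 = (mu - b1) / s  # z1 > z2 since b1 < b2
        z2 = (mu - b2) / s
        # log-stable difference of normal CDFs, mirrored in the upper tail
        if z1 + z2 <= 0:
            la, lb = log_ndtr(z1), log_ndtr(z2)
        else:
            la, lb = log_ndtr(-z2), log_ndtr(-z1)
        logZ = la + np.log1p(-np.exp(min(lb - la, -1e-12)))
        log_norm = -0.5 * np.log(2 * np.pi)
        r1 = np.exp(log_norm - 0.5 * z1 * z1 - logZ)  # phi(z1) / Z
        r2 = np.exp(log_norm - 0.5 * z2 * z2 - logZ)
        g1 = (r1 - r2) / s
        g2 = (-z1 * r1 + z2 * r2) / (s * s) - g1 * g1
        return float(logZ), float(g1), float(g2)
    raise ValueError(f"unknown tag {kind}")


@dataclass
class ADFState:
    """Gaussian posterior approximation over latent function values.

    One independent block per output dimension (the marginal likelihood
    factorizes over dimensions): posterior means ``mu[:, d]``, covariance
    blocks ``Sigma[d]``, site pseudo-observations ``site_m``/precisions
    ``site_tau`` back-derived from the moment matching, and the accumulated
    log partition ``log_z`` (per entry; its sum approximates the log
    marginal likelihood).
    """

    mu: np.ndarray  # (N, D)
    Sigma: np.ndarray  # (D, N, N)
    site_m: np.ndarray  # (N, D)
    site_tau: np.ndarray  # (N, D)
    log_z: np.ndarray  # (N, D)
    n_clipped: int = 0

    @property
    def log_marginal(self) -> float:
        return float(self.log_z.sum())

    def log_marginal_dim(self, d: int) -> float:
        return float(self.log_z[:, d].sum())


def _entry_args(noise: NoiseAssignment, n: int, d: int) -> dict:
    return dict(
        kind=int(noise.kind[n, d]),
        lam=noise.lam,
        b1=float(noise.b1[n, d]),
        b2=float(noise.b2[n, d]),
        y=float(noise.y[n, d]),
        beta=noise.beta,
    )


def adf_sweep_dim(K: np.ndarray, noise: NoiseAssignment, d: int,
                  order: np.ndarray | None = None):
    """Single ADF sweep over the entries of one output dimension.

    Moment-matches one likelihood factor at a time against the running
    Gaussian ``N(mu, Sigma)`` that starts at the prior ``N(0, K)``.  The
    default order folds in the exact (Gaussian) sites first, then the
    censored sites, each in ascending cell order: exact sites commute, so
    incorporating them first can only improve the cavities the approximate
    sites see.  Pass ``order`` to override.  Returns
    ``(mu, Sigma, site_m, site_tau, log_z, n_clipped)``.
    """
    N = K.shape[0]
    Sigma = add_jitter(np.asarray(K, dtype=float))
    mu = np.zeros(N)
    site_m = np.zeros(N)
    site_tau = np.zeros(N)
    log_z = np.zeros(N)
    n_clipped = 0
    if order is None:
        exact = np.isin(noise.kind[:, d], (GAUSSIAN, MISSING))
        idx = np.concatenate([np.where(exact)[0], np.where(~exact)[0]])
    else:
        idx = np.asarray(order)
    v_floor = 1e-10 * float(np.mean(np.diag(Sigma)))
    for n in idx:
        kind = int(noise.kind[n, d])
        if kind == MISSING:
            continue  # site precision stays exactly 0
        v = Sigma[n, n]
        if v <= v_floor:
            # running variance collapsed numerically; clamp and continue
            v = max(v_floor, 1e-300)
            Sigma[n, n] = v
        m = mu[n]
        logZ, g1, g2 = log_partition(m, v, **_entry_args(noise, n, d))
        log_z[n] = logZ
        s = Sigma[:, n].copy()
        mu = mu + g1 * s
        Sigma = Sigma + g2 * np.outer(s, s)
        if kind == GAUSSIAN:
            # conjugate case: the site is exact, no back-derivation needed
            # (avoids catastrophic cancellation at high precision beta)
            site_tau[n] = noise.beta
            site_m[n] = noise.y[n, d]
            continue
        # back-derive site parameters from the matched marginal moments
        denom = 1.0 + v * g2
        if denom <= 1e-12:
            # matched variance collapsed: clip the site precision
            site_tau[n] = 0.0
            site_m[n] = 0.0
            n_clipped += 1
            continue
        tau = -g2 / denom
        if tau < 0.0:
            n_clipped += 1
            tau = 0.0
        # keep site precisions in a numerically safe band: an effectively
        # flat site carries no information; an effectively exact site is
        # capped so its pseudo-noise stays above jitter scale
        if tau < 1e-12:
            tau = 0.0
        tau = min(tau, 1e12)
        site_tau[n] = tau
        if tau > 0.0:
            mu_hat = m + v * g1
            v_hat = v * denom
            site_m[n] = (mu_hat / v_hat - m / v) / tau
    return mu, Sigma, site_m, site_tau, log_z, n_clipped


def assimilate(Y_noise: NoiseAssignment, kernels) -> ADFState:
    """One ADF pass over all entries, dimension blocks in parallel.

    ``kernels`` is either a single (N, N) matrix shared by all dimensions or
    a sequence/array of per-dimension matrices ``K_d``.  Entries within each
    dimension are swept in fixed ascending cell order; dimensions are
    independent blocks, so their relative order does not affect the result.
    """
    N, D = Y_noise.shape
    Ks = np.asarray(kernels, dtype=float)
    if Ks.ndim == 2:
        Ks = np.broadcast_to(Ks, (D, N, N))
    mu = np.zeros((N, D))
    Sigma = np.zeros((D, N, N))
    site_m = np.zeros((N, D))
    site_tau = np.zeros((N, D))
    log_z = np.zeros((N, D))
    n_clipped = 0
    for d in range(D):
        mu_d, Sig_d, m_d, tau_d, lz_d, nc = adf_sweep_dim(Ks[d], Y_noise, d)
        mu[:, d] = mu_d
        Sigma[d] = Sig_d
        site_m[:, d] = m_d
        site_tau[:, d] = tau_d
        log_z[:, d] = lz_d
        n_clipped += nc
    if n_clipped:
        logger.warning("ADF clipped %d negative site precisions to 0", n_clipped)
    return ADFState(mu=mu, Sigma=Sigma, site_m=site_m, site_tau=site_tau,
                    log_z=log_z, n_clipped=n_clipped)


def effective_lambda(lam0: float, censor_var: float) -> float:
    """Effective probit slope of a steep base slope plus censored-diagonal variance."""
    return 1.0 / np.sqrt(1.0 / lam0**2 + censor_var)


def gaussian_log_marginal(K: np.ndarray, y: np.ndarray, beta: float) -> float:
    """Closed-form GP log marginal N(y; 0, K + I/beta) — the exact reference
    that ADF reproduces when every site is Gaussian."""
    N = len(y)
    A = add_jitter(K) + np.eye(N) / beta
    c, low = cho_factor(A, lower=True)
    alpha = cho_solve((c, low), y)
    return float(-0.5 * y @ alpha - np.sum(np.log(np.diag(c))) - 0.5 * N * np.log(2 * np.pi))
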