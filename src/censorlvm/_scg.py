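"""Scaled conjugate gradient minimizer (Møller, 1993).

Conjugate-gradient minimization with a Levenberg–Marquardt-style scaling of
the local curvature estimate instead of a line search: the second-order
information along the search direction is estimated from a finite gradient
difference and regularized by an adaptive trust parameter.  This is the
optimizer classically used for latent-variable GP models; a quasi-Newton
fallback (scipy L-BFGS-B) is wired in at the model layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SCGResult:
    x: np.ndarray
    fun: float
    n_iter: int
    n_fev: int
    converged: bool
    trace: list = field(default_factory=list)


def scg_minimize(fun_grad, x0: np.ndarray, max_iter: int = 100,
                 tol_x: float = 1e-8, tol_f: float = 1e-8) -> SCGResult:
    """Minimize ``f`` given ``fun_grad(x) -> (f, grad)``.

    Objective evaluations where ``f`` is non-finite are treated as rejected
    steps (the trust parameter is raised), so the optimizer backs away from
    divergent regions instead of aborting.
    """
    sigma0 = 1.0e-4
    x = np.asarray(x0, dtype=float).copy()
    n = x.size
    f_old, grad = fun_grad(x)
    n_fev = 1
    if not np.isfinite(f_old):
        raise FloatingPointError("objective non-finite at the initial point")
    d = -grad
    success = True
    n_success = 0
    lam = 1.0
    lam_min, lam_max = 1e-15, 1e100
    converged = False
    trace = [f_old]
    mu = kappa = theta = 0.0
    it = 0
    while it < max_iter:
        it += 1
        if success:
            mu = d @ grad
            if mu >= 0:
                d = -grad
                mu = d @ grad
            kappa = d @ d
            if kappa < 1e-300:
                converged = True
                break
            sigma = sigma0 / np.sqrt(kappa)
            _, grad_plus = fun_grad(x + sigma * d)
            n_fev += 1
            if not np.all(np.isfinite(grad_plus)):
                theta = lam * kappa  # force a conservative step
            else:
                theta = (d @ (grad_plus - grad)) / sigma
        # scale the curvature to be positive definite along d
        delta = theta + lam * kappa
        if delta <= 0:
            delta = lam * kappa
            lam = lam - theta / kappa
        alpha = -mu / delta
        x_new = x + alpha * d
        f_new, grad_new = fun_grad(x_new)
        n_fev += 1
        if np.isfinite(f_new):
            comparison = 2.0 * (f_new - f_old) / (alpha * mu)
        else:
            comparison = -1.0  # reject
        if comparison >= 0:
            success = True
            n_success += 1
            x = x_new
            if (np.max(np.abs(alpha * d)) < tol_x
                    and abs(f_new - f_old) < tol_f):
                converged = True
                f_old = f_new
                trace.append(f_old)
                break
            f_old = f_new
            trace.append(f_old)
            grad_old = grad
            grad = grad_new
            if grad @ grad == 0:
                converged = True
                break
        else:
            success = False
        if comparison < 0.25:
            lam = min(4.0 * lam, lam_max)
        if comparison > 0.75:
            lam = max(0.5 * lam, lam_min)
        if n_success == n:
            d = -grad
            n_success = 0
        elif success:
            gamma = ((grad_old - grad) @ grad) / mu
            d = gamma * d - grad
    return SCGResult(x=x, fun=f_old, n_iter=it, n_fev=n_fev,
                     converged=converged, trace=trace)
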