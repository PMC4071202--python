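import warnings

import numpy as np
import pytest

from censorlvm import censor_noise as cn


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def gaussian_noise_assignment(y, beta=1.0):
    """All-Gaussian noise assignment for a dense matrix."""
    y = np.asarray(y, dtype=float)
    return cn.NoiseAssignment(
        kind=np.zeros(y.shape, dtype=int), y=y,
        b1=np.zeros(y.shape), b2=np.ones(y.shape), beta=beta,
    )


def mp_log_z(mu, v, kind, lam, b1=0.0, b2=0.0, y=0.0, beta=1.0, dps=30):
    """Arbitrary-precision quadrature of the site partition function.

    Deep-tail Z values span hundreds of orders of magnitude; double
    precision adaptive quadrature cannot certify |delta log Z| < 1e-8
    there, so the log-partition oracle integrates in 30-digit arithmetic.
    """
    import mpmath as mp

    with mp.workdps(dps):
        sd = mp.sqrt(v)

        def tilt(f):
            if kind == cn.GAUSSIAN:
                return mp.npdf(y, f, 1 / mp.sqrt(beta))
            if kind == cn.MISSING:
                return mp.mpf(1)
            if kind == cn.CENSORED_RIGHT:
                return mp.ncdf(lam * (f - b1))
            if kind == cn.CENSORED_LEFT:
                return mp.ncdf(lam * (b1 - f))
            return mp.ncdf(lam * (f - b1)) - mp.ncdf(lam * (f - b2))

        w = max(np.sqrt(v), 1.0 / lam, 1.0 / np.sqrt(beta))
        lo = min(mu - 15 * np.sqrt(v), b1 - 15 * w, y - 15 * w)
        hi = max(mu + 15 * np.sqrt(v), b2 + 15 * w, y + 15 * w)
        pts = sorted({lo, hi, *(p for p in (b1, b2, mu, y) if lo < p < hi)})
        Z = mp.quad(lambda f: tilt(f) * mp.npdf(f, mu, sd), pts)
        return float(mp.log(Z))


def quad_log_partition(mu, v, kind, lam, b1=0.0, b2=0.0, y=0.0, beta=1.0):
    """Quadrature oracle for one site's log partition and mu-derivatives.

    log Z comes from high-precision quadrature (:func:`mp_log_z`); the
    derivative integrals are evaluated directly with adaptive double
    precision quadrature (no finite differences), independent of the closed
    forms they check.
    """
    from scipy.integrate import quad

    def tilt(f):
        return cn.censor_likelihood(f, kind, lam, b1, b2, y, beta)

    def gauss(f):
        return np.exp(-0.5 * (f - mu) ** 2 / v) / np.sqrt(2 * np.pi * v)

    # finite window with breakpoints at the bounds and the cavity mean:
    # epsabs=0 forces relative accuracy even when Z is deep-tail tiny
    s = max(np.sqrt(v), 1.0 / lam)
    lo = min(mu - 15 * np.sqrt(v), b1 - 15 * s, (y if kind == cn.GAUSSIAN else mu) - 15)
    hi = max(mu + 15 * np.sqrt(v), b2 + 15 * s, (y if kind == cn.GAUSSIAN else mu) + 15)
    pts = sorted(p for p in (b1, b2, mu, y) if lo < p < hi)
    opts = dict(limit=500, epsabs=0.0, epsrel=1e-12, points=pts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # quad round-off chatter at 1e-12
        Z, _ = quad(lambda f: tilt(f) * gauss(f), lo, hi, **opts)
        Zp, _ = quad(lambda f: tilt(f) * gauss(f) * (f - mu) / v, lo, hi, **opts)
        Zpp, _ = quad(
            lambda f: tilt(f) * gauss(f) * ((f - mu) ** 2 / v**2 - 1.0 / v),
            lo, hi, **opts,
        )
    g1 = Zp / Z
    g2 = Zpp / Z - g1**2
    logZ = mp_log_z(mu, v, kind, lam, b1=b1, b2=b2, y=y, beta=beta)
    return logZ, g1, g2


def quad_tilted_moments(mu, v, kind, lam, b1=0.0, b2=0.0, y=0.0, beta=1.0):
    """Quadrature mean/variance of the tilted density t(f) N(f; mu, v) / Z."""
    from scipy.integrate import quad

    def tilt(f):
        return cn.censor_likelihood(f, kind, lam, b1, b2, y, beta)

    def gauss(f):
        return np.exp(-0.5 * (f - mu) ** 2 / v) / np.sqrt(2 * np.pi * v)

    s = max(np.sqrt(v), 1.0 / lam)
    lo = min(mu - 15 * np.sqrt(v), b1 - 15 * s, (y if kind == cn.GAUSSIAN else mu) - 15)
    hi = max(mu + 15 * np.sqrt(v), b2 + 15 * s, (y if kind == cn.GAUSSIAN else mu) + 15)
    pts = sorted(p for p in (b1, b2, mu, y) if lo < p < hi)
    opts = dict(limit=500, epsabs=0.0, epsrel=1e-12, points=pts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Z, _ = quad(lambda f: tilt(f) * gauss(f), lo, hi, **opts)
        m1, _ = quad(lambda f: f * tilt(f) * gauss(f), lo, hi, **opts)
        m2, _ = quad(lambda f: f * f * tilt(f) * gauss(f), lo, hi, **opts)
    mean = m1 / Z
    return mean, m2 / Z - mean**2
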