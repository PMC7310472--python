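"""CMV serostatus from IgG concentrations via two-component mixture modeling.

Anti-CMV IgG titers in a mixed population are bimodal on the log scale:
a low seronegative component and a high seropositive component.  A
two-component Gaussian mixture is fitted to log concentrations by EM, and
the seropositivity cutoff is the point between the component means where
the two weighted component densities intersect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class MixtureError(RuntimeError):
    pass


@dataclass
class MixtureFit:
    """Two-component Gaussian fit on log titers, component 1 = lower mean."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    w1: float
    log_likelihood: float
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray


def _em_once(x, mu1, mu2, s1, s2, w1, tol, max_iter, min_sigma):
    trace = []
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d1 = w1 * stats.norm.pdf(x, mu1, s1)
        d2 = (1 - w1) * stats.norm.pdf(x, mu2, s2)
        total = d1 + d2
        if np.any(total <= 0) or not np.all(np.isfinite(total)):
            raise MixtureError("degenerate responsibilities")
        ll = float(np.log(total).sum())
        trace.append(ll)
        r1 = d1 / total
        n1 = r1.sum()
        n2 = len(x) - n1
        if n1 < 1e-8 or n2 < 1e-8:
            raise MixtureError("component collapsed to zero weight")
        mu1 = float((r1 * x).sum() / n1)
        mu2 = float(((1 - r1) * x).sum() / n2)
        s1 = float(np.sqrt((r1 * (x - mu1) ** 2).sum() / n1))
        s2 = float(np.sqrt(((1 - r1) * (x - mu2) ** 2).sum() / n2))
        if s1 < min_sigma or s2 < min_sigma:
            raise MixtureError("component variance collapsed")
        w1 = float(n1 / len(x))
        if ll - ll_old < tol and it > 1:
            converged = True
            break
        ll_old = ll
    return mu1, mu2, s1, s2, w1, ll, converged, it, np.array(trace)


def fit_two_component_mixture(log_titers, n_restarts: int = 5,
                              tol: float = 1e-8, max_iter: int = 500,
                              min_sigma: float = 1e-4,
                              seed: int | None = 0) -> MixtureFit:
    """EM fit of two Gaussians to log titers; best of several restarts.

    The log-likelihood is non-decreasing across EM iterations (an EM
    guarantee asserted in tests).  Restarts draw initial means from random
    pairs of sample quantiles; runs whose variance collapses are discarded.
    Components are relabeled so mu1 < mu2.
    """
    x = np.asarray(log_titers, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 titers to fit a mixture")
    if not np.all(np.isfinite(x)):
        raise ValueError("log titers must be finite")
    rng = np.random.default_rng(seed)
    s0 = float(x.std())
    best: MixtureFit | None = None
    for k in range(n_restarts):
        if k == 0:
            q1, q2 = np.quantile(x, [0.25, 0.75])
        else:
            q1, q2 = np.sort(rng.choice(x, size=2, replace=False))
            if q2 - q1 < 1e-6:
                continue
        try:
            mu1, mu2, s1, s2, w1, ll, conv, it, trace = _em_once(
                x, q1, q2, 0.5 * s0 + 1e-6, 0.5 * s0 + 1e-6, 0.5,
                tol, max_iter, min_sigma)
        except MixtureError:
            continue
        if mu1 > mu2:  # relabel so component 1 is the lower (seronegative)
            mu1, mu2, s1, s2, w1 = mu2, mu1, s2, s1, 1 - w1
        fit = MixtureFit(mu1, mu2, s1, s2, w1, ll, conv, it, trace)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if best is None:
        raise MixtureError("all EM restarts degenerated; "
                           "data may be a single tight cluster")
    return best


def seropositivity_cutoff(fit: MixtureFit) -> float:
    """Log-concentration where the two weighted densities intersect.

    Solves the quadratic density-equality equation in the log domain and
    returns the root between the component means.  With equal variances the
    quadratic degenerates to a linear equation.
    """
    if not fit.converged:
        raise MixtureError("mixture fit did not converge; no cutoff defined")
    m1, m2, s1, s2, w1 = fit.mu1, fit.mu2, fit.sigma1, fit.sigma2, fit.w1
    w2 = 1 - w1
    a = 1 / s2**2 - 1 / s1**2
    b = 2 * (m1 / s1**2 - m2 / s2**2)
    c = (m2**2 / s2**2 - m1**2 / s1**2
         + 2 * np.log((w1 * s2) / (w2 * s1)))
    if abs(a) < 1e-12:
        roots = np.array([-c / b])
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            raise MixtureError("densities never intersect")
        roots = (-b + np.array([-1.0, 1.0]) * np.sqrt(disc)) / (2 * a)
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size == 0:
        raise MixtureError(
            f"no density intersection between the component means "
            f"({m1:.4g}, {m2:.4g}); roots at {np.sort(roots)}")
    return float(inside[0])


def classify_serostatus(titers, cutoff: float,
                        log_scale: bool = False) -> np.ndarray:
    """Seropositive iff titer >= cutoff (ties count as positive).

    ``cutoff`` is on the log scale as returned by
    :func:`seropositivity_cutoff`; pass ``log_scale=True`` if ``titers``
    are already log concentrations.
    """
    t = np.asarray(titers, dtype=float)
    logt = t if log_scale else np.log(t)
    return np.where(logt >= cutoff, "positive", "negative")
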