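"""High-speed high-stakes (HSHS) trade-off score distribution.

The HSHS scoring rule assigns a learner the signed residual time

    S = (2Y - 1)(d - T),

where ``Y`` is accuracy (0/1), ``T`` the response time and ``d`` the time
limit: a fast correct answer scores close to ``+d``, a fast incorrect answer
(an instant guess) close to ``-d``.  Under the compensatory working model
with logit ``eta = sum_m theta_m - beta`` the score follows the
exponential-tilted density on (-d, d),

    f(s | eta) ∝ exp(eta * s),       s in (-d, d),

which is the unique generative model whose mean is the closed-form expected
score used by the rating engine,

    E(S) = d * coth(eta * d) - 1 / eta,

and whose implied accuracy marginal P(S > 0) = logistic(eta * d) coincides
with the compensatory IRT probability of a correct response.  At ``eta = 0``
the density degenerates to Uniform(-d, d) and E(S) = 0 (a removable
singularity handled by the series eta*d^2/3 - eta^3*d^4/45).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["mean_score", "prob_correct", "sample_score", "score_logpdf"]

_SERIES_CUTOFF = 1e-6


def mean_score(eta, d: float = 1.0):
    """Expected HSHS score E(S) = d*coth(eta*d) - 1/eta.

    Vectorised in ``eta``; exact 0 at ``eta = 0`` and numerically stable
    near it via the odd series ``eta*d**2/3 - eta**3*d**4/45``.
    """
    eta = np.asarray(eta, dtype=float)
    small = np.abs(eta * d) < _SERIES_CUTOFF
    safe = np.where(small, 1.0, eta)
    exact = d / np.tanh(safe * d) - 1.0 / safe
    series = eta * d * d / 3.0 - eta**3 * d**4 / 45.0
    out = np.where(small, series, exact)
    return out if out.ndim else float(out)


def prob_correct(eta, d: float = 1.0):
    """P(Y = 1) = P(S > 0) = logistic(eta * d) under the tilted density."""
    out = expit(np.asarray(eta, dtype=float) * d)
    return out if out.ndim else float(out)


def sample_score(eta, u, d: float = 1.0):
    """Inverse-CDF draw of S given uniform variates ``u`` in [0, 1).

    Solves F(s) = u for the CDF of the exponential-tilted density.  For
    ``eta > 0`` the stable form is ``s = d + log(u + (1-u) e^{-2 eta d}) / eta``;
    negative tilts use the reflection F_{-eta}(s) = 1 - F_{eta}(-s), so the
    result is an exact inverse CDF (increasing in u) for every eta.
    """
    eta = np.asarray(eta, dtype=float)
    u = np.asarray(u, dtype=float)
    a = np.abs(eta)
    small = a < 1e-8
    a_safe = np.where(small, 1.0, a)
    u_eff = np.where(eta < 0, 1.0 - u, u)
    s = d + np.log(u_eff + (1.0 - u_eff) * np.exp(-2.0 * a_safe * d)) / a_safe
    s = np.where(eta < 0, -s, s)
    s = np.where(small, -d + 2.0 * d * u, s)
    s = np.clip(s, -d, d)
    return s if s.ndim else float(s)


def score_logpdf(s, eta, d: float = 1.0):
    """Log-density of the tilted score distribution (for testing/oracles)."""
    s = np.asarray(s, dtype=float)
    eta = np.asarray(eta, dtype=float)
    # log normalising constant: log( (e^{eta d} - e^{-eta d}) / eta )
    a = np.abs(eta)
    small = a < 1e-8
    a_safe = np.where(small, 1.0, a)
    logz = a_safe * d + np.log1p(-np.exp(-2.0 * a_safe * d)) - np.log(a_safe)
    logz = np.where(small, np.log(2.0 * d), logz)
    out = np.where((s > -d) & (s < d), eta * s - logz, -np.inf)
    return out if out.ndim else float(out)
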