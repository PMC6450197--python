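"""Evaluation metrics: ROC/AUROC, per-occasion MSE and bias, EAP benchmark.

AUROC is computed as the rank (Mann-Whitney) statistic — the probability
that a randomly chosen positive's prediction exceeds a randomly chosen
negative's, ties counting one half — which equals the trapezoidal area
under the empirical ROC curve with the standard false-positive rate
FP / (FP + TN).

The expected-a-posteriori (EAP) benchmark is the posterior mean of the
M-dimensional ability under the compensatory working model (slopes 1 on
loaded dimensions, known difficulties) and a normal prior, computed by
product-rule Gauss-Hermite quadrature.  It is the batch, computing-
intensive counterpart against which the online Elo estimates are judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit
from scipy.stats import rankdata

from .item_bank import ItemBank

__all__ = [
    "RocResult",
    "MseCurve",
    "auroc",
    "mse_curve",
    "eap_estimate",
    "eap_estimate_batch",
    "corr_vs_eap",
]


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


def auroc(predicted, observed) -> RocResult:
    """Rank-based AUROC with the full empirical ROC sweep.

    ``observed`` must contain both classes; ties in ``predicted``
    contribute 1/2 to the statistic.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    y = y.astype(bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: only one class present")

    ranks = rankdata(p)  # average ranks handle ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # ROC sweep from the highest threshold down
    order = np.argsort(-p, kind="mergesort")
    p_sorted = p[order]
    y_sorted = y[order]
    distinct = np.r_[np.nonzero(np.diff(p_sorted))[0], p_sorted.size - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    thresholds = np.r_[np.inf, p_sorted[distinct]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auroc=float(auc))


@dataclass
class MseCurve:
    """Per-dimension, per-occasion accuracy of the ability estimates.

    ``mse[m, t]`` is the squared estimation error of dimension m at
    occasion t averaged over learners; ``abs_bias[m, t]`` the absolute
    value of the mean signed error.
    """

    occasions: np.ndarray
    mse: np.ndarray
    abs_bias: np.ndarray


def mse_curve(trajectories: np.ndarray, theta_true: np.ndarray) -> MseCurve:
    """Summarise (n_learners, n_occasions, M) estimate trajectories.

    Every learner must have a trajectory of equal length (the session
    design guarantees this); errors are taken against the constant true
    abilities.
    """
    traj = np.asarray(trajectories, dtype=float)
    theta = np.asarray(theta_true, dtype=float)
    if traj.ndim != 3:
        raise ValueError("trajectories must be (n_learners, n_occasions, M)")
    if theta.shape != (traj.shape[0], traj.shape[2]):
        raise ValueError("theta_true shape does not match trajectories")
    err = traj - theta[:, None, :]
    mse = np.mean(err**2, axis=0).T
    abs_bias = np.abs(np.mean(err, axis=0)).T
    return MseCurve(
        occasions=np.arange(1, traj.shape[1] + 1), mse=mse, abs_bias=abs_bias
    )


def _posterior_modes(y, loads, beta, prior_mean, prior_prec, n_iter=50, tol=1e-10):
    """Newton modes of the log posterior for every learner (concave problem)."""
    n, m = y.shape[0], prior_mean.size
    theta = np.tile(prior_mean, (n, 1))
    for _ in range(n_iter):
        logits = theta @ loads.T - beta  # (N, J)
        p = 1.0 / (1.0 + np.exp(-logits))
        grad = (y - p) @ loads - (theta - prior_mean) @ prior_prec
        w = p * (1.0 - p)  # (N, J)
        hess = -np.einsum("nj,ja,jb->nab", w, loads, loads) - prior_prec
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        theta = theta - step
        if np.abs(step).max() < tol:
            break
    logits = theta @ loads.T - beta
    w = expit(logits) * expit(-logits)
    neg_hess = np.einsum("nj,ja,jb->nab", w, loads, loads) + prior_prec
    return theta, neg_hess


def eap_estimate_batch(
    responses: np.ndarray,
    bank: ItemBank,
    prior_mean=None,
    prior_cov=None,
    n_nodes: int = 21,
) -> np.ndarray:
    """EAP ability estimates for learners with responses in bank order.

    ``responses`` is (n_learners, n_items) of 0/1.  The likelihood uses
    the working model: slopes 1 on loaded dimensions, known difficulties.
    The prior defaults to standard normal N(0, I).  Quadrature is adaptive
    Gauss-Hermite: the product rule is centred and scaled at each
    learner's posterior mode (Laplace approximation), so 21 nodes per
    dimension resolve even the tight posteriors of long sessions.
    Returns (n_learners, M) posterior means.
    """
    y = np.asarray(responses, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    if y.shape[1] != len(bank):
        raise ValueError("responses must have one column per bank item")
    m = bank.n_dims
    prior_mean = np.zeros(m) if prior_mean is None else np.asarray(prior_mean, float)
    prior_cov = np.eye(m) if prior_cov is None else np.asarray(prior_cov, float)
    if np.linalg.eigvalsh(prior_cov).min() <= 0:
        raise ValueError("prior covariance must be positive definite")
    prior_prec = np.linalg.inv(prior_cov)
    loads = bank.loadings
    beta = bank.difficulties

    modes, neg_hess = _posterior_modes(y, loads, beta, prior_mean, prior_prec)
    # per-learner scale: chol of the Laplace covariance (neg_hess^-1)
    lap_cov = np.linalg.inv(neg_hess)
    chol = np.linalg.cholesky(lap_cov)  # (N, M, M)

    x, w = hermgauss(n_nodes)
    grids = np.meshgrid(*([x] * m), indexing="ij")
    z = np.stack([g.ravel() for g in grids], axis=1)  # (K, M)
    logw = np.sum(
        np.stack(np.meshgrid(*([np.log(w)] * m), indexing="ij"), axis=0).reshape(m, -1),
        axis=0,
    )
    z_sq = np.sum(z**2, axis=1)

    n = y.shape[0]
    out = np.empty((n, m))
    sqrt2 = np.sqrt(2.0)
    for i in range(n):
        nodes = modes[i] + sqrt2 * z @ chol[i].T  # (K, M)
        logits = nodes @ loads.T - beta
        loglik = np.where(y[i] == 1, -np.logaddexp(0.0, -logits),
                          -np.logaddexp(0.0, logits)).sum(axis=1)
        dev = nodes - prior_mean
        logprior = -0.5 * np.einsum("ka,ab,kb->k", dev, prior_prec, dev)
        # GH weights against e^{-z'z}; the z'z term undoes the kernel
        logpost = loglik + logprior + z_sq + logw
        wt = np.exp(logpost - logpost.max())
        wt /= wt.sum()
        out[i] = wt @ nodes
    return out


def eap_estimate(
    responses,
    bank: ItemBank,
    prior_mean=None,
    prior_cov=None,
    n_nodes: int = 21,
) -> np.ndarray:
    """EAP estimate for one learner from an (item_id, y) response list.

    With zero responses the posterior is the prior and the prior mean is
    returned.  Items not answered simply contribute no likelihood term.
    """
    m = bank.n_dims
    if len(responses) == 0:
        return (np.zeros(m) if prior_mean is None
                else np.asarray(prior_mean, float).copy())
    id_to_col = {it.item_id: k for k, it in enumerate(bank.items)}
    y = np.full(len(bank), np.nan)
    for item_id, resp in responses:
        y[id_to_col[item_id]] = resp
    answered = ~np.isnan(y)
    sub = ItemBank(
        items=[bank.items[k] for k in np.nonzero(answered)[0]],
        n_dims=m,
        pattern_label=bank.pattern_label,
    )
    return eap_estimate_batch(
        y[answered][None, :], sub, prior_mean, prior_cov, n_nodes
    )[0]


def corr_vs_eap(final_elo: np.ndarray, eap: np.ndarray) -> np.ndarray:
    """Per-dimension Pearson correlation between two (N, M) estimate sets."""
    a = np.asarray(final_elo, dtype=float)
    b = np.asarray(eap, dtype=float)
    if a.shape != b.shape:
        raise ValueError("estimate matrices must have matching shapes")
    out = np.empty(a.shape[1])
    for m in range(a.shape[1]):
        if a[:, m].std() == 0 or b[:, m].std() == 0:
            raise ValueError(f"zero-variance column {m}")
        out[m] = np.corrcoef(a[:, m], b[:, m])[0, 1]
    return out
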