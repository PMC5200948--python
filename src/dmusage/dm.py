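"""Dirichlet-multinomial (DM) probability model.

The DM distribution models a vector of feature counts ``y = (y_1, ..., y_q)``
with total ``m`` whose underlying proportions are themselves random: counts are
multinomial given proportions, and proportions follow a Dirichlet with
parameter ``gamma = gamma_plus * pi``.  Marginally,

    f_DM(y; gamma) = C(m; y) * G(gamma_plus)/G(m + gamma_plus)
                     * prod_j G(y_j + gamma_j)/G(gamma_j)

with ``G`` the gamma function.  ``gamma_plus = sum_j gamma_j`` is the
concentration (precision): large values mean proportions tightly concentrated
around ``pi = gamma / gamma_plus`` and the model approaches the multinomial.
The equivalent dispersion is ``theta = 1/(1 + gamma_plus)``; ``theta = 0`` is
exactly multinomial.

All densities are computed in log space via log-gamma functions; no raw
factorials appear anywhere.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, polygamma, psi

from .data import DMParameters, GeneCounts, MomentSummary

__all__ = [
    "dm_log_pmf",
    "dm_log_pmf_theta",
    "multinomial_log_pmf",
    "dm_moments",
    "convert_parameterization",
    "gamma_from_parameters",
    "gene_log_likelihood",
    "estimate_proportions",
    "ProportionFit",
]

PROPORTION_FLOOR = 1e-10


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        yi = np.floor(y)
        if not np.array_equal(yi, y):
            raise ValueError("counts must be integers")
        y = y.astype(np.int64)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    return y


def _check_simplex(pi, q=None) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 1 or (q is not None and pi.size != q):
        raise ValueError("proportion vector has wrong shape")
    if (pi <= 0).any():
        raise ValueError("proportions must be strictly positive")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError(f"proportions sum to {pi.sum():.12g}, not 1")
    return pi


def multinomial_log_pmf(y, pi) -> float:
    """Log multinomial pmf, the theta = 0 limit of the DM."""
    y = _check_counts(y)
    pi = _check_simplex(pi, y.size)
    m = y.sum()
    coef = gammaln(m + 1) - gammaln(y + 1).sum()
    return float(coef + np.where(y > 0, y * np.log(pi), 0.0).sum())


def _lgamma_ratio(a: float, x: int) -> float:
    """log Gamma(a + x) - log Gamma(a) for integer x >= 0, stable for huge a.

    The difference of two log-gamma values cancels catastrophically when a is
    large; the ascending product sum_{r=0}^{x-1} log(a + r) is exact at any a
    and cheap for the count magnitudes seen here, so it is preferred whenever
    x is modest.
    """
    if x <= 4096 or a > 1e8:
        return float(np.log(a + np.arange(x)).sum())
    return float(gammaln(a + x) - gammaln(a))


def dm_log_pmf(y, pi, gamma_plus) -> float:
    """Log DM pmf at Dirichlet parameter ``gamma = gamma_plus * pi``.

    Parameters
    ----------
    y : array-like of int
        Observed counts, length q.
    pi : array-like of float
        Expected proportions; strictly positive, summing to 1.
    gamma_plus : float
        Concentration, > 0.
    """
    y = _check_counts(y)
    pi = _check_simplex(pi, y.size)
    if not np.isfinite(gamma_plus) or gamma_plus <= 0:
        raise ValueError("gamma_plus must be a positive finite scalar")
    m = int(y.sum())
    gamma = gamma_plus * pi
    coef = gammaln(m + 1) - gammaln(y + 1).sum()
    core = sum(_lgamma_ratio(g, int(c)) for g, c in zip(gamma, y))
    return float(coef - _lgamma_ratio(gamma_plus, m) + core)


def dm_log_pmf_theta(y, pi, theta) -> float:
    """Log DM pmf in the (pi, theta) dispersion parameterization.

    ``theta`` lies in [0, 1); ``theta = 0`` returns exactly the multinomial
    log-pmf, otherwise this equals :func:`dm_log_pmf` with
    ``gamma_plus = (1 - theta) / theta``.
    """
    if not np.isfinite(theta) or theta < 0 or theta >= 1:
        raise ValueError("theta must lie in [0, 1)")
    if theta == 0:
        return multinomial_log_pmf(y, pi)
    return dm_log_pmf(y, pi, (1.0 - theta) / theta)


def dm_moments(m, pi, gamma_plus) -> MomentSummary:
    """Mean, covariance and inflation factor of a DM count vector.

    mean = m * pi; covariance = c * m * (diag(pi) - pi pi^T) with
    c = (m + gamma_plus) / (1 + gamma_plus).
    """
    if m < 1 or int(m) != m:
        raise ValueError("m must be a positive integer")
    pi = _check_simplex(pi)
    if not np.isfinite(gamma_plus) or gamma_plus <= 0:
        raise ValueError("gamma_plus must be a positive finite scalar")
    c = (m + gamma_plus) / (1.0 + gamma_plus)
    cov = c * m * (np.diag(pi) - np.outer(pi, pi))
    return MomentSummary(mean=m * pi, covariance=cov, inflation_factor=float(c))


def convert_parameterization(gamma) -> DMParameters:
    """Convert a Dirichlet parameter vector gamma to (pi, gamma_plus)."""
    gamma = np.asarray(gamma, dtype=float)
    if (gamma <= 0).any() or not np.isfinite(gamma).all():
        raise ValueError("gamma entries must be strictly positive and finite")
    gamma_plus = gamma.sum()
    return DMParameters({"all": gamma / gamma_plus}, float(gamma_plus))


def gamma_from_parameters(params: DMParameters, group="all") -> np.ndarray:
    """Inverse of :func:`convert_parameterization`: gamma = gamma_plus * pi."""
    return params.gamma(group)


# ---------------------------------------------------------------------------
# Likelihood machinery (vectorised over samples; used by every fitting path)
# ---------------------------------------------------------------------------

def _loglik_matrix(counts: np.ndarray, pi: np.ndarray, gamma_plus: float) -> float:
    """Joint DM log-likelihood of a q x n count matrix, one shared (pi, gamma_plus)."""
    m = counts.sum(axis=0)
    gamma = gamma_plus * pi
    const = (
        gammaln(m + 1).sum()
        - gammaln(counts + 1).sum()
        + counts.shape[1] * gammaln(gamma_plus)
        - gammaln(m + gamma_plus).sum()
    )
    core = (gammaln(counts + gamma[:, None]) - gammaln(gamma)[:, None]).sum()
    return float(const + core)


def _score_full(counts: np.ndarray, pi: np.ndarray, gamma_plus: float) -> np.ndarray:
    """d loglik / d pi_j treating all q proportions as free (sum over samples)."""
    gamma = gamma_plus * pi
    return gamma_plus * (psi(counts + gamma[:, None]) - psi(gamma)[:, None]).sum(axis=1)


def observed_information(counts: np.ndarray, pi: np.ndarray, gamma_plus: float) -> np.ndarray:
    """Observed information for the q-1 free proportions (last one implied).

    Returns ``-H`` where ``H`` is the analytic Hessian of the DM log-likelihood
    of the count matrix with respect to ``pi_1..pi_{q-1}``, with
    ``pi_q = 1 - sum``.  Structure: the per-feature curvature sums
    ``S_j = sum_i psi'(y_ji + gamma_j) - n psi'(gamma_j)`` give
    ``H = gamma_plus^2 (diag(S_1..S_{q-1}) + S_q 1 1^T)``.
    """
    n = counts.shape[1]
    gamma = gamma_plus * pi
    S = polygamma(1, counts + gamma[:, None]).sum(axis=1) - n * polygamma(1, gamma)
    H = gamma_plus**2 * (np.diag(S[:-1]) + S[-1])
    return -H


class ProportionFit:
    """Result of a per-group proportion fit at fixed concentration."""

    def __init__(self, proportions: dict, loglik: float, converged: bool):
        self.proportions = proportions
        self.loglik = loglik
        self.converged = converged


def _pooled_init(counts: np.ndarray) -> np.ndarray:
    tot = counts.sum()
    if tot == 0:
        pi = np.full(counts.shape[0], 1.0 / counts.shape[0])
    else:
        pi = counts.sum(axis=1) / tot
    pi = np.maximum(pi, 1e-6)
    return pi / pi.sum()


def _fit_group(counts: np.ndarray, gamma_plus: float, pi_init=None,
               tol: float = 1e-8, maxiter: int = 1000):
    """Maximise the DM log-likelihood over the open simplex at fixed gamma_plus.

    Optimisation runs over q-1 free coordinates (additive log-ratio transform,
    last proportion the reference); the returned point is floored at
    PROPORTION_FLOOR and renormalised.  Returns (pi_hat, converged).
    """
    q = counts.shape[0]
    if q == 1:
        return np.array([1.0]), True
    if pi_init is None:
        pi_init = _pooled_init(counts)
    pi_init = np.maximum(np.asarray(pi_init, dtype=float), 1e-8)
    pi_init = pi_init / pi_init.sum()

    def negll_grad(z):
        ez = np.exp(np.append(z, 0.0) - max(z.max(initial=0.0), 0.0))
        pi = ez / ez.sum()
        pi = np.maximum(pi, PROPORTION_FLOOR)
        gamma = gamma_plus * pi
        ll = (gammaln(counts + gamma[:, None]) - gammaln(gamma)[:, None]).sum()
        g_full = _score_full(counts, pi, gamma_plus)
        gz = pi * (g_full - pi @ g_full)
        return -ll, -gz[:-1]

    z0 = np.log(pi_init[:-1]) - np.log(pi_init[-1])
    res = minimize(negll_grad, z0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-8})
    ez = np.exp(np.append(res.x, 0.0) - max(res.x.max(initial=0.0), 0.0))
    pi_hat = ez / ez.sum()
    pi_hat = np.maximum(pi_hat, PROPORTION_FLOOR)
    pi_hat = pi_hat / pi_hat.sum()
    # never return a point worse than the initialisation
    ll_hat = _loglik_matrix(counts, pi_hat, gamma_plus)
    ll_init = _loglik_matrix(counts, pi_init, gamma_plus)
    if ll_init > ll_hat:
        return pi_init, False
    return pi_hat, bool(res.success)


def _split_by_group(gene: GeneCounts, grouping: dict):
    """Yield (group, q x n_g submatrix) for samples with positive totals."""
    totals = gene.column_totals
    groups = {}
    for i, s in enumerate(gene.sample_ids):
        if s not in grouping:
            raise ValueError(f"sample {s} missing from grouping")
        if totals[i] == 0:
            continue  # zero-total samples carry no information about proportions
        groups.setdefault(grouping[s], []).append(i)
    return {g: gene.counts[:, idx] for g, idx in groups.items()}


def gene_log_likelihood(gene: GeneCounts, grouping: dict, params: DMParameters) -> float:
    """Joint DM log-likelihood of one gene under per-group proportions.

    Samples with zero total count are excluded (they contribute a constant
    under the ancillarity of ``m``).
    """
    total = 0.0
    for g, sub in _split_by_group(gene, grouping).items():
        if g not in params.proportions_by_group:
            raise ValueError(f"no proportion vector for group {g!r}")
        total += _loglik_matrix(sub, params.proportions_by_group[g], params.concentration)
    return total


def estimate_proportions(gene: GeneCounts, grouping: dict, gamma_plus: float,
                         init: dict | None = None) -> ProportionFit:
    """Per-group ML proportions at fixed concentration.

    Each group's proportion vector maximises that group's DM log-likelihood
    over the open simplex; initial value is the group's pooled observed
    proportions unless ``init`` supplies a warm start.
    """
    if not np.isfinite(gamma_plus) or gamma_plus <= 0:
        raise ValueError("gamma_plus must be a positive finite scalar")
    if gene.n_features < 2:
        raise ValueError(f"{gene.gene_id}: need at least 2 features to fit proportions")
    props, ll, ok = {}, 0.0, True
    for g, sub in _split_by_group(gene, grouping).items():
        pi0 = None if init is None else init.get(g)
        pi_hat, conv = _fit_group(sub, gamma_plus, pi_init=pi0)
        props[g] = pi_hat
        ll += _loglik_matrix(sub, pi_hat, gamma_plus)
        ok = ok and conv
    if not props:
        raise ValueError(f"{gene.gene_id}: no sample with positive total count")
    return ProportionFit(props, ll, ok)
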