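"""Structural models for the joint distribution of attribute profiles.

The joint distribution over the 2^K attribute profiles is modeled as a
log-linear model with 0/1 (dummy) coded main effects and interaction
products up to a chosen order:

    log mu_c = lambda_0 + sum_k lambda_k a_ck + sum_{k<l} lambda_kl a_ck a_cl + ...

``model_order`` 1 is attribute independence (main effects only), 2 is the
homogeneous-association model (all two-way, no higher interactions), and
K is saturated.  Under dummy coding exp(lambda_kl) is the conditional
odds ratio between attributes k and l given the others absent; for the
homogeneous-association model it is the common conditional odds ratio.

Fitting uses the Poisson log-linear representation of the multinomial
likelihood (statsmodels GLM), which accepts the fractional expected class
counts produced by EM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import statsmodels.api as sm

from .data import InvalidDimensionError, InvalidValueError, profile_matrix

_PTOL = 1e-10


@dataclass
class LatentClassDistribution:
    """Probability vector over the 2^K attribute profiles (canonical order)."""

    probs: np.ndarray
    model_order: int = None
    lambdas: np.ndarray = None
    lambda_labels: list = None
    lambda_ses: np.ndarray = None
    attribute_names: list = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        C = self.probs.shape[0]
        K = int(round(np.log2(C)))
        if 2**K != C:
            raise InvalidDimensionError("probability vector length must be a power of 2")
        if np.any(self.probs < -1e-12):
            raise InvalidValueError("class probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-8:
            raise InvalidValueError("class probabilities must sum to 1")
        self.probs = np.clip(self.probs, 0.0, None)
        self.probs = self.probs / self.probs.sum()
        if self.model_order is None:
            self.model_order = K
        if self.attribute_names is None:
            self.attribute_names = [f"A{k + 1}" for k in range(K)]

    @property
    def K(self) -> int:
        return int(round(np.log2(self.probs.shape[0])))

    def n_parameters(self) -> int:
        """Free structural parameters (the intercept is fixed by normalization)."""
        return structural_param_count(self.K, self.model_order)


def _n_loglinear_terms(K: int, max_order: int) -> int:
    from math import comb

    return sum(comb(K, m) for m in range(0, max_order + 1))


def structural_param_count(K: int, model_order: int) -> int:
    """Number of free structural parameters (design columns minus intercept)."""
    return _n_loglinear_terms(K, model_order) - 1


def loglinear_design(K: int, max_order: int, attribute_names=None):
    """Dummy-coded log-linear design over the 2^K profiles.

    Columns: intercept, K main effects (0/1), then all interaction
    products of size 2..max_order, attributes ordered by column.  Returns
    ``(design, labels)``; rows follow the canonical profile order.
    """
    if not (1 <= max_order <= K):
        raise InvalidValueError(f"max_order must be in [1, {K}], got {max_order}")
    if attribute_names is None:
        attribute_names = [f"A{k + 1}" for k in range(K)]
    prof = profile_matrix(K).astype(float)
    cols = [np.ones(2**K)]
    labels = ["Intercept"]
    for k in range(K):
        cols.append(prof[:, k])
        labels.append(attribute_names[k])
    for m in range(2, max_order + 1):
        for S in combinations(range(K), m):
            cols.append(prof[:, list(S)].prod(axis=1))
            labels.append(" × ".join(attribute_names[k] for k in S))
    return np.column_stack(cols), labels


def fit_loglinear(weights, max_order: int, attribute_names=None) -> LatentClassDistribution:
    """Maximum-likelihood log-linear fit to (possibly fractional) profile counts.

    ``weights`` are non-negative expected counts over the 2^K profiles in
    canonical order, e.g. the expected class counts from an EM E-step.  The
    multinomial MLE is obtained through the equivalent Poisson regression;
    fitted probabilities, lambda coefficients, and their standard errors
    are returned.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise InvalidValueError("profile weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise InvalidValueError("profile weights must have a positive total")
    C = w.shape[0]
    K = int(round(np.log2(C)))
    X, labels = loglinear_design(K, max_order, attribute_names)

    if max_order == K:
        # saturated: closed form, lambdas solved from log counts
        probs = w / total
        logw = np.log(np.clip(w, _PTOL, None))
        lam = np.linalg.solve(X, logw)
        ses = _poisson_ses(X, w)
        return LatentClassDistribution(
            probs=probs,
            model_order=max_order,
            lambdas=lam,
            lambda_labels=labels,
            lambda_ses=ses,
            attribute_names=attribute_names,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(w, X, family=sm.families.Poisson())
        try:
            res = model.fit(maxiter=200, tol=1e-10)
        except Exception as exc:  # pragma: no cover - convergence diagnostics
            raise InvalidValueError(f"log-linear fit failed: {exc}") from exc
    if not res.converged:
        raise InvalidValueError(
            f"log-linear fit did not converge in {res.fit_history.get('iteration', '?')} iterations"
        )
    mu = res.mu
    probs = mu / mu.sum()
    return LatentClassDistribution(
        probs=probs,
        model_order=max_order,
        lambdas=np.asarray(res.params),
        lambda_labels=labels,
        lambda_ses=np.asarray(res.bse),
        attribute_names=attribute_names,
    )


def _poisson_ses(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Poisson-information standard errors at a (possibly saturated) solution."""
    W = np.clip(w, _PTOL, None)
    info = X.T @ (W[:, None] * X)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return np.sqrt(np.clip(np.diag(cov), 0, None))


def interaction_odds_ratio(lambda_value: float) -> float:
    """Conditional odds ratio implied by a dummy-coded interaction coefficient."""
    return float(np.exp(lambda_value))


def marginals(dist: LatentClassDistribution) -> np.ndarray:
    """Attribute prevalences p_k = P(attribute k present)."""
    prof = profile_matrix(dist.K)
    return prof.T.astype(float) @ dist.probs


def independence_prior(dist: LatentClassDistribution) -> LatentClassDistribution:
    """Product distribution with the same attribute marginals as ``dist``.

    Keeps each individual attribute prevalence exactly while removing all
    between-attribute association.
    """
    p = marginals(dist)
    prof = profile_matrix(dist.K).astype(float)
    probs = np.exp(
        prof @ np.log(np.clip(p, _PTOL, 1)) + (1 - prof) @ np.log(np.clip(1 - p, _PTOL, 1))
    )
    probs = probs / probs.sum()
    return LatentClassDistribution(
        probs=probs, model_order=1, attribute_names=dist.attribute_names
    )
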