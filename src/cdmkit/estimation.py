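"""Marginal maximum-likelihood estimation of G-DINA family models by EM.

The latent state of respondent i is one of the 2^K attribute profiles.
Marginalizing over the profiles gives the observed-data likelihood

    L_i = sum_c pi_c prod_j P_j(c)^{x_ij} (1 - P_j(c))^{1 - x_ij},

which the EM algorithm maximizes by alternating posterior computation
(E-step), item-wise maximization of the expected complete-data
log-likelihood (M-step; closed form for the saturated G-DINA, numeric on
the link scale for the additive models), and a structural re-fit of the
profile distribution on the expected class counts.  All likelihood
accumulation is in the log domain with per-respondent max subtraction.

Standard errors come from the inverse of the outer-product-of-gradients
(empirical cross-product) information of the incomplete-data
log-likelihood, with scores obtained through Fisher's identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from .data import (
    InvalidQMatrixError,
    InvalidValueError,
    QMatrix,
    ResponseMatrix,
    check_alignment,
    reduced_index_map,
)
from .measurement import (
    ItemParameterSet,
    additive_design,
    item_prob_by_class,
    monotone_pairs,
    parameter_count,
)
from .structural import (
    LatentClassDistribution,
    fit_loglinear,
    structural_param_count,
)

logger = logging.getLogger(__name__)

_PCLIP = 1e-9


@dataclass
class FittedCDM:
    """A converged (or best-effort) CDM fit."""

    items: list
    structural: LatentClassDistribution
    posteriors: np.ndarray
    loglik: float
    loglik_trace: np.ndarray
    npar: int
    n_iterations: int
    converged: bool
    fit: dict
    N: int
    Q: QMatrix

    @property
    def prior(self) -> np.ndarray:
        return self.structural.probs

    @property
    def K(self) -> int:
        return self.Q.K


def class_prob_matrix(items, K: int) -> np.ndarray:
    """Per-item endorsement probabilities over the 2^K profiles, shape (J, 2^K)."""
    return np.vstack([item_prob_by_class(it, K) for it in items])


def e_step(responses, items, prior):
    """Posterior profile probabilities and expected quantities.

    Returns ``(posteriors, loglik)`` where ``posteriors[i, c]`` is
    proportional to ``prior[c] * prod_j P_j(c)^x_ij (1-P_j(c))^(1-x_ij)``,
    normalized over the 2^K profiles.  Accumulation is in the log domain,
    so patterns that are near-impossible under every class remain finite.
    """
    X = responses.values if isinstance(responses, ResponseMatrix) else np.asarray(responses)
    X = X.astype(float)
    K = items[0].K
    prior = np.asarray(prior, dtype=float)
    P = np.clip(class_prob_matrix(items, K), _PCLIP, 1 - _PCLIP)
    logP = np.log(P)
    log1mP = np.log1p(-P)
    # (N, C) log joint
    logjoint = X @ logP + (1.0 - X) @ log1mP + np.log(np.clip(prior, 1e-300, None))[None, :]
    norm = logsumexp(logjoint, axis=1)
    post = np.exp(logjoint - norm[:, None])
    return post, float(norm.sum())


def expected_item_counts(posteriors, responses, item: ItemParameterSet, col: int = None):
    """Expected success and trial counts per reduced class for one item.

    ``R_g`` is the posterior-weighted count of endorsements among classes
    collapsing to reduced class g; ``T_g`` the posterior mass.  ``col`` is
    the item's response column (defaults to the column recorded at fit
    time).
    """
    X = responses.values if isinstance(responses, ResponseMatrix) else np.asarray(responses)
    K = item.K
    ridx = reduced_index_map(item.qvector, K)
    nred = 2**item.Kj
    j = col if col is not None else getattr(item, "_col", 0)
    x = X[:, j].astype(float)
    w_c = posteriors.sum(axis=0)
    s_c = x @ posteriors
    R = np.bincount(ridx, weights=s_c, minlength=nred)
    T = np.bincount(ridx, weights=w_c, minlength=nred)
    return R, T


def _neg_ecll(p, R, T):
    p = np.clip(p, _PCLIP, 1 - _PCLIP)
    return -float(R @ np.log(p) + (T - R) @ np.log1p(-p))


def _dneg_dp(p, R, T):
    p = np.clip(p, _PCLIP, 1 - _PCLIP)
    return -(R / p - (T - R) / (1 - p))


def _monotone_project(p: np.ndarray, T: np.ndarray, Kj: int) -> np.ndarray:
    """Project reduced-class probabilities onto the monotone cone.

    Iterative weighted pooling of violating subset/superset pairs (the
    pool-adjacent-violators idea lifted to the subset partial order), with
    a guaranteed cumulative-max fallback pass.
    """
    p = p.copy()
    pairs = monotone_pairs(Kj)
    w = np.clip(T, 1e-8, None)
    for _ in range(200):
        viol = [(a, b) for a, b in pairs if p[a] > p[b] + 1e-12]
        if not viol:
            return p
        a, b = max(viol, key=lambda ab: p[ab[0]] - p[ab[1]])
        pooled = (w[a] * p[a] + w[b] * p[b]) / (w[a] + w[b])
        p[a] = p[b] = pooled
    # fallback: enforce monotonicity exactly by cumulative max over subsets
    order = sorted(range(2**Kj), key=lambda g: bin(g).count("1"))
    for b in order:
        subs = [a for a in range(2**Kj) if a != b and (a & b) == a]
        if subs:
            p[b] = max(p[b], max(p[a] for a in subs))
    return p


def _init_link_params(model_label, Kj, probs):
    from .measurement import link_transform

    lo = float(np.clip(probs[0], 0.02, 0.9))
    hi = float(np.clip(probs[-1], lo + 0.01, 0.98))
    g = link_transform(model_label, np.array([lo, hi]))
    slope = max((g[1] - g[0]) / Kj, 1e-3)
    return np.concatenate([[g[0]], np.full(Kj, slope)])


def m_step_item(R, T, model_label, qvector, prev: ItemParameterSet = None, item_id="item"):
    """Maximize the expected complete-data log-likelihood for one item.

    Saturated G-DINA updates are the closed-form ratios R_g / T_g followed
    by a monotone projection; the additive models (A-CDM, LLM, RRUM) are
    maximized numerically on their link scale under monotonicity
    (non-negative attribute effects); DINA/DINO pool their two groups.
    Reduced classes with zero expected trials keep their previous value.
    """
    qvector = np.asarray(qvector, dtype=np.int8)
    Kj = int(qvector.sum())
    nred = 2**Kj
    R = np.asarray(R, dtype=float)
    T = np.asarray(T, dtype=float)
    empty = T <= 1e-10
    if empty.any() and prev is None:
        logger.warning("item %s: empty reduced classes %s", item_id, np.flatnonzero(empty))

    if model_label == "GDINA" or Kj == 1:
        p = np.where(empty, prev.probs if prev is not None else 0.5, R / np.clip(T, 1e-10, None))
        p = np.clip(p, _PCLIP, 1 - _PCLIP)
        p = _monotone_project(p, T, Kj)
        return ItemParameterSet(model_label=model_label, qvector=qvector, probs=p, item_id=item_id)

    X = additive_design(Kj)

    if model_label == "ACDM":
        x0 = (
            prev.link_params
            if prev is not None and prev.link_params is not None
            else _init_link_params("ACDM", Kj, R / np.clip(T, 1e-10, None))
        )
        def obj(d):
            p = np.clip(X @ d, _PCLIP, 1 - _PCLIP)
            return _neg_ecll(p, R, T)
        def grad(d):
            p = np.clip(X @ d, _PCLIP, 1 - _PCLIP)
            return X.T @ _dneg_dp(p, R, T)
        bounds = [(1e-4, 1 - 1e-4)] + [(0.0, 1 - 1e-4)] * Kj
        cons = [{"type": "ineq", "fun": lambda d: 1 - 1e-4 - d.sum(),
                 "jac": lambda d: -np.ones_like(d)}]
        res = minimize(obj, x0, jac=grad, bounds=bounds, constraints=cons,
                       method="SLSQP", options={"maxiter": 200, "ftol": 1e-12})
        d = res.x
        probs = np.clip(X @ d, 0.0, 1.0)
        return ItemParameterSet(model_label="ACDM", qvector=qvector, probs=probs,
                                link_params=d, item_id=item_id)

    if model_label == "LLM":
        x0 = (
            prev.link_params
            if prev is not None and prev.link_params is not None
            else _init_link_params("LLM", Kj, R / np.clip(T, 1e-10, None))
        )
        def obj(b):
            p = expit(X @ b)
            return _neg_ecll(p, R, T)
        def grad(b):
            p = expit(X @ b)
            return -X.T @ (R - T * p)
        bounds = [(-15.0, 15.0)] + [(0.0, 15.0)] * Kj
        res = minimize(obj, x0, jac=grad, bounds=bounds, method="L-BFGS-B",
                       options={"maxiter": 300, "ftol": 1e-13, "gtol": 1e-10})
        b = res.x
        return ItemParameterSet(model_label="LLM", qvector=qvector, probs=expit(X @ b),
                                link_params=b, item_id=item_id)

    if model_label == "RRUM":
        x0 = (
            prev.link_params
            if prev is not None and prev.link_params is not None
            else _init_link_params("RRUM", Kj, R / np.clip(T, 1e-10, None))
        )
        def obj(c):
            p = np.clip(np.exp(X @ c), _PCLIP, 1 - _PCLIP)
            return _neg_ecll(p, R, T)
        def grad(c):
            p = np.clip(np.exp(X @ c), _PCLIP, 1 - _PCLIP)
            return -X.T @ (R - (T - R) * p / (1 - p))
        bounds = [(-15.0, -1e-9)] + [(0.0, 15.0)] * Kj
        cons = [{"type": "ineq", "fun": lambda c: -1e-8 - c.sum(),
                 "jac": lambda c: -np.ones_like(c)}]
        res = minimize(obj, x0, jac=grad, bounds=bounds, constraints=cons,
                       method="SLSQP", options={"maxiter": 200, "ftol": 1e-12})
        c = res.x
        probs = np.clip(np.exp(X @ c), 0.0, 1.0)
        return ItemParameterSet(model_label="RRUM", qvector=qvector, probs=probs,
                                link_params=c, item_id=item_id)

    if model_label in ("DINA", "DINO"):
        if model_label == "DINA":
            hi_mask = np.zeros(nred, dtype=bool)
            hi_mask[-1] = True
        else:
            hi_mask = np.ones(nred, dtype=bool)
            hi_mask[0] = False
        lo_mask = ~hi_mask
        T_lo, T_hi = T[lo_mask].sum(), T[hi_mask].sum()
        p_lo = R[lo_mask].sum() / max(T_lo, 1e-10)
        p_hi = R[hi_mask].sum() / max(T_hi, 1e-10)
        if p_lo > p_hi:
            pooled = (T_lo * p_lo + T_hi * p_hi) / max(T_lo + T_hi, 1e-10)
            p_lo = p_hi = pooled
        probs = np.where(hi_mask, p_hi, p_lo)
        probs = np.clip(probs, _PCLIP, 1 - _PCLIP)
        return ItemParameterSet(model_label=model_label, qvector=qvector, probs=probs,
                                link_params=np.array([p_lo, p_hi]), item_id=item_id)

    raise InvalidValueError(f"unknown model label {model_label!r}")


def _refit_structural(weights, structural_spec, attribute_names):
    total = weights.sum()
    K = int(round(np.log2(weights.shape[0])))
    if structural_spec == "saturated" or structural_spec == K:
        probs = np.clip(weights, 1e-12, None)
        return LatentClassDistribution(probs=probs / probs.sum(), model_order=K,
                                       attribute_names=attribute_names)
    order = int(structural_spec)
    return fit_loglinear(weights, order, attribute_names)


def _initial_items(responses, Q, item_models, rng):
    X = responses.values
    items = []
    for j in range(Q.J):
        q = Q.qvector(j)
        Kj = int(q.sum())
        nred = 2**Kj
        mean = float(np.clip(X[:, j].mean(), 0.05, 0.95))
        frac = np.array([bin(g).count("1") / Kj for g in range(nred)])
        p = np.clip(mean + 0.2 * (frac - 0.5), 0.05, 0.95)
        if rng is not None:
            p = np.clip(p + rng.uniform(-0.02, 0.02, size=nred), 0.02, 0.98)
            p = _monotone_project(p, np.ones(nred), Kj)
        label = item_models[j]
        it = ItemParameterSet(model_label=label, qvector=q, probs=p, item_id=Q.item_ids[j])
        if label in ("ACDM", "LLM", "RRUM") and Kj > 1:
            it.link_params = _init_link_params(label, Kj, p)
        items.append(it)
    return items


def fit_cdm(
    responses: ResponseMatrix,
    Q: QMatrix,
    item_models=None,
    structural="saturated",
    tol: float = 1e-4,
    loglik_tol: float = 1e-7,
    max_iter: int = 2000,
    seed: int = None,
) -> FittedCDM:
    """Fit a G-DINA family model by EM over the 2^K latent classes.

    ``item_models`` is a per-item list of labels from
    {GDINA, ACDM, LLM, RRUM, DINA, DINO}; default all-GDINA (saturated).
    ``structural`` is "saturated" or an integer log-linear order (1 =
    independence, 2 = homogeneous association).  Convergence requires both
    the maximum absolute parameter change below ``tol`` and the
    log-likelihood change below ``loglik_tol``.
    """
    check_alignment(responses, Q)
    if isinstance(item_models, str):
        item_models = [item_models] * Q.J
    if item_models is None:
        item_models = ["GDINA"] * Q.J
    if len(item_models) != Q.J:
        raise InvalidQMatrixError("item_models length must equal the number of items")
    rng = np.random.default_rng(seed) if seed is not None else None
    K = Q.K
    C = 2**K
    N = responses.N

    items = _initial_items(responses, Q, item_models, rng)
    for j, it in enumerate(items):
        it._col = j
    structural_dist = LatentClassDistribution(
        probs=np.full(C, 1.0 / C), model_order=K if structural == "saturated" else int(structural),
        attribute_names=Q.attribute_names,
    )

    trace = []
    prev_ll = -np.inf
    converged = False
    it_count = 0
    for it_count in range(1, max_iter + 1):
        post, ll = e_step(responses, items, structural_dist.probs)
        trace.append(ll)
        weights = post.sum(axis=0)

        max_delta = 0.0
        new_items = []
        for j, item in enumerate(items):
            R, T = expected_item_counts(post, responses, item)
            new = m_step_item(R, T, item.model_label, item.qvector, prev=item,
                              item_id=item.item_id)
            new._col = j
            max_delta = max(max_delta, float(np.max(np.abs(new.probs - item.probs))))
            new_items.append(new)
        new_structural = _refit_structural(weights, structural, Q.attribute_names)
        max_delta = max(
            max_delta, float(np.max(np.abs(new_structural.probs - structural_dist.probs)))
        )
        items = new_items
        structural_dist = new_structural

        if max_delta < tol and abs(ll - prev_ll) < loglik_tol and it_count > 1:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    post, ll = e_step(responses, items, structural_dist.probs)
    trace.append(ll)

    npar = sum(parameter_count(it.model_label, it.qvector) for it in items)
    if structural == "saturated":
        npar += C - 1
    else:
        npar += structural_param_count(K, int(structural))
    aic, bic = information_criteria(ll, npar, N)

    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations (last max delta above tol)",
            RuntimeWarning,
        )
    return FittedCDM(
        items=items,
        structural=structural_dist,
        posteriors=post,
        loglik=ll,
        loglik_trace=np.asarray(trace),
        npar=npar,
        n_iterations=it_count,
        converged=converged,
        fit={"AIC": aic, "BIC": bic},
        N=N,
        Q=Q,
    )


def information_criteria(loglik: float, npar: int, N: int):
    """AIC = -2 loglik + 2 npar; BIC = -2 loglik + npar ln(N)."""
    if npar < 1:
        raise InvalidValueError("npar must be >= 1")
    aic = -2.0 * loglik + 2.0 * npar
    bic = -2.0 * loglik + npar * np.log(N)
    return float(aic), float(bic)


@dataclass
class StandardErrors:
    """OPG covariance of all free parameters with block bookkeeping."""

    cov: np.ndarray
    labels: list
    item_slices: list
    structural_slice: slice
    singular: bool

    def item_cov(self, j: int) -> np.ndarray:
        sl = self.item_slices[j]
        return self.cov[sl, sl]

    def item_ses(self, j: int) -> np.ndarray:
        sl = self.item_slices[j]
        return np.sqrt(np.clip(np.diag(self.cov)[sl], 0, None))

    def structural_ses(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov)[self.structural_slice], 0, None))


def _item_prob_jacobian(item: ItemParameterSet) -> np.ndarray:
    """d probs / d free-params for one item (2^Kj x n_par)."""
    Kj = item.Kj
    nred = 2**Kj
    label = item.model_label
    if label == "GDINA" or Kj == 1:
        return np.eye(nred)
    X = additive_design(Kj)
    p = np.clip(item.probs, _PCLIP, 1 - _PCLIP)
    if label == "ACDM":
        return X
    if label == "LLM":
        return (p * (1 - p))[:, None] * X
    if label == "RRUM":
        return p[:, None] * X
    if label in ("DINA", "DINO"):
        J = np.zeros((nred, 2))
        if label == "DINA":
            J[:-1, 0] = 1.0
            J[-1, 1] = 1.0
        else:
            J[0, 0] = 1.0
            J[1:, 1] = 1.0
        return J
    raise InvalidValueError(label)


def score_matrix(fitted: FittedCDM, responses: ResponseMatrix):
    """Per-respondent scores of the observed-data log-likelihood.

    Columns: item blocks (probability scale for saturated items, link
    scale for additive models, two group probabilities for DINA/DINO),
    then the structural block (free class probabilities against the
    all-zero baseline for a saturated structural model, or the non-
    intercept lambda coefficients for a log-linear one).
    """
    X = responses.values.astype(float)
    N = responses.N
    K = fitted.K
    prior = np.clip(fitted.prior, 1e-12, None)
    post, _ = e_step(responses, fitted.items, prior)

    blocks = []
    labels = []
    item_slices = []
    pos = 0
    for j, item in enumerate(fitted.items):
        ridx = reduced_index_map(item.qvector, K)
        nred = 2**item.Kj
        onehot = np.zeros((2**K, nred))
        onehot[np.arange(2**K), ridx] = 1.0
        postG = post @ onehot  # (N, nred)
        p = np.clip(item.probs, _PCLIP, 1 - _PCLIP)
        x = X[:, j][:, None]
        s_prob = postG * (x - p[None, :]) / (p * (1 - p))[None, :]
        Jac = _item_prob_jacobian(item)
        s = s_prob @ Jac
        blocks.append(s)
        n_par = s.shape[1]
        item_slices.append(slice(pos, pos + n_par))
        if item.model_label == "GDINA" or item.Kj == 1:
            labels += [f"{item.item_id}:p{g}" for g in range(n_par)]
        else:
            labels += [f"{item.item_id}:{item.model_label}:b{g}" for g in range(n_par)]
        pos += n_par

    if fitted.structural.model_order == K:
        s_struct = post[:, 1:] / prior[None, 1:] - (post[:, [0]] / prior[0])
        labels += [f"struct:p{c}" for c in range(1, 2**K)]
    else:
        from .structural import loglinear_design

        D, dlabels = loglinear_design(K, fitted.structural.model_order,
                                      fitted.Q.attribute_names)
        Dm = D[:, 1:]
        s_struct = post @ Dm - (prior @ Dm)[None, :]
        labels += [f"struct:{lab}" for lab in dlabels[1:]]
    struct_slice = slice(pos, pos + s_struct.shape[1])
    blocks.append(s_struct)
    S = np.hstack(blocks)
    return S, labels, item_slices, struct_slice


def standard_errors(fitted: FittedCDM, responses: ResponseMatrix) -> StandardErrors:
    """OPG standard errors for all item and structural parameters.

    The covariance is the inverse of the empirical cross-product of the
    per-respondent scores of the incomplete-data log-likelihood; a
    pseudo-inverse is used (with a warning) when the information matrix is
    singular.
    """
    S, labels, item_slices, struct_slice = score_matrix(fitted, responses)
    info = S.T @ S
    singular = False
    try:
        cov = np.linalg.inv(info)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("OPG information singular; using pseudo-inverse", RuntimeWarning)
        cov = np.linalg.pinv(info)
        singular = True
    return StandardErrors(cov=cov, labels=labels, item_slices=item_slices,
                          structural_slice=struct_slice, singular=singular)
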