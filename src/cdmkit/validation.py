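"""Empirical Q-matrix validation and model comparison.

Q-matrix validation follows the G-DINA discrimination index (GDI): for a
candidate q-vector, collapse the latent classes into its reduced classes
and measure the weighted variance of the item endorsement probability
across them.  PVAF is the candidate's GDI relative to the GDI of the full
(all-attribute) q-vector; the mesa plot traces the best PVAF attainable
with 1, 2, ..., K attributes and flattens at the correct specification.

Model comparison offers the item-level Wald test of a reduced model
against the saturated G-DINA item block, the likelihood-ratio test for
nested full fits, and the limited-information M2 / RMSEA2 absolute fit
statistic built from univariate and bivariate response margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import linalg as sla
from scipy.stats import chi2

from .data import InvalidValueError, profile_matrix, reduced_index_map
from .estimation import FittedCDM, StandardErrors, class_prob_matrix, e_step, standard_errors
from .measurement import full_design, link_transform, parameter_count


class UndefinedPVAFError(InvalidValueError):
    pass


def class_success_probs(fitted: FittedCDM, responses, col: int) -> np.ndarray:
    """Nonparametric endorsement probability of one item in each full latent class.

    Posterior-weighted success rates, i.e. the saturated estimate the item
    would receive under an all-attribute q-vector with the rest of the
    model held fixed.  Classes with negligible posterior mass fall back to
    the overall item mean.
    """
    X = responses.values
    post = fitted.posteriors
    mass = post.sum(axis=0)
    succ = X[:, col].astype(float) @ post
    p = np.where(mass > 1e-8, succ / np.clip(mass, 1e-12, None), X[:, col].mean())
    return np.clip(p, 0.0, 1.0)


def gdi(candidate_qvector, class_success, class_weights) -> float:
    """G-DINA discrimination index of a candidate q-vector.

    Collapses the 2^K classes by the candidate's reduced profiles and
    returns the weighted variance of the collapsed success probabilities:
    sigma^2 = sum_g w_g (P_g - Pbar)^2.
    """
    w = np.asarray(class_weights, dtype=float)
    w = w / w.sum()
    p = np.asarray(class_success, dtype=float)
    K = int(round(np.log2(w.shape[0])))
    ridx = reduced_index_map(candidate_qvector, K)
    nred = int(ridx.max()) + 1
    wg = np.bincount(ridx, weights=w, minlength=nred)
    pg = np.bincount(ridx, weights=w * p, minlength=nred)
    pg = np.where(wg > 0, pg / np.clip(wg, 1e-300, None), 0.0)
    pbar = float(wg @ pg)
    return float(wg @ (pg - pbar) ** 2)


def pvaf(item_id, candidate_qvector, fitted: FittedCDM, responses) -> float:
    """Proportion of variance accounted for: GDI(candidate) / GDI(full q-vector)."""
    col = fitted.Q.item_ids.index(item_id) if isinstance(item_id, str) else int(item_id)
    p = class_success_probs(fitted, responses, col)
    w = fitted.prior
    full = gdi(np.ones(fitted.K, dtype=int), p, w)
    if full <= 1e-14:
        raise UndefinedPVAFError(
            f"item {item_id}: flat success probabilities, maximum GDI is zero"
        )
    return gdi(candidate_qvector, p, w) / full


@dataclass
class MesaData:
    """Best q-vector per attribute count for one item, for mesa plotting."""

    item_id: str
    best_qvectors: list
    best_pvafs: list
    original_qvector: np.ndarray
    original_pvaf: float
    epsilon: float


def _qvectors_of_size(K: int, m: int):
    for S in combinations(range(K), m):
        q = np.zeros(K, dtype=int)
        q[list(S)] = 1
        yield q


def mesa_data(item_id, fitted: FittedCDM, responses, epsilon: float = 0.95) -> MesaData:
    """Exhaustive best-PVAF-per-size search for one item (K <= 12)."""
    K = fitted.K
    if K > 12:
        raise InvalidValueError("exhaustive q-vector search capped at K <= 12")
    col = fitted.Q.item_ids.index(item_id) if isinstance(item_id, str) else int(item_id)
    item_id = fitted.Q.item_ids[col]
    p = class_success_probs(fitted, responses, col)
    w = fitted.prior
    full = gdi(np.ones(K, dtype=int), p, w)
    if full <= 1e-14:
        raise UndefinedPVAFError(f"item {item_id}: maximum GDI is zero")
    best_q, best_v = [], []
    for m in range(1, K + 1):
        cands = [(q, gdi(q, p, w) / full) for q in _qvectors_of_size(K, m)]
        # max PVAF; ties resolved lexicographically (first in subset order)
        vmax = max(v for _, v in cands)
        q_sel = next(q for q, v in cands if v >= vmax - 1e-12)
        best_q.append(q_sel)
        best_v.append(vmax)
    orig = fitted.Q.qvector(col)
    orig_v = gdi(orig, p, w) / full
    return MesaData(item_id=item_id, best_qvectors=best_q, best_pvafs=best_v,
                    original_qvector=np.asarray(orig), original_pvaf=float(orig_v),
                    epsilon=epsilon)


def suggest_qvector(item_id, fitted: FittedCDM, responses, epsilon: float = 0.95):
    """Simplest q-vector whose PVAF reaches ``epsilon``.

    Smallest attribute count m whose best q-vector reaches the cutoff;
    ties at equal m go to the higher PVAF, then to lexicographic order.
    Suggestions are advisory — they are never applied automatically.
    """
    if not (0 < epsilon <= 1):
        raise InvalidValueError("epsilon must be in (0, 1]")
    md = mesa_data(item_id, fitted, responses, epsilon)
    for q, v in zip(md.best_qvectors, md.best_pvafs):
        if v >= epsilon - 1e-12:
            return q, float(v)
    return md.best_qvectors[-1], float(md.best_pvafs[-1])


@dataclass
class WaldResult:
    item_id: str
    selected: str
    tests: dict  # label -> (W, df, p)
    note: str = ""


def _constraint_matrix(model_label: str, Kj: int):
    """Constraint rows R and link such that R @ link(p_saturated) = 0 under the model."""
    nred = 2**Kj
    A, subsets = full_design(Kj)
    Ainv = np.linalg.inv(A)
    inter_rows = [i for i, S in enumerate(subsets) if len(S) >= 2]
    if model_label in ("ACDM", "LLM", "RRUM"):
        link = {"ACDM": "GDINA", "LLM": "LLM", "RRUM": "RRUM"}[model_label]
        return Ainv[inter_rows], link
    if model_label == "DINA":
        rows = []
        for g in range(1, nred - 1):
            r = np.zeros(nred)
            r[g] = 1.0
            r[0] = -1.0
            rows.append(r)
        return np.array(rows), "GDINA"
    if model_label == "DINO":
        rows = []
        for g in range(2, nred):
            r = np.zeros(nred)
            r[g] = 1.0
            r[1] = -1.0
            rows.append(r)
        return np.array(rows), "GDINA"
    raise InvalidValueError(f"no Wald constraints for {model_label!r}")


def wald_select_item(
    fitted: FittedCDM,
    responses,
    item_id,
    candidates=("DINA", "DINO", "ACDM", "LLM", "RRUM"),
    alpha: float = 0.05,
    ses: StandardErrors = None,
) -> WaldResult:
    """Item-level Wald comparison of reduced models against the saturated item.

    For each candidate the additivity (or two-group) constraints are
    expressed on the candidate's link scale; W = (R g(p))' [R V_g R']^{-1}
    (R g(p)) with V_g the delta-method covariance of the transformed
    saturated item probabilities.  Among candidates with p > alpha the one
    with the fewest parameters wins; remaining ties go to the largest p.
    Single-attribute items are returned untested (all models coincide).
    """
    col = fitted.Q.item_ids.index(item_id) if isinstance(item_id, str) else int(item_id)
    item = fitted.items[col]
    item_id = fitted.Q.item_ids[col]
    if item.model_label != "GDINA":
        raise InvalidValueError("Wald selection requires a saturated (G-DINA) fitted item")
    if item.Kj < 2:
        return WaldResult(item_id=item_id, selected="GDINA", tests={},
                          note="single-attribute item: saturated and reduced models coincide")
    if ses is None:
        ses = standard_errors(fitted, responses)
    V = ses.item_cov(col)
    p = np.clip(item.probs, 1e-6, 1 - 1e-6)

    tests = {}
    for label in candidates:
        R, link = _constraint_matrix(label, item.Kj)
        if link == "GDINA":
            theta = p.copy()
            Jd = np.ones_like(p)
        elif link == "LLM":
            theta = link_transform("LLM", p)
            Jd = 1.0 / (p * (1 - p))
        else:  # RRUM / log
            theta = link_transform("RRUM", p)
            Jd = 1.0 / p
        Vg = (Jd[:, None] * V) * Jd[None, :]
        RV = R @ Vg @ R.T
        r = R @ theta
        try:
            W = float(r @ np.linalg.solve(RV, r))
        except np.linalg.LinAlgError:
            warnings.warn(f"item {item_id}: singular constrained covariance for {label}; skipped")
            continue
        if W < 0:
            continue
        df = R.shape[0]
        tests[label] = (W, df, float(chi2.sf(W, df)))

    acceptable = [(lab, *tests[lab]) for lab in tests if tests[lab][2] > alpha]
    if not acceptable:
        selected = "GDINA"
    else:
        acceptable.sort(key=lambda t: (parameter_count(t[0], item.qvector), -t[3]))
        selected = acceptable[0][0]
    return WaldResult(item_id=item_id, selected=selected, tests=tests)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def lrt(fit_restricted: FittedCDM, fit_general: FittedCDM) -> LRTResult:
    """Likelihood-ratio test of a nested restricted model against a general one."""
    stat = 2.0 * (fit_general.loglik - fit_restricted.loglik)
    if stat < -1e-4:
        raise InvalidValueError(
            f"negative LRT statistic ({stat:.4g}): models not nested or not converged"
        )
    stat = max(stat, 0.0)
    df = fit_general.npar - fit_restricted.npar
    if df < 0:
        raise InvalidValueError("restricted model has more parameters than the general model")
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return LRTResult(statistic=float(stat), df=int(df), p_value=p)


@dataclass
class M2Result:
    m2: float
    df: int
    p_value: float
    rmsea2: float
    n_margins: int


def _margin_list(J: int):
    margins = [(j,) for j in range(J)]
    margins += [(j, k) for j in range(J) for k in range(j + 1, J)]
    return margins


def _margin_products(P: np.ndarray, margins):
    """M[a, c] = product over items in margin a of P_jc."""
    M = np.empty((len(margins), P.shape[1]))
    for a, items in enumerate(margins):
        M[a] = P[list(items)].prod(axis=0)
    return M


def _margin_covariance(P, prior, margins, M, pi):
    """Model-implied covariance of the univariate/bivariate margin indicators."""
    J, C = P.shape
    wp = prior[None, :] * M
    E = wp @ M.T  # correct for disjoint margins; fix overlaps below
    n_uni = J
    bi_index = {}
    for a, items in enumerate(margins):
        if len(items) == 2:
            bi_index[items] = a
    # univariate diagonals and uni-bi overlaps
    for j in range(J):
        E[j, j] = pi[j]
        for k in range(J):
            if k == j:
                continue
            b = bi_index[(min(j, k), max(j, k))]
            E[j, b] = E[b, j] = pi[b]
    # bivariate pairs sharing exactly one item
    for j in range(J):
        rows = []
        partners = []
        for k in range(J):
            if k == j:
                continue
            rows.append(bi_index[(min(j, k), max(j, k))])
            partners.append(k)
        rows = np.array(rows)
        A = P[partners]  # (J-1, C)
        block = (A * (prior * P[j])[None, :]) @ A.T
        E[np.ix_(rows, rows)] = block
    # bivariate diagonals
    for items, a in bi_index.items():
        E[a, a] = pi[a]
    return E - np.outer(pi, pi)


def _margin_jacobian(fitted: FittedCDM, P, prior, margins, M):
    """d pi_margin / d theta for item and structural free parameters."""
    from .estimation import _item_prob_jacobian
    from .structural import loglinear_design

    K = fitted.K
    C = 2**K
    cols = []
    for j, item in enumerate(fitted.items):
        ridx = reduced_index_map(item.qvector, K)
        nred = 2**item.Kj
        onehot = np.zeros((C, nred))
        onehot[np.arange(C), ridx] = 1.0
        # d pi_a / d p_jg = sum_{c in g} prior_c * prod_{l in a, l != j} P_lc  (a containing j)
        dcols = np.zeros((len(margins), nred))
        for a, its in enumerate(margins):
            if j not in its:
                continue
            others = [l for l in its if l != j]
            prod_others = P[others].prod(axis=0) if others else np.ones(C)
            dcols[a] = (prior * prod_others) @ onehot
        cols.append(dcols @ _item_prob_jacobian(item))
    # structural block
    if fitted.structural.model_order == K:
        dprior = np.zeros((C, C - 1))
        dprior[1:, :] = np.eye(C - 1)
        dprior[0, :] = -1.0
    else:
        D, _ = loglinear_design(K, fitted.structural.model_order, fitted.Q.attribute_names)
        Dm = D[:, 1:]
        dprior = prior[:, None] * (Dm - (prior @ Dm)[None, :])
    cols.append(M @ dprior)
    return np.hstack(cols)


def rmsea2(fitted: FittedCDM, responses) -> M2Result:
    """Limited-information absolute fit from univariate and bivariate margins.

    The M2 statistic is the weighted quadratic form in the residuals of
    the J univariate and J(J-1)/2 bivariate endorsement margins, with the
    optimal weight matrix evaluated at the fitted parameters; RMSEA2 =
    sqrt(max(M2 - df, 0) / (df N)).  Values below .05 are conventionally
    read as adequate absolute fit.
    """
    X = responses.values.astype(float)
    N, J = X.shape
    K = fitted.K
    P = np.clip(class_prob_matrix(fitted.items, K), 1e-6, 1 - 1e-6)
    prior = np.clip(fitted.prior, 1e-12, None)
    prior = prior / prior.sum()
    margins = _margin_list(J)
    M = _margin_products(P, margins)
    pi = M @ prior

    # observed margins
    s_uni = X.mean(axis=0)
    XtX = (X.T @ X) / N
    s = np.concatenate([s_uni, [XtX[j, k] for j, k in margins[J:]]])

    keep = np.flatnonzero(pi * (1 - pi) > 1e-8)
    if keep.size < len(margins):
        warnings.warn(
            f"dropping {len(margins) - keep.size} degenerate margins from M2", RuntimeWarning
        )
    margins_k = [margins[a] for a in keep]
    Mk = M[keep]
    pik = pi[keep]
    r = s[keep] - pik

    Xi = _margin_covariance(P, prior, margins, M, pi)[np.ix_(keep, keep)]
    Delta = _margin_jacobian(fitted, P, prior, margins, M)[keep]

    jitter = 1e-12 * np.eye(Xi.shape[0])
    try:
        cF = sla.cho_factor(Xi + jitter)
        XiInv_r = sla.cho_solve(cF, r)
        XiInv_D = sla.cho_solve(cF, Delta)
    except np.linalg.LinAlgError:
        warnings.warn("margin covariance not positive definite; using pseudo-inverse",
                      RuntimeWarning)
        XiP = np.linalg.pinv(Xi)
        XiInv_r = XiP @ r
        XiInv_D = XiP @ Delta
    G = Delta.T @ XiInv_D
    h = Delta.T @ XiInv_r
    Gp = np.linalg.pinv(G, rcond=1e-10)
    rank = int(np.linalg.matrix_rank(G, tol=1e-10))
    m2 = float(N * (r @ XiInv_r - h @ Gp @ h))
    m2 = max(m2, 0.0)
    df = len(margins_k) - rank
    if df <= 0:
        raise InvalidValueError("no residual degrees of freedom for M2")
    val = float(np.sqrt(max(m2 - df, 0.0) / (df * N)))
    return M2Result(m2=m2, df=df, p_value=float(chi2.sf(m2, df)), rmsea2=val,
                    n_margins=len(margins_k))
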