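"""Respondent classification, accuracy indices, and prior-sensitivity analysis.

Classification attaches to each respondent the posterior distribution
over the 2^K attribute profiles, the MAP profile, and the EAP marginal
probability of each attribute.  Accuracy indices summarize how sharply
the posteriors identify respondents: the test-level index is the mean
posterior probability of the MAP profile, the attribute-level index the
mean of max(p, 1-p) over the marginal attribute posteriors.

The lens analysis quantifies how much the joint prevalence of the
attributes sharpens per-attribute estimation: posteriors are recomputed
under the independence prior (same attribute marginals, no association)
with the item parameters held fixed, and the per-attribute root mean
squared difference (RMSD) between the two posterior probability columns
summarizes the information contributed by the other attributes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import InvalidDimensionError, QMatrix, ResponseMatrix, profile_matrix
from .estimation import e_step
from .structural import LatentClassDistribution, independence_prior


@dataclass
class ClassificationResult:
    profile_posteriors: np.ndarray  # (N, 2^K)
    attribute_posteriors: np.ndarray  # (N, K)
    map_profiles: np.ndarray  # (N, K) 0/1
    map_indices: np.ndarray  # (N,)
    eap_attributes: np.ndarray  # alias of attribute_posteriors
    test_accuracy: float
    attribute_accuracy: np.ndarray  # (K,)
    prevalence_estimates: np.ndarray  # (2^K,) percentages, posterior-weighted
    prior_percent: np.ndarray  # (2^K,) percentages, the prior itself
    n_ties: int


def _map_assign(post: np.ndarray, K: int):
    """MAP profile per respondent; ties go to fewer attributes, then lexicographic."""
    C = post.shape[1]
    counts = np.array([bin(c).count("1") for c in range(C)])
    # order classes by (attribute count, canonical index); first argmax in
    # that order wins ties at equal posterior mass
    order = np.lexsort((np.arange(C), counts))
    post_ord = post[:, order]
    best = np.argmax(post_ord > post_ord.max(axis=1, keepdims=True) - 1e-12, axis=1)
    idx = order[best]
    ties = int((np.isclose(post, post.max(axis=1, keepdims=True), atol=1e-12).sum(axis=1) > 1).sum())
    return idx, ties


def classify(responses: ResponseMatrix, items, prior) -> ClassificationResult:
    """Posterior classification of respondents under a given profile prior."""
    if isinstance(prior, LatentClassDistribution):
        prior_vec = prior.probs
    else:
        prior_vec = np.asarray(prior, dtype=float)
    post, _ = e_step(responses, items, prior_vec)
    K = items[0].K
    prof = profile_matrix(K).astype(float)
    attr_post = post @ prof
    idx, ties = _map_assign(post, K)
    map_prof = profile_matrix(K)[idx]
    test_acc = float(post[np.arange(post.shape[0]), idx].mean())
    attr_acc = np.maximum(attr_post, 1 - attr_post).mean(axis=0)
    prevalence = post.mean(axis=0) * 100.0
    return ClassificationResult(
        profile_posteriors=post,
        attribute_posteriors=attr_post,
        map_profiles=map_prof,
        map_indices=idx,
        eap_attributes=attr_post,
        test_accuracy=test_acc,
        attribute_accuracy=attr_acc,
        prevalence_estimates=prevalence,
        prior_percent=prior_vec * 100.0,
        n_ties=ties,
    )


def accuracy_indices(result: ClassificationResult):
    """(test-level, attribute-level) classification accuracy indices."""
    return result.test_accuracy, result.attribute_accuracy


def rmsd_attribute(p_in_column, p_pr_column) -> float:
    """Root mean squared difference between two posterior probability columns."""
    a = np.asarray(p_in_column, dtype=float)
    b = np.asarray(p_pr_column, dtype=float)
    if a.shape != b.shape:
        raise InvalidDimensionError("posterior columns have different lengths")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class LensResult:
    p_in: np.ndarray  # (N, K) attribute posteriors under the independence prior
    p_pr: np.ndarray  # (N, K) under the prevalence prior
    rmsd: np.ndarray  # (K,)
    endorsed_counts: np.ndarray  # (N, K) per-attribute sum scores
    attribute_names: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        N, K = self.p_in.shape
        for k, name in enumerate(self.attribute_names):
            rows.append(pd.DataFrame({
                "respondent": np.arange(N),
                "attribute": name,
                "p_independence": self.p_in[:, k],
                "p_prevalence": self.p_pr[:, k],
                "sum_score": self.endorsed_counts[:, k],
            }))
        return pd.concat(rows, ignore_index=True)


def lens_analysis(responses: ResponseMatrix, items, prevalence_prior, Q: QMatrix) -> LensResult:
    """Posterior attribute probabilities under prevalence vs independence priors.

    Item parameters are held fixed; only the prior over the profiles
    changes.  The independence prior is the product distribution with the
    prevalence prior's attribute marginals, so any RMSD difference is due
    purely to the between-attribute associations in the joint prior.
    """
    if not isinstance(prevalence_prior, LatentClassDistribution):
        prevalence_prior = LatentClassDistribution(
            probs=np.asarray(prevalence_prior, dtype=float),
            attribute_names=Q.attribute_names,
        )
    indep = independence_prior(prevalence_prior)
    res_pr = classify(responses, items, prevalence_prior)
    res_in = classify(responses, items, indep)
    p_pr = res_pr.attribute_posteriors
    p_in = res_in.attribute_posteriors
    rmsd = np.array([rmsd_attribute(p_in[:, k], p_pr[:, k]) for k in range(Q.K)])
    endorsed = responses.values.astype(int) @ Q.entries.astype(int)
    return LensResult(p_in=p_in, p_pr=p_pr, rmsd=rmsd, endorsed_counts=endorsed,
                      attribute_names=Q.attribute_names)


def sumscore_scatter(responses: ResponseMatrix, Q: QMatrix, eap_attributes: np.ndarray):
    """Per-attribute sum scores vs EAP probabilities, plus sum-score correlations.

    Returns ``(table, correlations)``: a long table with one row per
    respondent-attribute pair and the K x K Pearson correlation matrix of
    the attribute sum scores over respondents.
    """
    scores = responses.values.astype(int) @ Q.entries.astype(int)
    N, K = scores.shape
    rows = []
    for k in range(K):
        rows.append(pd.DataFrame({
            "respondent": responses.respondent_ids,
            "attribute": Q.attribute_names[k],
            "sum_score": scores[:, k],
            "eap_probability": eap_attributes[:, k],
        }))
    table = pd.concat(rows, ignore_index=True)
    corr = pd.DataFrame(scores, columns=Q.attribute_names).corr()
    return table, corr
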