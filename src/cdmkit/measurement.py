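"""Item response functions for the G-DINA model family.

Each item depends on its required attributes only, so the 2^K latent
profiles collapse to 2^{K_j} reduced classes (K_j = number of required
attributes).  The saturated G-DINA model assigns a free endorsement
probability to every reduced class; reduced models constrain those
probabilities to be additive on a link scale:

* A-CDM  — identity link (probabilities add),
* LLM    — logit link,
* RRUM   — log link,
* DINA   — conjunctive two-parameter model (all-or-nothing),
* DINO   — disjunctive two-parameter model (any attribute suffices).

Reduced classes are indexed canonically: the first required attribute is
the most significant bit, so for a two-attribute item the order is
(0 0), (0 1), (1 0), (1 1), with (0 1) meaning only the SECOND required
attribute is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import expit, logit

from .data import (
    InvalidDimensionError,
    InvalidValueError,
    profile_matrix,
    reduced_index_map,
)

MODEL_LABELS = ("GDINA", "ACDM", "LLM", "RRUM", "DINA", "DINO")

_PCLIP = 1e-10


@dataclass
class ItemParameterSet:
    """Endorsement probabilities of one item over its reduced classes.

    ``probs`` always holds the probability scale values (length 2^{K_j});
    for reduced models ``link_params`` carries the additive coefficients on
    the model's link scale (intercept first, then one slope per required
    attribute).  Standard errors, when available, align with ``probs`` for
    G-DINA/DINA/DINO and with ``link_params`` otherwise.
    """

    model_label: str
    qvector: np.ndarray
    probs: np.ndarray
    item_id: str = "item"
    link_params: np.ndarray = None
    ses: np.ndarray = None

    def __post_init__(self):
        if self.model_label not in MODEL_LABELS:
            raise InvalidValueError(f"unknown model label {self.model_label!r}")
        self.qvector = np.asarray(self.qvector, dtype=np.int8)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[0] != 2**self.Kj:
            raise InvalidDimensionError(
                f"expected {2 ** self.Kj} reduced-class probabilities, got {self.probs.shape[0]}"
            )
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise InvalidValueError("endorsement probabilities must lie in [0, 1]")
        self.probs = np.clip(self.probs, 0.0, 1.0)

    @property
    def K(self) -> int:
        return self.qvector.shape[0]

    @property
    def Kj(self) -> int:
        return int(self.qvector.sum())


def reduced_design(Kj: int) -> np.ndarray:
    """(2^Kj, Kj) matrix of reduced profiles in canonical order."""
    return profile_matrix(Kj)


def additive_design(Kj: int) -> np.ndarray:
    """Main-effects design over reduced classes: intercept + one 0/1 column per attribute."""
    prof = reduced_design(Kj)
    return np.column_stack([np.ones(2**Kj), prof])


def full_design(Kj: int):
    """Saturated 0/1 design over reduced classes with all interactions.

    Columns are indexed by attribute subsets ordered by (size, attribute
    order); column for subset S at reduced class g is the product of the
    bits of g over S.  Returns ``(design, subsets)``.
    """
    prof = reduced_design(Kj)
    subsets = [()]
    for m in range(1, Kj + 1):
        subsets.extend(combinations(range(Kj), m))
    cols = [np.ones(2**Kj)]
    for S in subsets[1:]:
        cols.append(prof[:, list(S)].prod(axis=1))
    return np.column_stack(cols), subsets


def probs_from_link(model_label: str, Kj: int, params: np.ndarray) -> np.ndarray:
    """Reduced-class probabilities implied by additive link-scale coefficients."""
    X = additive_design(Kj)
    eta = X @ np.asarray(params, dtype=float)
    if model_label == "ACDM":
        p = eta
    elif model_label == "LLM":
        p = expit(eta)
    elif model_label == "RRUM":
        p = np.exp(eta)
    else:
        raise InvalidValueError(f"{model_label} has no additive link parameterization")
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        raise InvalidValueError(f"{model_label} parameters imply probabilities outside [0, 1]")
    return np.clip(p, 0.0, 1.0)


def link_transform(model_label: str, probs: np.ndarray) -> np.ndarray:
    """Map probabilities to the model's link scale (identity, logit, or log)."""
    p = np.clip(probs, _PCLIP, 1 - _PCLIP)
    if model_label in ("GDINA", "ACDM", "DINA", "DINO"):
        return np.asarray(probs, dtype=float)
    if model_label == "LLM":
        return logit(p)
    if model_label == "RRUM":
        return np.log(p)
    raise InvalidValueError(f"unknown model label {model_label!r}")


def item_prob(item: ItemParameterSet, profile) -> float:
    """Endorsement probability of ``item`` for a full attribute profile.

    The profile enters only through its reduced profile over the item's
    required attributes.
    """
    bits = np.asarray(tuple(profile), dtype=int)
    if bits.shape[0] != item.K:
        raise InvalidDimensionError("profile length does not match q-vector length")
    req = np.flatnonzero(item.qvector == 1)
    sub = bits[req]
    weights = 2 ** np.arange(len(req) - 1, -1, -1)
    return float(item.probs[int((sub * weights).sum())])


def item_prob_by_class(item: ItemParameterSet, K: int = None) -> np.ndarray:
    """Endorsement probabilities over all 2^K full profiles (canonical order)."""
    K = item.K if K is None else K
    return item.probs[reduced_index_map(item.qvector, K)]


def parameter_count(model_label: str, qvector) -> int:
    """Number of free item parameters: 2^{K_j} saturated, K_j+1 additive, 2 DINA/DINO."""
    if model_label not in MODEL_LABELS:
        raise InvalidValueError(f"unknown model label {model_label!r}")
    Kj = int(np.asarray(qvector).sum())
    if model_label == "GDINA":
        return 2**Kj
    if model_label in ("ACDM", "LLM", "RRUM"):
        return Kj + 1
    return 2


def discrimination(item: ItemParameterSet) -> float:
    """P(endorse | all required attributes) - P(endorse | none of them).

    The index lies in [-1, 1] and is non-negative under monotonicity.
    """
    return float(item.probs[-1] - item.probs[0])


def monotone_pairs(Kj: int):
    """Comparable reduced-class pairs (a, b) with a a strict subset of b."""
    pairs = []
    for a in range(2**Kj):
        for b in range(2**Kj):
            if a != b and (a & b) == a:
                pairs.append((a, b))
    return pairs


def check_monotonicity(item: ItemParameterSet, tol: float = 1e-12):
    """Check that adding a required attribute never lowers the endorsement probability.

    Weak inequalities: ties are allowed.  Returns ``(ok, violations)`` where
    violations are reduced-class index pairs (subset, superset).
    """
    viol = [
        (a, b)
        for a, b in monotone_pairs(item.Kj)
        if item.probs[a] > item.probs[b] + tol
    ]
    return len(viol) == 0, viol
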