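"""Core data structures and attribute-profile bookkeeping.

A diagnostic assessment links J binary items to K binary latent attributes
through a Q-matrix.  A respondent's latent state is an attribute profile,
one of the 2^K binary vectors over the attributes.  The canonical profile
order used everywhere in the package is binary counting with attribute 1 as
the most significant bit: (0,...,0), (0,...,0,1), ..., (1,...,1).  Any
ordering by number of attributes is a presentation option only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class CDMError(ValueError):
    """Base class for domain errors raised by cdmkit."""


class InvalidDimensionError(CDMError):
    pass


class InvalidValueError(CDMError):
    pass


class EmptyDataError(CDMError):
    pass


class InvalidQVectorError(CDMError):
    pass


class InvalidQMatrixError(CDMError):
    pass


class AlignmentError(CDMError):
    pass


@dataclass(frozen=True)
class AttributeProfile:
    """A length-K binary attribute pattern with its canonical index."""

    bits: tuple
    index: int

    @property
    def K(self) -> int:
        return len(self.bits)

    def __iter__(self):
        return iter(self.bits)


def profile_matrix(K: int) -> np.ndarray:
    """All 2^K attribute profiles as a (2^K, K) 0/1 array in canonical order.

    Attribute 1 (column 0) is the most significant bit, so row ``c`` holds
    the binary expansion of ``c``.
    """
    if K < 1:
        raise InvalidDimensionError(f"K must be >= 1, got {K}")
    if K > 20:
        raise InvalidDimensionError(f"K={K} exceeds the practical bound of 20")
    idx = np.arange(2**K)
    shifts = np.arange(K - 1, -1, -1)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.int8)


def enumerate_profiles(K: int) -> list:
    """Enumerate all 2^K attribute profiles in canonical order.

    The all-zero profile comes first; profile ``index`` equals the integer
    whose binary expansion (attribute 1 = most significant bit) is ``bits``.
    """
    mat = profile_matrix(K)
    return [AttributeProfile(bits=tuple(int(b) for b in row), index=i) for i, row in enumerate(mat)]


def profile_to_index(bits) -> int:
    """Canonical index of a profile (attribute 1 = most significant bit)."""
    idx = 0
    for b in bits:
        idx = (idx << 1) | int(b)
    return idx


def dichotomize(values) -> np.ndarray:
    """Map ordinal responses to binary: zero stays 0, any positive count -> 1.

    Missing entries (NaN) are preserved.  Negative entries are rejected.
    Accepts an array or DataFrame; returns a float array with NaN for
    missing so that downstream complete-case filtering can act on it.
    """
    arr = np.asarray(values, dtype=float)
    if np.nanmin(arr, initial=0) < 0:
        raise InvalidValueError("ordinal responses must be non-negative")
    out = np.where(np.isnan(arr), np.nan, (arr > 0).astype(float))
    return out


def complete_cases(values, respondent_ids=None):
    """Keep only rows with no missing entries; preserve row order.

    Returns ``(clean_values, kept_ids, n_removed)``.  Raises
    :class:`EmptyDataError` when no complete row remains.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise InvalidDimensionError("expected a 2-D response array")
    keep = ~np.isnan(arr).any(axis=1)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise EmptyDataError("no respondent has complete item responses")
    clean = arr[keep]
    if respondent_ids is None:
        kept_ids = [str(i) for i in np.flatnonzero(keep)]
    else:
        kept_ids = [respondent_ids[i] for i in np.flatnonzero(keep)]
    return clean, kept_ids, n_removed


def reduced_profile(profile, qvector) -> tuple:
    """Project a full attribute profile onto an item's required attributes.

    Returns the profile bits at the positions where the q-vector is 1, in
    attribute order.  Profiles sharing a reduced profile are
    indistinguishable to the item.
    """
    q = np.asarray(qvector, dtype=int)
    if q.sum() < 1:
        raise InvalidQVectorError("q-vector must require at least one attribute")
    bits = np.asarray(tuple(profile), dtype=int)
    if bits.shape[0] != q.shape[0]:
        raise InvalidDimensionError("profile and q-vector lengths differ")
    return tuple(int(b) for b in bits[q == 1])


def reduced_index_map(qvector, K: int) -> np.ndarray:
    """For each of the 2^K profiles, the canonical index of its reduced profile.

    The reduced index treats the FIRST required attribute (in attribute
    order) as the most significant bit, matching the canonical full-profile
    order restricted to the required attributes.
    """
    q = np.asarray(qvector, dtype=int)
    if q.shape[0] != K:
        raise InvalidDimensionError("q-vector length must equal K")
    if q.sum() < 1:
        raise InvalidQVectorError("q-vector must require at least one attribute")
    prof = profile_matrix(K)
    req = np.flatnonzero(q == 1)
    sub = prof[:, req]
    weights = 2 ** np.arange(len(req) - 1, -1, -1)
    return (sub * weights).sum(axis=1).astype(np.int64)


@dataclass
class QMatrix:
    """J x K binary item-attribute loading matrix.

    Rows are q-vectors; a 1 in cell (j, k) states that endorsing item j
    depends on attribute k.  Every item must load on at least one attribute
    and every attribute must be required by at least one item.
    """

    entries: np.ndarray
    item_ids: list = None
    attribute_names: list = None

    def __post_init__(self):
        self.entries = np.asarray(self.entries)
        if self.entries.ndim != 2:
            raise InvalidQMatrixError("Q-matrix must be 2-D")
        vals = np.unique(self.entries)
        if not np.all(np.isin(vals, [0, 1])):
            raise InvalidQMatrixError("Q-matrix entries must be exactly 0 or 1")
        self.entries = self.entries.astype(np.int8)
        if (self.entries.sum(axis=1) < 1).any():
            bad = np.flatnonzero(self.entries.sum(axis=1) < 1)
            raise InvalidQMatrixError(f"items with all-zero q-vectors: {bad.tolist()}")
        if (self.entries.sum(axis=0) < 1).any():
            bad = np.flatnonzero(self.entries.sum(axis=0) < 1)
            raise InvalidQMatrixError(f"attributes never required: {bad.tolist()}")
        if self.item_ids is None:
            self.item_ids = [f"item{j + 1}" for j in range(self.J)]
        if self.attribute_names is None:
            self.attribute_names = [f"A{k + 1}" for k in range(self.K)]
        if len(self.item_ids) != self.J:
            raise AlignmentError("item_ids length does not match Q-matrix rows")
        if len(self.attribute_names) != self.K:
            raise AlignmentError("attribute_names length does not match Q-matrix columns")

    @property
    def J(self) -> int:
        return self.entries.shape[0]

    @property
    def K(self) -> int:
        return self.entries.shape[1]

    def qvector(self, j: int) -> np.ndarray:
        return self.entries[j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.item_ids, columns=self.attribute_names)


@dataclass
class ResponseMatrix:
    """N x J binary (dichotomized, complete-case) response matrix."""

    values: np.ndarray
    respondent_ids: list = None
    item_ids: list = None
    n_removed: int = field(default=0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InvalidDimensionError("responses must be 2-D")
        if np.isnan(np.asarray(self.values, dtype=float)).any():
            raise InvalidValueError("responses contain missing values; apply complete_cases first")
        vals = np.unique(self.values)
        if not np.all(np.isin(vals, [0, 1])):
            raise InvalidValueError("responses must be binary 0/1; apply dichotomize first")
        self.values = self.values.astype(np.int8)
        if self.respondent_ids is None:
            self.respondent_ids = [f"r{i + 1}" for i in range(self.N)]
        if self.item_ids is None:
            self.item_ids = [f"item{j + 1}" for j in range(self.J)]
        if len(self.respondent_ids) != self.N:
            raise AlignmentError("respondent_ids length does not match rows")
        if len(self.item_ids) != self.J:
            raise AlignmentError("item_ids length does not match columns")

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_ordinal(cls, values, respondent_ids=None, item_ids=None) -> "ResponseMatrix":
        """Dichotomize ordinal responses (>0 -> 1) and drop incomplete rows."""
        if isinstance(values, pd.DataFrame):
            if respondent_ids is None:
                respondent_ids = [str(i) for i in values.index]
            if item_ids is None:
                item_ids = [str(c) for c in values.columns]
            values = values.to_numpy()
        binary = dichotomize(values)
        clean, kept_ids, n_removed = complete_cases(binary, respondent_ids)
        return cls(values=clean, respondent_ids=kept_ids, item_ids=item_ids, n_removed=n_removed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.respondent_ids, columns=self.item_ids)


def check_alignment(responses: ResponseMatrix, Q: QMatrix) -> None:
    """Raise AlignmentError when responses and Q-matrix disagree on items."""
    if responses.J != Q.J:
        raise AlignmentError(
            f"responses have {responses.J} items but Q-matrix has {Q.J} rows"
        )
    if responses.item_ids != Q.item_ids:
        mismatched = [
            (a, b) for a, b in zip(responses.item_ids, Q.item_ids) if a != b
        ]
        if mismatched:
            raise AlignmentError(f"item id mismatches (response, Q): {mismatched[:5]}")
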