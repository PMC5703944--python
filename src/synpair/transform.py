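"""Rank transformation and pairwise conversion types.

Rank-based pair features are robust to quantization effects and background
differences between genes: each gene's expression values are replaced by
their within-gene sample ranks R_ij, and a gene pair (p, q) is collapsed
into a single feature vector Z by one of five conversion types:

======  =======================================
sum     Z_i = R_ip + R_iq
diff    Z_i = R_ip - R_iq
mul     Z_i = R_ip * R_iq
sign    Z_i = 1 if R_ip >= R_iq else 0
abs     Z_i = |R_ip - R_iq|
======  =======================================

``abs`` is the conversion that captures the diagonal-band synergy pattern
(the phenotype depending on how far apart two genes' ranks are) that the
four classical doublet conversions and single-gene ranking miss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import PAIR_CONVERSIONS, ExpressionDataset

__all__ = [
    "RankMatrix",
    "PairFeature",
    "RankTransformer",
    "rank_transform",
    "convert_pair",
    "convert_pairs_matrix",
    "heatmap_values",
    "CONVERSION_FUNCS",
]

_TIE_METHODS = {"average": "average", "competition": "min"}


def _rank_rows(values: np.ndarray, ties: str = "average") -> np.ndarray:
    try:
        method = _TIE_METHODS[ties]
    except KeyError:
        raise ValueError(f"ties must be one of {sorted(_TIE_METHODS)}, got {ties!r}")
    return rankdata(values, axis=1, method=method).astype(float)


@dataclass
class RankMatrix:
    """Per-gene sample ranks R_ij (genes in rows) replacing expression values.

    Each row holds values in [1, n]; under average-rank tie handling every
    row sums to n(n+1)/2 exactly.
    """

    ranks: np.ndarray
    source: ExpressionDataset | None = None

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ranks.shape[1]


@dataclass
class PairFeature:
    """A gene pair (p, q), a conversion type, and its converted vector Z."""

    p: int
    q: int
    conversion: str
    z: np.ndarray


# elementwise conversions; operate on arrays of ranks of matching shape
CONVERSION_FUNCS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "sum": lambda rp, rq: rp + rq,
    "diff": lambda rp, rq: rp - rq,
    "mul": lambda rp, rq: rp * rq,
    "sign": lambda rp, rq: (rp >= rq).astype(float),
    "abs": lambda rp, rq: np.abs(rp - rq),
}


class RankTransformer(BaseEstimator, TransformerMixin):
    """Replace each feature's values by their within-feature sample ranks.

    Operates on samples-by-genes arrays (the scikit-learn orientation).
    Ranks are 1-based; ties receive the average of the ranks they span by
    default (``ties="average"``), which keeps each gene's rank sum at
    n(n+1)/2 exactly; ``ties="competition"`` gives integer minimum ranks.

    Ranks are computed within the sample set passed to :meth:`transform`,
    so transforming the full dataset reproduces the all-samples ranking
    used for screening, while transforming a CV fold re-ranks within that
    fold (the strict nested mode).
    """

    def __init__(self, ties: str = "average"):
        self.ties = ties

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        return _rank_rows(X.T, self.ties).T


def rank_transform(data: ExpressionDataset, ties: str = "average") -> RankMatrix:
    """Rank each gene's expression values across samples.

    Invariant to any strictly increasing per-gene transformation of the
    expression values.
    """
    return RankMatrix(ranks=_rank_rows(data.values, ties), source=data)


def convert_pair(ranks: RankMatrix | np.ndarray, p: int, q: int,
                 conversion: str) -> PairFeature:
    """Collapse the rank rows of genes p and q into one converted vector Z."""
    if p == q:
        raise ValueError("a pair requires two distinct genes (p != q)")
    if conversion not in PAIR_CONVERSIONS:
        raise ValueError(
            f"unknown conversion {conversion!r}; expected one of {PAIR_CONVERSIONS}"
        )
    R = ranks.ranks if isinstance(ranks, RankMatrix) else np.asarray(ranks, dtype=float)
    z = CONVERSION_FUNCS[conversion](R[p], R[q])
    return PairFeature(p=p, q=q, conversion=conversion, z=z)


def convert_pairs_matrix(R: np.ndarray, pp: np.ndarray, qq: np.ndarray,
                         conversion: str) -> np.ndarray:
    """Converted vectors for many pairs at once: rows follow (pp, qq)."""
    if conversion not in PAIR_CONVERSIONS:
        raise ValueError(f"unknown conversion {conversion!r}")
    return CONVERSION_FUNCS[conversion](R[pp], R[qq])


def heatmap_values(mat: np.ndarray) -> np.ndarray:
    """Affinely rescale each row to [-1, 1] for heat-map display.

    A row's minimum maps to -1 and its maximum to +1; constant rows map
    to all zeros.
    """
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if mat.size == 0:
        raise ValueError("empty matrix")
    lo = mat.min(axis=1, keepdims=True)
    hi = mat.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(mat)
    nonconst = (span > 0).ravel()
    out[nonconst] = -1.0 + 2.0 * (mat[nonconst] - lo[nonconst]) / span[nonconst]
    return out
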