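"""Plug-in interaction information I(X1; X2; Y) as a reference synergy measure.

The interaction information of two features with a binary phenotype is

    I(X1; X2; Y) = I(X1, X2; Y) - I(X1; Y) - I(X2; Y)

positive values indicate synergy (the pair carries information about Y
beyond the sum of its parts), negative values redundancy.  Continuous
features are discretized by equal-frequency binning and all mutual
informations are maximum-likelihood (plug-in) estimates in bits, with no
bias correction — adequate as a reference measure on small examples, not a
production estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SynergyScore", "interaction_information", "discretize", "mutual_information"]


@dataclass
class SynergyScore:
    """Interaction-information decomposition for one feature pair (bits)."""

    i_x1_y: float
    i_x2_y: float
    i_joint_y: float
    interaction: float
    bins: int


def discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning into integer codes 0..k-1 (k <= n_bins).

    Duplicate quantile edges (fewer distinct values than bins) collapse
    bins with a warning.
    """
    x = np.asarray(x, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    codes = np.searchsorted(edges, x, side="left")
    k = len(np.unique(codes))
    if k < n_bins:
        warnings.warn(
            f"fewer distinct values than bins: {n_bins} requested, {k} used"
        )
    # re-code to consecutive integers
    _, codes = np.unique(codes, return_inverse=True)
    return codes


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete code vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    ka = a.max() + 1
    kb = b.max() + 1
    counts = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb)
    n = counts.sum()
    p = counts / n
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (pa @ pb)[nz])))


def interaction_information(x1, x2, y, n_bins: int = 4) -> SynergyScore:
    """Estimate I(X1; X2; Y) by equal-frequency binning + plug-in MI.

    Parameters
    ----------
    x1, x2 : array-like
        Feature vectors (continuous or already discrete).
    y : array-like
        Binary phenotype in {0, 1}.
    n_bins : int
        Number of equal-frequency bins per feature (default 4).

    Returns
    -------
    SynergyScore
        The three MI terms (all >= 0) and their interaction
        ``i_joint_y - i_x1_y - i_x2_y``; symmetric in (x1, x2).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=int)
    if not (x1.shape == x2.shape == y.shape):
        raise ValueError("x1, x2 and y must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary 0/1")
    c1 = discretize(x1, n_bins)
    c2 = discretize(x2, n_bins)
    k2 = c2.max() + 1
    joint = c1 * k2 + c2
    i1 = mutual_information(c1, y)
    i2 = mutual_information(c2, y)
    ij = mutual_information(joint, y)
    return SynergyScore(i_x1_y=i1, i_x2_y=i2, i_joint_y=ij,
                        interaction=ij - i1 - i2, bins=n_bins)
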