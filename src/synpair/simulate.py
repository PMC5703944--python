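"""Synthetic datasets with planted absolute-difference (synergic) structure.

The generator family draws feature columns X ~ U(0, 1) i.i.d. and builds a
continuous phenotype from k absolute-difference pair terms, optionally plus
additive individual terms:

    y = sum_j x_ind_j  +  sum_j |x_pair_{2j-1} - x_pair_{2j}|

The binary class label is the median split of y (strictly above the
midpoint median -> class 1), which gives an exactly balanced 50/50 split
for even n since the draws are continuous.  Independent U(0, 1) noise
columns can be appended.  With no individual terms and no noise this is
the ten-dataset simulation family (k = 1..10 pairs, n = 200) used to show
that classifiers need the converted feature Z = |X1 - X2| rather than the
raw pair members.

Everything is reproducible from an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionDataset

__all__ = ["SimulatedDataset", "simulate_abs_pairs", "simulate_mixed"]


@dataclass
class SimulatedDataset:
    """One simulated instance with planted abs-pair (and optional additive) structure.

    ``x`` holds only the structural columns: ``n_ind`` additive individual
    columns first, then 2k pair-member columns.  ``z_true`` holds the k true
    converted features |x_{2j-1} - x_{2j}| computed on the pair columns;
    ``y_continuous`` is the row sum of the individual columns and ``z_true``.
    """

    k: int
    x: np.ndarray                       # (n, n_ind + 2k) structural columns
    y_continuous: np.ndarray            # (n,)
    labels: np.ndarray                  # (n,) median split of y_continuous
    z_true: np.ndarray                  # (n, k) true converted pair features
    seed: int
    n_ind: int = 0
    noise_genes: np.ndarray | None = None   # (n, n_noise) or None
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    @property
    def n_noise(self) -> int:
        return 0 if self.noise_genes is None else self.noise_genes.shape[1]

    def features(self) -> np.ndarray:
        """All feature columns (structural then noise), samples in rows."""
        if self.noise_genes is None:
            return self.x
        return np.hstack([self.x, self.noise_genes])

    def column_roles(self) -> list[str]:
        """Role of each feature column: 'ind', 'pair', or 'noise'."""
        return (["ind"] * self.n_ind
                + ["pair"] * (2 * self.k)
                + ["noise"] * self.n_noise)

    def to_expression_dataset(self) -> ExpressionDataset:
        """View the simulation as a genes-by-samples expression dataset."""
        feats = self.features()
        n = self.n_samples
        return ExpressionDataset(
            values=feats.T,
            gene_ids=list(self.feature_names),
            sample_ids=[f"S{i + 1}" for i in range(n)],
            labels=self.labels,
        )


def _finish(x_ind: np.ndarray, x_pairs: np.ndarray, noise: np.ndarray | None,
            k: int, seed: int) -> SimulatedDataset:
    n_ind = x_ind.shape[1]
    if k:
        z_true = np.abs(x_pairs[:, 0::2] - x_pairs[:, 1::2])
    else:
        z_true = np.empty((x_ind.shape[0], 0))
    y = x_ind.sum(axis=1) + z_true.sum(axis=1)
    labels = (y > np.median(y)).astype(int)
    names = ([f"X{j + 1}" for j in range(n_ind + 2 * k)]
             + [f"N{j + 1}" for j in range(0 if noise is None else noise.shape[1])])
    return SimulatedDataset(
        k=k,
        x=np.hstack([x_ind, x_pairs]),
        y_continuous=y,
        labels=labels,
        z_true=z_true,
        seed=seed,
        n_ind=n_ind,
        noise_genes=noise,
        feature_names=names,
    )


def _check_n(n: int) -> None:
    if n % 2:
        raise ValueError("n must be even so the median split balances the classes")
    if n < 20:
        raise ValueError("n must be >= 20")


def simulate_abs_pairs(k: int, n: int = 200, seed: int = 0,
                    n_noise: int = 0) -> SimulatedDataset:
    """Pure abs-pair architecture: y = |X1-X2| + ... + |X_{2k-1}-X_{2k}|.

    Parameters
    ----------
    k : int
        Number of abs pairs (the simulation family uses k = 1..10).
    n : int
        Even sample size >= 20 (default 200).
    seed : int
        RNG seed; identical parameters and seed give bit-identical data.
    n_noise : int
        Extra independent U(0, 1) columns unrelated to y (0 replicates the
        base family exactly).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_n(n)
    rng = np.random.default_rng(seed)
    x_pairs = rng.uniform(size=(n, 2 * k))
    noise = rng.uniform(size=(n, n_noise)) if n_noise else None
    return _finish(np.empty((n, 0)), x_pairs, noise, k, seed)


def simulate_mixed(n_ind: int, n_syn_pairs: int, n_noise: int,
                   n: int = 200, seed: int = 0) -> SimulatedDataset:
    """Mixed architecture: additive individual genes plus abs pairs.

    ``n_ind=2, n_syn_pairs=2, n_noise=0`` gives the illustrative model
    y = X1 + X2 + |X3 - X4| + |X5 - X6| whose optimal feature subset is
    {X1..X6}; with ``n_syn_pairs=0`` it degenerates to a purely additive
    individual model.
    """
    if n_ind < 0 or n_syn_pairs < 0 or n_noise < 0:
        raise ValueError("counts must be non-negative")
    if n_ind + n_syn_pairs == 0:
        raise ValueError("need at least one structural term")
    _check_n(n)
    rng = np.random.default_rng(seed)
    x_ind = rng.uniform(size=(n, n_ind))
    x_pairs = rng.uniform(size=(n, 2 * n_syn_pairs))
    noise = rng.uniform(size=(n, n_noise)) if n_noise else None
    return _finish(x_ind, x_pairs, noise, n_syn_pairs, seed)
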