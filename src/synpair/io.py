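"""Data containers and delimited-text input/output.

The central container is :class:`ExpressionDataset`: an m-gene by n-sample
real-valued matrix with a binary phenotype label per sample (0 = cancerous,
1 = normal by convention; the mapping applied at load time is recorded on
the dataset).  Screening results (ranked gene pairs or ranked individual
genes with their t-scores) are held in :class:`ScreenResult` and serialized
to plain TSV with a small key=value comment header.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("synpair")

#: conversion types for gene pairs plus "ind" for single-gene ranking
METHODS = ("ind", "sum", "diff", "mul", "sign", "abs")
PAIR_CONVERSIONS = ("sum", "diff", "mul", "sign", "abs")


class ValidationError(ValueError):
    """Raised when an input matrix or label vector violates the data contract."""


@dataclass
class ExpressionDataset:
    """Expression matrix (genes in rows) with binary sample labels.

    Parameters
    ----------
    values : ndarray of shape (m, n)
        Real expression levels, gene ``j`` in row ``j``, sample ``i`` in
        column ``i``.  No missing values allowed.
    gene_ids : list of str
        Distinct gene identifiers, length m.
    sample_ids : list of str
        Distinct sample identifiers, length n.
    labels : ndarray of shape (n,)
        Class codes in {0, 1}; both classes must have at least two samples.
    label_mapping : dict, optional
        Records which raw label value was mapped to 0 and which to 1.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    label_mapping: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        m, n = self.values.shape
        if m < 2:
            raise ValidationError(f"need at least 2 genes, got {m}")
        if n < 4:
            raise ValidationError(f"need at least 4 samples, got {n}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            g, s = bad[0]
            raise ValidationError(
                f"missing/non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r} (and {len(bad) - 1} more)"
            )
        if len(self.gene_ids) != m:
            raise ValidationError("gene_ids length does not match matrix")
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match matrix")
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValidationError(f"duplicate gene ids: {dup}")
        if _duplicates(self.sample_ids):
            raise ValidationError(f"duplicate sample ids: {_duplicates(self.sample_ids)}")
        if self.labels.shape != (n,):
            raise ValidationError("labels length does not match sample count")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be coded 0/1")
        n0 = int(np.sum(self.labels == 0))
        n1 = n - n0
        if n0 < 2 or n1 < 2:
            raise ValidationError(
                f"both classes need at least 2 samples (n0={n0}, n1={n1})"
            )

    # -- conveniences -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def class_counts(self) -> tuple[int, int]:
        n0 = int(np.sum(self.labels == 0))
        return n0, self.n_samples - n0

    def X(self) -> np.ndarray:
        """Samples-by-genes view for scikit-learn style estimators."""
        return self.values.T


@dataclass(frozen=True)
class ScreenEntry:
    """One ranked feature: a gene pair (or single gene) with its t-score."""

    rank: int
    gene_p: str
    gene_q: str | None  # None for individual-gene entries
    t_score: float

    @property
    def is_pair(self) -> bool:
        return self.gene_q is not None


@dataclass
class ScreenResult:
    """Ordered top-N screening output for one method.

    ``entries`` are sorted by descending |t| with deterministic tie-breaks;
    ranks are 1-based and consecutive.  ``gene_union`` lists the distinct
    genes appearing in the entries in first-appearance order (at most 2N for
    pair methods, exactly N for individual ranking).
    """

    method: str
    entries: list[ScreenEntry]
    top_n: int
    params: dict = field(default_factory=dict)
    gene_universe: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        for i, e in enumerate(self.entries, start=1):
            if e.rank != i:
                raise ValueError("entry ranks must be 1-based and consecutive")

    @property
    def gene_union(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.gene_p)
            if e.gene_q is not None:
                seen.setdefault(e.gene_q)
        return list(seen)

    def __len__(self) -> int:
        return len(self.entries)


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


def _sep_for(path: str | os.PathLike, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(os.fspath(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def map_labels(raw: Sequence, label_map: dict | None = None) -> tuple[np.ndarray, dict]:
    """Map two distinct raw label values onto {0, 1}.

    With no explicit ``label_map`` the lexicographically smaller raw value
    (as a string) becomes 0; the choice is logged so loads are reproducible.
    """
    raw_str = [str(v) for v in raw]
    levels = sorted(set(raw_str))
    if len(levels) != 2:
        raise ValidationError(
            f"label field must contain exactly two distinct values, got {levels}"
        )
    if label_map is None:
        if levels == ["0", "1"]:
            mapping = {"0": 0, "1": 1}
        else:
            mapping = {levels[0]: 0, levels[1]: 1}
        logger.info("label mapping (lexicographic default): %s", mapping)
    else:
        mapping = {str(k): int(v) for k, v in label_map.items()}
        if sorted(mapping) != levels or sorted(mapping.values()) != [0, 1]:
            raise ValidationError(
                f"label_map {label_map} does not cover the observed levels {levels}"
            )
    return np.array([mapping[v] for v in raw_str], dtype=int), mapping


def read_expression(
    path: str | os.PathLike,
    orientation: str = "genes_in_rows",
    label_row_or_col: str = "label",
    delimiter: str | None = None,
    label_map: dict | None = None,
) -> ExpressionDataset:
    """Read a delimited expression matrix with an embedded label row/column.

    Default layout (``genes_in_rows``): first column holds gene ids, one
    header row of sample ids, and one row whose id equals
    ``label_row_or_col`` holding the class labels.  ``samples_in_rows`` is
    the transpose with labels in the named column.  Delimiter is inferred
    from the extension (.csv -> comma, otherwise tab) unless given.
    """
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if label_row_or_col not in df.index:
        raise ValidationError(f"label row {label_row_or_col!r} not found")
    raw_labels = df.loc[label_row_or_col]
    expr = df.drop(index=label_row_or_col)
    labels, mapping = map_labels(list(raw_labels), label_map)
    values = expr.to_numpy(dtype=float)
    if expr.isna().to_numpy().any():
        i, j = np.argwhere(expr.isna().to_numpy())[0]
        raise ValidationError(
            f"missing value at gene {expr.index[i]!r}, sample {expr.columns[j]!r}"
        )
    return ExpressionDataset(
        values=values,
        gene_ids=[str(g) for g in expr.index],
        sample_ids=[str(s) for s in expr.columns],
        labels=labels,
        label_mapping=mapping,
    )


def write_expression(data: ExpressionDataset, path: str | os.PathLike,
                     delimiter: str | None = None) -> None:
    """Write a dataset in the default genes-in-rows layout (labels included)."""
    sep = _sep_for(path, delimiter)
    df = pd.DataFrame(data.values, index=data.gene_ids, columns=data.sample_ids)
    df.loc["label"] = data.labels
    df.to_csv(path, sep=sep, index_label="gene")


_RESULT_COLUMNS = ["rank", "gene_p", "gene_q", "conversion", "t_score"]


def write_screen_result(result: ScreenResult, path: str | os.PathLike,
                        delimiter: str | None = None) -> None:
    """Serialize a :class:`ScreenResult` as TSV/CSV with a comment header.

    Scores are printed with 6 significant digits; the ``gene_q`` column is
    empty for individual-gene results.
    """
    if not result.entries:
        raise ValueError("refusing to write an empty screen result")
    sep = _sep_for(path, delimiter)
    with open(path, "w") as fh:
        fh.write(f"# method={result.method} top_n={result.top_n}")
        for k, v in sorted(result.params.items()):
            fh.write(f" {k}={v}")
        fh.write("\n")
        fh.write(sep.join(_RESULT_COLUMNS) + "\n")
        for e in result.entries:
            row = [
                str(e.rank),
                e.gene_p,
                e.gene_q if e.gene_q is not None else "",
                result.method if e.is_pair else "",
                _format_score(e.t_score),
            ]
            fh.write(sep.join(row) + "\n")


def _format_score(t: float) -> str:
    if np.isinf(t):
        return "inf" if t > 0 else "-inf"
    return f"{t:.6g}"


def read_screen_result(path: str | os.PathLike,
                       delimiter: str | None = None) -> ScreenResult:
    """Read back a file written by :func:`write_screen_result`."""
    sep = _sep_for(path, delimiter)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("screen-result file must start with a '# key=value' header")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        df = pd.read_csv(fh, sep=sep, keep_default_na=False, dtype=str)
    entries = [
        ScreenEntry(
            rank=int(r["rank"]),
            gene_p=r["gene_p"],
            gene_q=r["gene_q"] or None,
            t_score=float(r["t_score"]),
        )
        for _, r in df.iterrows()
    ]
    method = meta.pop("method")
    top_n = int(meta.pop("top_n"))
    return ScreenResult(method=method, entries=entries, top_n=top_n, params=meta)
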