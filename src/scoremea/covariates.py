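"""Sequence-composition covariates.

Per-sequence k-mer frequencies (forward strand, N-containing windows
excluded), optional user-supplied numeric covariates, and PCA reduction of
the k-mer block to the minimal set of leading principal components
explaining at least 99% of its variance.  Reducing the multicollinear k-mer
frequencies to orthogonal components keeps the downstream logistic
regression stable; user covariates pass through the PCA untouched so they
stay directly interpretable.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .motifs import BASES
from .scanner import encode_sequence
from .seqio import ScoredSequence

KIND_KMER = "kmer"
KIND_USER = "user"
KIND_COMPONENT = "component"


@dataclass
class CovariateTable:
    """Per-sequence numeric covariates; one kind tag per column."""

    sequence_names: list[str]
    column_names: list[str]
    values: np.ndarray
    kinds: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.sequence_names), len(self.column_names)
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} != ({n} sequences, {m} columns)"
            )
        if len(self.kinds) != m:
            raise ValueError("one kind per column required")
        if m and not np.isfinite(self.values).all():
            raise ValueError("covariate table contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sequence_names, columns=self.column_names)

    def columns_of_kind(self, kind: str) -> list[int]:
        return [i for i, k in enumerate(self.kinds) if k == kind]


@dataclass
class PCAReduction:
    """Loadings and explained-variance bookkeeping for the kept components."""

    component_loadings: np.ndarray
    explained_variance_ratios: np.ndarray
    n_components: int


def all_kmers(k: int) -> list[str]:
    """The 4^k k-mers in fixed lexicographic (A<C<G<T) order."""
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def kmer_frequencies(sequence: str, k: int) -> np.ndarray:
    """Frequencies of the 4^k forward-strand k-mers in a sequence.

    Counts over windows whose k characters are all A/C/G/T, divided by the
    number of such valid windows; all-zero when no window is valid.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = encode_sequence(sequence)
    n_windows = codes.size - k + 1
    out = np.zeros(4**k)
    if n_windows <= 0:
        return out
    bad = (codes < 0).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        return out
    safe = np.where(codes < 0, 0, codes).astype(np.int64)
    idx = np.zeros(n_windows, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + safe[j : j + n_windows]
    counts = np.bincount(idx[valid], minlength=4**k)
    return counts / n_valid


def read_covariates_tsv(source: str | Path) -> pd.DataFrame:
    """User covariate TSV: header row, first column = sequence name."""
    df = pd.read_csv(source, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def build_covariate_table(
    sequences: Sequence[ScoredSequence],
    k: int,
    user_covariates: pd.DataFrame | None = None,
) -> CovariateTable:
    """Assemble the pre-reduction covariate table.

    ``k = 0`` contributes no k-mer columns; ``k >= 1`` contributes 4^k
    frequency columns.  User covariates (indexed by sequence name) are
    appended and must key every sequence exactly once.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    names = [s.name for s in sequences]
    blocks: list[np.ndarray] = []
    columns: list[str] = []
    kinds: list[str] = []
    if k >= 1:
        blocks.append(np.array([kmer_frequencies(s.sequence, k) for s in sequences]))
        columns.extend(all_kmers(k))
        kinds.extend([KIND_KMER] * 4**k)
    if user_covariates is not None:
        missing = sorted(set(names) - set(user_covariates.index))
        unknown = sorted(set(user_covariates.index) - set(names))
        if missing or unknown:
            raise ValueError(
                f"user covariates mismatch: missing sequences {missing[:5]}"
                f"{'...' if len(missing) > 5 else ''}, unknown names {unknown[:5]}"
                f"{'...' if len(unknown) > 5 else ''}"
            )
        if user_covariates.index.duplicated().any():
            raise ValueError("user covariate table has duplicated sequence names")
        aligned = user_covariates.loc[names]
        try:
            user_vals = aligned.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric user covariate value: {exc}") from exc
        if np.isnan(user_vals).any():
            raise ValueError("user covariate table contains missing values")
        blocks.append(user_vals)
        columns.extend(str(c) for c in aligned.columns)
        kinds.extend([KIND_USER] * aligned.shape[1])
    values = np.hstack(blocks) if blocks else np.zeros((len(names), 0))
    return CovariateTable(names, columns, values, kinds)


def pca_reduce(
    table: CovariateTable, variance_target: float = 0.99
) -> tuple[CovariateTable, PCAReduction]:
    """Replace the k-mer columns by their minimal >= ``variance_target`` PCA.

    K-mer columns are mean-centered (not scaled) and projected onto the
    fewest leading components whose cumulative explained-variance ratio
    reaches the target; user columns pass through untouched.  Component
    sign is fixed by making each component's largest-magnitude loading
    positive, so the output is deterministic.
    """
    kmer_idx = table.columns_of_kind(KIND_KMER)
    other_idx = [i for i in range(len(table.column_names)) if i not in kmer_idx]
    if not kmer_idx:
        reduction = PCAReduction(np.zeros((0, 0)), np.zeros(0), 0)
        return table, reduction
    if len(table.sequence_names) < 2:
        raise ValueError("PCA reduction needs at least 2 sequences")
    X = table.values[:, kmer_idx]
    if np.allclose(X.var(axis=0), 0.0):
        warnings.warn("k-mer covariates have zero variance; no components kept")
        reduction = PCAReduction(np.zeros((0, len(kmer_idx))), np.zeros(0), 0)
        new = CovariateTable(
            table.sequence_names,
            [table.column_names[i] for i in other_idx],
            table.values[:, other_idx],
            [table.kinds[i] for i in other_idx],
        )
        return new, reduction
    pca = PCA(svd_solver="full")
    transformed = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    n_keep = int(np.argmax(np.cumsum(ratios) >= variance_target - 1e-12)) + 1
    loadings = pca.components_[:n_keep].copy()
    scores = transformed[:, :n_keep].copy()
    for c in range(n_keep):
        if loadings[c, np.argmax(np.abs(loadings[c]))] < 0:
            loadings[c] *= -1.0
            scores[:, c] *= -1.0
    comp_names = [f"PC{c + 1}" for c in range(n_keep)]
    new = CovariateTable(
        table.sequence_names,
        comp_names + [table.column_names[i] for i in other_idx],
        np.hstack([scores, table.values[:, other_idx]]),
        [KIND_COMPONENT] * n_keep + [table.kinds[i] for i in other_idx],
    )
    return new, PCAReduction(loadings, ratios[:n_keep].copy(), n_keep)


def standardize_columns(
    values: np.ndarray, column_names: Sequence[str] | None = None
) -> tuple[np.ndarray, list[int]]:
    """Standardize columns to mean 0, sample (n-1) standard deviation 1.

    Zero-variance columns are dropped with a warning rather than divided by
    zero.  Returns the standardized matrix and the kept column indices.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("standardization needs at least 2 rows")
    sd = values.std(axis=0, ddof=1)
    keep = [i for i in range(values.shape[1]) if sd[i] > 0]
    dropped = [i for i in range(values.shape[1]) if sd[i] == 0]
    if dropped:
        labels = (
            [column_names[i] for i in dropped] if column_names is not None else dropped
        )
        warnings.warn(f"dropping zero-variance columns: {labels}")
    centered = values[:, keep] - values[:, keep].mean(axis=0)
    return centered / sd[keep], keep
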