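"""Accuracy and comparison machinery.

Percentile rank accuracy (PRA) of a target motif within a method's ranked
enrichment results, bootstrap rank-stability of a target motif under
resampling of the input sequences, paired nonparametric comparison of rank
vectors, and Fisher-exact enrichment of categorical flags in a 2x2 table.

Rank conventions: ranks are counted from the bottom so that the most
positively enriched motif gets the highest rank (N when all library motifs
are listed); tied enrichment scores all take the lowest rank of the tied
block; a motif absent from the results gets rank 0.  PRA = 100 * R_k / N.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from .covariates import CovariateTable, KIND_KMER, build_covariate_table, pca_reduce
from .enrichment import STATUS_OK, EnrichmentResult, enrich_all
from .motifs import Background, MotifMatrix, make_scoring_matrix
from .scanner import PresenceMatrix, build_presence_matrix
from .seqio import ScoredSequence


@dataclass
class RankedResultList:
    """Motif ids with enrichment scores (higher = more positively enriched)
    plus the library size N the ranks are taken out of."""

    entries: list[tuple[str, float]]
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size < len(self.entries):
            raise ValueError("library size smaller than number of listed motifs")


@dataclass
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (flag&fail, no-flag&fail, flag&pass, no-flag&pass)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def ranked_from_results(
    results: Sequence[EnrichmentResult], library_size: int | None = None
) -> RankedResultList:
    """Ranked list from enrichment results (score = signed coefficient);
    motifs whose fit failed are excluded (and so rank 0 if targeted)."""
    ok = [(r.motif_id, r.coefficient) for r in results if r.status == STATUS_OK]
    return RankedResultList(ok, library_size if library_size is not None else len(results))


def rank_of_motif(results: RankedResultList, motif_id: str) -> int:
    """Bottom-up rank of a motif: 1 + number of strictly lower scores.

    The best score gets the highest rank; ties all resolve to the lowest
    rank of the tied block; an absent motif gets 0.
    """
    target = [score for mid, score in results.entries if mid == motif_id]
    if not target:
        return 0
    t = target[0]
    return 1 + sum(1 for _, score in results.entries if score < t)


def _round_half_away(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentile_rank_accuracy(rank: float, n: int, decimals: int | None = 1) -> float:
    """PRA = 100 * rank / N, as a percent.

    ``rank`` may be fractional (e.g. a mean rank over experiments).  Display
    rounding (default one decimal) uses round-half-away-from-zero; pass
    ``decimals=None`` for the raw value.
    """
    if n <= 0:
        raise ValueError("library size N must be positive")
    if not (0 <= rank <= n):
        raise ValueError(f"rank {rank} outside [0, {n}]")
    pra = 100.0 * rank / n
    return pra if decimals is None else _round_half_away(pra, decimals)


@dataclass
class EnrichmentConfig:
    """Pipeline knobs shared by full runs and bootstrap replicates."""

    kmer: int = 2
    pcount: float = 0.001
    pval: float = 0.001
    variance_target: float = 0.99
    sort_mode: str = "coef"
    jobs: int = 1


def _rank_from_rows(
    present_rows: np.ndarray,
    motif_ids: list[str],
    names: list[str],
    scores: list[float],
    kmer_values: np.ndarray,
    kmer_names: list[str],
    config: EnrichmentConfig,
    target_motif: str,
    library_size: int,
) -> int:
    sequences = [ScoredSequence(n, "", s) for n, s in zip(names, scores)]
    pm = PresenceMatrix(names, motif_ids, present_rows, present_rows.astype(np.int64))
    table = None
    if kmer_values.shape[1]:
        raw = CovariateTable(names, kmer_names, kmer_values, [KIND_KMER] * len(kmer_names))
        table, _ = pca_reduce(raw, config.variance_target)
    results = enrich_all(pm, sequences, table, sort_mode=config.sort_mode)
    return rank_of_motif(ranked_from_results(results, library_size), target_motif)


def bootstrap_rank_distribution(
    sequences: Sequence[ScoredSequence],
    motif_library: Sequence[MotifMatrix],
    config: EnrichmentConfig,
    target_motif: str,
    B: int,
    seed: int,
    resample: bool = True,
    bg: Background | None = None,
) -> list[int]:
    """Rank of the target motif across B bootstrap resamples of the sequences.

    Each replicate draws the sequence list with replacement (same size) and
    reruns covariate reduction and enrichment; the scan itself is performed
    once on the original sequences and replicate presence rows are
    re-indexed, which is exact because resampled sequences are copies.
    With ``resample=False`` every replicate is the identity sample.
    Replicates whose fit fails for the target motif contribute rank 0.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sms = [make_scoring_matrix(m, config.pcount, config.pval, bg) for m in motif_library]
    pm = build_presence_matrix(sequences, sms, jobs=config.jobs)
    scores = [s.score for s in sequences]
    if config.kmer >= 1:
        raw = build_covariate_table(sequences, config.kmer)
        kmer_values, kmer_names = raw.values, raw.column_names
    else:
        kmer_values, kmer_names = np.zeros((len(sequences), 0)), []
    n = len(sequences)
    rng = np.random.default_rng(seed)
    ranks: list[int] = []
    library_size = len(motif_library)
    for b in range(B):
        idx = rng.integers(0, n, size=n) if resample else np.arange(n)
        names_b = [f"boot{b}_{i}" for i in range(n)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rank = _rank_from_rows(
                pm.present[idx],
                pm.motif_ids,
                names_b,
                [scores[i] for i in idx],
                kmer_values[idx],
                kmer_names,
                config,
                target_motif,
                library_size,
            )
        if rank == 0:
            warnings.warn(f"bootstrap replicate {b}: target fit failed, rank 0")
        ranks.append(rank)
    return ranks


def paired_rank_comparison(
    ranks_a: Sequence[float], ranks_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired rank vectors.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 informative pairs, the normal approximation with continuity
    correction beyond.  All-zero differences give p = 1 with a warning.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.size != b.size or a.size < 1:
        raise ValueError("rank vectors must have equal positive length")
    diffs = a - b
    nonzero = int(np.count_nonzero(diffs))
    if nonzero == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    method = "exact" if nonzero <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=True, alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Sample odds ratio (ad/bc) and two-sided conditional Fisher exact p.

    The two-sided p sums hypergeometric probabilities of tables no more
    likely than the observed one.  Both margins must be positive.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("Fisher exact test requires positive margins")
    a, b, c, d = table.a, table.b, table.c, table.d
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(odds), float(p)
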