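"""Position weight matrix handling.

Parses JASPAR-format motif libraries, converts count matrices to
pseudocounted log2-odds scoring matrices, and calibrates per-motif match
thresholds so that a random background word of the motif's width scores at
or above the threshold with probability at most a chosen p-value.  The
threshold calibration is exact (full 4^w enumeration of the score
distribution) for motif widths up to 10, and uses a discretized
dynamic-programming convolution for wider motifs.
"""
from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: exact enumeration limit: 4**10 ~ 1M words is cheap; beyond that use DP
EXACT_ENUMERATION_MAX_WIDTH = 10
#: score discretization scale for the DP path (quantum = 1/DP_SCALE bits)
DP_SCALE = 1000


class MotifParseError(ValueError):
    """Raised when a motif library cannot be parsed."""


@dataclass
class MotifMatrix:
    """A named nucleotide count matrix (rows A, C, G, T; one column per position)."""

    motif_id: str
    motif_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise MotifParseError(
                f"motif {self.motif_id!r}: counts must be a 4 x w matrix, "
                f"got shape {self.counts.shape}"
            )
        if self.counts.shape[1] < 1:
            raise MotifParseError(f"motif {self.motif_id!r}: zero-width matrix")
        if (self.counts < 0).any():
            raise MotifParseError(f"motif {self.motif_id!r}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise MotifParseError(
                f"motif {self.motif_id!r}: a position has zero total count"
            )

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        """Highest-count base per position (ties broken in A,C,G,T order)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    @classmethod
    def from_consensus(
        cls, motif_id: str, consensus: str, weight: float = 100.0, motif_name: str | None = None
    ) -> "MotifMatrix":
        """Build a sharp motif whose count matrix puts ``weight`` on the consensus base."""
        consensus = consensus.upper()
        if not consensus or any(b not in BASE_INDEX for b in consensus):
            raise ValueError(f"consensus must be a non-empty ACGT string, got {consensus!r}")
        counts = np.zeros((4, len(consensus)))
        for j, b in enumerate(consensus):
            counts[BASE_INDEX[b], j] = weight
        return cls(motif_id, motif_name or motif_id, counts)


@dataclass
class Background:
    """An i.i.d. mononucleotide background model (probabilities for A, C, G, T)."""

    base_probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.base_probabilities, dtype=float)
        if p.shape != (4,):
            raise ValueError("background needs exactly 4 probabilities (A, C, G, T)")
        if (p <= 0).any():
            raise ValueError("background probabilities must all be positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"background probabilities sum to {p.sum()}, not 1")
        self.base_probabilities = p

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequences(cls, sequences: Iterable[str], symmetrize: bool = True) -> "Background":
        """Mononucleotide composition of a sequence set.

        With ``symmetrize`` (default) A/T and C/G are averaged so the model is
        strand-symmetric, which lets a forward-strand threshold be reused
        unchanged on the reverse-complement matrix.
        """
        counts = np.zeros(4)
        for seq in sequences:
            s = str(seq).upper()
            for i, b in enumerate(BASES):
                counts[i] += s.count(b)
        if counts.sum() == 0:
            raise ValueError("no A/C/G/T characters found in sequences")
        counts = counts + 1.0  # avoid zero-probability bases
        if symmetrize:
            at = (counts[0] + counts[3]) / 2.0
            cg = (counts[1] + counts[2]) / 2.0
            counts = np.array([at, cg, cg, at])
        return cls(counts / counts.sum())


@dataclass
class ScoringMatrix:
    """Pseudocounted log2-odds matrix with an optional calibrated match threshold.

    ``threshold`` may be ``math.inf`` as a sentinel meaning "no word can
    match" (the requested p-value is below the probability of even the single
    best word).
    """

    motif_id: str
    log_odds: np.ndarray
    pseudocount: float
    pvalue: float | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if not np.isfinite(self.log_odds).all():
            raise ValueError(f"motif {self.motif_id!r}: non-finite log-odds")

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]

    def score_word(self, word: str) -> float:
        """Log-odds score of a single w-mer (must be ACGT only)."""
        word = word.upper()
        if len(word) != self.width:
            raise ValueError(f"word length {len(word)} != motif width {self.width}")
        return float(sum(self.log_odds[BASE_INDEX[b], j] for j, b in enumerate(word)))


_JASPAR_ROW = re.compile(r"^\s*([ACGTacgt])\s*[\[|]?\s*([-0-9.eE+\s]*?)\s*\]?\s*$")


def parse_jaspar(source: str | TextIO) -> list[MotifMatrix]:
    """Parse a JASPAR-format motif library.

    Accepts the 2016+ text dialect (``>ID NAME`` header followed by four rows
    like ``A [ 3 5 0 ... ]``) and, as a lenient fallback, bare 4-row numeric
    blocks without the letter/bracket decoration.  Record order is preserved;
    when the header carries no name the id doubles as the name.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    motifs: list[MotifMatrix] = []
    header: tuple[str, str] | None = None
    rows: list[tuple[str | None, list[float]]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None and not rows:
            return
        if header is None:
            raise MotifParseError("count rows found before any '>' header")
        motif_id, motif_name = header
        if len(rows) != 4:
            raise MotifParseError(
                f"motif {motif_id!r}: expected 4 count rows, got {len(rows)}"
            )
        widths = {len(vals) for _, vals in rows}
        if len(widths) != 1:
            raise MotifParseError(f"motif {motif_id!r}: ragged row widths {sorted(widths)}")
        letters = [letter for letter, _ in rows]
        if all(l is not None for l in letters):
            if sorted(l.upper() for l in letters) != list(BASES):
                raise MotifParseError(
                    f"motif {motif_id!r}: rows must cover A, C, G, T exactly once"
                )
            counts = np.zeros((4, widths.pop()))
            for letter, vals in rows:
                counts[BASE_INDEX[letter.upper()]] = vals
        else:
            # bare block: rows taken in A, C, G, T order
            counts = np.array([vals for _, vals in rows])
        motifs.append(MotifMatrix(motif_id, motif_name, counts))
        header, rows = None, []

    for raw in source:
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            if not parts:
                raise MotifParseError("empty '>' header line")
            motif_id = parts[0]
            motif_name = parts[1].strip() if len(parts) > 1 else motif_id
            header = (motif_id, motif_name)
            continue
        m = _JASPAR_ROW.match(line)
        if m and m.group(2).strip():
            letter = m.group(1)
            values = [float(v) for v in m.group(2).split()]
        else:
            try:
                values = [float(v) for v in line.replace("[", " ").replace("]", " ").split()]
            except ValueError as exc:
                who = header[0] if header else "<no header>"
                raise MotifParseError(f"motif {who!r}: unparseable row {line!r}") from exc
            letter = None
        if not values:
            who = header[0] if header else "<no header>"
            raise MotifParseError(f"motif {who!r}: empty count row {line!r}")
        rows.append((letter, values))
    flush()
    return motifs


def to_log_odds(motif: MotifMatrix, pseudocount: float, bg: Background) -> ScoringMatrix:
    """Convert a count matrix to a pseudocounted log2-odds scoring matrix.

    Per cell: ``p_ij = (count_ij + pseudocount * bg_i) / (colsum_j + pseudocount)``
    and ``log_odds_ij = log2(p_ij / bg_i)`` (the MOODS pseudocount convention).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = motif.counts
    colsums = counts.sum(axis=0)
    probs = (counts + pseudocount * bg.base_probabilities[:, None]) / (colsums + pseudocount)
    if (probs <= 0).any():
        raise ValueError(
            f"motif {motif.motif_id!r}: zero probability cell with pseudocount 0; "
            "use a positive pseudocount"
        )
    log_odds = np.log2(probs / bg.base_probabilities[:, None])
    return ScoringMatrix(motif.motif_id, log_odds, pseudocount)


def score_distribution(sm: ScoringMatrix, bg: Background) -> tuple[np.ndarray, np.ndarray]:
    """Exact background score distribution by full enumeration.

    Returns ``(scores, probabilities)`` with scores ascending and unique.
    Only feasible for small widths; used for threshold calibration at
    w <= EXACT_ENUMERATION_MAX_WIDTH and by the test oracles.
    """
    scores = np.zeros(1)
    probs = np.ones(1)
    for j in range(sm.width):
        scores = np.add.outer(scores, sm.log_odds[:, j]).ravel()
        probs = np.multiply.outer(probs, bg.base_probabilities).ravel()
    uniq, inverse = np.unique(scores, return_inverse=True)
    grouped = np.bincount(inverse, weights=probs, minlength=uniq.size)
    return uniq, grouped


def _threshold_from_distribution(scores: np.ndarray, probs: np.ndarray, pval: float) -> float:
    # scores ascending; tail[i] = P(score >= scores[i]) is non-increasing in i
    tails = np.cumsum(probs[::-1])[::-1]
    ok = np.nonzero(tails <= pval + 1e-15)[0]
    if ok.size == 0:
        return math.inf
    return float(scores[ok[0]])


def _dp_threshold(sm: ScoringMatrix, bg: Background, pval: float) -> float:
    """Threshold via DP over scores discretized to 1/DP_SCALE bits.

    Scores are rounded to the nearest quantum; the returned threshold is
    shifted down by one quantum so that borderline matches are admitted
    rather than dropped.
    """
    q = np.rint(sm.log_odds * DP_SCALE).astype(np.int64)
    offsets = q.min(axis=0)
    span = int((q.max(axis=0) - offsets).sum())
    dist = np.zeros(span + 1)
    dist[0] = 1.0
    filled = 0
    for j in range(sm.width):
        col = q[:, j] - offsets[j]
        width_j = int(col.max())
        new = np.zeros(filled + width_j + 1)
        for i in range(4):
            new[col[i] : col[i] + filled + 1] += bg.base_probabilities[i] * dist[: filled + 1]
        filled += width_j
        dist = new
    support = np.nonzero(dist > 0)[0]
    t_int = _threshold_from_distribution(
        support.astype(float), dist[support], pval
    )
    if math.isinf(t_int):
        return math.inf
    return (t_int + float(offsets.sum())) / DP_SCALE - 1.0 / DP_SCALE


def pvalue_threshold(sm: ScoringMatrix, bg: Background, pval: float) -> float:
    """Minimal score T with P_bg(score of a random w-mer >= T) <= pval.

    The random w-mer is drawn i.i.d. from ``bg``.  If even the single best
    word has tail mass above ``pval``, returns ``math.inf`` (nothing can
    match).  Exact enumeration for widths up to 10, discretized DP beyond.
    """
    if not (0.0 < pval <= 1.0):
        raise ValueError(f"pval must be in (0, 1], got {pval}")
    if sm.width <= EXACT_ENUMERATION_MAX_WIDTH:
        scores, probs = score_distribution(sm, bg)
        return _threshold_from_distribution(scores, probs, pval)
    return _dp_threshold(sm, bg, pval)


def reverse_complement(sm: ScoringMatrix) -> ScoringMatrix:
    """Scoring matrix for the reverse-complement strand.

    Rows are swapped A<->T and C<->G and columns reversed, so scoring a word
    under the result equals scoring its reverse complement under the
    original.  The threshold carries over unchanged, which is exact whenever
    the background is strand-symmetric (the default uniform background is).
    """
    return replace(sm, log_odds=sm.log_odds[::-1, ::-1].copy())


def make_scoring_matrix(
    motif: MotifMatrix,
    pseudocount: float = 0.001,
    pval: float = 0.001,
    bg: Background | None = None,
) -> ScoringMatrix:
    """Convenience: log-odds conversion plus p-value threshold calibration."""
    bg = bg or Background.uniform()
    sm = to_log_odds(motif, pseudocount, bg)
    sm.pvalue = pval
    sm.threshold = pvalue_threshold(sm, bg, pval)
    return sm
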