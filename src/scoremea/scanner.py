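"""Motif scanning.

Slides each calibrated scoring matrix over every sequence on both strands
and records windows scoring at or above the motif's threshold.  Windows
containing any character outside A/C/G/T (e.g. N) never match; soft-masked
lowercase bases are scanned as their uppercase equivalents.  The quantity
the enrichment model consumes is presence: "sequence contains >= 1 hit on
either strand", a boolean per sequence x motif; per-pair hit counts are
retained for reporting only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .motifs import BASE_INDEX, ScoringMatrix, reverse_complement
from .seqio import ScoredSequence


@dataclass
class MotifHit:
    """One match window; position is the forward-strand window start."""

    sequence_name: str
    motif_id: str
    position: int
    strand: str
    score: float


@dataclass
class PresenceMatrix:
    """Boolean sequence x motif indicator plus per-pair hit counts."""

    sequence_names: list[str]
    motif_ids: list[str]
    present: np.ndarray
    hit_counts: np.ndarray

    def presence_of(self, motif_id: str) -> np.ndarray:
        return self.present[:, self.motif_ids.index(motif_id)]


_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(sequence: str, mask_lowercase: bool = False) -> np.ndarray:
    """Map a sequence to int codes A=0 C=1 G=2 T=3; anything else (or
    lowercase when ``mask_lowercase``) becomes -1 and blocks any window
    covering it."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr].copy()
    if mask_lowercase:
        codes[(arr >= 97) & (arr <= 122)] = -1
    return codes


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Scores of all width-w windows; windows with a non-ACGT char get -inf."""
    w = log_odds.shape[1]
    n_windows = codes.size - w + 1
    if n_windows <= 0:
        return np.empty(0)
    bad = (codes < 0).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(bad)])
    invalid = (cum[w:] - cum[:-w]) > 0
    safe = np.where(codes < 0, 0, codes)
    scores = np.zeros(n_windows)
    for j in range(w):
        scores += log_odds[safe[j : j + n_windows], j]
    scores[invalid] = -math.inf
    return scores


def scan_sequence(
    seq: ScoredSequence | str,
    sm: ScoringMatrix,
    mask_lowercase: bool = False,
) -> list[MotifHit]:
    """All hits of one motif in one sequence, both strands.

    A minus-strand hit is reported at the forward-strand start of its window.
    Overlapping and double-strand hits are all reported.  Requires a
    calibrated threshold; ties at exactly the threshold count as matches.
    """
    if sm.threshold is None:
        raise ValueError(f"motif {sm.motif_id!r}: threshold not set")
    if isinstance(seq, str):
        seq = ScoredSequence("<anonymous>", seq, 0.0)
    if math.isinf(sm.threshold):
        return []
    codes = encode_sequence(seq.sequence, mask_lowercase=mask_lowercase)
    hits: list[MotifHit] = []
    for strand, matrix in (("+", sm), ("-", reverse_complement(sm))):
        scores = _window_scores(codes, matrix.log_odds)
        for pos in np.nonzero(scores >= sm.threshold)[0]:
            hits.append(
                MotifHit(seq.name, sm.motif_id, int(pos), strand, float(scores[pos]))
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _scan_one_motif(
    encoded: list[np.ndarray], sm: ScoringMatrix
) -> np.ndarray:
    counts = np.zeros(len(encoded), dtype=np.int64)
    if sm.threshold is None:
        raise ValueError(f"motif {sm.motif_id!r}: threshold not set")
    if math.isinf(sm.threshold):
        return counts
    rc = reverse_complement(sm)
    for i, codes in enumerate(encoded):
        n = 0
        for matrix in (sm, rc):
            scores = _window_scores(codes, matrix.log_odds)
            if scores.size:
                n += int(np.count_nonzero(scores >= sm.threshold))
        counts[i] = n
    return counts


def build_presence_matrix(
    sequences: Sequence[ScoredSequence],
    scoring_matrices: Sequence[ScoringMatrix],
    jobs: int = 1,
    mask_lowercase: bool = False,
) -> PresenceMatrix:
    """Presence/hit-count matrix over all sequence x motif pairs.

    Deterministic regardless of ``jobs``: parallelism is per motif and
    results are assembled in library order.
    """
    names = [s.name for s in sequences]
    if len(set(names)) != len(names):
        raise ValueError("sequence names must be unique")
    ids = [sm.motif_id for sm in scoring_matrices]
    if len(set(ids)) != len(ids):
        raise ValueError("motif ids must be unique")
    encoded = [encode_sequence(s.sequence, mask_lowercase) for s in sequences]
    if jobs == 1:
        columns = [_scan_one_motif(encoded, sm) for sm in scoring_matrices]
    else:
        columns = Parallel(n_jobs=jobs)(
            delayed(_scan_one_motif)(encoded, sm) for sm in scoring_matrices
        )
    hit_counts = (
        np.stack(columns, axis=1) if columns else np.zeros((len(names), 0), dtype=np.int64)
    )
    return PresenceMatrix(names, ids, hit_counts > 0, hit_counts)


def scan_all(
    sequences: Sequence[ScoredSequence],
    scoring_matrices: Sequence[ScoringMatrix],
    mask_lowercase: bool = False,
) -> list[MotifHit]:
    """Full hit table across all sequences and motifs (the --scan output)."""
    hits: list[MotifHit] = []
    for sm in scoring_matrices:
        for seq in sequences:
            hits.extend(scan_sequence(seq, sm, mask_lowercase))
    return hits


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.sequence_name, h.motif_id, h.position, h.strand, h.score) for h in hits],
        columns=["sequence_name", "motif_id", "position", "strand", "score"],
    )
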