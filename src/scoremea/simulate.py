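"""Synthetic scored-sequence datasets with known ground truth.

Generates sets of random DNA sequences with standard-normal activity
scores, a per-sequence GC fraction that can be made to correlate with the
score (the composition-vs-score confound this package exists to control
for), and planted motifs whose presence follows a specified logistic model
in score and GC.  When a motif is planted in a sequence its exact consensus
word is inserted at a uniformly chosen position, guaranteeing the scanner
detects it at the default per-window p-value, so the recorded truth table
stays aligned with scan output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .motifs import BASES, MotifMatrix
from .seqio import ScoredSequence

#: consensus words for the standard confound study fixture: a GC-balanced
#: "true" signal motif and a GC-free decoy whose presence tracks composition
TRUE_MOTIF_CONSENSUS = "ATGCGTCAAC"
DECOY_MOTIF_CONSENSUS = "AATATTTAAT"
NULL_MOTIF_CONSENSUSES = ("ACCGTTAGCA", "CAGTAGTCAG", "TACGATCGTA")


@dataclass
class PlantedMotif:
    """A motif planted with a logistic presence model.

    Presence is Bernoulli with logit = base_logit + beta_score * z_score +
    beta_gc * z_gc, where z_score and z_gc are the standardized sequence
    score and latent GC fraction.  A pure confounder (decoy) has
    beta_score = 0 and beta_gc != 0.
    """

    motif: MotifMatrix
    beta_score: float
    beta_gc: float = 0.0
    base_logit: float = -1.0


@dataclass
class SimulationSpec:
    n_sequences: int = 2000
    length: int = 200
    seed: int = 0
    gc_fraction: float = 0.5
    gc_score_correlation: float = 0.0
    gc_sd: float = 0.1
    planted: list[PlantedMotif] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise ValueError("n_sequences and length must be positive")
        if not (-1.0 <= self.gc_score_correlation <= 1.0):
            raise ValueError("gc_score_correlation must be in [-1, 1]")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must be in (0, 1)")


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def simulate_scored_sequences(
    spec: SimulationSpec,
) -> tuple[list[ScoredSequence], pd.DataFrame]:
    """Draw a scored sequence set and its ground-truth table.

    Scores are standard normal.  Latent GC is ``gc_fraction + gc_sd * (rho *
    z_score + sqrt(1 - rho^2) * noise)`` clipped to [0.05, 0.95], giving an
    empirical GC-score correlation close to ``rho`` when clipping is rare.
    Bases are drawn i.i.d. at the per-sequence GC.  For each planted motif,
    presence is drawn from its logistic model and, when present, the
    consensus word is inserted at a uniform position (positions for multiple
    motifs in one sequence are drawn without overlap).

    Returns the records and a truth table with one row per sequence: score,
    latent gc, and per planted motif a presence flag and insertion position
    (-1 when absent).
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_sequences, spec.length
    for pm in spec.planted:
        if pm.motif.width > L:
            raise ValueError(
                f"motif {pm.motif.motif_id!r} (width {pm.motif.width}) longer than "
                f"sequence length {L}"
            )
    scores = rng.standard_normal(n)
    rho = spec.gc_score_correlation
    noise = rng.standard_normal(n)
    z_score = _standardize(scores) if n > 1 else np.zeros(n)
    gc = np.clip(
        spec.gc_fraction + spec.gc_sd * (rho * z_score + np.sqrt(1.0 - rho**2) * noise),
        0.05,
        0.95,
    )
    z_gc = _standardize(gc) if n > 1 else np.zeros(n)

    presence: dict[str, np.ndarray] = {}
    for pm in spec.planted:
        logit = pm.base_logit + pm.beta_score * z_score + pm.beta_gc * z_gc
        p = 1.0 / (1.0 + np.exp(-logit))
        presence[pm.motif.motif_id] = rng.random(n) < p

    records: list[ScoredSequence] = []
    positions: dict[str, np.ndarray] = {
        pm.motif.motif_id: np.full(n, -1, dtype=int) for pm in spec.planted
    }
    base_probs_cols = np.empty((n, 4))
    base_probs_cols[:, 0] = (1.0 - gc) / 2.0  # A
    base_probs_cols[:, 1] = gc / 2.0          # C
    base_probs_cols[:, 2] = gc / 2.0          # G
    base_probs_cols[:, 3] = (1.0 - gc) / 2.0  # T
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    for i in range(n):
        cum = np.cumsum(base_probs_cols[i])
        draws = rng.random(L)
        codes = np.searchsorted(cum, draws)
        seq = np.frombuffer(base_arr[codes].tobytes(), dtype=np.uint8).copy()
        occupied: list[tuple[int, int]] = []
        for pm in spec.planted:
            if not presence[pm.motif.motif_id][i]:
                continue
            w = pm.motif.width
            for _ in range(200):  # rejection sampling keeps insertions disjoint
                pos = int(rng.integers(0, L - w + 1))
                if all(pos + w <= s or pos >= e for s, e in occupied):
                    break
            else:
                raise RuntimeError("could not place motif without overlap")
            word = pm.motif.consensus.encode()
            seq[pos : pos + w] = np.frombuffer(word, dtype=np.uint8)
            occupied.append((pos, pos + w))
            positions[pm.motif.motif_id][i] = pos
        records.append(ScoredSequence(f"seq_{i:05d}", seq.tobytes().decode(), float(scores[i])))

    truth = pd.DataFrame({"name": [r.name for r in records], "score": scores, "gc": gc})
    for pm in spec.planted:
        mid = pm.motif.motif_id
        truth[f"present_{mid}"] = presence[mid]
        truth[f"position_{mid}"] = positions[mid]
    return records, truth


def confound_motif_library() -> list[MotifMatrix]:
    """The five-motif library for the confound study: true signal, GC-tracking
    decoy, and three unplanted nulls."""
    lib = [
        MotifMatrix.from_consensus("TRUE_MOTIF", TRUE_MOTIF_CONSENSUS),
        MotifMatrix.from_consensus("DECOY_GC", DECOY_MOTIF_CONSENSUS),
    ]
    lib += [
        MotifMatrix.from_consensus(f"NULL_{i + 1}", cons)
        for i, cons in enumerate(NULL_MOTIF_CONSENSUSES)
    ]
    return lib


def gc_confound_spec(seed: int, n_sequences: int = 1000, length: int = 150) -> SimulationSpec:
    """Study conditions for the composition-confound experiment.

    GC content correlates with score at -0.7, i.e. high-scoring sequences
    are AT-rich.  The true motif carries beta_score = 1 with no composition
    dependence; the GC-poor decoy carries beta_gc = -2.5 and no score
    dependence, so its presence tracks AT-richness — the same direction as
    its chance background matches, which an AT-rich word inevitably
    accumulates in AT-rich sequences.  Without covariates the decoy's
    marginal score association therefore exceeds the true motif's;
    dinucleotide covariates absorb the composition signal and restore the
    true motif's precedence.
    """
    lib = confound_motif_library()
    return SimulationSpec(
        n_sequences=n_sequences,
        length=length,
        seed=seed,
        gc_fraction=0.5,
        gc_score_correlation=-0.7,
        planted=[
            PlantedMotif(lib[0], beta_score=1.0),
            PlantedMotif(lib[1], beta_score=0.0, beta_gc=-2.5),
        ],
    )
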