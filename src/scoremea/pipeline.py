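"""End-to-end enrichment run: scan -> covariates -> regression.

The glue used by both the command-line entry point and the bootstrap
harness, so that every path through the package runs the identical
computation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .covariates import CovariateTable, PCAReduction, build_covariate_table, pca_reduce
from .enrichment import EnrichmentResult, enrich_all
from .evaluation import EnrichmentConfig
from .motifs import Background, MotifMatrix, make_scoring_matrix
from .scanner import MotifHit, PresenceMatrix, build_presence_matrix, scan_all
from .seqio import ScoredSequence


@dataclass
class EnrichmentRun:
    """Everything a full run produced, for reporting and inspection."""

    results: list[EnrichmentResult]
    presence: PresenceMatrix
    covariate_table: CovariateTable | None
    reduction: PCAReduction | None
    hits: list[MotifHit] | None
    n_covariate_columns: int


def run_enrichment(
    sequences: Sequence[ScoredSequence],
    motifs: Sequence[MotifMatrix],
    config: EnrichmentConfig | None = None,
    user_covariates: pd.DataFrame | None = None,
    bg: Background | None = None,
    collect_hits: bool = False,
) -> EnrichmentRun:
    """Scan sequences against the motif library and fit the enrichment model.

    ``config`` carries the scan pseudocount and per-window p-value, the
    k-mer order for composition covariates (0 = none) and the PCA variance
    target.  User covariates pass through the PCA untouched.
    """
    config = config or EnrichmentConfig()
    bg = bg or Background.uniform()
    sms = [make_scoring_matrix(m, config.pcount, config.pval, bg) for m in motifs]
    presence = build_presence_matrix(sequences, sms, jobs=config.jobs)

    table: CovariateTable | None = None
    reduction: PCAReduction | None = None
    if config.kmer >= 1 or user_covariates is not None:
        raw = build_covariate_table(sequences, config.kmer, user_covariates)
        table, reduction = pca_reduce(raw, config.variance_target)

    names = {m.motif_id: m.motif_name for m in motifs}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = enrich_all(
            presence, sequences, table, sort_mode=config.sort_mode, motif_names=names
        )
    hits = scan_all(sequences, sms) if collect_hits else None
    n_cols = len(table.column_names) if table is not None else 0
    return EnrichmentRun(results, presence, table, reduction, hits, n_cols)
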