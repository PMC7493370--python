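#!/usr/bin/env python
"""Full-dataset reproduction harness (requires downloaded data files).

The complete analyses behind the published figures run on files that must
be obtained separately (they are far too large to ship here):

  * the scored FASTA of 20,087 differentially acetylated peak sequences
    ("deseq2-ifnb.diff-peaks.scored.fa" from the original tool's data
    directory), and
  * the JASPAR 2018 CORE vertebrate non-redundant motif library
    ("jaspar.txt", 579 motifs, from the JASPAR 2018 archive downloads).

Given those two files this script reruns the enrichment with and without
dinucleotide covariates and reports the ranks of the IRF9 and STAT1::STAT2
motifs, the number of PCA components kept, and (optionally) the bootstrap
rank comparison for STAT1::STAT2.

Usage:
    python scripts/reproduce_published_datasets.py scored.fa jaspar.txt \
        [--bootstrap B] [--seed 1] [--jobs 4]
"""
from __future__ import annotations

import argparse

import numpy as np

from scoremea.evaluation import (
    EnrichmentConfig,
    bootstrap_rank_distribution,
    paired_rank_comparison,
    percentile_rank_accuracy,
    rank_of_motif,
    ranked_from_results,
)
from scoremea.motifs import parse_jaspar
from scoremea.pipeline import run_enrichment
from scoremea.seqio import read_scored_fasta

TARGET_NAMES = ("IRF9", "STAT1::STAT2")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("scored_fasta")
    parser.add_argument("jaspar")
    parser.add_argument("--bootstrap", type=int, default=0,
                        help="bootstrap replicates for the rank comparison (0 = skip)")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--jobs", type=int, default=1)
    args = parser.parse_args()

    sequences = read_scored_fasta(args.scored_fasta)
    motifs = parse_jaspar(open(args.jaspar))
    print(f"{len(sequences)} sequences, {len(motifs)} motifs")
    by_name = {m.motif_name: m.motif_id for m in motifs}
    targets = {n: by_name[n] for n in TARGET_NAMES if n in by_name}

    for kmer in (2, 0):
        config = EnrichmentConfig(kmer=kmer, pcount=0.01, pval=0.001, jobs=args.jobs)
        run = run_enrichment(sequences, motifs, config)
        label = "with dinucleotide covariates" if kmer else "without covariates"
        n_pc = run.reduction.n_components if run.reduction else 0
        print(f"\n--kmer {kmer} ({label}): {n_pc} PCA components")
        ranked = ranked_from_results(run.results, len(motifs))
        for name, mid in targets.items():
            rank = rank_of_motif(ranked, mid)
            pra = percentile_rank_accuracy(rank, len(motifs))
            print(f"  {name}: rank {rank}/{len(motifs)} (PRA {pra})")

    if args.bootstrap and "STAT1::STAT2" in targets:
        mid = targets["STAT1::STAT2"]
        ranks = {}
        for kmer in (2, 0):
            config = EnrichmentConfig(kmer=kmer, pcount=0.01, pval=0.001, jobs=args.jobs)
            ranks[kmer] = bootstrap_rank_distribution(
                sequences, motifs, config, mid, args.bootstrap, args.seed
            )
            print(f"bootstrap mean rank (kmer={kmer}): {np.mean(ranks[kmer]):.1f}")
        stat, p = paired_rank_comparison(ranks[2], ranks[0])
        print(f"paired Wilcoxon signed-rank: statistic {stat}, p {p:.3g}")


if __name__ == "__main__":
    main()
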