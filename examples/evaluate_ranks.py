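"""Evaluation utilities: PRA, Fisher exact flags, bootstrap rank stability.

Shows the percentile-rank-accuracy computation on published-style rank
pairs, a warning-flag contingency test, and a small bootstrap of a target
motif's rank with and without composition covariates.
"""
import warnings

warnings.simplefilter("ignore")

import numpy as np

from scoremea import (
    ContingencyTable2x2,
    EnrichmentConfig,
    bootstrap_rank_distribution,
    fisher_exact_2x2,
    paired_rank_comparison,
    percentile_rank_accuracy,
    simulate_scored_sequences,
)
from scoremea.simulate import confound_motif_library, gc_confound_spec

print("Percentile rank accuracy (rank out of a 579-motif library):")
for rank in (564, 466, 578):
    print(f"  rank {rank}/579 -> PRA {percentile_rank_accuracy(rank, 579)}")

odds, p = fisher_exact_2x2(ContingencyTable2x2(8, 28, 18, 528))
print(f"\nWarning-flag 2x2 (8, 28, 18, 528): odds ratio {odds:.2f}, "
      f"two-sided Fisher p {p:.2g}")

sequences, _ = simulate_scored_sequences(gc_confound_spec(seed=1, n_sequences=500, length=120))
library = confound_motif_library()
ranks = {}
for kmer in (2, 0):
    config = EnrichmentConfig(kmer=kmer, pcount=0.01, pval=0.001)
    ranks[kmer] = bootstrap_rank_distribution(
        sequences, library, config, "TRUE_MOTIF", B=30, seed=7
    )
    print(f"\nbootstrap ranks of TRUE_MOTIF (kmer={kmer}): "
          f"mean {np.mean(ranks[kmer]):.1f} of {len(library)}")
stat, p = paired_rank_comparison(ranks[2], ranks[0])
print(f"paired Wilcoxon signed-rank on the two rank vectors: p = {p:.3g}")
print(
    "\nHigher rank = more positively enriched. The bootstrap shows the true\n"
    "motif ranks consistently higher once composition covariates are included."
)
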