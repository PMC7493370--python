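"""The headline capability: composition covariates rescue a confounded call.

Simulates 1000 scored sequences in which GC content correlates with the
activity score (corr -0.7).  A GC-balanced "true" motif is planted with a
genuine score effect (log-odds slope 1.0); a GC-free decoy is planted with
no score effect but strong composition tracking.  Enrichment is run twice:
without covariates (--kmer 0 conditions) the decoy spuriously tops the
table; with dinucleotide covariates (--kmer 2) the true motif is restored
to the top.
"""
import warnings

warnings.simplefilter("ignore")

from scoremea import EnrichmentConfig, run_enrichment, simulate_scored_sequences
from scoremea.simulate import confound_motif_library, gc_confound_spec

sequences, truth = simulate_scored_sequences(gc_confound_spec(seed=0))
library = confound_motif_library()
print(f"{len(sequences)} sequences, {len(library)} motifs "
      f"(GC-score correlation {truth['gc'].corr(truth['score']):.2f})")

for kmer in (0, 2):
    run = run_enrichment(
        sequences, library, EnrichmentConfig(kmer=kmer, pcount=0.01, pval=0.001)
    )
    label = "no covariates" if kmer == 0 else "dinucleotide covariates"
    print(f"\n--kmer {kmer} ({label}):")
    print(f"{'motif':<12}{'coef':>8}{'adj_p':>12}{'present':>9}")
    for r in run.results:
        print(f"{r.motif_id:<12}{r.coefficient:>8.3f}{r.adjusted_p:>12.2e}{r.n_present:>9}")

print(
    "\nThe score coefficient is the change in log-odds of containing the motif\n"
    "per standard deviation of score. Without covariates the composition-\n"
    "tracking decoy out-ranks the truly score-associated motif; the PCA-reduced\n"
    "dinucleotide covariates absorb the composition signal and reverse that."
)
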