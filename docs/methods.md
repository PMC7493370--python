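# Methods

## Model

For each motif *m* in the library, let *p* be the probability that a
sequence contains *m* — a boolean event, "at least one match window on
either strand at the calibrated threshold". With *x_s* the sequence's
activity score and *x_c* the reduced composition covariates, the model is

    log(p / (1 − p)) = β₀ + β_s·x_s + Σ_c β_c·x_c

fitted by maximum likelihood, one independent regression per motif. The
outcome is deliberately boolean while the score stays continuous: this
hybrid of set-based and score-based reasoning keeps the model applicable
to arbitrary score types (fold changes, signal ratios, composite scores)
without assuming that motif *strength* scales with score. All predictors
(score, components, user covariates) are standardized jointly to zero mean
and unit sample (n−1) standard deviation before fitting, so reported
coefficients are per-standard-deviation log-odds changes and are
dataset-relative. Significance of β_s is a two-sided Wald test (normal
reference for β̂_s / se); p-values are Benjamini–Hochberg corrected across
the motifs whose fit succeeded.

## Scanning and threshold calibration

Count matrices (JASPAR text format) become log₂-odds matrices via the
pseudocount convention `p_ij = (c_ij + pcount·bg_i) / (colsum_j + pcount)`,
`lo_ij = log2(p_ij / bg_i)`. The default background is uniform; an option
estimates it from the input's mononucleotide composition, symmetrized
(A/T and C/G averaged) so one threshold serves both strands. The original
scanning stack this package replaces delegates to an external scanner
whose exact background and threshold algorithm are not published; the
contract implemented here is the standard published semantics of such
scanners and should be read as an interpretation.

Per motif, the match threshold T is the minimal achievable score such that
a random background w-mer scores ≥ T with probability ≤ the chosen p-value
(default 0.001). For widths ≤ 10 the full 4^w score distribution is
enumerated exactly; for wider motifs a dynamic-programming convolution
over scores discretized to 1/1000 bit is used, and the resulting threshold
is shifted down by one quantum so discretization can only admit borderline
matches, never drop them. If even the best word's tail mass exceeds the
p-value (unavoidable for short motifs: a width-4 motif's best word already
has probability ≥ 4⁻⁴ ≈ 0.004 under a uniform background), the sentinel
+∞ is returned and the motif matches nothing — surfaced in the results as
a failed fit rather than silently absent.

Matching uses ≥ (ties at T match). Windows containing any non-ACGT
character never match. Lowercase (soft-masked) bases scan as uppercase by
default, with an optional mask flag. Overlapping hits and same-window
hits on both strands are all reported in the hit table; presence collapses
them to one boolean, so this choice cannot affect enrichment.

## Composition covariates

Per-sequence k-mer frequencies are counted on the forward strand over
windows free of non-ACGT characters, normalized by the number of valid
windows. Defaults follow the tool conventions: `--kmer 2` (dinucleotides,
16 columns), `--kmer 1` for mononucleotides, `--kmer 0` for none. K-mer
frequencies are strongly multicollinear, which destabilizes logistic
regression; they are therefore mean-centered (not variance-scaled, since
the columns share units) and replaced by the minimal set of leading
principal components whose cumulative explained variance reaches 99 %.
Component signs are fixed (largest-magnitude loading positive) so runs
are bit-reproducible. User covariates are standardized and entered into
the regression but deliberately not PCA-mixed with the k-mer block: the
published analyses interpret individual experimental covariates (e.g. a
DNase-coverage column) directly, which mixing would destroy. Both this
pass-through and the centering-only choice are interpretations where the
original description is silent.

## Fitting, separation, and failure policy

Fits use Newton iterations (statsmodels logistic regression), at most 100
iterations, tolerance 1e-8, standard errors from the inverse observed
information. A motif whose presence vector is all-true or all-false, or
whose fit diverges (any |coefficient| > 15 on the standardized scale, or a
perfect-separation error), is flagged `separation`; any other
non-convergence is flagged `nonconvergence`. Flagged motifs carry no
p-value and are excluded from the BH denominator — adjusted p-values are
therefore relative to the successfully fitted motifs, not the full
library. No penalized fallback is attempted; inference stays plain
MLE/Wald throughout. Sorting is by coefficient descending (or
|coefficient| with `--sortabs`), ties broken by motif id for determinism.

## Evaluation machinery

*Percentile rank accuracy.* PRA = 100·R_k/N where R_k is the target
motif's rank counted from the bottom of the enrichment table (best score →
rank N), ties all taking the lowest rank of the tied block, absent motifs
rank 0. Display rounding is round-half-away-from-zero to one decimal,
which reproduces the published worked values 97.4, 80.5, 99.8, 95.9 and
93.3 from their rank pairs; the single published pair 577/579 → "99.6" is
inconsistent with any one rounding convention (577/579 = 99.654 → 99.7
here) and is documented rather than chased.

*Bootstrap rank stability.* Sequences are resampled with replacement
(same size), covariate reduction and regression rerun per replicate, and
the target motif's rank recorded. The scan is performed once and replicate
presence rows re-indexed — exact, because resampled sequences are copies.
Seeded and bit-reproducible.

*Paired comparison.* Two rank vectors are compared by the two-sided
Wilcoxon signed-rank test (zero differences dropped; exact null ≤ 25
informative pairs, normal approximation with continuity correction
beyond). The signed-rank variant was chosen because bootstrap replicates
are paired; the original description says only "Wilcoxon".

*Flag enrichment.* 2×2 tables are tested with the conditional two-sided
Fisher exact test; the reported odds ratio is the sample ratio ad/bc.

## Synthetic data generator

The generator emulates the one structural feature of real scored
regulatory sequence sets that matters to this method: a continuous score
whose distribution is entangled with sequence composition. Scores are
standard normal; each sequence's latent GC fraction is
`gc₀ + σ_gc·(ρ·z_score + √(1−ρ²)·ε)` clipped to [0.05, 0.95] (defaults
gc₀ = 0.5, σ_gc = 0.1), giving empirical GC–score correlation within
±0.05 of ρ at n ≥ 2000; bases are drawn i.i.d. at that GC. Planted motifs
have presence drawn Bernoulli with logit = base_logit + β_score·z_score +
β_gc·z_gc (base_logit default −1, ≈ 27 % presence); when present, the
exact consensus word is inserted at a uniform position (insertions in one
sequence kept disjoint by rejection). Inserting the exact consensus rather
than a PWM-sampled word is a deliberate simplification guaranteeing the
scanner detects every planted instance, keeping the truth table aligned
with scan output.

The confound study conditions (`gc_confound_spec`): 1000 sequences of
length 150, GC–score correlation −0.7, a GC-balanced 10-mer "true" motif
with β_score = 1, and a GC-free 10-mer decoy with β_score = 0,
β_gc = −2.5, in a library padded with three unplanted null motifs. The
signs are chosen so the decoy's planted composition-tracking and its
inevitable chance background matches (an AT-rich word matches AT-rich
sequences far more often; ≈ 0.2 extra presences per sequence at the
default scan p-value) point the same way — the realistic mechanism by
which AT-rich motifs spuriously top uncorrected enrichment tables. The
magnitude 2.5 comes from an attenuation argument: the decoy's marginal
score slope ≈ β_gc·ρ shrunk by logistic noise attenuation ≈ 1.2, safely
above the true motif's ≈ 0.7 (itself diluted by chance matches), while
with covariates the decoy's residual slope falls to ≈ 0.2.

What passing these tests does **not** show about real data: sequences here
are i.i.d. at a per-sequence GC with no CpG islands, repeats, or
positional structure; scores are exactly normal; planted matches are
exact-consensus. Real covariate structure is richer, so the 99 % PCA cut
may keep different component counts and real effect sizes are attenuated
by inexact motif instances.

## Problem sizes and numerical choices

The shipped tests run at desk scale chosen to keep the statistical checks
sharp but cheap: threshold calibration is verified against full 4^w
enumeration for 25 random matrices of width ≤ 8; scanning against naive
rescoring on 50 random 200-mers × 10 motifs; the regression against an
independent BFGS likelihood maximizer (tolerance 1e-4) on 20 random
designs; Wald null calibration over 200 replicates at n = 1000 (expected
false-positive rate 0.05, accepted band [0.03, 0.07]); planted-effect
recovery (β = 1, n = 2000, tolerance ±0.2) on the generator's truth
presence — the scan-level integration is covered by the rank-based
confound-rescue check over 50 seeds, which is robust to the presence
dilution that per-window p = 0.001 scanning necessarily adds on 150–200 bp
sequences (≈ 0.73 attenuation of the planted slope in the recovery
conditions, per the logistic marginal-slope calculation). PRA arithmetic
uses decimal round-half-away; BH uses the step-up procedure; PCA
minimality is checked against an eigendecomposition oracle at tolerance
1e-12 on the ratios.

## Known limitations

- Presence is boolean: partial or degenerate motif matches below the
  threshold contribute nothing, which loses power when binding is
  mediated by non-canonical sites.
- No penalized regression: motifs that separate perfectly (typically
  very rare or ubiquitous ones) are flagged and dropped rather than
  shrunk.
- The scanner's background is i.i.d. mononucleotide; higher-order
  backgrounds, MEME/TRANSFAC motif formats, gapped k-mers, and positional
  (centrality) enrichment are out of scope.
- Coefficients are on the standardized-predictor scale and are not
  comparable across datasets with different score distributions.
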