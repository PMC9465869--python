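# Methods

## Scope and model

`clonotrace` analyses bulk TRB repertoires at the clone level: a clone is
the set of reads sharing one CDR3 amino-acid sequence. This identity is
deliberately V/J-agnostic — V and J calls are carried as annotation and
blanked when merged rows disagree, but never influence matching across
samples. Rows with empty CDR3s, non-positive counts, or ambiguity codes
(B, J, O, U, X, Z) are skipped and tallied per reason; stop-codon-containing
(non-productive) CDR3s are retained by default, with a `drop_nonproductive`
flag, because the upstream platform's productivity call is not re-derived
here and excluding them silently would change overlap statistics.

## Depth normalization

All cross-sample count comparisons first downsample every repertoire of the
compared set to the set's minimum depth. Sampling is without replacement
from the multiset of reads (one multivariate-hypergeometric draw), which
preserves integer counts, never inflates a clone, and hits the target depth
exactly; clones reduced to zero are removed. Draws are seeded and clone
keys are sorted before drawing, so results are reproducible and independent
of dictionary order. Rarefaction curves and replicate-averaged rarefaction
are out of scope: one seeded draw is used, and the seed is part of every
downstream function signature.

## Diversity and clonality

Richness (unique clones at the comparison depth) is the primary diversity
readout, with Shannon entropy (nats) reported alongside — which of the two
a given published "diversity" panel used is often unstated, so both are
emitted. Clonality is 1 − H/ln R, the standard immunosequencing
normalization; the degenerate monoclonal case (R = 1, H/ln R = 0/0) is
defined as clonality 1, and tiny negative round-off for perfectly even
repertoires is clipped to 0.

## Expansion testing

For a depth-matched pair (reference, comparison), every clone present in
either sample is tested with a two-sided Fisher exact test on
[clone reads vs all other reads] × [reference vs comparison], minimum-
likelihood convention, followed by Benjamini–Hochberg adjustment over all
clones of that pair (no independent filtering, no pooling across patients).
Repertoire studies commonly run this step through edgeR's negative-
binomial machinery; after exact depth matching of a single biological pair
there is no replicate dispersion to estimate, and the exact conditional
test is the assumption-free choice — the NB exact test reduces toward it
as dispersion → 0. This substitution is deliberate and validated:
the packaged Fisher route is checked against a brute-force hypergeometric
enumeration oracle (agreement ≤ 1e-9 over exhaustive small tables and a
seeded sweep of tables with margins up to 200), its type-I error under a
null simulation is ≤ 0.07 (conservative, as expected for a discrete exact
test), and 64-fold spike-ins are recovered with recall ≥ 0.9.

Fold change is log₂((alt + 0.5)/(ref + 0.5)). Base 2 is the differential-
expression convention and makes the "log FC > 5" volcano threshold a 32-fold
change; the 0.5 pseudocount keeps clones absent from one sample finite
(0 → 64 reads gives log₂ 129 ≈ 7.0). Tiers follow the volcano coloring:
*nominal* = log₂ FC > 5 and p < 0.05; *significant* additionally requires
BH-adjusted p < 0.05, so the significant set is nested in the nominal set.
Clones with any read in the patient's baseline sample are filtered out
before a clone may be called vaccine-enriched; the filter is a pure set
operation and removes deliberately leaked spikes with certainty.

## Tracking

"Detected" means count ≥ 1 after depth matching — the most permissive
reading, matching how single clones are reported as "detected" in biopsy
panels; no abundance threshold is imposed. Samples are depth-matched
within each compartment (PBMC and tumor separately), since blood and tumor
libraries differ systematically in depth and the fractions are only ever
compared within a compartment. Timepoints sort canonically
(baseline first, then weekN numerically), so tracking output is invariant
to input order. Tracked clones are ranked by the log₂ FC of their
nominating enrichment result (rank 1 = largest).

Persisting intratumoral clones (shared between baseline and post-treatment
biopsies after depth matching) are compared with a paired two-sided
Wilcoxon signed-rank test, exact null for ≤ 25 shared clones; with < 2
shared clones the test is skipped with an explicit flag, and when all
paired differences are zero the comparison is degenerate and p is reported
as 1. The signed-rank choice is the package's own: a paired, distribution-
free test is the minimal-assumption option for a handful of shared clones.

## Stimulation index and response calling

SI = mean(stimulated)/mean(unstimulated) over ≥ 3 replicates; a zero
unstimulated mean marks the sample invalid rather than producing an
infinite SI. The positivity threshold is SI ≥ 3, inclusive. A patient is a
responder iff any post-baseline sample within the evaluation window
(a timepoint predicate or label set; all post-baseline samples by default)
reaches threshold on any single peptide or the mixture. The alternative
reading — requiring a ≥ 3-fold rise over the patient's own baseline SI —
is not the default because the baseline sample has no vaccine-primed
culture to compare against; the per-sample reading is implemented and the
window/threshold are explicit parameters. Patients with only a baseline
assay are non-evaluable, excluded from response-rate denominators.
Positive-control (SEC3) counts are carried but not used for validity
gating, since no gating criterion is defined for them.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
sequence-level reality (no V(D)J recombination, PCR or sequencing-error
model; CDR3s are "CASS" + 4–10 random residues + "F" purely for domain
plausibility). Defaults define the study conditions used throughout the
tests:

| parameter | default | meaning |
|---|---|---|
| `n_clones` | 5000 | clones in the blood pool |
| `zipf_exponent` | 1.0 | clone-frequency power law (f ∝ rank⁻ᵃ) |
| `depth` | 50,000 | reads per sample |
| `persistence` | 0.8 | clone survival between consecutive timepoints |
| `tumor_share` | 0.2 | blood clones seeded into tumor |
| `n_spike` | 5 | vaccine-reactive clones |
| `spike_fold` | 64 | frequency fold under 10-day stimulation (log₂ = 6 > 5) |
| `spike_freq` | 1e-3 | spike frequency in week-7 unstimulated blood |
| `si_true` | 10 | true stimulation index |
| `noise_cv` | 0.1 | CV of replicate proliferation counts |

A Zipf law is the standard null for clone-size distributions; exponent 1
gives a realistically clonal bulk repertoire (top clone a few percent).
`spike_freq = 1e-3` puts the expected pre-stimulation count at 50 reads at
the default depth, comfortably above the recovery analysis's ≥ 20-read
eligibility cut. Spiked clones are excluded from baseline by construction
so the baseline-filter path has known positives; `leak_spikes_into_baseline`
inverts that to test the filter's removal behaviour. Stimulation multiplies
the spiked clones' frequencies by `spike_fold` and renormalizes, so the
realized stimulated/unstimulated ratio concentrates slightly below the
nominal fold (by the factor 1 + n·f·(fold−1)); with the defaults this still
leaves log₂ FC ≈ 5.5–6, above the calling threshold. Assay replicates are
log-normal with the exact configured mean (μ = ln m − σ²/2), so
`noise_cv = 0` recovers the true SI to machine precision.

What the generator does **not** emulate — shared/public clonotypes between
patients, in-vivo expansion dynamics beyond a persistence mask, depth
heterogeneity within a compartment, PCR amplification bias — bounds what
passing tests show: they validate the statistics under the stated
generative model, not robustness to those real-data features.

## Problem sizes and numerical choices

The validation experiments run at the defaults above: 20 seed replicates
for both the null type-I-error and spike-in-recovery analyses (~80,000
clone tests pooled under the null), an exhaustive Fisher-oracle sweep of
all 2×2 tables with small totals plus thousands of seeded tables with
margins up to 200, and 100 Monte-Carlo replicates for SI recovery. The
cohort used for response-rate calling is a reconstruction: eleven true
per-patient maximum SIs chosen to exhibit the summary pattern of interest
(exactly one patient below the 3-fold threshold at 2.3, median 11.5,
maximum 60.0) plus one baseline-only non-evaluable patient, run through
the noisy assay generator and the caller end to end. Fisher
p-values are cached per (ref, alt) count pair within a test (margins are
identical across clones after depth matching), which keeps a 5,000-clone
pair at ~2 s.

One estimator property worth knowing: a patient's reported quantity is the
*maximum* SI over peptides and timepoints, and the maximum of several noisy
ratios is biased upward — at CV 0.1 over four peptides the cohort maximum
overshoots its true value by roughly 10%. Medians are much less affected.

Seeds enter every stochastic step (downsampling, simulation) explicitly;
derived sub-seeds come from `numpy.random.SeedSequence.spawn`, so
pipelines are reproducible end to end from a single integer.

## Known limitations

- Clone identity by CDR3 amino-acid sequence alone merges distinct
  rearrangements that converge on one junction (and splits nothing); with
  V/J-aware identity the overlap and enrichment statistics would change.
- The Fisher substitution tests each pair independently; it cannot borrow
  strength across replicates the way a dispersion-sharing NB model would
  if biological replicates existed.
- Depth matching discards reads; at extreme depth imbalance the shallower
  sample dictates sensitivity.
- The immune-response caller models the assay's numeric outputs only; the
  10–12-day pre-stimulation culture itself is a wet-lab procedure outside
  the model.
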