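# clonotrace

Tools for asking whether a peptide vaccine actually mobilised T cells — and
for following those T cells around the body. Given bulk T-cell-receptor
beta-chain (TRB) repertoires sequenced from blood and tumor at several
timepoints, `clonotrace` identifies the clonotypes that expand when a
patient's PBMCs are stimulated in vitro with the vaccine peptides, filters
out clones that pre-existed at baseline, and tracks the surviving
"vaccine-enriched" clonotypes through later blood samples and tumor
biopsies. A companion module calls per-patient immune responses from
classical 3H-thymidine proliferation assays via the stimulation index.

It is aimed at translational immunologists analysing small vaccination-trial
cohorts: a handful of patients, a few samples each, and the need for
assumption-free statistics on exactly depth-matched integer counts.

## The statistics at the core

* **Clone identity.** All receptor reads sharing one CDR3 amino-acid
  sequence are one clone; V/J calls are annotation only.
* **Depth normalization.** Compared samples are downsampled without
  replacement (multivariate hypergeometric) to the minimum depth of the
  compared set, so counts stay integral and no clone is ever inflated.
* **Diversity and clonality.** Richness *R*, Shannon entropy
  *H* = −Σ *p<sub>i</sub>* ln *p<sub>i</sub>* (nats), and clonality
  1 − *H*/ln *R* ∈ [0, 1] (0 = perfectly even, 1 = monoclonal).
* **Expansion testing.** For each clone present in either of a depth-matched
  pair, a two-sided Fisher exact test on the 2×2 table
  (clone vs all-other-reads) × (reference vs comparison), with
  Benjamini–Hochberg FDR over all clones of the pair. Fold change is
  log₂((*n*<sub>alt</sub> + ½)/(*n*<sub>ref</sub> + ½)). A clone is called
  *nominal* at log₂ FC > 5 and p < 0.05, *significant* when additionally
  the adjusted p < 0.05. Clones present in the baseline sample are filtered
  out before any clone is called vaccine-enriched.
* **Repertoire fraction.** For a clone set, the summed normalized read
  count divided by the sample's total read count.
* **Stimulation index.** SI = mean(stimulated wells)/mean(unstimulated
  wells) from triplicate proliferation counts; a sample is positive at
  SI ≥ 3, a patient is a responder if any post-baseline sample within the
  evaluation window is positive (patients with no evaluable post-baseline
  sample are non-evaluable, not non-responders).

Because raw trial repertoires of this kind are rarely deposited, the
package ships a first-class synthetic-data module (`clonotrace.synthetic_data`)
generating longitudinal, multi-compartment repertoires with Zipf clone-size
distributions, known spiked-in vaccine-reactive clones, blood↔tumor sharing
and noisy triplicate assays — every pipeline stage is testable against
known ground truth.

## Worked example

```python
from clonotrace import (
    SimConfig, Tier, expansion_test, filter_baseline, vaccine_enriched,
    track_clones, clonality, simulate_patient,
)

cfg = SimConfig(n_clones=2000, depth=30_000, n_spike=3, spike_fold=64,
                spike_freq=1e-3, seed=11)
samples, truth = simulate_patient(cfg)

results = expansion_test(samples["pbmc_week7_unstim"],
                         samples["pbmc_week7_stim"], seed=1)
results = filter_baseline(results, samples["pbmc_baseline"])
enriched = vaccine_enriched(results, Tier.NOMINAL)
print(f"vaccine-enriched clones: {len(enriched)}")

tracked = track_clones(enriched, list(samples.values()), seed=2,
                       enrichment=results)
top = tracked[0]
print(f"top clone {top.cdr3_aa} (rank {top.rank}, log2 FC {top.log_fc:.2f})")
for entry in top.trace:
    m = entry.meta
    print(f"  {m.compartment.value:5s} {m.timepoint:8s} "
          f"count={entry.count:5d} fraction={entry.fraction:.4f}")
print(f"detected in tumor: {top.detected_in_tumor}")
```

prints

```
vaccine-enriched clones: 3
top clone CASSISLKIENF (rank 1, log2 FC 6.03)
  PBMC  baseline count=    0 fraction=0.0000
  PBMC  week7    count= 1602 fraction=0.0534
  PBMC  week7    count=   24 fraction=0.0008
  PBMC  week18   count=   36 fraction=0.0012
  tumor baseline count=    0 fraction=0.0000
  tumor week15   count=   31 fraction=0.0010
detected in tumor: True
```

All three spiked clones are recovered; the top-ranked one is absent at
baseline, explodes under 10-day stimulation (5.3% of the stimulated
repertoire), persists in unstimulated blood at week 18 and is detected in
the post-treatment biopsy — exactly the trajectory the tracking module is
built to expose.

The same workflow is available from the shell:

```bash
clonotrace simulate --config sim.yaml --out simdir/
clonotrace metrics  --manifest simdir/manifest.csv --depth auto --seed 1
clonotrace enrich   --ref simdir/pbmc_week7_unstim.tsv \
                    --alt simdir/pbmc_week7_stim.tsv \
                    --baseline simdir/pbmc_baseline.tsv --seed 2 --out enriched.csv
clonotrace track    --manifest simdir/manifest.csv --clones enriched.csv --seed 3
clonotrace respond  --assays simdir/assays.csv --threshold 3
```

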