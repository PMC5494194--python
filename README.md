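# atacohort

Cohort-scale chromatin accessibility analysis for two-subtype disease
cohorts profiled by ATAC-seq.

Given per-sample peak calls and sequencing fragments for tens of samples,
the package builds the cohort **consensus map** (the interval union of all
peak calls, the shared coordinate frame for every downstream statistic) and
then asks the questions a regulatory-epigenomics study of such a cohort
asks:

- How complete is the map? A **saturation curve** counts unique merged
  regions as samples are added in random order; per-region **support**
  splits the map into constitutively open (> 95% of samples), shared
  (5–95%) and rare (< 5%) regions.
- How variable is accessibility? A quantile-normalized region-by-sample
  matrix yields per-region mean, s.d., variance-to-mean ratio and squared
  coefficient of variation, gene-level promoter/distal summaries, and
  **accessibility-corridor tracks** (cohort mean and 5/25/75/95th
  percentile coverage per base).
- Do disease subtypes differ? Samples are labelled from IGHV germline
  homology (> 98% = unmutated). A two-sided **F test** per region finds
  subtype differences in *variance* (Bonferroni-corrected p < 0.05 and mean
  accessibility > 1); a random-forest classifier under **patient-aware
  leave-one-out cross-validation** (all samples of the test sample's
  patient are withheld from training) separates the subtypes, is
  calibrated against a shuffled-label null, and yields a data-driven
  **signature** — the regions whose fold-averaged Gini importance exceeds
  10⁻⁴ — used for clustering and intermediate-subtype discovery.
- Who regulates whom? TF footprints with purity > 0.7 inside accessible
  chromatin (TFs with ≥ 500 such sites) are assigned to genes (gene body
  or 2,500 bp upstream, else nearest TSS) and aggregated into an
  interaction score
  `S_t,g = Σᵢ 2(Pᵢ − 0.5) · 10^(−d_i,g / 10⁶)`
  (purity above chance, decaying one decade per megabase; both terms
  configurable). Scores > 1 become directed TF→gene edges; two networks
  are compared by the log2 ratio of edge-count-normalized node degrees.

A **synthetic cohort generator** reproduces the statistical structure this
pipeline assumes — core/shared/rare region architecture, negative-binomial
counts, planted subtype mean shifts, planted variance ratios at equal
means, intermediate samples with midpoint expected signal, and footprint
tables with recoverable planted TF→gene edges plus decoys — so every stage
is testable end-to-end without external data.

## Worked example

```python
import atacohort as a

cohort = a.generate_cohort(a.CohortSpec(seed=1))       # 40 samples / 25 patients
consensus = a.merge_peak_sets(cohort.peak_sets)        # 2,000 regions
support, breakdown = a.region_support(consensus, cohort.peak_sets)

matrix = a.quantify_regions(consensus, cohort.fragments)
a.add_normalized_layer(matrix)
labels = a.ighv_labels(cohort.sample_sheet)
patients = cohort.sample_sheet.set_index("sample_id")["patient_id"]
result = a.patient_aware_loocv(matrix.normalized_frame(), labels, patients, seed=1)
print(round(breakdown["constitutive"], 3), round(breakdown["shared"], 3),
      round(breakdown["rare"], 3))
print(result.auc, result.operating_point["sensitivity"],
      result.operating_point["specificity"])
```

prints

```
0.121 0.576 0.303
1.0 1.0 1.0
```

— 12.1% of consensus regions are constitutively open, 57.6% shared and
30.3% rare (the planted architecture), and the cross-validated classifier
separates the two planted subtypes perfectly (AUC 1.0 at the ROC point
closest to the top-left corner), which is expected at the planted
1.5-log2 effect size.

The same analysis as a narrative pipeline lives under `analysis/`
(`01_simulate.py` … `05_grn.py`; small summaries go to `results/`, bulky
intermediates to `scratch/`), and as a CLI:

```
atacohort run-all --out run_dir --seed 1
```

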