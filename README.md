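# omicspanel

Multi-omics biomarker panel discovery for matched case–control cohorts.

`omicspanel` is aimed at studies that profile the same stool (or other)
samples on several omics layers — 16S taxon counts, protein spectral
counts, metabolite/amino-acid concentrations — and ask which small
combination of features best separates two diagnostic groups (e.g.
colorectal cancer vs. control, adenoma vs. control). It provides, as a
tested library plus a thin CLI:

* **Stability selection** with combined LASSO and elastic-net penalized
  logistic regression: per iteration, a stratified 75% training draw,
  10-fold cross-validated tuning of the penalty λ for both methods, and a
  record of which features carry nonzero coefficients; over 100
  iterations the per-feature selection frequencies are summed and the
  **first quartile** of the ever-selected features becomes the marker
  set. The penalized fits solve

      min  (1/n) Σᵢ log(1 + e^(−ηᵢ(2yᵢ−1))) + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)

  with a numba-compiled coordinate-descent path solver (exact zeros,
  warm starts from λ_max down a 50-point log grid).
* **Honest panel evaluation**: unpenalized logistic panel fit, AUC on a
  25% test split held out *before* any feature selection, an apparent
  (full-data) AUC labeled as such, a bootstrap AUC distribution scored
  out-of-bag, a random-label ("random AUC") permutation null, and
  sensitivity/specificity at the Youden threshold — plus a hemoglobin-
  subunit reference panel (HBA1, HBB, HBD.HBE1, HBG2.HBG1) standing in
  for fecal immunochemical testing.
* **Univariate statistics**: a beta-binomial likelihood-ratio test for
  spectral-count differences (overdispersion profiled out, χ²(1)
  reference), fold changes with a ≥2 flag, Welch's t, per-feature AUCs,
  Shannon alpha diversity and Bray–Curtis + PERMANOVA beta diversity.
* **Cross-omics integration**: Pearson (plus Spearman/Kendall
  consistency) correlation networks over the selected features, keeping
  edges with |r| ≥ 0.3 and p < .05; GraphML and TSV export.
* A **synthetic cohort generator** that emulates a matched fecal
  multi-omics study (12 CRC / 21 adenoma / 20 control; 225 taxa at a
  median depth of ~23,000 reads; 521 proteins with ~169 detected per
  sample; 44 amino acids with ~26 quantified per sample) with planted
  group effects and cross-layer latent factors, so every downstream
  stage can be validated against known ground truth.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import numpy as np
from omicspanel import ComparisonConfig, PenaltyConfig, generate_cohort, run_comparison
from omicspanel.simulate import design_from_dict

design = design_from_dict({
    "seed": 7,
    "group_sizes": {"CRC": 20, "control": 20},
    "planted": [   # one known marker per layer, 2 log-fold / 2 SD effects
        {"layer": "microbiota", "feature_index": 1,
         "contrast": ["CRC", "control"], "effect_size": 2.0},
        {"layer": "proteome", "feature_index": 2,
         "contrast": ["CRC", "control"], "effect_size": 2.0},
        {"layer": "amino_acid", "feature_index": 0,
         "contrast": ["CRC", "control"], "effect_size": 2.0},
    ],
})
tables, metadata, truth = generate_cohort(design)

config = ComparisonConfig(
    groups=("CRC", "control"), seed=11,
    penalty=PenaltyConfig(n_iterations=50, seed=11),
    n_eval_iterations=100,
)
report = run_comparison(config, tables, metadata)

panel = report.combined_panel
print("planted truth :", truth.planted_ids())
print("combined panel:", panel.model.feature_ids)
print(f"test AUC        {panel.auc_test:.3f}")
print(f"apparent AUC    {panel.auc_apparent:.3f}")
boot, null = panel.distributions.bootstrap, panel.distributions.permuted
print(f"bootstrap AUC   {boot.mean():.3f} "
      f"[{np.percentile(boot, 2.5):.3f}, {np.percentile(boot, 97.5):.3f}]")
print(f"random AUC      {null.mean():.3f}")
```

Output:

```
planted truth : ['OTU0002', 'PROT0003', 'AA0001']
combined panel: ['OTU0002', 'OTU0092', 'OTU0106', 'OTU0146', 'OTU0200', 'OTU0216',
                 'PROT0003', 'PROT0008', 'PROT0246', 'PROT0266', 'PROT0303',
                 'PROT0380', 'PROT0396', 'PROT0406', 'PROT0418']
test AUC        0.840
apparent AUC    1.000
bootstrap AUC   0.960 [0.862, 1.000]
random AUC      0.531
```

Reading it: the two-stage selection recovered the planted taxon and
protein inside a 15-feature cross-omics panel (the planted amino acid was
lost at the second stage at this sample size). The panel separates the
held-out test samples at AUC 0.84 — against a random-label null of 0.53 —
while the apparent full-data AUC of 1.0 illustrates exactly the optimism
that the held-out estimate corrects for.

The same workflow runs from the shell on TSV tables:

```bash
omicspanel simulate --config design.yaml --out cohort/ --seed 7
omicspanel run --config comparison.yaml \
    --microbiota cohort/taxa.tsv --proteome cohort/proteins.tsv \
    --amino cohort/amino_acids.tsv --metadata cohort/metadata.tsv \
    --out results/
```

Artifacts per comparison: per-layer and combined stability-frequency
tables, panel reports (JSON) with bootstrap and null distributions (TSV),
the reference-panel report, the correlation network (edge TSV + GraphML),
a PCA variance summary, and a structured run log.

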