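# nanosorb

Predicting the adsorption affinity (log *k*) of enteric microbial
metabolites to metal and carbon nanomaterials.

Ingested nanomaterials meet hundreds of gut-microbial metabolites —
short-chain fatty acids, bile acids, indoles, phenolics, vitamins — that can
physisorb onto the particle surface and form a "biocorona" that changes the
particle's fate. `nanosorb` is a library for the in-silico side of that
problem, aimed at computational chemists and nanotoxicologists. It chains:

1. **Inventory** — a curated table of 170 unique enteric microbial
   metabolites across 13 categories, with literature-saturation and
   category-count analyses.
2. **BSAI models** — the biological surface adsorption index, a linear
   free-energy relationship

   log *k* = *c* + *E·r_e* + *S·p_s* + *A·a* + *B·b* + *V·v*

   where [*E, S, A, B, V*] are the Abraham solute descriptors of the
   molecule and [*c, r_e, p_s, a, b, v*] are per-nanomaterial
   "nanodescriptors" weighting lone-pair, polarity/polarizability,
   hydrogen-bond acidity/basicity and hydrophobicity interactions.
3. **Descriptor-based QSAR** — secondary multiple linear regressions of
   BSAI-predicted log *k* on cheap molecular descriptors, built by forward
   selection of five descriptors under a variance-inflation-factor (VIF ≤ 2)
   collinearity guard, so that log *k* can be predicted from structure
   alone. A frozen registry of 19 such five-descriptor models (one per
   nanomaterial: 13 metal particles, 5 multiwalled carbon nanotubes, 1
   fullerene) is packaged.
4. **Applicability domains** — Insubria graphs (prediction vs leverage with
   the critical hat threshold *h\** = 3(*N*+1)/*n* and an optional
   mean ± 3σ prediction band from probe compounds), Williams plots
   (standardized leave-one-out residual vs leverage), and an NMDS-centroid
   distance rule on pairwise Mahalanobis distances.
5. **Nanomaterial statistics** — min-shift + Bray–Curtis dissimilarities
   between nanomaterials' log *k* profiles, distance-based redundancy
   analysis (dbRDA) with marginal permutation *F*-tests of each
   nanodescriptor, Kruskal–Wallis/Dunn post-hoc comparisons with Holm
   correction, and Spearman correlations.
6. **PMF affinities** — adsorption constants from molecular-dynamics
   potentials of mean force, *k* = ∫₀ᶜ exp(−β·w(z)) dz with automatic
   plateau-onset detection of the cutoff *c*, for molecules outside the
   QSAR applicability domain.

A synthetic-data module generates every input the pipeline needs at desk
scale with known ground truth, so the whole package tests without any
external download.

## Worked example

```python
from nanosorb import (GeneratorConfig, forward_select, gen_table_from_model,
                      load_frozen_models)

frozen = load_frozen_models()["AlOOH"]       # log k ~ 1.79 + 0.49*ALogP + ...
table, logk = gen_table_from_model(frozen, GeneratorConfig(n=200, seed=1),
                                   n_decoys=10)
result = forward_select(table, logk)
for step in result.trace:
    print(f"{step.descriptor:<8s} R2={step.r2:.4f} maxVIF={step.max_vif:.2f}")
print({name: round(coef, 4) for name, coef in result.model.terms})
```

prints

```
ALogP    R2=0.4575 maxVIF=1.00
nHBDon   R2=0.7779 maxVIF=1.00
ATSm1    R2=0.8901 maxVIF=1.01
nBase    R2=0.9900 maxVIF=1.01
Fsp3     R2=1.0000 maxVIF=1.02
{'ALogP': 0.49, 'nHBDon': 0.45, 'ATSm1': 0.004, 'nBase': -0.41, 'Fsp3': -0.57}
```

The responses were generated noise-free from the aluminium-hydroxide-oxide
model's own equation, so forward selection picks the five true descriptors
ahead of all ten decoy columns (the R² column is the cumulative variance
explained, reaching 1.0) and ordinary least squares returns the generating
coefficients exactly — the recovered ALogP coefficient is 0.49, the
equation's printed value.

Longer narrative scripts, one per capability, live in `examples/`:

```bash
python examples/inventory_overview.py
python examples/bsai_prediction.py
python examples/train_qsar_model.py
python examples/applicability_domain.py
python examples/compare_nanomaterials.py
python examples/pmf_affinity.py
```

A thin CLI wraps the batch workflows (`nanosorb inventory-stats`,
`nanosorb bsai-predict`, `nanosorb qsar-predict`, `nanosorb pmf-logk`,
`nanosorb synth`). Note that the per-nanomaterial nanodescriptor values are
experimental data you supply as a YAML/JSON registry; the package does not
ship them.

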