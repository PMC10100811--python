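# rumiherit

Heritability, co-occurrence and growth-trait prediction analysis of the
rumen bacteriota in dam–lamb pairs.

Some rumen bacteria are *heritable*: their abundance in a lamb's rumen is
partly determined by the lamb's (and hence its mother's) genetics rather
than by chance colonization alone. `rumiherit` implements the full analysis
used to find such taxa in a flock of ewes and their lambs, starting from an
ASV count table, sample metadata and a pedigree:

1. **Table processing** — prevalence filtering, rarefaction, relative
   abundance, alpha diversity (Chao1, Shannon, Pielou evenness),
   Bray–Curtis / binary-Jaccard / weighted-UniFrac dissimilarities, PCoA,
   PERMANOVA and Wilcoxon comparisons.
2. **Heritability** — for each ASV, the additive + maternal animal model

       y = Xb + Za + Wm + e,
       a ~ N(0, A σ²ₐ),  m ~ N(0, I σ²ₘ),  e ~ N(0, I σ²ₑ)

   where `y` is the log-transformed relative abundance, `X` carries the
   fixed effects (year-season, group dam/lamb, age as covariate), `A` is
   the pedigree numerator relationship matrix and `W` maps each sample to
   the dam of the sampled animal.  Variance components are estimated by
   AI-REML (average-information updates, EM fallback) and heritability is

       h² = σ²ₐ / (σ²ₐ + σ²ₘ + σ²ₑ)

   with a delta-method (first-order Taylor) standard error and a two-tailed
   Student *t* p-value.  ASVs with h² > 0.2 and p < 0.05 are screened as
   heritable.
3. **Networks** — compositionally aware SparCC correlations with
   permutation pseudo-p-values, thresholded co-occurrence graphs (|r| > 0.5,
   p < 0.01, prevalence > 20% per cohort), hub (max degree) and keystone
   (max betweenness) calls and MCODE dense-module detection.
4. **Associations** — Spearman correlations of prevalent ASVs (≥50% of dams
   or lambs) with lamb growth traits (BW, WW, PWG = WW − BW) and rumen
   fermentation parameters, Benjamini–Hochberg corrected.
5. **Prediction** — litter-stratified high/low (top/bottom 25%) trait
   groups classified by tuned random forests from lamb and/or maternal log
   abundances, with 7-fold CV accuracy, 70/30 ROC/AUC and importance
   reports split by cohort.

Because real flock data are not bundled, the `synthio` module generates
synthetic populations — pedigree, compositional ASV counts with known
(σ²ₐ, σ²ₘ, σ²ₑ) per ASV, traits linked to designated causal ASVs, and a
phylogenetic tree — so every stage can be validated against planted truth.

## Worked example

Simulate a flock of 48 ewes where 10 of 40 ASVs carry additive genetic
variance (true h² = 0.5/1.0) and 5 ASVs drive weaning weight, then run the
whole pipeline:

```python
import dataclasses, numpy as np
from rumiherit import pipeline

sigma_a2 = np.zeros(40); sigma_a2[:10] = 0.5
cfg = pipeline.RunConfig(seed=7, sparcc_boot=50)
cfg.synth = dataclasses.replace(cfg.synth, n_dams=48, n_asvs=40, n_trait_asvs=5,
                                sigma_a2=sigma_a2, sigma_m2=0.1,
                                sigma_e2=np.maximum(0.9 - sigma_a2, 0.05),
                                base_log_mean_sd=1.0, trait_effect_size=2.0,
                                trait_noise_sd=0.3)
report = pipeline.run_pipeline(cfg)

h = report["stages"]["heritability"]
print("prevalent ASVs:", report["stages"]["tables"]["n_prevalent_asvs"])
print("heritable ASVs:", h["n_heritable"], f"({h['pct_heritable']}% of prevalent)")
print("h2 range:", [round(v, 2) for v in h["h2_range_heritable"]])
print("combined abundance (dam):  %.1f%%" % h["combined_abundance"]["dam"]["mean_pct"])
print("combined abundance (lamb): %.1f%%" % h["combined_abundance"]["lamb"]["mean_pct"])
print("screen sensitivity:", h["planted_recovery"]["sensitivity"],
      " FPR:", h["planted_recovery"]["false_positive_rate"])
for key in ("WW/dam", "WW/both"):
    r = report["stages"]["predict"][key]
    print(f"WW prediction ({key.split('/')[1]}): acc=%.2f auc=%.2f"
          % (r["cv_accuracy"], r["auc"]))
```

which prints:

```
prevalent ASVs: 40
heritable ASVs: 6 (15.0% of prevalent)
h2 range: [0.48, 0.69]
combined abundance (dam):  15.7%
combined abundance (lamb): 14.8%
screen sensitivity: 0.6  FPR: 0.0
WW prediction (dam): acc=0.67 auc=1.00
WW prediction (both): acc=0.81 auc=0.94
```

Six of the ten planted heritable ASVs pass the screen (sensitivity 0.6) and
none of the thirty null ASVs do (false-positive rate 0).  The estimated h²
of the screened set (0.48–0.69) brackets the planted value of 0.5, and
weaning-weight groups are predicted markedly better when lamb and maternal
ASVs are combined — the same qualitative behaviour reported for real
dam–lamb flocks.

A command-line interface wraps the most common entry points:

```bash
rumiherit simulate --seed 3 --n-dams 128 --n-asvs 100 --out pop/
rumiherit heritability --table pop/asv_table.tsv --meta pop/metadata.tsv \
    --pedigree pop/pedigree.csv --out h2.tsv
rumiherit run --seed 1 --out results/
```

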