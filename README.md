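# rescuescreen

Four-group **aging × rescue** transcriptome screening: a tested, reusable
implementation of the classic microarray screening procedure for factorial
rescue designs, where aged animals receive a restorative treatment and the
question is which aging-dependent expression changes the treatment
*counters*.

The design has four groups — young control (**YC**), aged control (**AC**),
and aged animals given short-term (**ST**) or long-term (**LT**) treatment —
with n = 6 arrays per group on an unlogged RMA intensity scale. The screen:

1. **Prefilter** — keep annotated, "present" genes (unlogged intensity ≥ 40
   on ≥ 4 arrays anywhere in the study; duplicate annotations collapsed to
   the strongest probe).
2. **Per-gene statistics** — mask within-group outliers (> 2 SDs of the
   group mean, single pass), fit a one-way fixed-effects ANOVA across the
   four groups, and evaluate Fisher's **protected LSD** contrasts
   t = (x̄ᵢ − x̄ⱼ) / √(MSE (1/nᵢ + 1/nⱼ)) on the pooled residual df, a
   contrast counting as significant only when the omnibus ANOVA is
   (α = 0.05 throughout). Multiple testing is summarized by the ratio
   estimator FDR = α·m / #{p ≤ α}.
3. **Template classification** — a gene with significant ANOVA and YC–AC
   contrast is *aging-dependent*, direction = sign(x̄_AC − x̄_YC). Its
   rescue arms (ST–AC, LT–AC) then assign one of four templates:
   aging-down/rescue-unchanged (**I**), aging-down/rescue-up (**II**),
   aging-up/rescue-unchanged (**III**), aging-up/rescue-down (**IV**) —
   II and IV are the *countered* templates — or **ANOMALOUS** when a
   significant arm moves *with* aging (exacerbation).
4. **Monte Carlo null** — rerun the identical ANOVA → pLSD → template
   procedure on freshly drawn random numbers (default 1000 iterations) to
   estimate how many genes land in each template by chance; observed counts
   are reported as fold over that expectation with exact binomial tails.
5. **Concordance & overlap** — fraction of rescue-sensitive genes moved the
   same direction by both arms (exact binomial test vs 0.5), Pearson r of
   the arms' log2 fold changes vs AC, and the chance-expected ST/LT list
   overlap (expected = n_ST·n_LT/N).
6. **Enrichment** — EASE-score (jackknifed one-tailed Fisher's exact:
   the hypergeometric tail P(X ≥ h−1)) overrepresentation of GMT gene sets
   against the filtered background, retaining categories with > 3 list
   genes and EASE p ≤ 0.05.

A first-class **synthetic-data generator** plants every template class with
known truth labels (log-normal baselines, multiplicative noise, configurable
effect sizes and rescue splits), so the whole pipeline is testable without
any download.

## Worked example

```python
import rescuescreen as rs

design = rs.SimulationDesign(n_genes=2000, seed=1)   # planted study
study, truth = rs.generate_study(design)
filtered, report = rs.filter_present(study)
stats = rs.screen_study(filtered)
screen = rs.summarize_screen(stats, alpha=0.05)
labels = rs.classify(stats)
summary = rs.summarize_classification(labels)
```

With the default planted design (≈15% aging-dependent genes at 3 within-group
SDs, full restoration) this prints, via the report helpers:

```text
retained 1887/2000 present genes
ANOVA-significant: 373 (20%), FDR = 0.25
aging-dependent: 313 (84% of significant)
rescue-sensitive: 148 (47% of aging-dependent); countered: 137 (92.6%)
arms: LT-only 75, ST-only 44, both 29
ST/LT same-direction: 97/148 (65.5%), binomial p = 9.72e-05; log2FC r = 0.31
planted countered genes recovered: 99.1%
```

Reading: the presence filter drops the dim 5–6% of genes; 373 genes pass the
omnibus ANOVA, of which 313 also pass the protected YC–AC contrast
(aging-dependent); 148 of those have a significant rescue arm, and 137
(92.6%) moved *opposite* to aging — the countered templates II/IV. Recovery
is measured against the planted truth: 99.1% of genes planted as countered
are recovered as such.

The same pipeline runs from the shell:

```bash
rescuescreen simulate --out-dir sim --seed 1 --n-genes 2000
rescuescreen run --config run.yaml     # filter -> test -> classify -> null -> enrich
```

emitting deterministic TSV tables (`filter_report`, `gene_stats`,
`templates`, `summary`, `concordance`, `null_report`, `enrichment_<T>`) and
a machine-readable `summary.json`.

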