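# frontloadseq

Corals native to highly variable reef-flat habitats can hold stress-response
genes at constitutively high expression — *frontloading* — instead of
inducing them when conditions change. `frontloadseq` is a tested Python
implementation of the analysis chain used to detect that signature in a
two-origin (reef flat vs. reef slope) × two-pCO₂-treatment (stable vs.
variable) coral transplant experiment with tag-seq expression profiling and
skeletal micromorphometry. It is written for quantitative ecologists and
genomicists who want each statistical step available as a library function,
reproducible on synthetic data with planted ground truth.

## What it computes

Per gene *g* with counts `y_gj`, the expression model is a
negative-binomial mixed model with a log link,

```
y_gj ~ NB(mu_gj, alpha_g)            Var(y) = mu + alpha mu^2
log mu_gj = log s_j + x_j' beta_g + u_g,colony(j),    u ~ N(0, sigma_u^2)
```

with median-of-ratios size factors `s_j`, sum-to-zero origin × treatment
contrasts `x_j`, a colony random intercept (fragments are clones), and a
fixed dispersion `alpha_g` from a robustly fitted trend
`alpha(mu) = alpha_asym + alpha_extra/mu`. The random effect is integrated
by a Laplace approximation; type-III Wald χ² tests per term get Storey
q-values. From the model-estimated cell means `m`, each gene's

* control ratio `C = m(flat,stable) / m(slope,stable)` and
* fold-change ratio `F = [m(flat,var)/m(flat,stable)] / [m(slope,var)/m(slope,stable)]`

classify it as **frontloaded** when `C > 1` and `F < 1`: constitutively
higher in flat-origin corals, with a damped treatment response.

Around that core the package provides: detection and pOverA count filters
and a variance-stabilizing transform derived from the dispersion trend;
signed weighted co-expression networks (soft power β, topological overlap,
dynamic hybrid tree cut, eigengene merging, module–trait correlation);
gene-length-bias-corrected GO over-representation (isotonic probability
weighting function + Wallenius noncentral hypergeometric test with BH
adjustment); and colony random-intercept linear mixed models for skeletal
micromorphometry with estimated marginal means and Tukey HSD contrasts.
A synthetic-data generator emulates the full study design — 12 colonies
per origin, NB counts with colony intercepts, planted frontloaded genes,
planted co-expression modules tied to physiological traits, gene-length/DE
bias, diel pCO₂ sinusoids, and morphometric tables — so every stage is
testable without downloads.

## Worked example

Simulate the classifier-validation experiment (200 genes, 10% planted
frontloaded at 2-fold effects, colony SD 0.3, the 46-sample analysis set),
run the pipeline and classify:

```python
from frontloadseq.simulate import simulate_frontload_validation
from frontloadseq.preprocess import size_factors, estimate_dispersion_trend
from frontloadseq.de_glmm import fit_all_genes
from frontloadseq.frontloading import classify_table, frontload_summary

counts, meta, truth = simulate_frontload_validation(n_genes=200, seed=7)
meta = meta[meta["genotype"] != "F12"]          # 46-sample analysis set
counts = counts[meta.index]
sf = size_factors(counts)
trend = estimate_dispersion_trend(counts, sf)
table = fit_all_genes(counts, meta, trend.trended(), sf)
records = classify_table(table)

n_front, prop = frontload_summary(records)
print(f"frontloaded: {n_front}/{len(records)} genes ({100*prop:.1f}%)")
truth_flag = (truth.genes["class_label"] == "frontloaded").reindex(records.index)
pred = records["frontloaded"]
print(f"sensitivity: {(pred & truth_flag).sum() / truth_flag.sum():.2f}")
print(f"specificity: {(~pred & ~truth_flag).sum() / (~truth_flag).sum():.2f}")
print(records.loc[pred].head(3).round(2).to_string())
```

prints

```
frontloaded: 26/200 genes (13.0%)
sensitivity: 1.00
specificity: 0.97
           control_ratio  foldchange_ratio  frontloaded  classifiable
gene
gene00001           1.56              0.48         True          True
gene00003           2.07              0.46         True          True
gene00007           2.20              0.40         True          True
```

All 20 planted frontloaded genes are recovered (sensitivity 1.00) with a
handful of false calls among the 180 genes planted in the other quadrants
of (C, F) space (specificity 0.97); each called gene's ratios sit in the
frontloaded quadrant, e.g. gene00001 is expressed 1.56× higher in
flat-origin corals under the common stable treatment and responds to the
variable treatment only half as strongly as its slope-origin counterpart.

## The analysis, step by step

Numbered drivers under `analysis/` run the full narrative on a 2,000-gene
simulated experiment and write tables to `results/`:

```
python analysis/01_simulate_experiment.py    # counts, truth, traits, morpho
python analysis/02_filter_normalise.py       # filters, size factors, VST
python analysis/03_differential_expression.py
python analysis/04_frontloading.py
python analysis/05_coexpression_modules.py
python analysis/06_go_enrichment.py
python analysis/07_micromorphometry.py
```

The same stages are exposed as a CLI (`frontloadseq all --outdir out`),
with subcommands `simulate / filter / vst / de / frontload / network /
enrich / morpho`; identical config and seed reproduce byte-identical
outputs.

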