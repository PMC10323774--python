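# hmrisk

Chromatin-mark signal profiling, mark-importance ranking, entropy-based
gene selection, and prognostic Cox risk-score modelling for tumor/normal
comparisons.

## The problem

Histone modifications (HMs) reorganise during tumorigenesis, and the marks
deposited over gene bodies during transcription elongation — H3K36me3 and
H3K79me2 — are particularly tightly coupled to expression change. `hmrisk`
implements, as a tested and reusable pipeline, an analysis chain that asks
three questions of a tumor/normal cell-line pair and a survival cohort:

1. **Which marks matter?** HM ChIP signal is quantified on 100 bins of
   100 bp spanning TSS ± 5 kb, normalised RPKM-style per bin:
   `H = n_bin · 10⁹ / (N · l_bin)`. Per-bin tumor/normal log2 signal
   changes feed a random-forest classifier of up- vs down-regulated genes
   (|log2 FC| > 1, p < 0.01), scored by the AUC of pooled out-of-training
   vote fractions. All 2^k − 1 mark subsets are swept (2047 for the
   11-mark panel), and mark frequencies are tallied among fixed-size
   subsets whose AUC exceeds 95% of the full panel's.
2. **Which genes carry differential mark levels?** Per gene, the mark
   signal summed over bins is standardised per sample
   (`SH = (H − H_min)/H_max`), normalised across samples into a
   distribution P, and scored by Shannon entropy `E = −Σ P log₂ P`. Genes
   with E below a threshold (default 1.549) for H3K36me3 or H3K79me2 have
   sample-concentrated — "differential" — mark levels.
3. **Do those genes carry prognostic signal?** Differential-mark DEGs
   expressed in >90% of tumor samples are screened by univariate Cox
   regression (p < 0.05), shrunk by an L1 Cox path (penalty by 10-fold CV
   partial likelihood), and combined in a multivariate Cox fit. The risk
   score `RS = Σ coefⱼ · xⱼ` is split at the median into high/low-risk
   groups, compared by Kaplan–Meier/log-rank, and evaluated by
   IPCW time-dependent ROC at 3 and 5 years.

A first-class synthetic-data generator (`hmrisk.simulate`) produces gene
models, ChIP reads with mark-specific spatial profiles, replicate
expression, and a survival cohort with planted driver genes — so the whole
chain runs, and is tested, with no external data. See `docs/methods.md`
for models, assumptions and limitations.

## Worked example

```python
from hmrisk import diffexpr, entropy, importance, quantify, survival
from hmrisk.pipeline import subset_samples
from hmrisk.simulate import SimConfig, simulate

sim = simulate(SimConfig(n_genes=300, seed=1))
reads = {**sim.reads["tumor"], **sim.reads["normal"]}
tensor = quantify.quantify_bin_signals(reads, sim.genes)
tumor = subset_samples(tensor, [s for s in tensor.samples if s.startswith("tumor")])
normal = subset_samples(tensor, [s for s in tensor.samples if s.startswith("normal")])
changes = quantify.signal_change(tumor, normal)
degs = diffexpr.call_degs(sim.expression)

X, y = importance.build_features(changes, degs, ["H3K36me3"])
ev = importance.evaluate_model(X, y, cv=importance.CVConfig(mode="oob"),
                               n_trees=100, seed=1)
print(f"H3K36me3 single-mark AUC: {ev.auc:.3f}")

tables = {m: entropy.gene_hm_entropy(tensor, m) for m in ("H3K36me3", "H3K79me2")}
diff = entropy.select_differential(tables)
print(f"differential-mark genes: {len(diff)}")

cond = sim.cohort_condition
tumor_cohort = cond.index[cond == "tumor"].tolist()
cand = survival.build_candidates(diff.index.tolist(), degs,
                                 sim.cohort_expr, tumor_cohort)
seeds, _ = survival.univariate_screen(cand, sim.cohort_expr, sim.survival)
sel, _ = survival.lasso_select(seeds, sim.cohort_expr, sim.survival, seed=1)
model, fit = survival.multivariate_fit(sel, sim.cohort_expr, sim.survival,
                                       drop_insignificant=0.05)
scores = survival.risk_score(model, sim.cohort_expr[tumor_cohort])
km = survival.km_curves(scores, sim.survival)
auc = survival.time_dependent_roc(scores, sim.survival)
print(f"candidates {len(cand)} -> screened {len(seeds)} -> model {len(model.genes)}")
print(f"log-rank p = {km['logrank_p']:.2e}; tdAUC 3y/5y = "
      f"{auc[3.0]:.3f}/{auc[5.0]:.3f}")
```

Output (seed 1):

```
H3K36me3 single-mark AUC: 1.000
differential-mark genes: 228
candidates 55 -> screened 7 -> model 5
log-rank p = 2.14e-19; tdAUC 3y/5y = 0.720/0.759
```

The two gene-body marks are the planted drivers of expression change, so
H3K36me3 separates up- from down-regulated genes perfectly; intersecting
the entropy-selected genes with the DEGs and the expression filter leaves
55 candidates, of which the Cox chain keeps a five-gene model; the fitted
risk score separates the median-split groups decisively (log-rank
p ≈ 2e-19), with 3/5-year time-dependent AUCs of 0.72/0.76.

The same chain is available from the shell: `hmrisk simulate --out data/`
then `hmrisk pipeline --input-dir data/ --out-dir data/run`; every stage
writes TSV/JSON outputs plus a manifest with a parameter hash.

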