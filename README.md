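# alrpipe

A tested, reusable pipeline for discriminating two populations from
metagenomic feature-count tables (KEGG/COG IDs or taxa), built around
compositional data analysis:

1. **synthetic data** (`alrpipe.simulate`) — logistic-normal–multinomial
   two-population count tables with planted differential features and a
   ground-truth record, so every downstream stage has recovery tests;
2. **compositional transform** (`alrpipe.compositional`) — PCA outlier
   removal, zero-fraction feature filtering (with a presence/absence
   exception), pseudocount, automatic additive log-ratio (ALR) reference
   selection (lowest CV of log-counts among high-abundance candidates,
   gated by a Procrustes isometry check > 0.9 against the centered
   log-ratio geometry), the ALR transform, and auto-scaling;
3. **PLS-DA** (`alrpipe.plsda`) — from-scratch NIPALS PLS-DA with
   Mahalanobis-distance classification, balanced error rate (BER),
   repeated stratified fourfold cross-validation, VIP scoring, the
   iterative VIP>1 selection loop (stops at BER < 0.02 or no
   improvement), and confusion / label-permuted confusion validation;
4. **Bayesian screen** (`alrpipe.bayes`) — per-feature flat-prior Gibbs
   sampling of the two-group difference, split-chain R-hat, posterior mean
   in SD units, P0, HPD95, and the relevance rule (|meanDiff| > 0.5 and
   P0 > 0.9);
5. **diversity** (`alrpipe.diversity`) — Shannon H′ and inverse Simpson
   with a Mann–Whitney U group test, Bray–Curtis dissimilarity, nonmetric
   MDS (Kruskal stress-1, PAVA isotonic regression + SMACOF updates), and
   PERMANOVA on the first two ordination dimensions;
6. **orchestration** (`alrpipe.pipeline`, `alrpipe.cli`) — the full
   protocol under one YAML config with a deterministic seed-splitting
   scheme and a JSON run report.

## CLI

```sh
alrpipe simulate  --config sim.yaml --outdir out/sim
alrpipe transform --counts out/sim/counts.tsv --metadata out/sim/metadata.tsv \
                  --outdir out/tr
alrpipe plsda     --alr out/tr/alr.tsv --metadata out/tr/alr_metadata.tsv \
                  --outdir out/pls --repeats 100
alrpipe bayes     --alr out/tr/alr.tsv --metadata out/tr/alr_metadata.tsv \
                  --features out/pls/selected_features.tsv --out out/bayes.tsv
alrpipe diversity --counts out/sim/counts.tsv --metadata out/sim/metadata.tsv \
                  --outdir out/dv
alrpipe run-all   --config pipeline.yaml --outdir out/full
```

All I/O is tab-delimited text; `sim.yaml` holds `SimulationDesign` fields
and `pipeline.yaml` holds `PipelineConfig` fields (defaults follow the
protocol: zero threshold 0.2, pseudocount 1, 10 components, fourfold CV,
100 tuning / 10,000 confusion repeats, BER target 0.02, VIP > 1, 4 chains
x 50,000 iterations, lag 10, burn-in 1,000, R-hat < 1.05, SD > 0.5,
P0 > 0.9).

## Layout

```
src/alrpipe/
  tables.py         CountTable / ALRTable containers + TSV I/O
  simulate.py       synthetic two-population count tables with truth
  compositional.py  filtering, pseudocount, reference selection, ALR, scaling
  plsda.py          NIPALS PLS-DA, BER, CV, VIP, selection, confusion
  bayes.py          Gibbs two-group model, R-hat, HPD, relevance screen
  diversity.py      alpha indices, Mann-Whitney U, Bray-Curtis, NMDS, PERMANOVA
  pipeline.py       end-to-end orchestration and run report
  cli.py            click command-line interface
tests/              pytest suite (unit, property, and acceptance tests)
scripts/acceptance.py
```
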