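# miresponse

Discovery of **circulating miRNA biomarkers of drug response** from paired
miRNA/mRNA expression profiles, and prediction of responder status with an
RBF-kernel support vector machine.

The package targets the common clinical setting in which a small discovery
cohort (here modeled on rheumatoid-arthritis patients treated with an
anti-rheumatic drug, ~6 responders vs ~6 non-responders, profiled in
PBMCs) must yield a handful of blood-borne miRNA markers plus a working
response classifier. It chains:

1. **Differential screening** with a random-variance-model (RVM) moderated
   t-test. Per-feature variances s² are shrunk toward an inverse-gamma
   prior fitted across features (s²·a·b ~ F(d, 2a)); the moderated
   statistic t = (x̄₁−x̄₂)/(σ̃·√(1/n₁+1/n₂)) with
   σ̃² = (d·s² + 2/b)/(d + 2a) gains 2a degrees of freedom — decisive at
   n = 6 + 6. Screen: |log2FC| > 0.5 and p < 0.05 (strict), BH-FDR
   q-values reported.
2. **Target-prediction intersection**: miRNA→gene pairs kept only when two
   prediction sources agree.
3. **Anti-correlated co-expression network**: a bipartite edge (m, g)
   requires both endpoints differentially expressed, Pearson r < 0 with
   p < 0.05 across samples, and opposite fold-change direction; the key
   miRNA is the highest-degree node.
4. **Interaction-network topology**: gene–gene interactions with combined
   score strictly above the global median form the signal-transduction
   network; per node, degree, relative betweenness
   C′B(v) = [2/(n²−3n+2)]·Σ σst(v)/σst and closeness C(i) = 1/Σ d(y,i)
   are computed; hubs exceed all three medians simultaneously; Markov
   clustering (expansion/inflation flow simulation) splits the network
   into functional modules, with hypergeometric gene-set enrichment; edge
   betweenness ranks the key interactions.
5. **Panel assembly**: the endpoint genes of the top edge-betweenness
   interactions anchor the panel; each contributes its most significantly
   dysregulated upstream miRNA.
6. **Classification**: RBF-SVM (K(xi,xj) = exp(−γ‖xi−xj‖²)), responder
   = +1, evaluated by repeated stratified 5-fold cross-validation with
   train-only feature scaling; sensitivity/specificity/accuracy from
   confusion counts, AUC as the Mann–Whitney probability, DeLong tests for
   AUC comparisons, and a 2^−ΔΔCt helper for qPCR validation cohorts.

A synthetic-cohort generator with planted ground truth (effect sizes,
miRNA→target coupling, decoy predictions, a community-structured
interaction graph with a high-betweenness bridge) makes every stage
testable end to end without clinical data.

## Worked example

One command simulates a discovery cohort at the default study conditions
(6 vs 6 samples, 4 planted miRNAs with |log2FC| = 1.5, noise sd 0.3) and
runs the full pipeline:

```bash
miresponse demo --seed 7 --out demo_run/
```

```text
Circulating miRNA response-biomarker discovery
======================================================
Samples: 12 (6 responders / 6 non-responders)
DE screen: |log2FC| > 0.5, p < 0.05 (RVM t-test)
  miRNAs: 4 significant (2 up / 2 down) of 60
  mRNAs:  21 significant (11 up / 10 down) of 150
Predicted pairs (both sources): 20
Co-expression network: 4 miRNAs, 20 genes, 20 anti-correlated edges
Interaction network: 9 genes, 17 edges (score > median)
  hub genes (all features > median): GENE001
  MCL modules: sizes [5, 4]
  top edge betweenness: ('GENE001', 'GENE007') = 20
Panel (4 miRNAs): miR-01, miR-02, miR-03, miR-04
Cross-validation (5-fold x 5):
  accuracy    1.0000
  sensitivity 1.0000
  specificity 1.0000
  AUC         1.0000
Single-marker CV AUC:
  miR-01           1.0000
  miR-02           1.0000
  miR-03           0.9722
  miR-04           1.0000
```

Reading the output: the screen finds exactly the 4 planted miRNAs (plus a
handful of target genes among the 21 mRNAs); the prediction intersection
strips all decoy pairs, leaving the 20 true miRNA→target couplings; the
median-score filter reduces the interaction table to the two planted
gene communities joined by their bridge, whose edge betweenness (20 here:
every cross-community shortest path) tops the ranking; the bridge and
tied key interactions anchor the panel, which recovers the planted miRNA
set; and the cross-validated SVM on those 4 markers separates responders
from non-responders perfectly — matching, and never beaten by, each
single marker.

Stage outputs (DE tables, network GraphML/TSV, topology and
edge-betweenness tables, module assignments, panel with provenance, CV
report, manifest with digests) land under `demo_run/results/`.

The library API mirrors the familiar model/results pattern:

```python
from miresponse import ResponseBiomarkerModel, RunConfig, SyntheticSpec
from miresponse.simulate import generate_all

mi, mr, ann, ta, tb, inter, truth = generate_all(SyntheticSpec(seed=7))
res = ResponseBiomarkerModel(mi, mr, ann, ta, tb, inter,
                             config=RunConfig(seed=7)).fit()
print(res.summary())
res.panel_mirnas          # ['miR-01', 'miR-02', 'miR-03', 'miR-04']
res.cv_report.mean_auc    # 1.0
```

`examples/worked_example/` holds a tiny fixed cohort (12 samples,
8 miRNAs, 12 genes, seed 2024) in every input format the pipeline reads —
useful for inspecting the file contracts. Real data enter through
`read_expression` (plain TSV or GEO series-matrix dialect),
`read_target_pairs` and `read_interactions`.

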