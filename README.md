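# methnet

Methylation-directed analysis of *cis*-regulatory networks in tumor
cohorts. The package scores enhancer and silencer activity from
bidirectional reporter-assay read counts, maps associations between CpG
methylation and gene expression across a cohort, clusters the associated
sites into same-sign regulatory units, and builds small combinatorial
methylation-based models that predict a gene's expression — validated by
leave-one-out cross-validation. A synthetic cohort generator with planted
ground truth makes every stage testable without external data.

## Who this is for

Computational epigenomics groups analysing matched methylation +
expression tumor cohorts (eQTM-style mapping) and massively parallel
reporter assays (MPRA/STARR-seq) adapted to detect both enhancers and
silencers, and anyone who needs a transparent, seeded reference
implementation of this analysis chain.

## The model

**Reporter activity.** For a genomic element *j* with RNA and DNA read
counts, the transcriptional activity score is

    TAS_j = log2( (RNA_j / DNA_j) / (RNA_total / DNA_total) )

so TAS > 0 marks enhancers and TAS < 0 silencers relative to the
library-wide baseline. Scores are aggregated in 500-bp half-overlapping
windows, tested by a 2×2 Pearson chi-square against the library totals,
and BH-corrected; elements need q < 0.05 and ≥ 100 RNA reads. Comparing
unmethylated vs in-vitro-methylated runs classifies methylation-sensitive
elements (|ΔTAS| ≥ log2 1.5) into groups: I (enhancer weakened/switched),
II (enhancer strengthened), III (silencer strengthened), IV (silencer
weakened/switched).

**Circuits.** A *cis*-regulatory circuit is a Spearman association
between one CpG site's beta value and one gene's log2 expression within
±1 Mb of the gene's TSS, retained at BH FDR < 5% and ρ² > 0.3 (sites
observed in ≥ 8 samples). Filters flag — never delete — circuits
explained by blood contamination (site tracks PTPRC expression,
ρ² > 0.1), secondary effects through another gene's promoter or gene
body, or a mismatch with the reporter-assay response class.

**Units and networks.** A regulatory unit is a genomic cluster of a
gene's retained sites that share the association sign (greedy merge,
max gap 1 kb). A gene's expression is modelled as the signed sum of its
positive and negative unit effects.

**Models and validation.** For each gene, every combination of 1–4
retained sites with jointly complete data in ≥ 12 samples is fitted by
OLS; the overall-F p-values are BH-corrected per gene and the strongest
significant model wins (synergic when it beats every member site alone).
A LASSO variant with no site cap cross-checks the site counts.
Leave-one-out validation re-derives circuits and models on N−1 samples
and predicts the held-out tumor; a prediction within 2-fold (|log2
error| ≤ 1) is a success, and a gene is verified when it succeeds in
≥ ceil(20/24·N) rounds.

## Worked example

```python
from methnet import (SimulationConfig, simulate_cohort, map_circuits,
                     build_units_all, unit_stats, loo_validate)

cfg = SimulationConfig(seed=42, n_genes=4, unit_coupling=1.0,
                       sites_per_unit_min=2, sites_per_unit_lambda=1.0,
                       missing_rate=0.02, n_reference_samples=2000)
meth, expr, genes, truth = simulate_cohort(cfg)

circuits = map_circuits(meth, expr, genes)
print(f"tested pairs: {len(circuits)}, retained circuits: {int(circuits['retained'].sum())}")

units = build_units_all(circuits)
stats = unit_stats(units, circuits)
print(f"units: {stats['n_units']}, mean span: {stats['mean_size_bp']:.0f} bp, "
      f"mean sites/unit: {stats['mean_sites_per_unit']:.1f}")

predictions, report = loo_validate(meth, expr, genes)
modeled = predictions[predictions["had_model"]]
print(f"leave-one-out: {len(modeled)} predictions, "
      f"{100*modeled['success'].mean():.1f}% within 2-fold, "
      f"{int(report['verified'].sum())}/{len(report)} genes verified")
```

Output:

```
tested pairs: 90, retained circuits: 30
units: 10, mean span: 900 bp, mean sites/unit: 3.0
leave-one-out: 96 predictions, 89.6% within 2-fold, 3/4 genes verified
```

Ninety gene × site pairs fall inside the four genes' ±1 Mb domains; the
30 retained circuits are exactly the planted regulatory sites, which
cluster into 10 units whose spans and site counts match the planted
architecture. At the generator's default expression noise (0.25 log2
units), roughly 90% of held-out predictions land within 2-fold of the
observation and 3 of 4 genes clear the verification threshold.

The same chain is available from the shell:

```sh
methnet simulate --seed 17 --out fixtures/
methnet tas      --segments fixtures/segments.tsv --regions fixtures/regions.bed --out elements.tsv
methnet circuits --meth fixtures/meth.tsv --expr fixtures/expr.tsv --genes fixtures/genes.tsv --out circuits.tsv
methnet units    --circuits circuits.tsv --out units.tsv
methnet models   --circuits circuits.tsv --meth fixtures/meth.tsv --expr fixtures/expr.tsv \
                 --genes fixtures/genes.tsv --out models.tsv
methnet run      --config run.yaml   # full pipeline with a manifest
```

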