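# dcenet

Within-individual time-series co-expression networks for repeated-measures
transcriptomics.

## The problem

In longitudinal expression studies — e.g. adipose-tissue biopsies taken from
each participant before weight loss, after weight loss and after a weight
maintenance phase, under two different diet arms — the interesting signal is
how genes move *together over time within each person*. Pooling samples
across individuals to compute gene–gene correlations destroys exactly that
structure and is confounded by between-individual baseline differences.

`dcenet` implements a complete, testable workflow for such designs:

1. **Background filtering.** Y-chromosome genes are silent in females, so
   their measured signal in female samples estimates the platform noise
   floor. Genes whose median expression over the whole dataset is equal to or
   below that floor are removed.
2. **Paired differential expression.** Per gene, per individual differences
   d_i = x(t_B, i) − x(t_A, i) within one group; a one-sample t on the d_i
   (plain, or with limma-style empirical-Bayes variance moderation
   s̃²_g = (d₀s₀² + df·s²_g)/(d₀ + df), d₀ and s₀² fitted by method of
   moments on log sample variances). Genes pass with |FC| ≥ 1.2 and
   p < 0.05, with Storey q-values reported alongside (π₀ fixed at 1 makes
   them exactly Benjamini–Hochberg).
3. **Within-individual correlation networks.** Pearson correlations of gene
   pairs across each individual's own T time points. A pair becomes an edge
   when |r_i| ≥ 0.6 for at least 25 % of the group's individuals and all
   qualifying correlations share one sign; edge weight is the mean r over
   the qualifying individuals, so positive edges mean similar trajectories
   and negative edges mirrored ones.
4. **Overlap network.** Sign-consistent edge intersection of the two group
   networks — the co-expression behaviour shared across conditions.
5. **Variability diagnostics.** Frobenius distance
   ‖A − B‖_F = √(Σᵢ Σⱼ |aᵢⱼ − bᵢⱼ|²) between each individual's correlation
   matrix and the group mean matrix ranks individuals by how atypical their
   co-expression structure is.
6. **Clustering and enrichment.** Modularity communities of the overlap
   network (small components stay "unclustered"), degree reports, and
   hypergeometric over-representation of clusters in user-supplied GMT gene
   sets (gates: overlap ≥ 2, p ≤ 0.01, optional number-or-percentage rule).

A synthetic study generator with planted co-expression modules and full
ground truth (module membership, loading signs, planted edges) makes every
stage testable end to end without any external data.

## Worked example

```python
from dcenet import run_pipeline
from dcenet.simulate import default_study_spec, generate_study, truth_edge_metrics

spec = default_study_spec(seed=42)           # 2 groups x 12 individuals x 3 time points
expr, chrom, truth = generate_study(spec)    # 260 genes: 40 module, 200 background, 20 Y
result = run_pipeline(expr, chrom)
for line in result.log:
    print(line)
shared = truth_edge_metrics(result.overlap, truth, scope="shared")
print(f"shared planted-edge recall: {shared['recall']:.3f}")
print(result.distances["LCD"].head(3).to_string())
```

prints

```
background filter: threshold 4.3127, kept 60/260 genes
DE LCD 2-1: 32 significant of 60 genes (pi0 0.583)
DE LCD 3-1: 25 significant of 60 genes (pi0 0.017)
DE union LCD: 33 genes
DE VLCD 2-1: 27 significant of 60 genes (pi0 0.540)
DE VLCD 3-1: 20 significant of 60 genes (pi0 0.986)
DE union VLCD: 27 genes
network LCD: 33 nodes, 160 edges (63 negative)
network VLCD: 26 nodes, 64 edges (24 negative)
overlap: 19 genes, 32 edges (7 negative)
clusters: sizes [8, 6, 5], 0 unclustered genes
shared planted-edge recall: 0.381
LCD08    25.389618
LCD10    22.755353
LCD09    21.027049
```

Reading this: the pooled female Y-gene median (4.31 log2 units) removes all
200 background genes while every planted module gene survives; paired DE
recovers most active-module genes per diet group; the per-group networks
retain strong sign-consistent correlations; their intersection keeps 19
genes in 32 same-direction edges, which cluster cleanly into the three
planted shared modules (sizes 8/6/5). With only three time points per
individual, per-individual Pearson correlations are intrinsically noisy, so
the overlap recovers a conservative subset of the planted shared edges
(recall 0.38 here) while excluding all group-unique module edges. The last
three lines are the most atypical LCD individuals by Frobenius distance.

The same workflow is scriptable from the shell:

```sh
dcenet simulate --out-dir sim --seed 42
dcenet run-all --config pipeline.yaml      # filter -> DE -> networks -> overlap -> cluster
```

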