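# chromonet

Mutual-information co-expression networks and the loss of inter-chromosomal
co-regulation in tumour transcriptomes.

`chromonet` is for computational biologists who want to contrast the
*structure* of transcriptional co-regulation between two phenotypes —
typically tumour vs. normal tissue — from gene-level RNA-seq counts. It
implements the full chain: count/annotation integration, bias-aware
normalization, moderated differential expression, per-phenotype
mutual-information (MI) network inference, and chromosomal network topology.
A synthetic-data generator reproduces the two regimes the analysis is built
to detect, so the whole pipeline is testable end to end without any cohort
download.

## The analysis

For each phenotype, pairwise dependence between genes i and j is scored by
mutual information,

    MI(i, j) = Σ p(x_i, x_j) ln [ p(x_i, x_j) / (p(x_i) p(x_j)) ],

estimated by rank-based equal-frequency binning with bias correction
(for bivariate Gaussian dependence MI = −½ ln(1 − ρ²), which serves as the
oracle). Each phenotype's network keeps the top fraction f of all C(G, 2)
pair values — `ceil(f · C(G, 2))` edges (at G = 15,281 genes and f = 10⁻⁴
that is 11,675 edges) — recording the resulting MI cut-off. Optional
ARACNE-style pruning removes, in every triangle, the weakest edge (a likely
indirect interaction).

Differential expression fits the gene-wise two-group model
`y_ij = μ + α_i + ε_j` on normalized log2 expression, moderates the
variances empirically (posterior `(d₀s₀² + d s²)/(d₀ + d)`, moderated t with
d₀ + d df), adjusts p-values by Benjamini–Hochberg, and flags genes with
FDR < 10⁻⁵ and |log₂FC| > 1.

The headline statistic is chromosomal: every network edge is classified
intra- or inter-chromosomal, connected components are profiled for
chromosome- and expression-sign purity, and the two phenotypes are compared.
The expected signature is a healthy network whose giant component bridges
chromosomes, against a tumour network fragmented into dense, single-
chromosome, coherently shifted gene clusters.

## Worked example

Run the pipeline on simulated data (300 genes, 80 samples per condition,
keeping the top 0.5% of MI values):

```python
from chromonet import SimulationConfig
from chromonet.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=3, top_fraction=0.005, outdir="example_out",
    simulation=SimulationConfig(n_genes=300, n_healthy=80, n_cancer=80, seed=3),
)
result = run_pipeline(cfg)
for cond, summary in result.report["conditions"].items():
    print(cond, summary["inter_fraction"], summary["topology"]["largest_component"],
          summary["topology"]["n_components"])
```

which prints

```
healthy 0.8222222222222222 171 22
cancer 0.035555555555555556 29 28
```

Both networks keep the same number of edges (225), but they are organised
very differently: 82% of the healthy network's edges join genes on
*different* chromosomes and 171 of its 233 nodes form one giant component,
while the cancer-regime network is almost purely intra-chromosomal (3.6%
inter) and fragments into 28 small components (largest: 29 genes). The run
also reports 72 of 300 genes as differentially expressed (expected false
count 0.003) and writes per-stage TSV artifacts, a manifest and
`report.json` under `example_out/`.

The same pipeline is available from the shell:

```bash
chromonet simulate --n-genes 300 --seed 3 --out data/   # synthetic TSVs + ground truth
chromonet run-all --seed 3 --out full_out               # end-to-end with default config
chromonet network --expr full_out/expression_log2.tsv --samples full_out/samples.tsv \
    --condition cancer --top-fraction 0.005 --out net/  # one stage on existing files
```

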