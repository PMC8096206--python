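# coexnet

Cis/trans gene co-expression network analysis: infer co-expression networks
from two-group expression matrices, detect weighted communities, quantify
chromosomal and expression assortativity, run hypergeometric
overrepresentation analyses, and annotate communities with TF-regulon,
copy-number-peak and CTCF-boundary evidence. A seeded synthetic-data
generator plants the statistical structure the analysis measures (a tunable
"loss of trans- co-expression" contrast between two phenotypes), so the whole
pipeline is testable offline.

## Modules

| module                | what it does |
|-----------------------|--------------|
| `coexnet.simulate`    | toy genome annotation, latent-factor log2 expression with planted cis/trans modules, BED peak tracks (uniform / gene-spanning / boundary-enriched), TF regulon tables, GMT term sets |
| `coexnet.inference`   | pairwise MI (equal-frequency binning, Miller–Madow correction, nats) or Pearson; pooled permutation p-values; top-k selection; cis/trans edge labels; cis-fraction curves; score histograms; position-ordered correlation matrix |
| `coexnet.communities` | four igraph community algorithms (Louvain default), weighted Newman–Girvan modularity, Jaccard partition comparison, chromosomal / expression assortativity, PageRank community naming |
| `coexnet.diffexpr`    | two-group gene-wise t-test with optional empirical-Bayes variance moderation, over/under/unchanged calls (|LFC| >= 0.5, p < 0.05) |
| `coexnet.enrichment`  | exact hypergeometric upper tail, Benjamini–Hochberg, community-vs-term and community-vs-CNA-peak overrepresentation |
| `coexnet.context`     | peak -> fully-spanned-gene remapping, strand-aware promoter windows, per-TF regulatory degree, three-way CTCF site classification, cis-community boundary analysis |
| `coexnet.pipeline`    | YAML-driven end-to-end run with report + artifact-hash manifest (bit-identical under a fixed seed) |

## CLI

Every stage is a subcommand of `coexnet`; `pipeline run` chains them all.

```sh
# synthetic input bundle (expression, phenotype, annotation, peaks, regulons, GMT)
coexnet simulate --out demo --seed 1

# one network
coexnet infer --expr demo/inputs/expression.tsv --pheno demo/inputs/phenotype.tsv \
    --group tumor --annotation demo/inputs/annotation.tsv \
    --measure mi --top-k 5000 --out net.tsv --seed 1

coexnet de --expr demo/inputs/expression.tsv --pheno demo/inputs/phenotype.tsv \
    --ref healthy --alt tumor --out de.tsv
coexnet communities --net net.tsv --annotation demo/inputs/annotation.tsv \
    --de de.tsv --out comm/ --seed 1
coexnet enrich --communities comm/communities_louvain.tsv --gmt demo/inputs/terms.gmt \
    --universe demo/inputs/expression.tsv --out enrichment.tsv
coexnet context ctcf --profiles comm/community_profiles_louvain.tsv \
    --communities comm/communities_louvain.tsv \
    --annotation demo/inputs/annotation.tsv --peaks demo/inputs/ctcf.bed --out ctcf/

# everything from one config
coexnet pipeline run --config run.yaml --out out/
```

A minimal `run.yaml`:

```yaml
seed: 1
simulate:
  n_genes: 600
  n_modules: 8
  genes_per_module: 15
  n_samples: {healthy: 113, tumor: 217}
inference: {measure: mi, top_k: 5000}
communities: {algorithm: louvain}
curves: {k_grid: [1000, 5000]}
```

Real data drops in by replacing the `simulate` block with an `inputs` block
pointing at expression/phenotype/annotation TSVs, BED peak tracks, a regulon
TSV and a GMT file.

## Conventions

* Coordinates are 0-based half-open in memory and in BED; the annotation TSV
  is written 1-based inclusive behind a `# coords=1-based-inclusive` header.
* Chromosome names are normalized (leading `chr` stripped) on load.
* MI is reported in nats; `n_bins` defaults to `max(2, ceil(sqrt(n)/2))`.
* Three promoter-window presets exist (`regulon` −1000/+100,
  `tss_minimal` −100/+10, `ctcf` +1000/−500); nothing is silently merged.
* All randomness flows from explicit seeds; pipeline reruns are
  byte-identical and hashed into `manifest.json`.
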