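# penguinproc

Downstream microbiome analytics for a two-species × two-stage (feeding vs
moulting) faecal-community study design, exercised end-to-end on synthetic
OTU tables and phylogenies:

- **Preprocessing** — singleton removal, rarefaction (uniform
  without-replacement subsampling to a fixed depth), Hellinger transform,
  relative abundances, taxonomic rank aggregation.
- **Diversity & ordination** — Shannon index / richness, Bray–Curtis
  dissimilarities, NMDS (Kruskal stress-1 with pool-adjacent-violators
  isotonic regression, multiple random starts), group SD ellipses.
- **Inference** — two-factor PERMANOVA with interaction (sequential SS,
  unrestricted permutations), Welch's t-tests, per-taxon differential
  relative abundance with Benjamini–Hochberg adjustment.
- **Community-assembly partitioning** — abundance-weighted βMNTD, βNTI via a
  tip-label-shuffle null, Bray–Curtis Raup–Crick (RC) via a probabilistic
  reassembly null, and the five-way classification of pairwise turnover into
  variable selection, homogeneous selection, dispersal limitation,
  homogenizing dispersal and drift, summarized per group.
- **Synthetic data** — Yule trees, Brownian traits, skewed metacommunities,
  and community generators for neutral/drift, environmental-filtering
  (variable or homogeneous selection) and patch-restricted (dispersal
  limited) regimes, so process recovery can be validated against a known
  ground truth.

## Command line

All analyses are exposed through one CLI:

```bash
# generate a synthetic study (shared TSV + newick + taxonomy + metadata)
penguinproc simulate --config scenario.yaml --seed 1 --outdir sim/

# individual stages
penguinproc diversity --shared sim/shared.tsv --depth 500 --seed 1 --out div.tsv
penguinproc distance  --shared sim/shared.tsv --depth 500 --seed 1 --out bc.tsv
penguinproc ordinate  --shared sim/shared.tsv --depth 500 --seed 1 --out nmds.tsv
penguinproc permanova --shared sim/shared.tsv --metadata sim/metadata.tsv \
    --depth 500 --seed 1 --out permanova.tsv
penguinproc diffabund --shared sim/shared.tsv --taxonomy sim/taxonomy.tsv \
    --metadata sim/metadata.tsv --species gentoo --depth 500 --seed 1 --out da.tsv
penguinproc processes --shared sim/shared.tsv --tree sim/tree.nwk \
    --metadata sim/metadata.tsv --depth 500 --seed 1 --outdir proc/

# everything in one seeded, manifest-logged run (synthetic or file inputs)
penguinproc run --config scenario.yaml --seed 1 --outdir out/
penguinproc run --shared shared.tsv --tree tree.nwk --taxonomy tax.tsv \
    --metadata meta.tsv --seed 1 --outdir out/
```

A scenario YAML looks like:

```yaml
n_taxa: 500
depth: 20000
filter_sigma: 0.35
groups:
  - {species: chinstrap, stage: feeding,  n_samples: 7, regime: variable_selection}
  - {species: chinstrap, stage: moulting, n_samples: 6, regime: neutral}
  - {species: gentoo,    stage: feeding,  n_samples: 7, regime: variable_selection}
  - {species: gentoo,    stage: moulting, n_samples: 5, regime: neutral}
```

`penguinproc run` writes every stage output (diversity, distances, NMDS
scores, ellipses, PERMANOVA table, differential abundance, βNTI/RC matrices,
pair classifications, per-group process percentages) plus `manifest.json`;
identical config + seed reproduces the output directory byte for byte.

## Package layout

```
src/penguinproc/
  io_formats.py          shared/taxonomy/newick/metadata readers & writers
  synthetic_data.py      trees, traits, metacommunities, regime generators
  community_matrix.py    singletons, rarefaction, Hellinger, Bray-Curtis, Shannon
  multivariate_stats.py  NMDS, PERMANOVA, Welch t, BH, ellipses
  assembly_processes.py  βMNTD, βNTI, RC, process classification & summaries
  cli_pipeline.py        orchestration, manifest, click CLI
```
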