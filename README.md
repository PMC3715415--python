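# cooccur3

Triplet-based analysis of disrupted gene co-occurrence across genomes.

Interacting proteins often fail to show matching phylogenetic profiles.
One explanation is multi-functionality: a protein shared between two
complexes is retained as long as *either* complex is needed, so its two
partner modules can be lost in complementary lineage sets.  `cooccur3`
implements the full analysis around this idea:

- **Pair classification** — Dollo gain/loss reconstruction on a species
  tree, partial correlation of per-branch event vectors corrected for
  the global trend, subset and taxonomic-subset tests, and the 4-way
  classification (*matching / taxonomic / subset / other*) against
  empirical percentile backgrounds.
- **Triplet scoring** — the complementarity score
  `min(nGood_B, nGood_C) − nBad` for a central gene A and partners B, C,
  with the central-gene (half-of-species) filter and triangle typing
  (*open*, *open with two A in-paralogs*, *closed*) from interaction
  networks with protein-pair provenance.
- **Bin analysis** — equal-count score bins over open + closed triangles
  plus sampled non-interacting triples, with Spearman trends of
  triangle-type fractions.
- **Integration** — cross-tab of classified pairs against
  positive-scoring open triangles, over-representation chi-square tests,
  and a 2-D pair-score × triplet-score log2-enrichment grid.
- **Duplication analysis** — duplication-retention percentages of shared
  subunits (role A) vs. partner genes, with chi-square contrast.
- **Synthetic data** — Yule trees, gene content evolving by origin /
  loss / duplication, planted shared-subunit architectures and planted
  pair categories with ground-truth labels for recovery tests.

The package ships the two worked-example triplets (TOR complex and
emerin-related complexes; 6 orthologous groups × 51 species) as packaged
TSV data: `cooccur3.table2_fixture()`.

## Command line

```bash
cooccur3 simulate --config sim.yaml --seed 42 -o outdir/
    # -> tree.nwk, profiles.tsv, complexes.tsv, pairs.tsv, og_map.tsv, truth.json

cooccur3 net-stats --pairs pairs.tsv [--complexes cx.tsv]
cooccur3 classify-pairs --profiles m.tsv --tree t.nwk --pairs og_pairs.tsv \
    --percentile 90 --seed 1 -o pairs_out.tsv
cooccur3 score-triplets --profiles m.tsv --tree t.nwk --network pairs.tsv \
    --og-map map.tsv --sample 1000 --seed 1 -o triplets.tsv
cooccur3 bin-analysis --triplets triplets.tsv --n-bins 20 -o bins.tsv
cooccur3 integrate --pairs pairs_out.tsv --triplets triplets.tsv -o crosstab.json
cooccur3 duplication --triplets triplets.tsv --profiles m.tsv -o dup_stats.tsv
cooccur3 run --config run.yaml     # full pipeline -> report.json
```

All tabular formats are plain TSV (UTF-8, `#` comments ignored); trees
are Newick.  Every stochastic step takes an explicit seed.

## Layout

```
src/cooccur3/
  model.py        core types (panel, profiles, complexes, networks)
  tree.py         rooted species tree, branch IDs, LCA
  io.py           TSV/Newick readers and writers
  network.py      covered-complex removal, pair expansion, OG projection
  pairwise.py     Dollo events, partial correlation, pair classification
  triplets.py     complementarity score, triangle typing
  binning.py      equal-count bins, non-interacting sampling, trends
  integration.py  cross-tab, over-representation, enrichment grid
  duplication.py  duplication-retention contrasts
  simulate.py     synthetic trees, gene content, planted architectures
  pipeline.py     end-to-end orchestration and JSON report
  cli.py          click-based CLI
  data/           worked-example profiles (TSV), species panel
```
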