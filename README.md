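# plexrank

Consensus ranking for multiplex social networks. Given per-layer weighted
edge lists over a shared node set, `plexrank`:

1. computes a configured weighted centrality per layer (eigenvector,
   in-degree, total degree, or shortest-path betweenness with distance
   `1/weight`);
2. collapses each layer's centralities into **rank tiers** by 1-D
   complete-linkage hierarchical clustering, cutting at the minimum tier
   count whose tier means explain at least a threshold fraction (default
   99%) of the centrality variance;
3. aggregates tier ranks across layers by **Borda count** (mean layer rank,
   lowest score wins; dense ranks with exact rational tie handling);
4. relates the reversed consensus ranks to node attributes with
   negative-binomial regression (group random intercept via Gauss–Hermite
   quadrature, AICc candidate sets, Akaike weights) and node-label
   **permutation inference** (attribute rows shuffled within group, the
   model refit per replicate, two-tailed empirical p-values);
5. reports pairwise Spearman correlations (midrank ties) between layer
   rankings.

A synthetic multiplex group generator (`plexrank.synth`) produces
macaque-style societies — a latent dominance hierarchy driving directed
aggression / status-signaling / policing layers, and matriline kin blocks
driving undirected grooming / huddling layers — with calibrated layer
densities, so the whole pipeline is testable with no external data. Seven
bundled presets (`GROUP_PRESETS`, groups A–G) match the group sizes, sex
ratios, and layer densities of a published seven-group captive population.

## CLI

```bash
# generate a synthetic group (writes edge lists, attributes, layers.yaml)
plexrank simulate --preset A --seed 7 --out demo/

# layers -> tiers -> consensus (+ layer correlations, r²-vs-k curves)
plexrank rank --layers demo/layers.yaml --attributes demo/attributes.csv \
              --threshold 0.99 --out results/

# pairwise Spearman correlations only
plexrank correlate --layers demo/layers.yaml --out corr.csv

# model fitting, AICc selection, permutation p-values
plexrank infer --layers demo/layers.yaml --attributes demo/attributes.csv \
               --replicates 1000 --seed 0 --out inference/
```

Layer configuration is YAML (`name`, `path`, `directed`, `metric`, optional
`threshold`); edge lists are CSV/TSV with a `source,target[,weight]` header
(duplicate rows sum — weights are interaction frequencies); attributes are
CSV with columns `node, group, sex, age, dominance_rank,
dominance_certainty, matriline_size, rearing`. Dominance certainty is
transformed on load (`dc = 1 − certainty`, 0 = fully certain) and matriline
size is bucketed into `1-5 / 6-10 / 11+`.

## Package layout

| module | contents |
|---|---|
| `plexrank.core_io` | domain types (layers, multiplex, attribute table), CSV/YAML readers and writers |
| `plexrank.centrality` | weighted eigenvector / degree / betweenness centralities, dense ranks |
| `plexrank.tiering` | 1-D complete-linkage tiers with explained-variance cut |
| `plexrank.consensus` | Borda scores, dense consensus ranks, reversed ranks |
| `plexrank.similarity` | Spearman layer-correlation matrices |
| `plexrank.inference` | NB regression (random/fixed group effect), AICc, permutation tests |
| `plexrank.synth` | synthetic group generator, presets, null-attribute redraws |
| `plexrank.pipeline` | end-to-end orchestration shared by CLI and scripts |
| `plexrank.cli` | `plexrank rank / correlate / infer / simulate` |

## Conventions worth knowing

- Eigenvector centrality uses the out-going convention (a node's score grows
  with the scores of nodes it points to) and adds uniform teleportation mass
  `1e-3/N` when the layer is not strongly connected.
- Dense-rank ties are judged after rounding to 12 significant digits.
- Tiering distance ties merge the leftmost (highest-centrality) pair first.
- Permutation p-values are reported both as corrected two-tailed empirical
  p `2·min(q, 1−q)` with the `(1+count)/(1+R)` adjustment and as the raw
  2.5%/97.5% tail rule.
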