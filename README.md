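# ghfcooc — GH-family co-occurrence networks in prokaryotic genomes

Glycoside hydrolases (GHs) are the core enzymes with which bacteria and
archaea break down polysaccharides; the CAZy classification sorts them
into sequence-based families (GH1, GH13, ...).  Families that act on
the same substrate tend to travel together across genomes — a species
that debranches rhamnogalacturonan II usually carries the whole set of
families needed to do it.  `ghfcooc` turns strain-level GH-family gene
counts into validated co-occurrence networks and functional
classifications, for microbiologists and bioinformaticians studying
carbohydrate utilisation, enzyme mining, or genome-scale comparative
analysis.

The pipeline:

1. **Bias control.** Strain tables are collapsed to one row per
   species three ways: `aveF` (mean counts, rounded), `minF` / `maxF`
   (the strain with fewest / most distinct families, alphabetic tie
   break), so no heavily sequenced species dominates.
2. **Occurrence statistics.** Per family and domain: occurrence
   frequency `n_present / n_species` and average gene number
   `total_genes / n_present`, with bacteria-vs-archaea comparison
   flags that must hold in all three matrices.
3. **Edge validation.** A family pair is an edge only if its Spearman
   rank correlation satisfies ρ > 0.45 with p < 0.001 in aveF, minF
   *and* maxF; strength classes (strong ρ > 0.6, moderate 0.45–0.6)
   follow aveF.  Species networks use ρ > 0.8 on aveF profiles.
4. **Network analysis.** Weighted undirected graphs, seeded Louvain
   modules at resolution 1, Newman–Girvan modularity Q, clustering
   coefficient and hop-based path metrics, GEXF/GraphML export for
   Gephi.
5. **Functional groups.** A curated 12-group table (A–L) maps modules
   to enzymatic functions; species become *type-X* microbes when they
   carry ≥ 2 families of group X (fit levels partial / large ≥ 75 % /
   perfect).  Group gene doses are summarised per species as `aveG`,
   displayed after a √ then row-wise z-score transform.
6. **Co-evolution screening.** The mirror-tree statistic: Pearson
   correlation between two families' matched inter-protein distance
   matrices.
7. **Synthetic communities.** A seeded generator plants co-occurring
   family groups in zero-inflated count profiles and returns the
   ground truth, so edge and module recovery can be scored exactly.

## Worked example

```python
from ghfcooc import (build_all, build_graph, detect_modules,
                     generate_community, pair_fraction,
                     pairwise_family_edges, score_recovery,
                     topology_summary)
from ghfcooc.synthetic_data import SimParams

records, truth = generate_community(SimParams(seed=7, n_species=200))
ave, minm, maxm = build_all(records)            # 200 species x 60 families
edges = pairwise_family_edges(ave, minm, maxm)  # all 1770 pairs
validated = [e for e in edges if e.validated]
print(len(validated), pair_fraction(len(validated), len(ave.columns)))

graph = build_graph(validated)
part = detect_modules(graph, seed=7)
s = topology_summary(graph, part)
print(f"nodes={s.n_nodes} edges={s.n_edges} Q={s.modularity_Q:.3f} "
      f"modules={s.n_modules}")
score = score_recovery(truth, edges, part)
print(f"recall={score.recall:.2f} precision={score.precision:.2f} "
      f"ARI={score.adjusted_rand:.2f}")
```

prints

```
75 4.2
nodes=30 edges=75 Q=0.800 modules=5
recall=1.00 precision=1.00 ARI=1.00
```

The generator planted 5 groups of 6 co-occurring families among 60;
the three-matrix rule validated exactly the 75 within-group pairs
(4.2 % of all family pairs), and Louvain recovered the 5 planted
groups as modules (adjusted Rand 1.0) with a strongly modular network
(Q = 0.80).

The same run is available from the shell:

```sh
ghfcooc run-all --out-dir results/demo --seed 7
```

which writes the genome table, the three matrices, occurrence
statistics, the edge table, the Gephi-ready network, type
assignments, the aveG dose matrix and a JSON summary — byte-identical
for identical seeds.

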