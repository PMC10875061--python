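# mbgraph

Visualize microbiome abundance tables as **attributed bipartite composition
graphs** — without aggregating taxa into higher taxonomic levels and without
dropping low-abundance reads.

Most composition plots (stacked bars, heat maps, Venn diagrams) either
aggregate OTUs/ASVs into a taxonomic level or fold rare taxa into an
"other" bucket. `mbgraph` instead keeps every observed taxon: the
samples×taxa count table `X` is transformed into a directed bipartite graph
in which every sample (row) and every taxon (column) is a node and every
strictly positive cell `X[s,t] > 0` becomes an edge `s → t` carrying both
the absolute count and the within-sample relative abundance
`X[s,t] / Σ_t X[s,t]`. The transformation is lossless — the positive cells
are exactly recoverable from the edge list — and the graph's topology
directly answers the questions practitioners ask first: which taxa are
unique to single samples, and which are shared (the core microbiome).

Who it is for: microbiome / 16S researchers doing in-depth exploration of
small, carefully chosen sample sets (tens of samples), and tool builders
who want the graph, layout, and color encodings as a library.

## What it computes

* **Node attributes** — per taxon: taxonomy ranks, prevalence (number of
  samples it occurs in), total relative abundance (column sum / grand
  total); per sample: Chao1, Shannon (nats), Inverse-Simpson, plus
  metadata such as a grouping variable.
* **Beta diversity** — Bray-Curtis, binary Jaccard, and Jensen-Shannon
  divergence (nats) as pairwise sample matrices.
* **Layout** — a cooled, velocity-damped force simulation with many-body
  repulsion, edge springs, centering, a *radial bipartite* force (samples
  pushed to a circle's periphery; each taxon pulled to radius
  `r_max·(n−k)/(n−1)` for prevalence `k` of `n` samples, so the core
  microbiome collapses to the center), and optional group-separation
  forces that pull cohorts to distinct screen regions.
* **Color encodings** — categorical hues, single-hue saturation ramps,
  binned and sequential multi-hue ramps, and an MDS→CIELAB mapping:
  classical (Torgerson) scaling embeds a beta-diversity matrix in 3-D and
  the axes drive L*, a*, b*, so similar samples get perceptually similar
  colors (ΔE ≈ geometric distance).
* **Views** — node-link SVG, per-genus small multiples with a common
  layout, hover-highlight states, and a seriated adjacency matrix
  (hierarchical clustering + optimal leaf ordering) with a prevalence
  barcode and a brushable column range.

## Worked example

```bash
python examples/01_build_graph.py
```

```
table: 10 samples x 85 taxa, 300 positive cells
graph: 95 nodes, 300 edges

sample01: group=group01, chao1=30.0, shannon=3.204 nats, inverse_simpson=21.45
core_001: genus=g__core, prevalence=10/10, total_relative_abundance=0.0153
```

300 positive cells become exactly 300 edges (losslessness); `core_001`
occurs in all 10 samples, so the radial force will place it at the layout
center. `examples/02_layout_and_render.py` then prints

```
group01: sample x-range [ -145.6,  -128.1]
group02: sample x-range [  117.8,   150.6]
mean radius: core taxa 12 px, sample-specific taxa 208 px
```

— the two cohorts occupy disjoint x-ranges (group forces) and core taxa sit
~12 px from the center while sample-specific taxa sit near the 200 px rim
(radial force). The remaining examples cover beta-diversity coloring,
highlights/small multiples, and the seriated matrix.

The same pipeline is scriptable from the shell:

```bash
mbgraph synth --seed 1 demo/
mbgraph build demo/abundance.tsv --taxonomy demo/taxonomy.tsv \
        --metadata demo/metadata.tsv demo/graph.json
mbgraph layout demo/graph.json --seed 2 --group-by group demo/layout.json
mbgraph render demo/graph.json demo/layout.json --table demo/abundance.tsv \
        --color-samples beta:bray --color-taxa prevalence demo/fig.svg
mbgraph matrix demo/abundance.tsv demo/matrix.svg
```

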