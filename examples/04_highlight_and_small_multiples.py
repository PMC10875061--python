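"""Hover highlight and taxonomy small multiples.

Computes the highlight state for one core taxon (which samples contain
it, colored by its within-sample relative abundance) and renders one
panel per genus with a common layout to scratch/small_multiples.svg.
"""
import os

import mbgraph as mg
from mbgraph import color as mc

table, taxonomy, metadata = mg.generate(mg.SyntheticSpec(seed=1))
graph = mg.build_graph(table, taxonomy=taxonomy, metadata=metadata)

focal = "core_001"
state = mc.highlight(graph, focal)
print(f"hovering {focal}: observed in {len(state.neighbor_colors)} of "
      f"{len(graph.samples)} samples; {len(state.faded_ids)} other nodes faded")
for s in sorted(state.neighbor_colors)[:3]:
    w = graph.edge_weight_relative(s, focal)
    print(f"  {s}: relative abundance {w:.4f} -> {state.neighbor_colors[s]}")
print("  (more saturated = higher relative abundance in that sample)")

positions = mg.run_layout(graph, mg.LayoutConfig(seed=2))
svg = mg.render.render_small_multiples(graph, positions, "genus",
                                       max_panels=12)
os.makedirs("scratch", exist_ok=True)
with open("scratch/small_multiples.svg", "w") as fh:
    fh.write(svg)
print("wrote scratch/small_multiples.svg "
      "(one panel per genus, red = that genus, common layout)")
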