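"""Rank marker genes by lineage-monophyly congruence and select the top 25%.

Simulates 100 gene trees with 40% regraft events, scores each tree by
the fraction of predefined lineages it keeps monophyletic, and shows
that the top-ranked quarter is strongly enriched in event-free markers.
"""

from markersieve import (
    SimulationConfig,
    clades_from_taxonomy,
    rank_and_select,
    score_marker,
    simulate_gene_trees,
    simulate_species_tree,
)

cfg = SimulationConfig(n_clades_A=2, n_clades_B=2, taxa_per_clade=4,
                       n_outgroup=2, focal_size=2, n_markers=100,
                       hgt_rate=0.4, contaminant_rate=0.1, seed=7)
species, taxmap = simulate_species_tree(cfg)
trees, truth = simulate_gene_trees(species, taxmap, cfg)
clades = clades_from_taxonomy(taxmap)

scores = [score_marker(t, clades) for t in trees]
sel = rank_and_select(scores, top_fraction=0.25)
clean = set(truth.clean_ids())

print(f"scored {len(scores)} markers against {len(clades)} lineages")
top_clean = sum(1 for m in sel.selected if m in clean)
bottom = sel.ranked[-len(sel.selected):]
bottom_clean = sum(1 for m in bottom if m in clean)
print(f"top 25% ({len(sel.selected)} markers): {top_clean} event-free")
print(f"bottom 25%: {bottom_clean} event-free")
# Event-free markers recover every lineage (score 1.0) and so concentrate
# at the top; regrafts/contaminants break lineages and sink the marker.
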