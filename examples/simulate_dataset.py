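"""Generate a synthetic phylogenomic study with known ground truth.

Builds a species tree (outgroup, TACK-like series A, Asgard-like series
B, a focal clade), derives 40 gene trees of which a fraction carry a
focal-clade regraft or a contaminant leaf, and prints the event ledger.
"""

from collections import Counter

from markersieve import SimulationConfig, simulate_gene_trees, simulate_species_tree

cfg = SimulationConfig(
    n_clades_A=2, n_clades_B=2, taxa_per_clade=3, n_outgroup=2, focal_size=2,
    n_markers=40, hgt_rate=0.3, contaminant_rate=0.1, seed=42,
)
species, taxmap = simulate_species_tree(cfg)
trees, truth = simulate_gene_trees(species, taxmap, cfg)

print(f"species tree: {len(species.leaf_ids)} genomes, "
      f"{len(taxmap.clades())} named clades")
events = Counter(r.graft_group for r in truth.records.values())
n_contam = sum(1 for r in truth.records.values() if r.contaminant_leaf)
print(f"gene trees: {len(trees)}  grafts A/B/none = "
      f"{events['A']}/{events['B']}/{events['none']}  contaminants = {n_contam}")
print("clean markers (match the species topology exactly):",
      len(truth.clean_ids()))
# A clean marker is one whose bipartitions equal the species tree's; every
# non-clean marker carries at least one recorded discordance event.
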