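"""Pool marker sets from several studies into a nonredundant catalog.

Uses the synthetic stand-in for the deposited marker table: seven source
sets pooling to 248 nonredundant markers, with four ranked selections
sharing a 19-marker core.
"""

from markersieve import count_by_source, dereplicate, subset_catalog
from markersieve.simulate import synthetic_published_sets

source_sets, selections = synthetic_published_sets()
catalog = dereplicate(source_sets)
print(f"pooled {sum(len(v) for v in source_sets.values())} accessions from "
      f"{len(source_sets)} sets -> {len(catalog)} nonredundant markers")
print(f"asCOG-derived markers: {count_by_source(catalog, 'asCOG')}")

subs = {name: subset_catalog(catalog, ids) for name, ids in selections.items()}
for name, sub in subs.items():
    print(f"  {name}: {len(sub)} markers")
core = set.intersection(*(set(s.marker_ids) for s in subs.values()))
print(f"4-way intersection: {len(core)} markers")
# Dereplication is by normalized accession (case-fold, version strip)
# plus an optional alias table; provenance (which study contributed each
# marker) is retained on every entry.
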