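"""Build pathway feature vectors from metabolite substructure counts.

Generates a small synthetic metabolite count matrix with a pathway catalog,
sums member counts into per-category vectors, normalizes within each
bond-inclusion level, and de-duplicates the pathway columns.
"""

from pathpairs import SynthConfig, build_feature_sets, generate

matrix, catalog = generate(SynthConfig(n_metabolites=150, n_pathways=4,
                                       n_features=60, seed=0))
sets = build_feature_sets(matrix, catalog)

print(f"metabolites: {matrix.n_rows} x {matrix.n_features} raw counts")
for pid, members in catalog.pathways:
    print(f"  {pid}: {len(members)} member metabolites")
print(f"pathway block: {sets.pathway_full.n_features} columns -> "
      f"{sets.pathway.n_features} after de-duplication "
      f"({len(sets.dedup_map.alias_of)} duplicates removed)")

# each (row, bond level) group of the normalized blocks sums to 1:
# the values are proportions of atom-color occurrences within a level,
# which makes categories with different membership sizes comparable.
row = sets.pathway.values[0]
levels = sets.pathway.bond_levels
for lv in sorted(set(levels)):
    print(f"  {catalog.pathway_ids[0]} level-{lv} proportions sum to "
          f"{row[levels == lv].sum():.6f}")
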