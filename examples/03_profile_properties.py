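"""Profile lead-likeness, chemical diversity and shape of library payloads.

Computes the six standard descriptors (MWt, clog P, HBD, TPSA, NRB, NAr) for
the full (non-truncate) members of the demonstration library, summarises
them, embeds the set with a 2-component PCA, and places a few members on the
PMI shape triangle.
"""

from delforge.blocks import toy_block_sets
from delforge.chem import enumerate_library
from delforge.codons import CodonDesignConfig, generate_codon_set
from delforge.profiling import descriptor_table, pca_embed, pmi_table, summarize

blocks = toy_block_sets(5, 5, 4, controls=True)
codon_sets = [generate_codon_set(CodonDesignConfig(n_required=10), c) for c in (1, 2, 3)]
members = [m for m in enumerate_library(blocks, codon_sets) if not m.is_truncate]

table = descriptor_table(
    [m.product for m in members],
    [f"{m.bb1_id}|{m.bb2_id}|{m.bb3_id}" for m in members],
)
print("descriptor summary (mean +- std over", len(table), "compounds):")
for name, row in summarize(table).iterrows():
    print(f"  {name:>5}: {row['mean']:7.2f} +- {row['std']:.2f}")

coords, evr = pca_embed(table.to_numpy(), standardize=True)
print(f"PCA: first two components explain {100 * evr.sum():.1f}% of variance")

pmi = pmi_table([m.product for m in members[:5]], seed=7)
print("PMI coordinates of five members (npr1, npr2 near (0,1)=rod, (.5,.5)=disc, (1,1)=sphere):")
print(pmi.round(3).to_string())
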