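"""Enumerate a small three-cycle amide-coupled library in silico.

Builds a 7 x 7 x 6-well design (5 + 5 amino acids, 4 capping acids, plus two
control wells per cycle), couples each combination through
couple -> deprotect -> couple -> deprotect -> cap, and assigns every member
its DNA tag.
"""

from delforge.blocks import toy_block_sets
from delforge.chem import Headpiece, TagSchema, enumerate_library, library_size
from delforge.codons import CodonDesignConfig, generate_codon_set

blocks = toy_block_sets(5, 5, 4, controls=True)
codon_sets = [generate_codon_set(CodonDesignConfig(n_required=10), c) for c in (1, 2, 3)]
schema = TagSchema(headpiece_sequence=Headpiece().dna_sequence, codon_length=12)

members = list(enumerate_library(blocks, codon_sets, Headpiece(), schema))

print(f"library size: {len(members)} (closed form: {library_size(5, 5, 4, 2)})")
truncates = sum(m.is_truncate for m in members)
print(f"truncates (members touching a control well): {truncates}")
example = next(m for m in members if not m.is_truncate)
print(f"example member {example.bb1_id} + {example.bb2_id} + {example.bb3_id}:")
print(f"  payload SMILES: {example.product}")
print(f"  DNA tag ({len(example.tag)} nt): {example.tag}")
# every member's tag is unique; the three codons record its synthetic history
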