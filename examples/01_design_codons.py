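"""Design an error-tolerant DNA codon set for one encoding cycle.

Generates 20 twelve-base codons at minimum pairwise Hamming distance 3 —
enough separation to correct any single sequencing substitution uniquely —
with palindromic and hairpin-forming candidates removed.
"""

from delforge.codons import CodonDesignConfig, generate_codon_set, validate_codon_set

config = CodonDesignConfig(length=12, min_distance=3, n_required=20)
codon_set = generate_codon_set(config, cycle_id=1)
report = validate_codon_set(codon_set)

print(f"designed {len(codon_set)} codons, e.g. {codon_set.sequences[:3]}")
print(f"min pairwise Hamming distance: {report.min_pairwise_distance}")
print(f"GC fraction range: {report.gc_range[0]:.2f}-{report.gc_range[1]:.2f}")
print(f"palindrome/hairpin violations: {len(report.palindromes) + len(report.hairpins)}")
# distance >= 3 is what makes single-error correction of reads possible
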