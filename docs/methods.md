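# Methods

## Codon design

Codons are fixed-length DNA codewords over {A,C,G,T}. The generator is a
greedy lexicode: candidates are visited in a deterministic order
(lexicographic by default; a seeded shuffle is available when set diversity
matters more than canonical ordering) and accepted when they pass every
per-sequence filter and keep Hamming distance ≥ `min_distance` to all
previously accepted codons. Greedy accretion over a fixed order makes the
output a pure function of the configuration — no RNG is consumed in the
default mode.

Filters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `length` | 12 bases | comfortably yields 200 codewords at distance 3 under all filters |
| `min_distance` | 3 | unique correction of one substitution per codon |
| `gc_min`, `gc_max` | 0.25, 0.75 | amplification/sequencing robustness |
| `max_homopolymer` | 3 | avoids slippage-prone runs |
| `hairpin_min_stem`, `hairpin_min_loop` | 4, 3 | canonical minimal DNA hairpin geometry |

A *palindrome* here is a sequence equal to its own reverse complement
(possible only at even length); a *hairpin* exists when a substring of at
least `min_stem` bases is followed, after a gap of at least `min_loop`
bases, by its exact reverse complement. The hairpin predicate is purely
combinatorial — no thermodynamic (ΔG) folding model is attempted; sequences
this short are adequately screened by exact-stem detection, and the
predicate is verified in tests against an independent brute-force triple
loop over all (start, start′, stem-length) combinations.

Distance is enforced within each cycle's set; the three cycles may reuse
codewords because decoding is positional. Cross-cycle separation can be
requested via the `exclude` argument of `generate_codon_set`.

## Library enumeration

The library topology is: surrogate linker amine → amide coupling of an
N-Fmoc amino acid → Fmoc removal → second coupling/removal → capping
carboxylic acid. Reactions are RDKit reaction SMARTS:

* coupling: `C(=O)[OH]` + free primary/secondary aliphatic amine → amide,
  excluding amide/carbamate/sulfonamide nitrogens, guanidines and aryl
  amines from the amine role so that protected nitrogens never react;
* deprotection: the Fmoc carbamate (matched as the full
  fluorenylmethyloxycarbonyl substructure) is replaced by the free amine,
  losing C₁₅H₁₀O₂ (dibenzofulvene + CO₂).

Masses are monoisotopic throughout; every full (non-truncate) member obeys
`m(product) = m(linker) + Σ m(blocks) − 3·18.0106 − 2·222.0681` Da to within
0.05 Da, which the tests assert for the entire demonstration library. If a
building block presents several carboxyl groups the first matched site
couples and a warning is logged; monomer curation should avoid such blocks,
mirroring real library practice.

The DNA oligo is never modelled atomistically: the payload is built on a
small aminated linker (2-(2-aminoethoxy)ethanol) because descriptors and
reactions concern the small molecule, while the tag is tracked as a string
`headpiece(14 nt) + codon×3 + closing primer(10 nt)` (spacers configurable,
empty by default). Control wells — one with no acid, one with no reagents —
are chemically identical pass-throughs distinguished only by role and codon,
so truncate-driven enrichment remains visible after decoding. Cycle-3 caps
are not deprotected (they carry no Fmoc); tag-only enumeration
(`build_structures=False`) streams the full 3.09 M-member expanded design in
seconds for combinatorial checks.

## Property profiling

Descriptors: molecular weight, Crippen atom-contribution clog P (the method
is stated in `CLOGP_METHOD` metadata; other log P schemes will differ by a
few tenths), hydrogen-bond donors, Ertl TPSA, rotatable bonds, aromatic
rings — all RDKit implementations, computed on the payload only (DNA
excluded, consistent with lead-likeness analysis). Summaries report mean and
sample standard deviation (`ddof=1`; population via `ddof=0`).

PCA diversity accepts either the six z-scored descriptors or hashed Morgan
fingerprints (radius 2, 1024 bits); both bases are exposed because diversity
conclusions depend on representation. Sign indeterminacy is removed by
forcing each component's largest-magnitude loading positive.

PMI shape coordinates come from a seeded ETKDGv3 ensemble (5 conformers),
MMFF94-relaxed (UFF when MMFF parameters are missing), taking the
lowest-energy conformer. Outputs satisfy NPR1 ≤ NPR2 and NPR1 + NPR2 ≥ 1
within 1e-6; reference molecules (diacetylene, benzene, adamantane) land on
the rod/disc/sphere corners within 0.05. Batch profiling skips unembeddable
structures with a warning rather than failing the set.

## Selection simulator

The simulator is the package's synthetic-data generator; its defaults are
the study conditions: 10⁶ copies per member, two selection rounds,
pre-clearing against a half portion of beads, and a planted cycle-3 target
binder alongside an imidazole-type bead binder. Affinity lives at the
cycle-3 building-block level because the experimental readout of interest is
cycle-3 marginal enrichment with flat cycle-1/2 marginals; a member-level
override is out of scope.

Per round, member copies follow `Binomial(copies, p)` with
`p = p_target` (default 0.3) for target-cap members, `p_bead` (0.5) for
bead-cap members and `p_background` (0.005) otherwise. The probabilities are
per-round retention odds, so two rounds give the closed-form expected fold
enrichment `(p_target/p_background)²` — a property the tests verify.
Pre-clearing removes `Binomial(copies, p_bead × fraction)` from bead binders
before round 1 (default fraction 0.5, i.e. half the bead quantity), leaving
other members untouched in expectation. An optional blocking factor < 1
scales the bead and background terms, modelling blocking agents.

Sequencing draws `read_depth` reads multinomially ∝ abundance; PCR is
treated as uniform amplification absorbed by that draw, with an optional
per-member lognormal bias behind `pcr_lognormal_sigma`. Errors are i.i.d.
per-base substitutions (default 0.5 %); indels are deliberately not modelled
because decoding is positional, and quality scores are a constant
placeholder. Read order is shuffled so file position carries no identity
information. Everything is driven by one `numpy` generator seeded from the
config, making the FASTQ byte-reproducible.

What the generator does *not* emulate: bead-capacity saturation, binding
kinetics/thermodynamics, sequence-dependent error profiles, PCR duplicates
and UMI structure, or round-to-round wash-stringency changes. Passing tests
therefore demonstrate the correctness of the counting/correction machinery
and the qualitative selection logic, not quantitative agreement with any
particular wet-lab run.

## Decoding

Reads are parsed positionally: constant regions (headpiece, spacers, closing
primer) must match within a total mismatch budget (default 1), then each
codon slice is matched exactly or corrected through a precomputed
single-mutant index. For a distance-3 set every codon's 3L mutants are
unique, so correction can never mis-assign — asserted exhaustively in tests
(200 × 36 mutants). If a supplied set violates the distance guarantee,
colliding mutants are marked ambiguous and rejected rather than guessed.
Unassigned reads are tallied by reason (length / constant region / codon),
and `Σ counts + unassigned = reads` holds on every input.

Raw summed counts per unique (bb1, bb2, bb3) barcode are the primary
statistic; per-cycle marginals and rank orders form the report, control
codons are flagged, and a baseline-normalized frequency ratio (pseudocount
1) is available as a clearly separate extra. A chi-square goodness-of-fit
p-value against a uniform marginal quantifies "no enrichment" in cycles 1–2;
only forward-orientation matching is performed (reverse-complement scanning
sits behind a flag in design, not needed for simulator output).

## Pipeline

`run_all` fans a single global seed into per-stage seeds through
`numpy.random.SeedSequence(entropy=seed, spawn_key=(stage,))`, so stages are
individually reproducible and the whole run is a pure function of its
config. Stage failures abort with the stage named, leaving earlier artifacts
intact. The demonstration defaults use a 7 × 7 × 6-well design, pre-clearing
enabled and a moderate bead binder (`p_bead = 0.2`), reflecting the final
experimental protocol in which the sulfonamide dominates a pre-cleared
selection.

## Problem sizes and numerical choices

Tests run the demonstration design (294 members) end to end; replicate-based
checks use 20 seeded replicates at 200 000 reads each. The full 3 089 664-
member expanded design is exercised tag-only (combinatorics and tag
uniqueness are structure-independent). Descriptor work in the orchestrated
pipeline is capped at `profile_max_compounds` (default 2000) since property
summaries converge long before that. Degenerate inputs fail loudly: empty
descriptor tables, empty count tables, zero surviving molecules and
exhausted codon candidate spaces all raise with actionable messages rather
than returning silent defaults.

## Known limitations

* clog P is implementation-dependent; cross-package comparisons of absolute
  values should expect ~0.5-unit discrepancies.
* The amide transform takes the first matched site on polyacids; regiochemistry
  of ambiguous monomers is not modelled.
* Hairpin screening is exact-stem only; G·U-type wobbles, bulged stems and
  thermodynamic stability are out of scope.
* The selection model is a binomial cascade without competition for binding
  sites; enrichment magnitudes saturate in reality.
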