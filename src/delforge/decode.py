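"""Barcode decoding and enrichment counting for selection sequencing output.

Reads are parsed positionally against the tag schema: the constant regions
(headpiece, spacers, closing primer) are verified within a small mismatch
budget, then the three codons are sliced out and matched against their
per-cycle codon sets.  Because codon sets are designed at minimum pairwise
Hamming distance 3, any single substitution inside a codon is corrected
uniquely; codons with two or more errors (or ambiguous matches, if a
sub-spec set is supplied) are rejected and the read tallied as unassigned.
Counts for unique barcode combinations are summed, and per-cycle marginal
counts give the selection readout: the enriched cycle-3 building block is
the hit call, and control codons are flagged so that enrichment driven by
truncated side-products remains visible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .chem import TagSchema
from .codons import CodonSet, hamming_distance

__all__ = [
    "CountTable",
    "EnrichmentReport",
    "CodonMatcher",
    "match_codon",
    "decode_read",
    "count_reads",
    "iter_fastq",
    "enrichment_report",
    "marginal_uniformity_pvalue",
]

# unassignment reasons
REASON_LENGTH = "length"
REASON_CONSTANT = "constant_region"
REASON_CODON = "codon"


class CodonMatcher:
    """Single-error codon correction via a precomputed mutant index.

    For a distance-3 set every codon and each of its 3L single-substitution
    mutants map to a unique source codon; the lookup is exact-match first,
    then the mutant table.  If the supplied set violates the distance
    guarantee, colliding mutants are marked ambiguous and rejected at match
    time rather than mis-assigned.
    """

    _AMBIGUOUS = -1

    def __init__(self, codon_set: CodonSet | Sequence[str]):
        seqs = codon_set.sequences if isinstance(codon_set, CodonSet) else list(codon_set)
        if not seqs:
            raise ValueError("empty codon set")
        self.length = len(seqs[0])
        self._exact: dict[str, int] = {}
        for i, s in enumerate(seqs):
            if s in self._exact:
                raise ValueError(f"duplicate codon {s!r}")
            self._exact[s] = i
        self._mutants: dict[str, int] = {}
        for i, s in enumerate(seqs):
            for pos in range(self.length):
                for base in "ACGT":
                    if base == s[pos]:
                        continue
                    mut = s[:pos] + base + s[pos + 1 :]
                    prev = self._mutants.get(mut)
                    if prev is not None and prev != i:
                        self._mutants[mut] = self._AMBIGUOUS
                    else:
                        self._mutants[mut] = i

    def match(self, observed: str) -> int | None:
        """Index of the matching codon, or None if unassignable."""
        if len(observed) != self.length:
            return None
        hit = self._exact.get(observed)
        if hit is not None:
            return hit
        hit = self._mutants.get(observed)
        if hit is None or hit == self._AMBIGUOUS:
            return None
        return hit


def match_codon(observed: str, codon_set: CodonSet | Sequence[str]) -> int | None:
    """One-shot codon match; build a :class:`CodonMatcher` for bulk decoding."""
    return CodonMatcher(codon_set).match(observed)


@dataclass
class CountTable:
    """Decoded read counts keyed by (cycle1, cycle2, cycle3) block ids."""

    counts: Counter = field(default_factory=Counter)
    unassigned: Counter = field(default_factory=Counter)
    n_reads: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unassigned(self) -> int:
        return sum(self.unassigned.values())

    def marginal(self, cycle: int) -> Counter:
        """Summed counts per building block of one cycle (1-based)."""
        if cycle not in (1, 2, 3):
            raise ValueError("cycle must be 1, 2 or 3")
        out: Counter = Counter()
        for key, n in self.counts.items():
            out[key[cycle - 1]] += n
        return out


@dataclass
class EnrichmentReport:
    """Per-cycle marginal counts, rank orders, and optional baseline ratios."""

    marginals: list[dict]          # one {block_id: count} per cycle
    ranks: list[list[str]]         # block ids, descending count, per cycle
    control_flags: list[dict]      # {block_id: bool} per cycle
    ratios: list[dict] | None = None  # selected/baseline frequency, pseudocount 1

    def top_block(self, cycle: int) -> str:
        return self.ranks[cycle - 1][0]


def decode_read(
    read: str,
    tag_schema: TagSchema,
    matchers: Sequence[CodonMatcher],
    block_ids: Sequence[Sequence[str]] | None = None,
    constant_mismatch_budget: int = 1,
) -> tuple[tuple, None] | tuple[None, str]:
    """Decode one read; returns ((bb1, bb2, bb3), None) or (None, reason).

    With ``block_ids`` given, codon indices are translated to building-block
    ids; indices beyond the supplied lists count as unassigned (codons exist
    in the design but encode no block).
    """
    if len(read) != tag_schema.tag_length:
        return None, REASON_LENGTH
    mismatches = 0
    for offset, expected in tag_schema.constant_regions():
        mismatches += hamming_distance(read[offset : offset + len(expected)], expected)
        if mismatches > constant_mismatch_budget:
            return None, REASON_CONSTANT
    key = []
    for sl, matcher, cycle_blocks in zip(
        tag_schema.codon_slices(),
        matchers,
        block_ids if block_ids is not None else ((), (), ()),
    ):
        idx = matcher.match(read[sl])
        if idx is None:
            return None, REASON_CODON
        if block_ids is not None:
            if idx >= len(cycle_blocks):
                return None, REASON_CODON
            key.append(cycle_blocks[idx])
        else:
            key.append(idx)
    return tuple(key), None


def iter_fastq(path: str | Path) -> Iterable[tuple[str, str]]:
    """Yield (id, sequence) from a FASTQ file, flagging malformed records."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        record_no = 0
        try:
            for title, seq, _qual in FastqGeneralIterator(fh):
                record_no += 1
                yield title, seq
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record near record {record_no + 1}: {exc}") from exc


def count_reads(
    fastq: str | Path | Iterable[tuple[str, str]],
    tag_schema: TagSchema,
    codon_sets: Sequence[CodonSet],
    block_ids: Sequence[Sequence[str]] | None = None,
    constant_mismatch_budget: int = 1,
) -> CountTable:
    """Decode every read of a FASTQ file and sum counts per unique barcode.

    The invariant ``sum(counts) + unassigned == reads processed`` always
    holds; unassigned reads are tallied by reason (wrong length, constant
    region failure, uncorrectable codon).
    """
    matchers = [CodonMatcher(cs) for cs in codon_sets]
    table = CountTable()
    reads = iter_fastq(fastq) if isinstance(fastq, (str, Path)) else fastq
    for _rid, seq in reads:
        table.n_reads += 1
        key, reason = decode_read(seq, tag_schema, matchers, block_ids, constant_mismatch_budget)
        if key is None:
            table.unassigned[reason] += 1
        else:
            table.counts[key] += 1
    return table


def enrichment_report(
    table: CountTable,
    baseline: CountTable | None = None,
    control_ids: Iterable[str] = (),
) -> EnrichmentReport:
    """Summarise a count table into the per-cycle selection readout.

    Raw summed counts are the primary statistic.  If a baseline count table
    (naive library or no-target control sequencing) is supplied, a
    normalized enrichment ratio (selected frequency / baseline frequency,
    with pseudocount 1) is reported as a clearly-separate extra.
    """
    if not table.counts:
        raise ValueError("count table is empty; nothing to report")
    controls = set(control_ids)
    marginals, ranks, flags = [], [], []
    for cycle in (1, 2, 3):
        marg = table.marginal(cycle)
        marginals.append(dict(marg))
        ranks.append([b for b, _ in marg.most_common()])
        flags.append({b: (b in controls) for b in marg})
    ratios = None
    if baseline is not None:
        if not baseline.counts:
            raise ValueError("baseline count table is empty")
        ratios = []
        for cycle in (1, 2, 3):
            sel = table.marginal(cycle)
            base = baseline.marginal(cycle)
            blocks = set(sel) | set(base)
            n_sel = sum(sel.values()) + len(blocks)
            n_base = sum(base.values()) + len(blocks)
            ratios.append(
                {
                    b: ((sel.get(b, 0) + 1) / n_sel) / ((base.get(b, 0) + 1) / n_base)
                    for b in blocks
                }
            )
    return EnrichmentReport(marginals=marginals, ranks=ranks, control_flags=flags, ratios=ratios)


def marginal_uniformity_pvalue(table: CountTable, cycle: int, n_blocks: int | None = None) -> float:
    """Chi-square goodness-of-fit p-value against a uniform cycle marginal.

    A large p-value means no building block of that cycle is significantly
    enriched; blocks with zero observed counts are included when
    ``n_blocks`` states the design size.
    """
    marg = table.marginal(cycle)
    k = n_blocks if n_blocks is not None else len(marg)
    if k < 2:
        raise ValueError("need at least two blocks for a uniformity test")
    observed = np.zeros(k)
    observed[: len(marg)] = sorted(marg.values(), reverse=True)
    return float(stats.chisquare(observed).pvalue)
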