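"""Error-tolerant DNA codon (barcode) design for encoded-library synthesis.

Each synthesis cycle of a DNA-encoded library is recorded by ligating a short
DNA codon; the concatenated codons identify the compound after sequencing.
To keep decoding robust against sequencing noise, codons within a cycle are
generated at a minimum pairwise Hamming distance of 3, which guarantees that
any single base substitution can be corrected uniquely.  Palindromic and
hairpin-forming candidates are removed because they fold on themselves or
cross-hybridise during ligation and PCR, and (optionally) extreme GC content
and long homopolymer runs are excluded for sequencing robustness.

The generator is a deterministic greedy "lexicode": candidates are visited in
a fixed order (lexicographic, or a seeded shuffle) and accepted whenever they
pass all per-sequence filters and keep the required distance to every codon
accepted so far.
"""

from __future__ import annotations

import csv
import itertools
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal

__all__ = [
    "Codon",
    "CodonDesignConfig",
    "CodonSet",
    "ValidationReport",
    "hamming_distance",
    "reverse_complement",
    "gc_fraction",
    "max_homopolymer_run",
    "is_palindrome",
    "has_hairpin",
    "generate_codon_set",
    "validate_codon_set",
    "write_codon_csv",
    "read_codon_csv",
    "write_codon_fasta",
]

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _check_alphabet(seq: str) -> None:
    if not seq or any(c not in _ALPHABET for c in seq):
        raise ValueError(f"sequence must be a non-empty string over ACGT, got {seq!r}")


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    return max(len(list(g)) for _, g in itertools.groupby(seq))


def is_palindrome(seq: str) -> bool:
    """True iff the sequence equals its own reverse complement.

    Such sequences are self-complementary duplex formers; odd-length
    sequences can never satisfy this.
    """
    _check_alphabet(seq)
    if len(seq) % 2 == 1:
        return False
    return seq == reverse_complement(seq)


def has_hairpin(seq: str, min_stem: int = 4, min_loop: int = 3) -> bool:
    """Detect potential intramolecular hairpins.

    A hairpin exists when a substring of length >= ``min_stem`` is followed,
    after a gap (loop) of at least ``min_loop`` bases, by its reverse
    complement.  Only exact stems are considered; no thermodynamics.
    """
    if min_stem < 2:
        raise ValueError("min_stem must be >= 2")
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    n = len(seq)
    k = min_stem  # a longer stem always contains a stem of length min_stem
    for i in range(n - 2 * k - min_loop + 1):
        stem_rc = reverse_complement(seq[i : i + k])
        if seq.find(stem_rc, i + k + min_loop) != -1:
            return True
    return False


@dataclass(frozen=True)
class Codon:
    """One DNA codeword of a per-cycle barcode set."""

    sequence: str

    def __post_init__(self) -> None:
        _check_alphabet(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodonDesignConfig:
    """Parameters controlling codon generation.

    GC and homopolymer filters are practical sequencing-robustness filters;
    set ``gc_min=0, gc_max=1, max_homopolymer=length`` to disable them and
    retain only the distance / palindrome / hairpin constraints.
    """

    length: int = 12
    min_distance: int = 3
    gc_min: float = 0.25
    gc_max: float = 0.75
    max_homopolymer: int = 3
    hairpin_min_stem: int = 4
    hairpin_min_loop: int = 3
    n_required: int = 200
    candidate_order: Literal["lexicographic", "seeded_shuffle"] = "lexicographic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")
        if not (0 <= self.gc_min <= self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if self.length < self.min_distance:
            raise ValueError(
                f"length {self.length} cannot support Hamming distance "
                f"{self.min_distance}"
            )
        if self.n_required < 1:
            raise ValueError("n_required must be >= 1")


@dataclass
class CodonSet:
    """An ordered set of codons for one encoding cycle."""

    cycle_id: int
    codons: list[Codon]
    config: CodonDesignConfig

    def __len__(self) -> int:
        return len(self.codons)

    def __iter__(self) -> Iterator[Codon]:
        return iter(self.codons)

    @property
    def sequences(self) -> list[str]:
        return [c.sequence for c in self.codons]


@dataclass
class ValidationReport:
    min_pairwise_distance: int | None
    gc_range: tuple[float, float] | None
    palindromes: list[str] = field(default_factory=list)
    hairpins: list[str] = field(default_factory=list)
    distance_violations: list[tuple[str, str, int]] = field(default_factory=list)
    duplicates: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (
            self.palindromes or self.hairpins or self.distance_violations or self.duplicates
        )


def _passes_filters(seq: str, cfg: CodonDesignConfig) -> bool:
    if not (cfg.gc_min <= gc_fraction(seq) <= cfg.gc_max):
        return False
    if max_homopolymer_run(seq) > cfg.max_homopolymer:
        return False
    if is_palindrome(seq):
        return False
    if has_hairpin(seq, cfg.hairpin_min_stem, cfg.hairpin_min_loop):
        return False
    return True


def _candidates(cfg: CodonDesignConfig) -> Iterable[str]:
    if cfg.candidate_order == "lexicographic":
        for tup in itertools.product(_ALPHABET, repeat=cfg.length):
            yield "".join(tup)
    elif cfg.candidate_order == "seeded_shuffle":
        # materialising 4^L strings is viable up to L ~ 12
        pool = ["".join(t) for t in itertools.product(_ALPHABET, repeat=cfg.length)]
        random.Random(cfg.seed).shuffle(pool)
        yield from pool
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown candidate order {cfg.candidate_order!r}")


def generate_codon_set(
    config: CodonDesignConfig,
    cycle_id: int = 1,
    exclude: Iterable[str] = (),
) -> CodonSet:
    """Greedily build a codon set satisfying all design constraints.

    Candidates are visited in ``config.candidate_order``; one is accepted iff
    it passes the GC / homopolymer / palindrome / hairpin filters and sits at
    Hamming distance >= ``config.min_distance`` from every codon accepted so
    far (and from every sequence in ``exclude``, which enables optional
    cross-cycle separation).  Deterministic given the config.

    Raises ``RuntimeError`` if the candidate space is exhausted before
    ``config.n_required`` codons are found.
    """
    accepted: list[str] = []
    guard = list(exclude)
    d = config.min_distance
    for cand in _candidates(config):
        if not _passes_filters(cand, config):
            continue
        if any(hamming_distance(cand, a) < d for a in accepted):
            continue
        if any(len(g) == len(cand) and hamming_distance(cand, g) < d for g in guard):
            continue
        accepted.append(cand)
        if len(accepted) == config.n_required:
            break
    else:
        raise RuntimeError(
            f"candidate space exhausted: found {len(accepted)} of "
            f"{config.n_required} codons at length {config.length}, "
            f"distance {d}"
        )
    return CodonSet(cycle_id=cycle_id, codons=[Codon(s) for s in accepted], config=config)


def validate_codon_set(cset: CodonSet) -> ValidationReport:
    """Exhaustively re-check every invariant of a codon set."""
    seqs = cset.sequences
    cfg = cset.config
    report = ValidationReport(min_pairwise_distance=None, gc_range=None)
    if not seqs:
        return report
    report.gc_range = (min(map(gc_fraction, seqs)), max(map(gc_fraction, seqs)))
    seen: set[str] = set()
    for s in seqs:
        if s in seen:
            report.duplicates.append(s)
        seen.add(s)
        if is_palindrome(s):
            report.palindromes.append(s)
        if has_hairpin(s, cfg.hairpin_min_stem, cfg.hairpin_min_loop):
            report.hairpins.append(s)
    if len(seqs) >= 2:
        mind = len(seqs[0]) + 1
        for a, b in itertools.combinations(seqs, 2):
            dist = hamming_distance(a, b)
            mind = min(mind, dist)
            if dist < cfg.min_distance:
                report.distance_violations.append((a, b, dist))
        report.min_pairwise_distance = mind
    return report


# ---------------------------------------------------------------------------
# persistence

def write_codon_csv(codon_sets: Iterable[CodonSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cycle_id", "codon_index", "sequence"])
        for cset in codon_sets:
            for i, codon in enumerate(cset):
                w.writerow([cset.cycle_id, i, codon.sequence])


def read_codon_csv(path: str | Path, config: CodonDesignConfig | None = None) -> list[CodonSet]:
    by_cycle: dict[int, list[tuple[int, str]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            by_cycle.setdefault(int(row["cycle_id"]), []).append(
                (int(row["codon_index"]), row["sequence"])
            )
    sets = []
    for cycle_id in sorted(by_cycle):
        rows = sorted(by_cycle[cycle_id])
        seqs = [s for _, s in rows]
        cfg = config or CodonDesignConfig(length=len(seqs[0]), n_required=len(seqs))
        sets.append(CodonSet(cycle_id, [Codon(s) for s in seqs], cfg))
    return sets


def write_codon_fasta(codon_sets: Iterable[CodonSet], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(codon.sequence), id=f"cycle{cset.cycle_id}_{i}", description="")
        for cset in codon_sets
        for i, codon in enumerate(cset)
    ]
    seqio_write(records, str(path), "fasta")
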