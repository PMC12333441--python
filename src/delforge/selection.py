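"""Synthetic affinity-selection and sequencing engine.

Models the selection experiment generatively: every library member starts at
a fixed copy number (~10^6 copies, i.e. hundreds of femtomoles of a pooled
library); each selection round retains copies as a binomial draw with a
per-member retention probability determined by its cycle-3 building block —
high for true target binders (the aryl-sulfonamide cap), elevated for
matrix binders that stick to the His-affinity beads (the imidazole cap),
and low nonspecific background otherwise.  Optional pre-clearing incubates
the pool with a half portion of bare beads first, depleting bead binders
before the target sees the library.  Sequencing draws reads multinomially
from the post-selection pool and corrupts each base independently at a fixed
substitution rate (PCR is treated as uniform amplification, with an optional
lognormal per-member bias).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import LibraryMember

__all__ = [
    "GroundTruth",
    "SelectionConfig",
    "simulate_selection",
    "generate_reads",
    "write_fastq",
    "write_truth",
    "read_truth",
]

TRUTH_SCHEMA_VERSION = 1

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i


@dataclass(frozen=True)
class GroundTruth:
    """Planted affinities, assigned at the cycle-3 building-block level."""

    target_binder_block_ids: frozenset = frozenset()
    bead_binder_block_ids: frozenset = frozenset()
    p_target: float = 0.3
    p_bead: float = 0.5
    p_background: float = 0.005

    def __post_init__(self) -> None:
        for name in ("p_target", "p_bead", "p_background"):
            p = getattr(self, name)
            if not 0 < p <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {p}")
        if self.p_target <= self.p_background:
            raise ValueError("p_target must exceed p_background")
        object.__setattr__(self, "target_binder_block_ids", frozenset(self.target_binder_block_ids))
        object.__setattr__(self, "bead_binder_block_ids", frozenset(self.bead_binder_block_ids))


@dataclass(frozen=True)
class SelectionConfig:
    """Experimental parameters of the simulated selection + sequencing run."""

    copies_per_member: int = 1_000_000
    rounds: int = 2
    preclear: bool = False
    preclear_bead_fraction: float = 0.5
    blocking: bool = False
    blocking_factor: float = 0.5  # multiplies bead/background terms when blocking
    read_depth: int = 200_000
    substitution_error_rate: float = 0.005
    pcr_lognormal_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")
        if not 0 <= self.substitution_error_rate < 0.25:
            raise ValueError("substitution_error_rate must be in [0, 0.25)")
        if not 0 <= self.preclear_bead_fraction <= 1:
            raise ValueError("preclear_bead_fraction must be in [0, 1]")
        if not 0 < self.blocking_factor <= 1:
            raise ValueError("blocking_factor must be in (0, 1]")


def _members_frame(library: Iterable[LibraryMember] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(library, pd.DataFrame):
        return library.reset_index(drop=True).copy()
    rows = [
        {"bb1": m.bb1_id, "bb2": m.bb2_id, "bb3": m.bb3_id, "tag": m.tag,
         "is_truncate": m.is_truncate}
        for m in library
    ]
    return pd.DataFrame(rows)


def retention_probabilities(
    bb3_ids: Sequence[str], truth: GroundTruth, cfg: SelectionConfig
) -> np.ndarray:
    """Per-member per-round retention probability from the cycle-3 identity."""
    block = cfg.blocking_factor if cfg.blocking else 1.0
    p = np.full(len(bb3_ids), truth.p_background * block)
    bb3 = np.asarray(bb3_ids, dtype=object)
    p[np.isin(bb3, list(truth.bead_binder_block_ids))] = truth.p_bead * block
    p[np.isin(bb3, list(truth.target_binder_block_ids))] = truth.p_target
    return p


def simulate_selection(
    library: Iterable[LibraryMember] | pd.DataFrame,
    truth: GroundTruth,
    cfg: SelectionConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Run pre-clearing and the selection rounds; return the abundance table.

    The returned frame carries one row per member with its identities, tag,
    initial copy number and post-selection ``copies``.  Reproducible for a
    fixed config seed.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    table = _members_frame(library)
    copies = np.full(len(table), cfg.copies_per_member, dtype=np.int64)
    table["initial_copies"] = copies.copy()

    p = retention_probabilities(table["bb3"].to_numpy(), truth, cfg)

    if cfg.preclear:
        # bead-only pass on a fraction of the bead portion: bead binders are
        # captured (removed) with probability p_bead * fraction
        is_bead = np.isin(table["bb3"].to_numpy(dtype=object), list(truth.bead_binder_block_ids))
        p_capture = truth.p_bead * cfg.preclear_bead_fraction
        removed = rng.binomial(copies, np.where(is_bead, p_capture, 0.0))
        copies = copies - removed

    for _ in range(cfg.rounds):
        copies = rng.binomial(copies, p)

    if copies.sum() == 0:
        raise RuntimeError(
            "no molecules survived selection; increase copies_per_member or "
            "retention probabilities"
        )
    table["copies"] = copies
    return table


def generate_reads(
    abundances: pd.DataFrame,
    cfg: SelectionConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Draw sequencing reads from a post-selection abundance table.

    ``read_depth`` reads are sampled multinomially in proportion to member
    abundance (optionally skewed by lognormal PCR bias), and each base is
    substituted independently at the configured error rate.  Returns
    ``(read_id, sequence)`` pairs ready for FASTQ serialisation.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    if cfg.read_depth == 0:
        return []
    copies = abundances["copies"].to_numpy(dtype=np.float64)
    if copies.sum() <= 0:
        raise ValueError("total post-selection abundance must be positive")
    weights = copies
    if cfg.pcr_lognormal_sigma > 0:
        weights = copies * rng.lognormal(0.0, cfg.pcr_lognormal_sigma, len(copies))
    counts = rng.multinomial(cfg.read_depth, weights / weights.sum())

    tags = abundances["tag"].to_list()
    tag_len = len(tags[0])
    if any(len(t) != tag_len for t in tags):
        raise ValueError("all tags must have equal length")
    # indices 0..3 per base, rows repeated per sampled read
    tag_mat = _BASE_TO_IDX[
        np.frombuffer("".join(tags).encode(), dtype=np.uint8).reshape(len(tags), tag_len)
    ]
    reads = np.repeat(tag_mat, counts, axis=0)
    if cfg.substitution_error_rate > 0 and reads.size:
        mask = rng.random(reads.shape) < cfg.substitution_error_rate
        # substitute with one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        reads[mask] = (reads[mask] + shift) % 4
    # shuffle read order so the file does not reveal member identity by position
    rng.shuffle(reads)
    seqs = _BASES[reads]
    return [
        (f"read_{i:07d}", seqs[i].tobytes().decode())
        for i in range(seqs.shape[0])
    ]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> int:
    """Serialise reads as 4-line FASTQ with a constant placeholder quality."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def write_truth(truth: GroundTruth, cfg: SelectionConfig, path: str | Path) -> None:
    """Persist everything a recovery test needs as a JSON sidecar."""
    payload = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "truth": {
            **asdict(truth),
            "target_binder_block_ids": sorted(truth.target_binder_block_ids),
            "bead_binder_block_ids": sorted(truth.bead_binder_block_ids),
        },
        "config": asdict(cfg),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_truth(path: str | Path) -> tuple[GroundTruth, SelectionConfig]:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != TRUTH_SCHEMA_VERSION:
        raise ValueError(f"unsupported truth schema version {version!r}")
    t = payload["truth"]
    truth = GroundTruth(
        target_binder_block_ids=frozenset(t["target_binder_block_ids"]),
        bead_binder_block_ids=frozenset(t["bead_binder_block_ids"]),
        p_target=t["p_target"],
        p_bead=t["p_bead"],
        p_background=t["p_background"],
    )
    cfg = SelectionConfig(**payload["config"])
    return truth, cfg
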