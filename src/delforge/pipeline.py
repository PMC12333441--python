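"""End-to-end orchestration: design → enumerate → profile → select → decode.

One :class:`PipelineConfig` (loadable from YAML) drives all five stages with
a single global seed, fanned out deterministically so each stage is also
reproducible standalone.  Stage outputs are pure functions of (inputs, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import blocks as blocks_mod
from .chem import (
    Headpiece,
    TagSchema,
    enumerate_library,
    read_building_blocks,
    write_library,
    read_library,
)
from .codons import CodonDesignConfig, generate_codon_set, write_codon_csv, validate_codon_set
from .decode import count_reads, enrichment_report, marginal_uniformity_pvalue
from .profiling import descriptor_table, summarize
from .selection import (
    GroundTruth,
    SelectionConfig,
    generate_reads,
    simulate_selection,
    write_fastq,
    write_truth,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "derive_seed", "run_all", "load_config"]

_STAGES = {"codons": 1, "enumerate": 2, "profile": 3, "select": 4, "reads": 5}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the single pipeline seed."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible end-to-end run."""

    out_dir: str = "delforge_run"
    seed: int = 0
    # codon design
    codon_length: int = 12
    min_distance: int = 3
    # building blocks: CSV path, or None for the built-in demonstration sets
    blocks_csv: str | None = None
    toy_wells: tuple[int, int, int] = (5, 5, 4)
    include_controls: bool = True
    # selection: demo defaults mirror the final pre-cleared protocol, where
    # the target binder dominates and the bead binder is partially depleted
    truth: GroundTruth = field(
        default_factory=lambda: GroundTruth(
            target_binder_block_ids=frozenset({blocks_mod.TARGET_BINDER_ID}),
            bead_binder_block_ids=frozenset({blocks_mod.BEAD_BINDER_ID}),
            p_bead=0.2,
        )
    )
    selection: SelectionConfig = field(default_factory=lambda: SelectionConfig(preclear=True))
    profile_max_compounds: int = 2000  # cap descriptor work on huge designs

    def validate(self) -> None:
        if self.blocks_csv is not None and not Path(self.blocks_csv).exists():
            raise FileNotFoundError(f"building-block CSV not found: {self.blocks_csv}")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML mapping."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "truth" in raw:
        t = raw["truth"]
        t["target_binder_block_ids"] = frozenset(t.get("target_binder_block_ids", ()))
        t["bead_binder_block_ids"] = frozenset(t.get("bead_binder_block_ids", ()))
        raw["truth"] = GroundTruth(**t)
    if "selection" in raw:
        raw["selection"] = SelectionConfig(**raw["selection"])
    if "toy_wells" in raw:
        raw["toy_wells"] = tuple(raw["toy_wells"])
    return PipelineConfig(**raw)


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage, writing artifacts under ``config.out_dir``.

    Produces codons.csv, library.csv, descriptors.csv, summary.json,
    reads.fastq, truth.json, counts.csv, marginals.csv and report.json.
    Idempotent for a fixed config; any stage failure aborts with the stage
    named, leaving earlier outputs in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage 1: codon design -------------------------------------------------
    logger.info("stage codons: designing per-cycle codon sets")
    if config.blocks_csv is not None:
        bb_sets = read_building_blocks(config.blocks_csv)
    else:
        n1, n2, n3 = config.toy_wells
        bb_sets = blocks_mod.toy_block_sets(n1, n2, n3, controls=config.include_controls)
    n_needed = max(len(s) for s in bb_sets)
    codon_cfg = CodonDesignConfig(
        length=config.codon_length,
        min_distance=config.min_distance,
        n_required=n_needed,
        seed=derive_seed(config.seed, "codons"),
    )
    codon_sets = [generate_codon_set(codon_cfg, cycle_id=c) for c in (1, 2, 3)]
    for cs in codon_sets:
        rep = validate_codon_set(cs)
        if not rep.clean:
            raise RuntimeError(f"stage codons: generated set for cycle {cs.cycle_id} failed validation")
    write_codon_csv(codon_sets, out / "codons.csv")

    # stage 2: enumeration --------------------------------------------------
    logger.info("stage enumerate: building the combinatorial library")
    headpiece = Headpiece()
    schema = TagSchema(headpiece_sequence=headpiece.dna_sequence, codon_length=config.codon_length)
    members = list(enumerate_library(bb_sets, codon_sets, headpiece, schema))
    write_library(members, out / "library.csv")

    # stage 3: profiling ----------------------------------------------------
    logger.info("stage profile: computing lead-likeness descriptors")
    payloads = [(f"{m.bb1_id}|{m.bb2_id}|{m.bb3_id}", m.product)
                for m in members if not m.is_truncate][: config.profile_max_compounds]
    desc = descriptor_table([p for _, p in payloads], [i for i, _ in payloads])
    desc.to_csv(out / "descriptors.csv")
    summary = summarize(desc)
    summary.to_json(out / "summary.json", indent=2)

    # stage 4: selection ----------------------------------------------------
    logger.info("stage select: simulating affinity selection")
    sel_cfg = SelectionConfig(**{**asdict(config.selection), "seed": derive_seed(config.seed, "select")})
    abundances = simulate_selection(members, config.truth, sel_cfg)
    write_truth(config.truth, sel_cfg, out / "truth.json")

    # stage 5: sequencing + decoding ----------------------------------------
    logger.info("stage reads: sequencing and decoding")
    reads = generate_reads(abundances, sel_cfg,
                           rng=np.random.default_rng(derive_seed(config.seed, "reads")))
    write_fastq(reads, out / "reads.fastq")
    block_ids = [[b.id for b in s] for s in bb_sets]
    table = count_reads(out / "reads.fastq", schema, codon_sets, block_ids)
    pd.DataFrame(
        [(k[0], k[1], k[2], n) for k, n in sorted(table.counts.items())],
        columns=["bb1", "bb2", "bb3", "count"],
    ).to_csv(out / "counts.csv", index=False)

    control_ids = [b.id for s in bb_sets for b in s if b.role.is_control]
    report = enrichment_report(table, control_ids=control_ids)
    rows = [
        {"cycle": c, "block": b, "count": n, "is_control": report.control_flags[c - 1][b]}
        for c in (1, 2, 3)
        for b, n in sorted(report.marginals[c - 1].items(), key=lambda kv: -kv[1])
    ]
    pd.DataFrame(rows).to_csv(out / "marginals.csv", index=False)

    report_json = {
        "n_members": len(members),
        "reads_total": table.n_reads,
        "reads_assigned": table.n_assigned,
        "unassigned_by_reason": dict(table.unassigned),
        "top_block_per_cycle": {c: report.top_block(c) for c in (1, 2, 3)},
        "cycle_uniformity_pvalues": {
            c: marginal_uniformity_pvalue(table, c, n_blocks=len(bb_sets[c - 1]))
            for c in (1, 2)
        },
        "planted_target_blocks": sorted(config.truth.target_binder_block_ids),
        "target_recovered": report.top_block(3) in config.truth.target_binder_block_ids,
        "seed": config.seed,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report_json, fh, indent=2)
    logger.info("pipeline complete: %s", out)
    return out
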