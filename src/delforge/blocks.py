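"""Curated synthetic building-block sets for demonstration and testing.

The real library was built from validated N-Fmoc amino acids (cycles 1-2)
and capping carboxylic acids (cycle 3).  The functions here provide small
chemically sensible stand-in sets with the same roles, including the two
pharmacologically meaningful cycle-3 caps used to read out a selection:

* a primary aryl sulfonamide cap (4-sulfamoylbenzoic acid) — the canonical
  carbonic-anhydrase active-site binder, planted as the true target binder;
* an imidazole cap (imidazole-4-carboxylic acid) — binds His-affinity
  (NTA-cobalt) beads directly and acts as the matrix false positive.

Every cycle list can be extended with the two control pseudo-blocks (a
no-acid well and a no-reagent well) that encode truncates.
"""

from __future__ import annotations

from .chem import BuildingBlock, Role

__all__ = [
    "TARGET_BINDER_ID",
    "BEAD_BINDER_ID",
    "toy_fmoc_amino_acids",
    "toy_capping_acids",
    "control_blocks",
    "with_controls",
    "toy_block_sets",
]

_FMOC = "C(=O)OCC1c2ccccc2-c2ccccc21"

# name -> SMILES of the full N-Fmoc amino acid
_FMOC_AMINO_ACIDS: list[tuple[str, str]] = [
    ("Fmoc-Gly", f"OC(=O)CN{_FMOC}"),
    ("Fmoc-Ala", f"CC(N{_FMOC})C(=O)O"),
    ("Fmoc-Val", f"CC(C)C(N{_FMOC})C(=O)O"),
    ("Fmoc-Leu", f"CC(C)CC(N{_FMOC})C(=O)O"),
    ("Fmoc-Phe", f"OC(=O)C(Cc1ccccc1)N{_FMOC}"),
    ("Fmoc-Ser", f"OCC(N{_FMOC})C(=O)O"),
    ("Fmoc-Met", f"CSCCC(N{_FMOC})C(=O)O"),
    ("Fmoc-Pro", f"OC(=O)C1CCCN1{_FMOC}"),
    ("Fmoc-beta-Ala", f"OC(=O)CCN{_FMOC}"),
    ("Fmoc-4-aminomethylbenzoic", f"OC(=O)c1ccc(CN{_FMOC})cc1"),
]

TARGET_BINDER_ID = "cap-4-sulfamoylbenzoic"
BEAD_BINDER_ID = "cap-imidazole-4-carboxylic"

_CAPPING_ACIDS: list[tuple[str, str]] = [
    (TARGET_BINDER_ID, "NS(=O)(=O)c1ccc(C(=O)O)cc1"),
    (BEAD_BINDER_ID, "OC(=O)c1c[nH]cn1"),
    ("cap-benzoic", "OC(=O)c1ccccc1"),
    ("cap-acetic", "CC(=O)O"),
    ("cap-nicotinic", "OC(=O)c1cccnc1"),
    ("cap-cyclopropanecarboxylic", "OC(=O)C1CC1"),
    ("cap-2-furoic", "OC(=O)c1ccco1"),
    ("cap-pivalic", "CC(C)(C)C(=O)O"),
    ("cap-phenylacetic", "OC(=O)Cc1ccccc1"),
    ("cap-4-methoxybenzoic", "COc1ccc(C(=O)O)cc1"),
]


def toy_fmoc_amino_acids(n: int, cycle: int) -> list[BuildingBlock]:
    """First ``n`` stand-in N-Fmoc amino acids for an amide-coupling cycle."""
    if not 1 <= n <= len(_FMOC_AMINO_ACIDS):
        raise ValueError(f"n must be 1..{len(_FMOC_AMINO_ACIDS)}")
    return [
        BuildingBlock(id=f"aa{cycle}-{name}", cycle=cycle, role=Role.FMOC_AMINO_ACID, smiles=smi)
        for name, smi in _FMOC_AMINO_ACIDS[:n]
    ]


def toy_capping_acids(n: int) -> list[BuildingBlock]:
    """First ``n`` capping acids; the target and bead binders come first."""
    if not 1 <= n <= len(_CAPPING_ACIDS):
        raise ValueError(f"n must be 1..{len(_CAPPING_ACIDS)}")
    return [
        BuildingBlock(id=name, cycle=3, role=Role.CAPPING_ACID, smiles=smi)
        for name, smi in _CAPPING_ACIDS[:n]
    ]


def control_blocks(cycle: int) -> list[BuildingBlock]:
    """The two encoded control wells of one cycle (no acid; no reagents)."""
    return [
        BuildingBlock(id=f"ctrl{cycle}-no-acid", cycle=cycle, role=Role.CONTROL_NO_ACID),
        BuildingBlock(id=f"ctrl{cycle}-no-reagent", cycle=cycle, role=Role.CONTROL_NO_REAGENT),
    ]


def with_controls(blocks: list[BuildingBlock], cycle: int) -> list[BuildingBlock]:
    return blocks + control_blocks(cycle)


def toy_block_sets(n1: int = 5, n2: int = 5, n3: int = 4, controls: bool = True):
    """Three per-cycle block lists for a small demonstration library.

    Defaults give a 7 x 7 x 6 = 294-member design once the two control wells
    per cycle are appended.
    """
    sets = [
        toy_fmoc_amino_acids(n1, cycle=1),
        toy_fmoc_amino_acids(n2, cycle=2),
        toy_capping_acids(n3),
    ]
    if controls:
        sets = [with_controls(blocks, cycle) for cycle, blocks in enumerate(sets, start=1)]
    return sets
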