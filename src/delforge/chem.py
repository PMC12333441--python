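"""In-silico synthesis of a three-cycle amide-coupled encoded library.

The library topology follows on-DNA peptoid-style synthesis: a DNA headpiece
carrying a free aliphatic amine is elaborated by two cycles of N-Fmoc amino
acid amide coupling (each followed by Fmoc removal) and terminated by a
capping carboxylic acid.  Each coupling cycle also contains two control
wells — one run without any acid, one without any reagents — whose members
carry a codon but no chemistry, so truncated side-products remain
identifiable after selection.

Chemistry is modelled on the small-molecule payload only: the DNA tag is
tracked as a sequence string, and the oligonucleotide attachment point is
represented by a surrogate aminated linker, since the downstream property
analysis concerns the payload, not the oligo.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.Descriptors import ExactMolWt

from .codons import CodonSet

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "BuildingBlock",
    "Headpiece",
    "TagSchema",
    "LibraryMember",
    "ChemistryError",
    "couple_amide",
    "deprotect_fmoc",
    "apply_control",
    "library_size",
    "enumerate_library",
    "exact_mass",
    "count_fmoc",
    "write_library",
    "read_library",
    "read_building_blocks",
    "write_building_blocks",
    "WATER_MASS",
    "FMOC_LOSS_MASS",
]

# monoisotopic masses of the leaving groups
WATER_MASS = 18.010565  # H2O lost per amide bond
FMOC_LOSS_MASS = 222.068080  # C15H10O2: dibenzofulvene + CO2 lost on deprotection

# acid partner: a free carboxylic acid
# amine partner: free primary/secondary aliphatic amine — not amide, carbamate,
# sulfonamide, guanidine or aryl amine nitrogen
_AMIDE_RXN = AllChem.ReactionFromSmarts(
    "[CX3:1](=[OX1:2])[OX2H1]."
    "[NX3;H2,H1;!$(N[C,S]=[O,S,N]);!$(N=*);!$(N-a):3]"
    ">>[CX3:1](=[OX1:2])[NX3:3]"
)

_FMOC_PATTERN = Chem.MolFromSmarts(
    "[NX3][CX3](=O)[OX2][CH2][CH]1[c]2[c][c][c][c][c]2-[c]2[c][c][c][c][c]21"
)
_FMOC_RXN = AllChem.ReactionFromSmarts(
    "[NX3:1][CX3](=O)[OX2][CH2][CH]1[c]2[c][c][c][c][c]2-[c]2[c][c][c][c][c]21"
    ">>[NX3:1]"
)
_ACID_PATTERN = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")
_AMINE_PATTERN = Chem.MolFromSmarts(
    "[NX3;H2,H1;!$(N[C,S]=[O,S,N]);!$(N=*);!$(N-a)]"
)


class ChemistryError(ValueError):
    """A reaction precondition failed on a specific structure."""


class Role(str, Enum):
    FMOC_AMINO_ACID = "fmoc_amino_acid"
    CAPPING_ACID = "capping_acid"
    CONTROL_NO_ACID = "control_no_acid"
    CONTROL_NO_REAGENT = "control_no_reagent"

    @property
    def is_control(self) -> bool:
        return self in (Role.CONTROL_NO_ACID, Role.CONTROL_NO_REAGENT)


@dataclass(frozen=True)
class BuildingBlock:
    """One well of a synthesis cycle: a monomer, cap, or control pseudo-block.

    ``validated_conversion`` is pass-through metadata (LCMS conversion of the
    on-DNA validation reaction); it plays no role in any computation here.
    """

    id: str
    cycle: int
    role: Role
    smiles: str = ""
    validated_conversion: float | None = None

    def __post_init__(self) -> None:
        if self.role.is_control:
            if self.smiles:
                raise ValueError(f"control block {self.id} must have empty structure")
        elif not self.smiles:
            raise ValueError(f"block {self.id}: structure required for role {self.role.value}")

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ChemistryError(f"block {self.id}: unparsable SMILES {self.smiles!r}")
        return m


@dataclass(frozen=True)
class Headpiece:
    """The starting DNA oligo and its chemical attachment point.

    The 14-nt single-stranded headpiece carries the amine on which synthesis
    begins; in silico the oligo portion is a plain sequence string and the
    amine is a small surrogate linker.
    """

    dna_sequence: str = "AGGTCGATGACGTC"
    linker_amine: str = "NCCOCCO"  # 2-(2-aminoethoxy)ethanol surrogate

    def __post_init__(self) -> None:
        if len(self.dna_sequence) != 14:
            raise ValueError("headpiece DNA must be 14 bases")


@dataclass(frozen=True)
class TagSchema:
    """Layout of the full DNA tag read out by sequencing.

    tag = headpiece + codon1 + spacer1 + codon2 + spacer2 + codon3 + spacer3
          + closing_primer
    Spacers default to empty; the closing primer is a fixed 10-base region at
    the 3' end used as a decoding sanity check.
    """

    headpiece_sequence: str = "AGGTCGATGACGTC"
    codon_length: int = 12
    spacers: tuple[str, str, str] = ("", "", "")
    closing_primer: str = "GACTCGTCAG"

    @property
    def tag_length(self) -> int:
        return (
            len(self.headpiece_sequence)
            + 3 * self.codon_length
            + sum(map(len, self.spacers))
            + len(self.closing_primer)
        )

    def build_tag(self, c1: str, c2: str, c3: str) -> str:
        s1, s2, s3 = self.spacers
        return (
            self.headpiece_sequence + c1 + s1 + c2 + s2 + c3 + s3 + self.closing_primer
        )

    def codon_slices(self) -> list[slice]:
        """Positions of the three codons within a tag."""
        out = []
        pos = len(self.headpiece_sequence)
        for spacer in self.spacers:
            out.append(slice(pos, pos + self.codon_length))
            pos += self.codon_length + len(spacer)
        return out

    def constant_regions(self) -> list[tuple[int, str]]:
        """(offset, expected sequence) pairs for all fixed regions."""
        regions = [(0, self.headpiece_sequence)]
        pos = len(self.headpiece_sequence)
        for spacer in self.spacers:
            pos += self.codon_length
            if spacer:
                regions.append((pos, spacer))
                pos += len(spacer)
        if self.closing_primer:
            regions.append((pos, self.closing_primer))
        return regions


@dataclass(frozen=True)
class LibraryMember:
    """One encoded compound: three wells, a payload structure, a DNA tag."""

    bb1_id: str
    bb2_id: str
    bb3_id: str
    tag: str
    product: str | None  # payload SMILES; None in tag-only enumeration
    is_truncate: bool


# ---------------------------------------------------------------------------
# reaction transforms

def _to_mol(smiles: str, what: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ChemistryError(f"unparsable {what} SMILES: {smiles!r}")
    return m


def couple_amide(amine_substrate: str, acid: str) -> str:
    """Form an amide between the substrate's free amine and the acid's COOH.

    The substrate supplies a free primary/secondary aliphatic amine; the acid
    supplies a carboxylic acid.  Water is lost.  If the acid carries several
    carboxyl groups the first matched site reacts and a warning is logged.
    """
    sub = _to_mol(amine_substrate, "substrate")
    ac = _to_mol(acid, "acid")
    if not sub.HasSubstructMatch(_AMINE_PATTERN):
        raise ChemistryError(f"substrate has no free reactive amine: {amine_substrate!r}")
    n_acid = len(ac.GetSubstructMatches(_ACID_PATTERN))
    if n_acid == 0:
        raise ChemistryError(f"acid partner has no carboxylic acid group: {acid!r}")
    if n_acid > 1:
        logger.warning("acid %r has %d carboxyl groups; coupling at first match", acid, n_acid)
    products = _AMIDE_RXN.RunReactants((ac, sub))
    if not products:
        raise ChemistryError(f"amide coupling produced no product: {amine_substrate!r} + {acid!r}")
    prod = products[0][0]
    Chem.SanitizeMol(prod)
    return Chem.MolToSmiles(prod)


def count_fmoc(smiles: str) -> int:
    """Number of distinct Fmoc-carbamate-protected nitrogens."""
    m = _to_mol(smiles, "molecule")
    return len({match[0] for match in m.GetSubstructMatches(_FMOC_PATTERN)})


def deprotect_fmoc(product: str) -> str:
    """Remove a single Fmoc carbamate, liberating the amine.

    Loses C15H10O2 (dibenzofulvene plus CO2).  Exactly one Fmoc group must be
    present.
    """
    m = _to_mol(product, "product")
    n = len({match[0] for match in m.GetSubstructMatches(_FMOC_PATTERN)})
    if n == 0:
        raise ChemistryError(f"no Fmoc carbamate found in {product!r}")
    if n > 1:
        raise ChemistryError(f"{n} Fmoc carbamates found in {product!r}; expected exactly one")
    out = _FMOC_RXN.RunReactants((m,))[0][0]
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def apply_control(substrate: str, control: BuildingBlock) -> str:
    """Pass the substrate through a control well unchanged.

    Both control types (no acid added; no reagents added) leave the chemistry
    untouched — they differ only in provenance — but their codon is still
    ligated, so the truncate remains decodable.
    """
    if not control.role.is_control:
        raise ChemistryError(f"block {control.id} has role {control.role.value}, not a control")
    return substrate


def exact_mass(smiles: str) -> float:
    """Monoisotopic molecular mass in Da."""
    return ExactMolWt(_to_mol(smiles, "molecule"))


# ---------------------------------------------------------------------------
# combinatorics and enumeration

def library_size(n1: int, n2: int, n3: int, controls_per_cycle: int = 2) -> int:
    """Closed-form member count: every cycle contributes its wells + controls."""
    if min(n1, n2, n3, controls_per_cycle) < 0:
        raise ValueError("well counts must be non-negative")
    c = controls_per_cycle
    return (n1 + c) * (n2 + c) * (n3 + c)


def _cycle_intermediate(substrate: str, bb: BuildingBlock) -> str:
    """Apply one amino-acid cycle (couple then deprotect) or a control."""
    if bb.role.is_control:
        return apply_control(substrate, bb)
    try:
        coupled = couple_amide(substrate, bb.smiles)
        return deprotect_fmoc(coupled)
    except ChemistryError as exc:
        raise ChemistryError(f"cycle {bb.cycle} block {bb.id}: {exc}") from exc


def _cap(substrate: str, bb: BuildingBlock) -> str:
    if bb.role.is_control:
        return apply_control(substrate, bb)
    try:
        return couple_amide(substrate, bb.smiles)
    except ChemistryError as exc:
        raise ChemistryError(f"cycle {bb.cycle} block {bb.id}: {exc}") from exc


def enumerate_library(
    bb_sets: Sequence[Sequence[BuildingBlock]],
    codon_sets: Sequence[CodonSet],
    headpiece: Headpiece | None = None,
    tag_schema: TagSchema | None = None,
    build_structures: bool = True,
) -> Iterator[LibraryMember]:
    """Stream all members of the combinatorial library.

    ``bb_sets`` holds the three per-cycle block lists (controls included);
    codons are assigned to blocks by position within each cycle, so each list
    must fit inside its codon set.  With ``build_structures=False`` only tags
    and identities are produced (useful to count or decode very large
    designs without paying for RDKit chemistry).
    """
    if len(bb_sets) != 3 or len(codon_sets) != 3:
        raise ValueError("exactly three cycles are required")
    headpiece = headpiece or Headpiece()
    tag_schema = tag_schema or TagSchema(
        headpiece_sequence=headpiece.dna_sequence,
        codon_length=len(codon_sets[0].codons[0]) if codon_sets[0].codons else 0,
    )
    codon_by_cycle: list[list[str]] = []
    for cycle, (blocks, cset) in enumerate(zip(bb_sets, codon_sets), start=1):
        if len(blocks) > len(cset):
            raise ValueError(
                f"cycle {cycle}: {len(blocks)} blocks but only {len(cset)} codons"
            )
        assigned = cset.sequences[: len(blocks)]
        if len(set(assigned)) != len(assigned):
            raise ValueError(f"cycle {cycle}: duplicate codon assignment")
        codon_by_cycle.append(assigned)

    b1s, b2s, b3s = bb_sets
    s1, s2, s3 = tag_schema.spacers
    suffixes = [c3 + s3 + tag_schema.closing_primer for c3 in codon_by_cycle[2]]
    for i1, bb1 in enumerate(b1s):
        inter1 = _cycle_intermediate(headpiece.linker_amine, bb1) if build_structures else None
        prefix1 = tag_schema.headpiece_sequence + codon_by_cycle[0][i1] + s1
        for i2, bb2 in enumerate(b2s):
            inter2 = _cycle_intermediate(inter1, bb2) if build_structures else None
            prefix2 = prefix1 + codon_by_cycle[1][i2] + s2
            for i3, bb3 in enumerate(b3s):
                product = _cap(inter2, bb3) if build_structures else None
                tag = prefix2 + suffixes[i3]
                yield LibraryMember(
                    bb1_id=bb1.id,
                    bb2_id=bb2.id,
                    bb3_id=bb3.id,
                    tag=tag,
                    product=product,
                    is_truncate=(
                        bb1.role.is_control or bb2.role.is_control or bb3.role.is_control
                    ),
                )


# ---------------------------------------------------------------------------
# persistence

_LIBRARY_COLUMNS = ["bb1", "bb2", "bb3", "smiles", "tag", "is_truncate"]


def write_library(members: Iterable[LibraryMember], path: str | Path) -> int:
    """Stream members to CSV; returns the number written."""
    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LIBRARY_COLUMNS)
        for m in members:
            w.writerow([m.bb1_id, m.bb2_id, m.bb3_id, m.product or "", m.tag, int(m.is_truncate)])
            n += 1
    return n


def read_library(path: str | Path) -> list[LibraryMember]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                LibraryMember(
                    bb1_id=row["bb1"],
                    bb2_id=row["bb2"],
                    bb3_id=row["bb3"],
                    product=row["smiles"] or None,
                    tag=row["tag"],
                    is_truncate=bool(int(row["is_truncate"])),
                )
            )
    return out


_BLOCK_COLUMNS = ["id", "cycle", "role", "smiles"]


def write_building_blocks(blocks: Iterable[BuildingBlock], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_BLOCK_COLUMNS)
        for b in blocks:
            w.writerow([b.id, b.cycle, b.role.value, b.smiles])


def read_building_blocks(path: str | Path) -> list[list[BuildingBlock]]:
    """Read a block CSV (columns id, cycle, role, smiles) into per-cycle lists.

    SMILES are validated on read; malformed structures and duplicate ids are
    rejected with the offending row identified.
    """
    per_cycle: dict[int, list[BuildingBlock]] = {1: [], 2: [], 3: []}
    seen: set[str] = set()
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):  # header is row 1
            if row["id"] in seen:
                raise ValueError(f"row {i}: duplicate block id {row['id']!r}")
            seen.add(row["id"])
            role = Role(row["role"])
            smiles = row["smiles"].strip()
            if smiles and Chem.MolFromSmiles(smiles) is None:
                raise ValueError(f"row {i}: invalid SMILES {smiles!r}")
            block = BuildingBlock(id=row["id"], cycle=int(row["cycle"]), role=role, smiles=smiles)
            if block.cycle not in per_cycle:
                raise ValueError(f"row {i}: cycle must be 1-3, got {block.cycle}")
            per_cycle[block.cycle].append(block)
    return [per_cycle[1], per_cycle[2], per_cycle[3]]
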