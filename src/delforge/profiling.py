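"""Lead-likeness profiling: physicochemical descriptors, PCA diversity, PMI shape.

Six descriptors summarise lead-likeness of the library payloads: molecular
weight (MWt, Da), calculated log P (Crippen atom-contribution method),
hydrogen-bond donors (HBD), topological polar surface area (TPSA, A^2),
rotatable bonds (NRB) and aromatic rings (NAr).  Chemical-space diversity is
assessed with a PCA over either z-scored descriptors or hashed circular
(Morgan) fingerprints, and three-dimensional shape with normalized principal
moments of inertia (NPR1 = I1/I3, NPR2 = I2/I3), whose values classify a
molecule as rod- (0, 1), disc- (0.5, 0.5) or sphere-like (1, 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Descriptors3D, rdMolDescriptors
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorRecord",
    "PmiCoordinates",
    "DESCRIPTOR_NAMES",
    "compute_descriptors",
    "descriptor_table",
    "summarize",
    "fingerprint_matrix",
    "pca_embed",
    "pmi_coordinates",
    "pmi_table",
    "load_smiles_file",
]

DESCRIPTOR_NAMES = ["mwt", "clogp", "hbd", "tpsa", "nrb", "nar"]

CLOGP_METHOD = "Crippen atom contributions"  # reported in output metadata


@dataclass(frozen=True)
class DescriptorRecord:
    """Lead-likeness descriptors for a single payload structure."""

    member_id: str
    mwt: float
    clogp: float
    hbd: int
    tpsa: float
    nrb: int
    nar: int


@dataclass(frozen=True)
class PmiCoordinates:
    """Normalized principal-moment-of-inertia ratios (NPR1 <= NPR2)."""

    npr1: float
    npr2: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.npr1 <= self.npr2 <= 1 + 1e-9):
            raise ValueError(f"invalid PMI ratios ({self.npr1}, {self.npr2})")


def _mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return m


def compute_descriptors(smiles: str, member_id: str = "") -> DescriptorRecord:
    """All six lead-likeness descriptors for one structure; deterministic."""
    m = _mol(smiles)
    return DescriptorRecord(
        member_id=member_id,
        mwt=Descriptors.MolWt(m),
        clogp=Crippen.MolLogP(m),
        hbd=rdMolDescriptors.CalcNumHBD(m),
        tpsa=rdMolDescriptors.CalcTPSA(m),
        nrb=rdMolDescriptors.CalcNumRotatableBonds(m),
        nar=rdMolDescriptors.CalcNumAromaticRings(m),
    )


def descriptor_table(
    smiles: Iterable[str], ids: Iterable[str] | None = None
) -> pd.DataFrame:
    """Descriptor records for a compound set as a DataFrame."""
    smiles = list(smiles)
    ids = list(ids) if ids is not None else [str(i) for i in range(len(smiles))]
    records = [compute_descriptors(s, i) for s, i in zip(smiles, ids)]
    return pd.DataFrame([asdict(r) for r in records]).set_index("member_id")


def summarize(records: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-descriptor mean and standard deviation (sample std by default)."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty descriptor table")
    cols = [c for c in DESCRIPTOR_NAMES if c in records.columns]
    return pd.DataFrame({"mean": records[cols].mean(), "std": records[cols].std(ddof=ddof)})


def fingerprint_matrix(
    smiles: Iterable[str], n_bits: int = 1024, radius: int = 2
) -> np.ndarray:
    """Hashed circular (Morgan) fingerprints as a dense 0/1 matrix."""
    gen = AllChem.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = []
    for s in smiles:
        fp = gen.GetFingerprintAsNumPy(_mol(s))
        rows.append(fp.astype(np.float64))
    return np.asarray(rows)


def pca_embed(
    matrix: np.ndarray,
    n_components: int = 2,
    standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA embedding with a fixed sign convention.

    Components are ordered by decreasing explained variance; each component's
    sign is fixed so that its largest-magnitude loading is positive, making
    the embedding fully deterministic.  Returns (coordinates,
    explained_variance_ratio).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two compounds")
    if X.shape[0] < n_components:
        raise ValueError(
            f"cannot extract {n_components} components from {X.shape[0]} compounds"
        )
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for k in range(n_components):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, k] *= -1
    return coords, pca.explained_variance_ratio_


def pmi_coordinates(smiles: str, seed: int = 0, n_confs: int = 5) -> PmiCoordinates:
    """Normalized PMI ratios from the lowest-energy seeded conformer.

    Embeds ``n_confs`` ETKDG conformers with a fixed random seed, relaxes
    them with MMFF94 (UFF fallback for atoms without MMFF parameters) and
    evaluates the inertia ratios on the lowest-energy one.

    Raises ``ValueError`` if the structure cannot be embedded in 3D.
    """
    m = Chem.AddHs(_mol(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    cids = AllChem.EmbedMultipleConfs(m, numConfs=n_confs, params=params)
    if len(cids) == 0:
        raise ValueError(f"3D embedding failed for {smiles!r}")
    if AllChem.MMFFHasAllMoleculeParams(m):
        results = AllChem.MMFFOptimizeMoleculeConfs(m, maxIters=500)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(m, maxIters=500)
    best = int(cids[int(np.argmin([e for _, e in results]))])
    npr1 = Descriptors3D.NPR1(m, confId=best)
    npr2 = Descriptors3D.NPR2(m, confId=best)
    return PmiCoordinates(npr1=float(npr1), npr2=float(npr2))


def pmi_table(
    smiles: Iterable[str], ids: Iterable[str] | None = None, seed: int = 0
) -> pd.DataFrame:
    """PMI coordinates for a compound set; embedding failures are skipped."""
    smiles = list(smiles)
    ids = list(ids) if ids is not None else [str(i) for i in range(len(smiles))]
    rows = []
    for s, i in zip(smiles, ids):
        try:
            c = pmi_coordinates(s, seed=seed)
        except ValueError as exc:
            logger.warning("skipping %s: %s", i, exc)
            continue
        rows.append({"member_id": i, "npr1": c.npr1, "npr2": c.npr2})
    return pd.DataFrame(rows, columns=["member_id", "npr1", "npr2"]).set_index("member_id")


def load_smiles_file(path: str | Path) -> list[str]:
    """Read an external SMILES set (one SMILES per line, optional name column).

    Intended for comparative profiling against a reference screening
    collection; invalid lines are rejected with their line number.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smi = line.split()[0]
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"line {lineno}: invalid SMILES {smi!r}")
            out.append(smi)
    return out
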