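"""Chemical-space characterization: PMI shape analysis, the 11-descriptor
property profile, and PCA.

Shape is summarized by the principal moments of inertia I1 <= I2 <= I3 of a
conformer and the normalized ratios npr1 = I1/I3, npr2 = I2/I3, which place
every rigid body inside the rod-disc-sphere triangle (vertices (0,1),
(0.5,0.5), (1,1)).  Property space uses the 11 descriptors standard in
library comparison (HBD, HBA, RB, MW, logP, TPSA, heavy atoms, chiral
centers, rotatable-bond fraction, ring count, aromatic atoms), z-scored and
projected by PCA.

The inertia tensor is mass-weighted and includes hydrogens when present;
``mass_weighted=False`` switches to unit masses, since published shape
analyses differ on this and it shifts NPR values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors
from sklearn.decomposition import PCA as _SKPCA

logger = logging.getLogger("scaffscreen.chemspace")

DESCRIPTOR_NAMES = [
    "HBD", "HBA", "RB", "MW", "logP", "TPSA",
    "NH", "chiral", "FRB", "ring", "NA",
]

EMBED_SEED = 20240612  # ETKDG seed for the one-conformer embedding step

__all__ = [
    "ShapeTriple",
    "DescriptorVector",
    "PcaModel",
    "DESCRIPTOR_NAMES",
    "principal_moments",
    "compute_descriptors",
    "pca",
    "profile_library",
    "embed_conformer",
]


@dataclass(frozen=True)
class ShapeTriple:
    """Principal moments of inertia (ascending) and their NPR pair."""

    I1: float
    I2: float
    I3: float

    @property
    def npr1(self) -> float:
        return self.I1 / self.I3

    @property
    def npr2(self) -> float:
        return self.I2 / self.I3


def principal_moments(
    coords: np.ndarray,
    masses: np.ndarray | None = None,
) -> ShapeTriple:
    """Principal moments of the inertia tensor about the center of mass.

    coords: (n, 3); masses: (n,) or None for unit masses.  Eigenvalues are
    sorted ascending.  Degenerate geometry (<2 atoms, or all points
    coincident) raises ValueError.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise ValueError("principal_moments: need >=2 atoms with 3D coordinates")
    if not np.all(np.isfinite(coords)):
        raise ValueError("principal_moments: non-finite coordinates")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    r = coords - com
    if np.allclose(r, 0.0):
        raise ValueError("principal_moments: all atoms coincident")
    # I = sum_i m_i (|r|^2 E - r r^T)
    r2 = (r**2).sum(axis=1)
    tensor = np.einsum("i,ijk->jk", masses, r2[:, None, None] * np.eye(3))
    tensor -= np.einsum("i,ij,ik->jk", masses, r, r)
    moments = np.sort(np.linalg.eigvalsh(tensor))
    moments = np.clip(moments, 0.0, None)  # clip -0.0 eigenvalue noise
    return ShapeTriple(I1=moments[0], I2=moments[1], I3=moments[2])


def shape_from_mol(mol: Chem.Mol, conf_id: int = -1, mass_weighted: bool = True) -> ShapeTriple:
    """PMI triple of an embedded RDKit conformer (hydrogens as present)."""
    conf = mol.GetConformer(conf_id)
    coords = conf.GetPositions()
    masses = (
        np.array([a.GetMass() for a in mol.GetAtoms()]) if mass_weighted else None
    )
    return principal_moments(coords, masses)


@dataclass(frozen=True)
class DescriptorVector:
    """The 11-descriptor profile used for library PCA."""

    HBD: int
    HBA: int
    RB: int
    MW: float
    logP: float
    TPSA: float
    NH: int       # heavy atoms
    chiral: int   # chiral centers (assigned + unassigned)
    FRB: float    # RB / heavy-heavy bonds, 0 when no such bonds
    ring: int
    NA: int       # aromatic atoms

    def as_array(self) -> np.ndarray:
        d = asdict(self)
        return np.array([d[k] for k in DESCRIPTOR_NAMES], dtype=float)


def compute_descriptors(mol: Chem.Mol) -> DescriptorVector:
    """All 11 descriptors from the 2D structure (no conformer needed)."""
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("compute_descriptors: empty or unparseable structure")
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    heavy_bonds = sum(
        1
        for b in mol.GetBonds()
        if b.GetBeginAtom().GetAtomicNum() > 1 and b.GetEndAtom().GetAtomicNum() > 1
    )
    chiral = len(
        Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    )
    return DescriptorVector(
        HBD=rdMolDescriptors.CalcNumHBD(mol),
        HBA=rdMolDescriptors.CalcNumHBA(mol),
        RB=rb,
        MW=Descriptors.MolWt(mol),
        logP=Crippen.MolLogP(mol),
        TPSA=rdMolDescriptors.CalcTPSA(mol),
        NH=mol.GetNumHeavyAtoms(),
        chiral=chiral,
        FRB=rb / heavy_bonds if heavy_bonds else 0.0,
        ring=rdMolDescriptors.CalcNumRings(mol),
        NA=sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()),
    )


@dataclass
class PcaModel:
    """Standardized PCA of a descriptor table.

    ``loadings`` rows (components) are orthonormal;
    ``explained_variance_fraction`` covers ALL components (sums to 1) even
    when fewer scores are kept; ``scores`` = standardized data @ loadings.T
    for the first ``n_components`` components.
    """

    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    scores: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    descriptor_names: list[str]


def pca(
    table: pd.DataFrame | np.ndarray,
    n_components: int | None = None,
) -> PcaModel:
    """Z-score each descriptor, then PCA.

    Zero-variance descriptors are dropped with a warning before
    standardization.  Requires >=2 samples and no missing values.
    """
    if isinstance(table, pd.DataFrame):
        names = list(table.columns)
        X = table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ValueError("pca: need >=2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("pca: missing or non-finite values")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        dropped = [n for n, k in zip(names, keep) if not k]
        logger.warning("pca: dropping zero-variance descriptors %s", dropped)
        X, names, sd = X[:, keep], [n for n, k in zip(names, keep) if k], sd[keep]
    mean = X.mean(axis=0)
    Z = (X - mean) / sd
    full = _SKPCA(n_components=min(Z.shape), svd_solver="full").fit(Z)
    k = full.n_components_ if n_components is None else min(n_components, full.n_components_)
    evf = full.explained_variance_ratio_.copy()
    return PcaModel(
        loadings=full.components_[:k].copy(),
        explained_variance_fraction=evf,
        scores=Z @ full.components_[:k].T,
        mean=mean,
        scale=sd,
        descriptor_names=names,
    )


def embed_conformer(mol: Chem.Mol, seed: int = EMBED_SEED) -> Chem.Mol | None:
    """One ETKDG-embedded, MMFF-relaxed conformer with explicit hydrogens.

    Returns None when embedding fails.
    """
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(molh, params) != 0:
        return None
    try:
        AllChem.MMFFOptimizeMolecule(molh)
    except Exception:  # noqa: BLE001 - keep the unoptimized conformer
        pass
    return molh


def profile_library(
    mols: list[tuple[str, Chem.Mol]],
    conformers: dict[str, Chem.Mol] | None = None,
    mass_weighted: bool = True,
    seed: int = EMBED_SEED,
) -> pd.DataFrame:
    """Per-molecule chemical-space table: NPR pair + 11 descriptors + status.

    3D conformers may be supplied per id (e.g. read from SDF); otherwise one
    conformer is embedded with a fixed seed.  Rows whose embedding fails are
    flagged ``EMBED_FAIL`` (descriptors still computed), never dropped.
    """
    rows = []
    for mol_id, mol in mols:
        desc = compute_descriptors(mol)
        row: dict = {"id": mol_id, **asdict(desc)}
        conf_mol = (conformers or {}).get(mol_id)
        if conf_mol is None:
            conf_mol = embed_conformer(mol, seed=seed)
        if conf_mol is None:
            row.update(npr1=np.nan, npr2=np.nan, status="EMBED_FAIL")
        else:
            shape = shape_from_mol(conf_mol, mass_weighted=mass_weighted)
            row.update(npr1=shape.npr1, npr2=shape.npr2, status="OK")
        rows.append(row)
    return pd.DataFrame(rows)
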