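"""Bemis-Murcko scaffold decomposition and scaffold-keyed library indexing.

The Bemis-Murcko framework of a molecule is what remains after iteratively
pruning terminal (side-chain) atoms: the ring systems plus the acyclic
linkers connecting them.  Libraries are partitioned by canonical scaffold
key, which is what makes scaffold-hierarchical screening possible: score one
representative per scaffold first, then expand only the winners.

Atoms double-bonded to the framework (e.g. the oxindole carbonyl oxygen) are
retained in the scaffold by default, matching common Bemis-Murcko practice;
``strip_exocyclic`` switches this off.  Acyclic molecules have an empty
scaffold and are indexed under the reserved key ``ACYCLIC``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import RWMol
from rdkit.Chem.Scaffolds import MurckoScaffold

from .enumeration import LibraryRecord, canonical_smiles

logger = logging.getLogger("scaffscreen.scaffolds")

ACYCLIC_KEY = "ACYCLIC"

__all__ = [
    "ACYCLIC_KEY",
    "MurckoDecomposition",
    "ScaffoldIndex",
    "murcko_scaffold",
    "scaffold_key",
    "decompose_units",
    "build_scaffold_index",
    "extract_sublibrary",
    "enumerate_monosubstituted",
]


def murcko_scaffold(mol: Chem.Mol, strip_exocyclic: bool = False) -> Chem.Mol:
    """Bemis-Murcko scaffold: rings + linkers, side chains pruned.

    Idempotent; returns an empty molecule for acyclic input.  With
    ``strip_exocyclic`` the generic variant that also removes atoms
    double-bonded to the framework is approximated by pruning them too.
    """
    if mol is None:
        raise ValueError("murcko_scaffold: unparseable structure")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if strip_exocyclic and scaffold.GetNumAtoms():
        # drop exocyclic terminal atoms regardless of bond order
        rw = RWMol(scaffold)
        changed = True
        while changed:
            changed = False
            for atom in rw.GetAtoms():
                if atom.GetDegree() == 1 and not atom.IsInRing():
                    rw.RemoveAtom(atom.GetIdx())
                    changed = True
                    break
        scaffold = rw.GetMol()
        Chem.SanitizeMol(scaffold)
    return scaffold


def scaffold_key(mol: Chem.Mol, generic: bool = False, **kw) -> str:
    """Canonical scaffold key: isomeric SMILES of the Murcko scaffold with
    charges and isotopes stripped; ``ACYCLIC`` for ring-free molecules.

    ``generic=True`` additionally abstracts all atoms to carbon and bonds to
    single (the all-carbon "graph framework"), a coarser grouping.
    """
    scaffold = murcko_scaffold(mol, **kw)
    if scaffold.GetNumAtoms() == 0:
        return ACYCLIC_KEY
    if generic:
        scaffold = MurckoScaffold.MakeScaffoldGeneric(scaffold)
    scaffold = Chem.Mol(scaffold)
    for atom in scaffold.GetAtoms():
        charge = atom.GetFormalCharge()
        if charge > 0:  # neutralize by giving up protons where possible
            atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() - charge))
        elif charge < 0:
            atom.SetNumExplicitHs(atom.GetTotalNumHs() - charge)
        atom.SetFormalCharge(0)
        atom.SetIsotope(0)
    Chem.SanitizeMol(scaffold)
    return canonical_smiles(scaffold)


@dataclass
class MurckoDecomposition:
    """The four Bemis-Murcko unit classes of one molecule (as SMILES lists)."""

    scaffold: str  # "" when acyclic
    ring_systems: list[str]
    linkers: list[str]
    side_chains: list[str]
    # atom index sets on the input molecule, for the conservation invariant
    ring_atoms: set[int] = field(default_factory=set)
    linker_atoms: set[int] = field(default_factory=set)
    side_chain_atoms: set[int] = field(default_factory=set)


def _fragment_smiles(mol: Chem.Mol, atom_ids: set[int]) -> list[str]:
    """SMILES of the connected components induced by atom_ids."""
    if not atom_ids:
        return []
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in sorted(atom_ids):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            a = stack.pop()
            comp.append(a)
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                j = nb.GetIdx()
                if j in atom_ids and j not in seen:
                    seen.add(j)
                    stack.append(j)
        comps.append(sorted(comp))
    out = []
    for comp in comps:
        out.append(
            Chem.MolFragmentToSmiles(mol, atomsToUse=comp, canonical=True)
        )
    return sorted(out)


def decompose_units(mol: Chem.Mol) -> MurckoDecomposition:
    """Label every atom as ring system, linker or side chain.

    Ring systems are maximal fused/spiro ring components, extended by atoms
    multiply-bonded to a ring (the exocyclic carbonyls the scaffold keeps).
    Linkers are the remaining scaffold atoms (acyclic paths between ring
    systems); everything outside the scaffold is side chain.
    """
    if mol is None:
        raise ValueError("decompose_units: unparseable structure")
    scaffold = murcko_scaffold(mol)
    if scaffold.GetNumAtoms() == 0:
        side = set(range(mol.GetNumAtoms()))
        return MurckoDecomposition(
            scaffold="",
            ring_systems=[],
            linkers=[],
            side_chains=_fragment_smiles(mol, side),
            side_chain_atoms=side,
        )
    match = mol.GetSubstructMatch(scaffold)
    if not match:  # fall back: match ignoring H counts
        match = mol.GetSubstructMatch(Chem.MolFromSmarts(Chem.MolToSmarts(scaffold)))
    scaffold_atoms = set(match)
    ring_atoms = {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}
    # exocyclic atoms double/triple-bonded to a ring belong to the ring system
    for bond in mol.GetBonds():
        if bond.GetBondType() == Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.IsInRing() != b.IsInRing():
            out_atom = b if a.IsInRing() else a
            if out_atom.GetIdx() in scaffold_atoms:
                ring_atoms.add(out_atom.GetIdx())
    linker_atoms = scaffold_atoms - ring_atoms
    side_atoms = set(range(mol.GetNumAtoms())) - scaffold_atoms
    return MurckoDecomposition(
        scaffold=canonical_smiles(scaffold),
        ring_systems=_fragment_smiles(mol, ring_atoms),
        linkers=_fragment_smiles(mol, linker_atoms),
        side_chains=_fragment_smiles(mol, side_atoms),
        ring_atoms=ring_atoms,
        linker_atoms=linker_atoms,
        side_chain_atoms=side_atoms,
    )


@dataclass
class ScaffoldIndex:
    """Partition of a library by canonical scaffold key."""

    entries: dict[str, list[str]]  # scaffold key -> record ids (sorted)
    library_size: int

    @property
    def keys(self) -> list[str]:
        return sorted(self.entries)

    def members(self, key: str) -> list[str]:
        return list(self.entries.get(key, []))


def build_scaffold_index(
    records: list[LibraryRecord], generic: bool = False
) -> tuple[ScaffoldIndex, list[LibraryRecord]]:
    """Index a library by scaffold key.

    Returns the index plus the records with their ``scaffold_key`` field
    filled (records are frozen, so keyed copies are returned).
    """
    entries: dict[str, list[str]] = {}
    keyed: list[LibraryRecord] = []
    for rec in records:
        key = scaffold_key(rec.mol, generic=generic)
        entries.setdefault(key, []).append(rec.record_id)
        keyed.append(
            LibraryRecord(
                record_id=rec.record_id,
                smiles=rec.smiles,
                template_id=rec.template_id,
                block_ids=rec.block_ids,
                scaffold_key=key,
            )
        )
    for key in entries:
        entries[key].sort()
    return ScaffoldIndex(entries=entries, library_size=len(records)), keyed


def extract_sublibrary(
    index: ScaffoldIndex,
    selected_keys: set[str],
    records: list[LibraryRecord],
) -> list[LibraryRecord]:
    """All members of the selected scaffold keys, in record-id order.

    Unknown keys warn but do not fail.
    """
    unknown = set(selected_keys) - set(index.entries)
    if unknown:
        logger.warning("extract_sublibrary: unknown scaffold keys %s", sorted(unknown))
    wanted: set[str] = set()
    for key in selected_keys:
        wanted.update(index.entries.get(key, []))
    return sorted(
        (r for r in records if r.record_id in wanted), key=lambda r: r.record_id
    )


def _attachment_sites(scaffold: Chem.Mol, sites: list[int] | None) -> list[int]:
    if sites is not None:
        return list(sites)
    out = []
    for atom in scaffold.GetAtoms():
        if atom.GetTotalNumHs() < 1:
            continue
        if atom.GetIsAromatic() or (
            atom.IsInRing() and atom.GetHybridization() == Chem.HybridizationType.SP3
        ):
            out.append(atom.GetIdx())
    return out


def _attachment_atom(sub: Chem.Mol) -> tuple[Chem.Mol, int]:
    """Resolve a substituent's attachment point.

    A dummy atom (``*``) marks the attachment; it is removed and its neighbor
    becomes the attachment atom.  Without a dummy, atom 0 is used.
    """
    dummies = [a.GetIdx() for a in sub.GetAtoms() if a.GetAtomicNum() == 0]
    if not dummies:
        return sub, 0
    rw = RWMol(sub)
    dummy = dummies[0]
    nbrs = [n.GetIdx() for n in rw.GetAtomWithIdx(dummy).GetNeighbors()]
    rw.RemoveAtom(dummy)
    att = nbrs[0] - (1 if nbrs[0] > dummy else 0)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol, att


def enumerate_monosubstituted(
    scaffold: Chem.Mol,
    substituents: list[tuple[str, Chem.Mol]],
    sites: list[int] | None = None,
    include_ring_substituents: bool = False,
) -> tuple[list[LibraryRecord], list[LibraryRecord]]:
    """Expand a scaffold into its monosubstituted sub-library.

    Each product differs from the scaffold by exactly one substituent at one
    allowed site (default: any H-bearing aromatic or sp3 ring atom).
    Duplicates by canonical key are removed.  Ring-containing substituents
    change the Murcko scaffold, so their products are returned separately as
    flagged records (and merged in only with ``include_ring_substituents``).

    Returns (sub_library, flagged_scaffold_changing).
    """
    base_key = scaffold_key(scaffold)
    site_ids = _attachment_sites(scaffold, sites)
    if not site_ids:
        logger.warning("enumerate_monosubstituted: scaffold has no allowed sites")
        return [], []
    kept: list[LibraryRecord] = []
    flagged: list[LibraryRecord] = []
    seen: set[str] = set()
    for sub_id, sub in substituents:
        sub_clean, att = _attachment_atom(sub)
        has_ring = sub_clean.GetRingInfo().NumRings() > 0
        for site in site_ids:
            combo = RWMol(Chem.CombineMols(scaffold, sub_clean))
            combo.AddBond(site, scaffold.GetNumAtoms() + att, Chem.BondType.SINGLE)
            try:
                prod = combo.GetMol()
                Chem.SanitizeMol(prod)
            except Exception:  # noqa: BLE001 - chemically invalid attachment
                continue
            smi = canonical_smiles(prod)
            if smi in seen:
                continue
            seen.add(smi)
            rec = LibraryRecord(
                record_id=f"monosub:{base_key}:{sub_id}@{site}",
                smiles=smi,
                template_id="monosub",
                block_ids=(base_key, sub_id),
                scaffold_key=scaffold_key(prod),
            )
            if has_ring or rec.scaffold_key != base_key:
                flagged.append(rec)
            else:
                kept.append(rec)
    if include_ring_substituents:
        kept = sorted(kept + flagged, key=lambda r: r.record_id)
        flagged = []
    return kept, flagged
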