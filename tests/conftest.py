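import numpy as np
import pytest
from rdkit import Chem, RDLogger

from scaffscreen import (
    FixtureSpec,
    build_scaffold_index,
    enumerate_products,
    generate_planted_library,
)

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def planted():
    """Small planted-active library: blocks, template, truth, records, index."""
    spec = FixtureSpec(
        seed=7, scenario="planted_library",
        parameters={"n_scaffolds": 9, "n_per_scaffold": 12},
    )
    blocks, template, truth = generate_planted_library(spec)
    records = enumerate_products(template, blocks)
    index, keyed = build_scaffold_index(records)
    return {
        "blocks": blocks, "template": template, "truth": truth,
        "records": records, "index": index, "keyed": keyed,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240612)


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------

def murcko_oracle(smiles: str) -> str:
    """Bemis-Murcko framework by independent iterative terminal pruning.

    Repeatedly delete non-ring atoms of degree <= 1; then restore any
    deleted atom multiple-bonded to a surviving atom (exocyclic carbonyls
    etc.).  Returns canonical SMILES of the framework, '' if acyclic.
    """
    mol = Chem.MolFromSmiles(smiles)
    n = mol.GetNumAtoms()
    in_ring = [a.IsInRing() for a in mol.GetAtoms()]
    adj = {i: {n2.GetIdx() for n2 in mol.GetAtomWithIdx(i).GetNeighbors()} for i in range(n)}
    alive = set(range(n))
    changed = True
    while changed:
        changed = False
        for i in sorted(alive):
            deg = len(adj[i] & alive)
            if not in_ring[i] and deg <= 1:
                alive.discard(i)
                changed = True
    if not any(in_ring[i] for i in alive):
        return ""
    restored = set(alive)
    for bond in mol.GetBonds():
        if bond.GetBondTypeAsDouble() > 1.0:
            a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if (a in alive) != (b in alive):
                restored.add(a)
                restored.add(b)
    frag = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(restored), canonical=True)
    out = Chem.MolFromSmiles(frag)
    return Chem.MolToSmiles(out) if out is not None else frag


ATOMIC_WEIGHTS = {  # standard atomic weights for the MW summation oracle
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "S": 32.06, "Cl": 35.45, "Br": 79.904, "P": 30.974, "I": 126.904,
}


def mw_oracle(smiles: str) -> float:
    """Molecular weight by atomic-mass summation over the molecular formula."""
    mol = Chem.MolFromSmiles(smiles)
    total = 0.0
    for atom in mol.GetAtoms():
        total += ATOMIC_WEIGHTS[atom.GetSymbol()]
        total += ATOMIC_WEIGHTS["H"] * atom.GetTotalNumHs()
    return total
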