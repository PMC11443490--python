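"""Per-atom circular environments as canonical rooted fragment SMILES.

Each heavy atom's environment of radius r is the subgraph of bonds within r
bonds of the atom, rendered as a canonical SMILES rooted at that atom.  When
the molecule is smaller than the requested radius the available neighborhood
is used; an isolated atom falls back to an invariant string (symbol, degree,
hydrogen count, charge, aromaticity).  Unlike hashed Morgan environments this
representation is never deduplicated across symmetric atoms, so every heavy
atom contributes exactly one environment.
"""

from __future__ import annotations

import hashlib

from rdkit import Chem


def atom_environment(mol: Chem.Mol, atom_idx: int, radius: int) -> str:
    bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx) if radius > 0 else []
    if not bonds:
        a = mol.GetAtomWithIdx(atom_idx)
        return (
            f"{a.GetSymbol()}|{a.GetDegree()}|{a.GetTotalNumHs()}"
            f"|{a.GetFormalCharge()}|{int(a.GetIsAromatic())}"
        )
    atoms = set()
    for b in bonds:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=sorted(atoms),
        bondsToUse=list(bonds),
        rootedAtAtom=atom_idx,
        canonical=True,
    )


def molecule_environments(mol: Chem.Mol, radius: int) -> list[str]:
    """One environment string per heavy atom (largest neighborhood <= radius)."""
    return [atom_environment(mol, i, radius) for i in range(mol.GetNumAtoms())]


def environment_hash(env: str) -> int:
    """Stable 64-bit integer hash of an environment string."""
    return int.from_bytes(hashlib.blake2b(env.encode(), digest_size=8).digest(), "big")
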