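"""RECAP retrosynthetic fragmentation and fragment-library construction.

RECAP cleaves acyclic bonds of the kinds formed by common synthetic
reactions — amide, ester, amine, urea, ether, olefin, quaternary nitrogen,
aromatic nitrogen-aliphatic carbon, lactam nitrogen-aliphatic carbon,
biaryl carbon-carbon and sulfonamide — while rings are kept intact.
Every rule-matching acyclic bond found on the parent molecule is cleaved
simultaneously; the resulting pieces are the leaf fragments, with cut
sites marked by dummy atoms ("*" in keys, "A" in human-readable reports).
Because cleavage never deletes atoms, heavy atoms are conserved between a
parent and its leaves.

Fragment libraries aggregate leaf counts across a library (after a
molecular-weight pre-filter) and annotate each fragment with rule-of-three
descriptors computed on the hydrogen-capped fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .io_curation import MoleculeRecord

#: canonical RECAP bond rules; each SMARTS has exactly two mapped atoms and the
#: mapped-atom bond is the one cleaved (acyclic bonds only, enforced by !@).
RECAP_RULES: tuple[tuple[str, str], ...] = (
    ("amide", "[CX3;!$(C([NX3])[NX3]):1](=O)-!@[NX3:2]"),
    ("ester", "[CX3:1](=O)-!@[OX2;$(O([#6])[#6]):2]"),
    ("urea", "[NX3:1]-!@[CX3:2](=O)[NX3]"),
    ("amine", "[NX3;H1,H0;!$(N=*);!$(N-C=[O,S,N]);!$(N-S(=O)=O);!$(N-[!#6;!#1]):1]-!@[CX4:2]"),
    ("ether", "[#6:1]-!@[OX2;$(O([#6])[#6]);!$(O-C=O):2]"),
    ("olefin", "[CX3;!$(C=[!#6]):1]=!@[CX3;!$(C=[!#6]):2]"),
    ("quaternary_nitrogen", "[NX4+:1]-!@[CX4:2]"),
    ("aromatic_nitrogen_aliphatic_carbon", "[n:1]-!@[CX4:2]"),
    ("lactam_nitrogen_aliphatic_carbon", "[NX3;R;$(N@[CX3]=O):1]-!@[CX4:2]"),
    ("aromatic_carbon_aromatic_carbon", "[c:1]-!@[c:2]"),
    ("sulfonamide", "[NX3:1]-!@[SX4:2](=O)=O"),
)


@dataclass
class RecapRuleSet:
    """Ordered cleavage rules; individual rules can be disabled.

    ``min_fragment_atoms``: a bond is only cleaved when both sides of the cut
    would leave fragments with at least this many heavy atoms (1 = cleave
    everything the rules match).
    """

    enabled: dict[str, bool] = field(default_factory=lambda: {name: True for name, _ in RECAP_RULES})
    min_fragment_atoms: int = 1

    def patterns(self) -> list[tuple[str, Chem.Mol]]:
        out = []
        for name, smarts in RECAP_RULES:
            if self.enabled.get(name, False):
                out.append((name, Chem.MolFromSmarts(smarts)))
        return out


DEFAULT_RULES = RecapRuleSet()


def _mapped_bond(pattern: Chem.Mol, match: tuple[int, ...], mol: Chem.Mol) -> Optional[int]:
    """Bond index in ``mol`` between the two map-numbered atoms of a match."""
    idx = {}
    for atom in pattern.GetAtoms():
        num = atom.GetAtomMapNum()
        if num:
            idx[num] = match[atom.GetIdx()]
    bond = mol.GetBondBetweenAtoms(idx[1], idx[2])
    return bond.GetIdx() if bond is not None else None


def cleavable_bonds(mol: Chem.Mol, rules: RecapRuleSet = DEFAULT_RULES) -> dict[int, str]:
    """bond index -> first matching rule name, over all enabled rules."""
    found: dict[int, str] = {}
    for name, pattern in rules.patterns():
        # uniquify=False: symmetric patterns (urea) must yield both bonds
        for match in mol.GetSubstructMatches(pattern, uniquify=False):
            b = _mapped_bond(pattern, match, mol)
            if b is not None and b not in found and not mol.GetBondWithIdx(b).IsInRing():
                found[b] = name
    return found


def _fragment_sizes_ok(mol: Chem.Mol, bond_idx: int, min_atoms: int) -> bool:
    if min_atoms <= 1:
        return True
    em = Chem.RWMol(mol)
    bond = em.GetBondWithIdx(bond_idx)
    em.RemoveBond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    frags = Chem.GetMolFrags(em)
    return all(len(f) >= min_atoms for f in frags)


def recap_fragments(record, rules: RecapRuleSet = DEFAULT_RULES) -> set[str]:
    """Leaf fragments of one molecule as canonical SMILES with ``*`` cut markers.

    Returns an empty set when no rule matches (the molecule is its own leaf;
    callers tally such molecules separately).  Stereochemistry is kept.
    """
    if isinstance(record, MoleculeRecord):
        mol = record.mol()
    elif isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
    else:
        mol = record
    if mol is None:
        raise ValueError("invalid structure")
    bonds = [
        b
        for b in cleavable_bonds(mol, rules)
        if _fragment_sizes_ok(mol, b, rules.min_fragment_atoms)
    ]
    if not bonds:
        return set()
    fragmented = Chem.FragmentOnBonds(mol, bonds, addDummies=True, dummyLabels=[(0, 0)] * len(bonds))
    keys = set()
    for frag in Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=False):
        Chem.SanitizeMol(frag)
        keys.add(Chem.MolToSmiles(frag))
    return keys


def human_readable(fragment_key: str) -> str:
    """Render a fragment key with 'A' disconnection symbols."""
    return fragment_key.replace("[*]", "[A]").replace("*", "A")


def cap_fragment(fragment_key: str) -> Chem.Mol:
    """Hydrogen-cap the attachment points of a fragment for property calculation."""
    mol = Chem.MolFromSmiles(fragment_key)
    if mol is None:
        raise ValueError(f"cannot parse fragment {fragment_key!r}")
    em = Chem.RWMol(mol)
    for atom in em.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetIsotope(0)
    capped = em.GetMol()
    Chem.SanitizeMol(capped)
    return Chem.RemoveHs(capped)


@dataclass
class FragmentLibrary:
    dataset: str
    rows: pd.DataFrame  # fragment_key, count, MW, cLogP, HBD, HBA, ro3_pass
    n_skipped_mw: int = 0
    n_unfragmented: int = 0

    def keys(self) -> set[str]:
        return set(self.rows["fragment_key"])

    @property
    def ro3_fraction(self) -> float:
        if len(self.rows) == 0:
            return 0.0
        return float(self.rows["ro3_pass"].mean())


def _ro3_props(fragment_key: str) -> tuple[float, float, int, int, bool]:
    capped = cap_fragment(fragment_key)
    mw = Descriptors.MolWt(capped)
    clogp = Crippen.MolLogP(capped)
    hbd = Lipinski.NHOHCount(capped)
    hba = Lipinski.NOCount(capped)
    ro3 = (mw < 300) and (clogp <= 3) and (hbd <= 3) and (hba <= 3)
    return mw, clogp, hbd, hba, ro3


def build_fragment_library(
    records: Sequence,
    mw_cap: float = 1350.0,
    rules: RecapRuleSet = DEFAULT_RULES,
    dataset: str = "",
) -> FragmentLibrary:
    """Aggregate leaf-fragment counts over a library.

    Molecules heavier than ``mw_cap`` are skipped (counted); molecules with
    no cleavable bond contribute nothing to the table and are tallied in
    ``n_unfragmented``.
    """
    if mw_cap <= 0:
        raise ValueError("mw_cap must be positive")
    counts: dict[str, int] = {}
    skipped = 0
    unfragmented = 0
    for r in records:
        mol = r.mol() if isinstance(r, MoleculeRecord) else Chem.MolFromSmiles(r) if isinstance(r, str) else r
        if mol is None:
            continue
        if Descriptors.MolWt(mol) > mw_cap:
            skipped += 1
            continue
        frags = recap_fragments(mol, rules)
        if not frags:
            unfragmented += 1
            continue
        for key in frags:
            counts[key] = counts.get(key, 0) + 1
    rows = []
    for key, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        mw, clogp, hbd, hba, ro3 = _ro3_props(key)
        rows.append(
            {
                "fragment_key": key,
                "count": count,
                "MW": mw,
                "cLogP": clogp,
                "HBD": hbd,
                "HBA": hba,
                "ro3_pass": ro3,
            }
        )
    frame = pd.DataFrame(rows, columns=["fragment_key", "count", "MW", "cLogP", "HBD", "HBA", "ro3_pass"])
    return FragmentLibrary(dataset=dataset, rows=frame, n_skipped_mw=skipped, n_unfragmented=unfragmented)


def ro3_filter(lib: FragmentLibrary) -> FragmentLibrary:
    """Keep only fragments passing the rule of three (MW<300, cLogP<=3, HBD<=3, HBA<=3)."""
    kept = lib.rows[lib.rows["ro3_pass"]].reset_index(drop=True)
    return FragmentLibrary(
        dataset=lib.dataset,
        rows=kept,
        n_skipped_mw=lib.n_skipped_mw,
        n_unfragmented=lib.n_unfragmented,
    )
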