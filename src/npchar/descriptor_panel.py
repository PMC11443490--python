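"""Physicochemical/constitutional descriptor panel, drug-likeness rules, group profiles.

Definitions follow the topological conventions standard in library profiling:
HBA/HBD are Lipinski-style counts (HBA = N+O; HBD = N-H/O-H hydrogens), with
the stricter pharmacophore-style HBA available behind ``hba_definition``;
logP is the Crippen atomic-contribution estimate; TPSA the Ertl fragment sum.
Chiral centers count assigned plus unassigned potential tetrahedral centers.
Acid/basic atom counts use a transparent SMARTS set documented below.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields as dataclass_fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .io_curation import MoleculeRecord

# Acidic positions: carboxylic, sulfonic/sulfinic, phosphonic/phosphoric acids
# (neutral or deprotonated).  Each match contributes one acid atom (the
# ionizable oxygen).
_ACID_SMARTS = [
    "[CX3](=O)[OX2H1,OX1-]",
    "[SX4](=O)(=O)[OX2H1,OX1-]",
    "[SX3](=O)[OX2H1,OX1-]",
    "[PX4](=O)[OX2H1,OX1-]",
]
# Basic nitrogens: aliphatic amines not adjacent to carbonyl/sulfonyl or
# another heteroatom, plus amidine/guanidine sp2 nitrogens.
_BASIC_SMARTS = [
    "[NX3;H2,H1,H0;+0;!$(N-[!#6;!#1]);!$(N-C=[O,N,S]);!$(N-a)]",
    "[NX2;$(N=C-[NX3]);+0]",
]
_ACID_PATTERNS = [Chem.MolFromSmarts(s) for s in _ACID_SMARTS]
_BASIC_PATTERNS = [Chem.MolFromSmarts(s) for s in _BASIC_SMARTS]

_HALOGENS = {9, 17, 35, 53}


@dataclass(frozen=True)
class DescriptorVector:
    HBA: int
    HBD: int
    logP: float
    TPSA: float
    MW: float
    CSP3: float
    heavy_atoms: int
    rings_total: int
    heteroatoms: int
    RB: int
    RB_fraction: float
    carbo_alicyclic_rings: int
    hetero_alicyclic_rings: int
    carbo_aromatic_rings: int
    hetero_aromatic_rings: int
    aromatic_rings_total: int
    acid_atoms: int
    basic_atoms: int
    aromatic_atoms: int
    n_N: int
    n_O: int
    n_halogen: int
    chiral_centers: int


DESCRIPTOR_NAMES = [f.name for f in dataclass_fields(DescriptorVector)]


@dataclass(frozen=True)
class RuleFlags:
    lipinski_pass: bool
    lipinski_criteria: dict
    veber_pass: bool
    veber_criteria: dict
    ro3_pass: bool
    ro3_criteria: dict


@dataclass
class GroupProfile:
    group_label: str
    n: int
    summary: pd.DataFrame  # rows: descriptors; cols: mean, median, sd, q1, q3


def _ring_counts(mol: Chem.Mol) -> tuple[int, int, int, int]:
    """(carbo_alicyclic, hetero_alicyclic, carbo_aromatic, hetero_aromatic) over SSSR."""
    ri = mol.GetRingInfo()
    counts = [0, 0, 0, 0]
    for ring_bonds, ring_atoms in zip(ri.BondRings(), ri.AtomRings()):
        aromatic = all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring_bonds)
        hetero = any(mol.GetAtomWithIdx(a).GetAtomicNum() != 6 for a in ring_atoms)
        counts[2 * aromatic + hetero] += 1
    return tuple(counts)


def compute_descriptors(
    record: MoleculeRecord | Chem.Mol | str,
    hba_definition: str = "lipinski",
) -> DescriptorVector:
    """Compute the full descriptor panel for one curated structure.

    ``hba_definition``: "lipinski" (N+O count) or "topological"
    (RDKit's pharmacophoric HBA).
    """
    if isinstance(record, MoleculeRecord):
        mol = record.mol()
    elif isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
    else:
        mol = record
    if mol is None:
        raise ValueError("invalid structure")

    if hba_definition == "lipinski":
        hba = Lipinski.NOCount(mol)
    elif hba_definition == "topological":
        hba = rdMolDescriptors.CalcNumHBA(mol)
    else:
        raise ValueError(f"unknown hba_definition {hba_definition!r}")

    n_heavy_bonds = mol.GetNumBonds()
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    carbo_ali, het_ali, carbo_aro, het_aro = _ring_counts(mol)
    chiral = len(
        Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    )
    nums = [a.GetAtomicNum() for a in mol.GetAtoms()]
    acid = sum(len(mol.GetSubstructMatches(p)) for p in _ACID_PATTERNS)
    basic = sum(len(mol.GetSubstructMatches(p)) for p in _BASIC_PATTERNS)

    return DescriptorVector(
        HBA=int(hba),
        HBD=int(Lipinski.NHOHCount(mol)),
        logP=float(Crippen.MolLogP(mol)),
        TPSA=float(rdMolDescriptors.CalcTPSA(mol)),
        MW=float(Descriptors.MolWt(mol)),
        CSP3=float(rdMolDescriptors.CalcFractionCSP3(mol)),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        rings_total=rdMolDescriptors.CalcNumRings(mol),
        heteroatoms=rdMolDescriptors.CalcNumHeteroatoms(mol),
        RB=int(rb),
        RB_fraction=float(rb / n_heavy_bonds) if n_heavy_bonds else 0.0,
        carbo_alicyclic_rings=carbo_ali,
        hetero_alicyclic_rings=het_ali,
        carbo_aromatic_rings=carbo_aro,
        hetero_aromatic_rings=het_aro,
        aromatic_rings_total=carbo_aro + het_aro,
        acid_atoms=acid,
        basic_atoms=basic,
        aromatic_atoms=sum(a.GetIsAromatic() for a in mol.GetAtoms()),
        n_N=nums.count(7),
        n_O=nums.count(8),
        n_halogen=sum(n in _HALOGENS for n in nums),
        chiral_centers=chiral,
    )


def rule_flags(d: DescriptorVector) -> RuleFlags:
    """Lipinski (MW<=500, logP<=5, HBD<=5, HBA<=10), Veber (RB<=10, TPSA<=140),
    rule-of-three (MW<300 strict, cLogP<=3, HBD<=3, HBA<=3)."""
    lip = {
        "MW": d.MW <= 500,
        "logP": d.logP <= 5,
        "HBD": d.HBD <= 5,
        "HBA": d.HBA <= 10,
    }
    veb = {"RB": d.RB <= 10, "TPSA": d.TPSA <= 140}
    ro3 = {
        "MW": d.MW < 300,
        "logP": d.logP <= 3,
        "HBD": d.HBD <= 3,
        "HBA": d.HBA <= 3,
    }
    return RuleFlags(
        lipinski_pass=all(lip.values()),
        lipinski_criteria=lip,
        veber_pass=all(veb.values()),
        veber_criteria=veb,
        ro3_pass=all(ro3.values()),
        ro3_criteria=ro3,
    )


def vectors_to_frame(vectors: Sequence[DescriptorVector]) -> pd.DataFrame:
    return pd.DataFrame([v.__dict__ for v in vectors], columns=DESCRIPTOR_NAMES)


def summarize_library(vectors: Sequence[DescriptorVector]) -> pd.DataFrame:
    """Per-descriptor mean/median/sd/quartiles (sd is the population sd for n=1 -> 0)."""
    if len(vectors) == 0:
        raise ValueError("cannot summarize an empty library")
    df = vectors_to_frame(vectors)
    out = pd.DataFrame(
        {
            "mean": df.mean(),
            "median": df.median(),
            "sd": df.std(ddof=1).fillna(0.0) if len(df) > 1 else pd.Series(0.0, index=df.columns),
            "q1": df.quantile(0.25),
            "q3": df.quantile(0.75),
        }
    )
    out.index.name = "descriptor"
    return out


def profile_by_group(
    records: Sequence[MoleculeRecord],
    vectors: Sequence[DescriptorVector],
    group_field: str = "solvent_label",
) -> tuple[list[GroupProfile], pd.DataFrame]:
    """Per-label descriptor summaries plus a label frequency table (descending).

    Records with a missing label are excluded.  Returns ``([], empty_table)``
    with a warning when no record carries the label.
    """
    labels = [getattr(r, group_field, None) for r in records]
    pairs = [(lab, v) for lab, v in zip(labels, vectors) if lab]
    if not pairs:
        import warnings

        warnings.warn(f"no records carry a {group_field!r} label")
        return [], pd.DataFrame(columns=["label", "n"])
    by_label: dict[str, list[DescriptorVector]] = {}
    for lab, v in pairs:
        by_label.setdefault(lab, []).append(v)
    freq = pd.DataFrame(
        sorted(((lab, len(vs)) for lab, vs in by_label.items()), key=lambda t: (-t[1], t[0])),
        columns=["label", "n"],
    )
    profiles = [
        GroupProfile(group_label=lab, n=len(by_label[lab]), summary=summarize_library(by_label[lab]))
        for lab in freq["label"]
    ]
    return profiles, freq


def histogram_table(
    vectors: Sequence[DescriptorVector], descriptor: str, bins: int = 20
) -> pd.DataFrame:
    """Histogram bin table (bin_left, bin_right, count) for distribution plots."""
    values = vectors_to_frame(vectors)[descriptor].to_numpy(dtype=float)
    counts, edges = np.histogram(values, bins=bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def write_descriptor_csv(
    records: Sequence[MoleculeRecord], vectors: Sequence[DescriptorVector], path
) -> None:
    df = vectors_to_frame(vectors)
    df.insert(0, "entry_id", [r.entry_id for r in records])
    df.to_csv(path, index=False)
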