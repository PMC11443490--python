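"""Synthetic labeled compound libraries with known ground truth.

Real natural-product registries are emulated by an assembly grammar:
molecules are built by decorating a curated pool of cores with substituent
fragments, so every product is parseable, valence-correct and carries a
known recipe (core, substituents, cluster, intended curation outcome).

Profiles
--------
``np_like``
    Oxygen-rich, nitrogen-free polycyclic cores (chromone, coumarin,
    flavanone, pyranose, decalin, terpenoid-like) with hydroxy / methoxy /
    acetoxy / hydroxymethyl substituents — high sp3-carbon fraction, many
    stereocenters, next to no nitrogen, mirroring the constitution of
    natural-product collections.
``drug_like``
    Nitrogen-rich heteroaromatic cores (pyridine, pyrimidine, quinoline,
    benzothiazole, indole) with amine / amide / sulfonamide / halogen
    substituents — flat, aromatic, nitrogen-heavy, mirroring synthetic
    drug space.
``cluster``
    A small number of internally homogeneous families (one core per
    cluster, light decoration) with cluster labels, giving diversity and
    embedding analyses a known answer.
``edge_cases``
    Valid molecules plus controlled fractions of salts (multi-component,
    should survive curation), disallowed-element entries (should be removed)
    and valence-broken entries (should be removed), with the intended
    outcome recorded per entry.

Solvent labels emulate NMR-solvent solubility categories through a simple
threshold rule on TPSA/HBD, optionally corrupted by label noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .io_curation import KEPT, REMOVED_ELEMENT, REMOVED_VALENCE, RawEntry

NP_CORES = (
    "O=C1C=COc2ccccc21",  # chromone
    "O=C1C=Cc2ccccc2O1",  # coumarin
    "O=C1CC(c2ccccc2)Oc2ccccc21",  # flavanone
    "OC1OC(CO)C(O)C(O)C1O",  # pyranose
    "C1CCC2CCCCC2C1",  # decalin
    "CC1(C)CCCC2(C)CCCC12",  # terpenoid-like bicycle
    "O=C1CCC2(C)C(CCC3C2CCC2(C)CCCC32)C1",  # steroid-like tetracycle
    "C1CC2CCC1O2",  # oxabicyclic bridge
)
NP_SUBSTITUENTS = ("O", "OC", "CO", "OC(C)=O", "C(=O)O", "C", "CC(C)O", "OCC(O)CO")

DRUG_CORES = (
    "c1ccncc1",  # pyridine
    "c1cncnc1",  # pyrimidine
    "c1ccc2ncccc2c1",  # quinoline
    "c1ccc2sc(nc2c1)C",  # methylbenzothiazole
    "c1ccc2[nH]ccc2c1",  # indole
    "c1ccc(-c2ccncc2)cc1",  # phenylpyridine
    "C1CN(CCN1)c1ccccc1",  # phenylpiperazine
)
DRUG_SUBSTITUENTS = ("N", "NC", "N(C)C", "C(=O)NC", "NC(C)=O", "S(=O)(=O)N", "F", "Cl", "C#N", "OC")

CLUSTER_CORES = (
    "C1CCC2CCCCC2C1",  # saturated carbocycle family
    "c1ccc2ccccc2c1",  # aromatic naphthalene family
    "OC1OC(CO)C(O)C(O)C1O",  # sugar family
)
CLUSTER_SUBSTITUENTS = (("C", "CC"), ("F", "Cl"), ("O", "CO"))

SALT_COUNTERIONS = ("[Na+]", "[K+]", "[Cl-]", "O")
DISALLOWED_ELEMENTS = (78, 80, 50, 26)  # Pt, Hg, Sn, Fe

DEFAULT_SOLVENT_RULE = {"tpsa_high": 75.0, "tpsa_low": 25.0}
SOLVENT_LABELS = ("DMSO-d6", "CD3OD", "CDCl3")


@dataclass
class GeneratorSpec:
    profile: str  # np_like | drug_like | cluster | edge_cases
    n: int
    seed: int
    salt_fraction: float = 0.0
    disallowed_element_fraction: float = 0.0
    invalid_valence_fraction: float = 0.0
    core_pool: Optional[Sequence[str]] = None
    substituent_pool: Optional[Sequence[str]] = None
    n_clusters: int = 3
    solvent_rule: dict = field(default_factory=lambda: dict(DEFAULT_SOLVENT_RULE))
    label_noise: float = 0.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        fracs = (self.salt_fraction, self.disallowed_element_fraction, self.invalid_valence_fraction)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("edge-case fractions must lie in [0,1] and sum to <= 1")


def _attachable_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0 and a.GetAtomicNum() == 6]


def _attach(core: Chem.Mol, sub_smiles: str, atom_idx: int) -> Optional[Chem.Mol]:
    """Bond the first atom of ``sub_smiles`` to ``atom_idx`` of the core."""
    sub = Chem.MolFromSmiles(sub_smiles)
    if sub is None:
        return None
    combined = Chem.RWMol(Chem.CombineMols(core, sub))
    combined.AddBond(atom_idx, core.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        mol = combined.GetMol()
        Chem.SanitizeMol(mol)
        return mol
    except Exception:
        return None


def _assemble(
    rng: np.random.Generator,
    cores: Sequence[str],
    substituents: Sequence[str],
    max_substituents: int = 4,
    min_substituents: int = 1,
) -> tuple[str, str, int]:
    """Random decorated molecule; returns (smiles, core, n_substituents_attached)."""
    core_smiles = cores[int(rng.integers(len(cores)))]
    mol = Chem.MolFromSmiles(core_smiles)
    n_sub = int(rng.integers(min_substituents, max_substituents + 1))
    attached = 0
    for _ in range(n_sub):
        sites = _attachable_atoms(mol)
        if not sites:
            break
        idx = sites[int(rng.integers(len(sites)))]
        sub = substituents[int(rng.integers(len(substituents)))]
        candidate = _attach(mol, sub, idx)
        if candidate is not None:
            mol = candidate
            attached += 1
    return Chem.MolToSmiles(mol), core_smiles, attached


def _bad_valence_smiles(rng: np.random.Generator) -> str:
    """A pentavalent-carbon SMILES string; parseable but chemically invalid."""
    arms = ["C" * int(rng.integers(1, 4)) for _ in range(3)]
    return f"CC({arms[0]})({arms[1]})({arms[2]})(C)C"


def _with_disallowed_element(mol: Chem.Mol, rng: np.random.Generator) -> Optional[str]:
    """Attach a disallowed metal atom into the parent component."""
    sites = _attachable_atoms(mol)
    if not sites:
        return None
    em = Chem.RWMol(mol)
    metal = int(DISALLOWED_ELEMENTS[int(rng.integers(len(DISALLOWED_ELEMENTS)))])
    new_idx = em.AddAtom(Chem.Atom(metal))
    em.AddBond(sites[int(rng.integers(len(sites)))], new_idx, Chem.BondType.SINGLE)
    try:
        out = em.GetMol()
        out.UpdatePropertyCache(strict=False)
        return Chem.MolToSmiles(out)
    except Exception:
        return None


def assign_solvent_labels(
    smiles_list: Sequence[str],
    solvent_rule: dict = DEFAULT_SOLVENT_RULE,
    label_noise: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> list[Optional[str]]:
    """Threshold rule: TPSA >= tpsa_high -> DMSO-d6; TPSA < tpsa_low and
    HBD = 0 -> CDCl3; otherwise CD3OD.  With probability ``label_noise`` a
    uniformly random label replaces the rule's answer."""
    if rng is None:
        rng = np.random.default_rng(0)
    labels: list[Optional[str]] = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            labels.append(None)
            continue
        tpsa = rdMolDescriptors.CalcTPSA(mol)
        hbd = rdMolDescriptors.CalcNumHBD(mol)
        if tpsa >= solvent_rule["tpsa_high"]:
            label = "DMSO-d6"
        elif tpsa < solvent_rule["tpsa_low"] and hbd == 0:
            label = "CDCl3"
        else:
            label = "CD3OD"
        if label_noise > 0 and rng.random() < label_noise:
            label = SOLVENT_LABELS[int(rng.integers(len(SOLVENT_LABELS)))]
        labels.append(label)
    return labels


def generate(spec: GeneratorSpec) -> tuple[list[RawEntry], pd.DataFrame]:
    """Generate a labeled library; deterministic for a given spec.

    Returns raw entries plus a ground-truth table with one row per entry:
    entry_id, smiles, profile, core, cluster, n_substituents, edge_case
    (salt / disallowed_element / invalid_valence / none), intended_outcome
    (curation outcome the construction implies) and solvent_label.
    """
    rng = np.random.default_rng(spec.seed)
    prefix = {"np_like": "np", "drug_like": "dr", "cluster": "cl", "edge_cases": "ec"}.get(spec.profile)
    if prefix is None:
        raise ValueError(f"unknown profile {spec.profile!r}")
    if spec.core_pool is not None and len(spec.core_pool) == 0:
        raise ValueError("core pool must not be empty")

    rows = []
    if spec.profile in ("np_like", "drug_like"):
        cores = tuple(spec.core_pool) if spec.core_pool else (NP_CORES if spec.profile == "np_like" else DRUG_CORES)
        subs = tuple(spec.substituent_pool) if spec.substituent_pool else (
            NP_SUBSTITUENTS if spec.profile == "np_like" else DRUG_SUBSTITUENTS
        )
        for i in range(spec.n):
            smi, core, n_sub = _assemble(rng, cores, subs)
            rows.append(
                dict(entry_id=f"{prefix}{i:05d}", smiles=smi, profile=spec.profile, core=core,
                     cluster=None, n_substituents=n_sub, edge_case="none", intended_outcome=KEPT)
            )
    elif spec.profile == "cluster":
        cores = tuple(spec.core_pool) if spec.core_pool else CLUSTER_CORES[: spec.n_clusters]
        for i in range(spec.n):
            c = i % len(cores)
            subs = CLUSTER_SUBSTITUENTS[c % len(CLUSTER_SUBSTITUENTS)] if spec.substituent_pool is None else tuple(spec.substituent_pool)
            smi, core, n_sub = _assemble(rng, (cores[c],), subs, max_substituents=2, min_substituents=0)
            rows.append(
                dict(entry_id=f"{prefix}{i:05d}", smiles=smi, profile=spec.profile, core=core,
                     cluster=c, n_substituents=n_sub, edge_case="none", intended_outcome=KEPT)
            )
    else:  # edge_cases
        n_salt = round(spec.salt_fraction * spec.n)
        n_elem = round(spec.disallowed_element_fraction * spec.n)
        n_val = round(spec.invalid_valence_fraction * spec.n)
        kinds = (["salt"] * n_salt + ["disallowed_element"] * n_elem + ["invalid_valence"] * n_val)
        kinds += ["none"] * (spec.n - len(kinds))
        rng.shuffle(kinds)
        cores = tuple(spec.core_pool) if spec.core_pool else NP_CORES + DRUG_CORES
        subs = tuple(spec.substituent_pool) if spec.substituent_pool else NP_SUBSTITUENTS + DRUG_SUBSTITUENTS
        for i, kind in enumerate(kinds):
            base, core, n_sub = _assemble(rng, cores, subs)
            if kind == "salt":
                ion = SALT_COUNTERIONS[int(rng.integers(len(SALT_COUNTERIONS)))]
                smi, outcome = f"{base}.{ion}", KEPT
            elif kind == "disallowed_element":
                tagged = _with_disallowed_element(Chem.MolFromSmiles(base), rng)
                smi, outcome = (tagged, REMOVED_ELEMENT) if tagged else (base, KEPT)
            elif kind == "invalid_valence":
                smi, outcome, core, n_sub = _bad_valence_smiles(rng), REMOVED_VALENCE, None, 0
            else:
                smi, outcome = base, KEPT
            rows.append(
                dict(entry_id=f"{prefix}{i:05d}", smiles=smi, profile=spec.profile, core=core,
                     cluster=None, n_substituents=n_sub, edge_case=kind, intended_outcome=outcome)
            )

    truth = pd.DataFrame(rows)
    truth["solvent_label"] = assign_solvent_labels(
        truth["smiles"], spec.solvent_rule, spec.label_noise, rng
    )
    entries = [
        RawEntry(
            entry_id=r["entry_id"],
            smiles=r["smiles"],
            source_set=spec.profile,
            solvent_label=r["solvent_label"],
        )
        for r in truth.to_dict("records")
    ]
    return entries, truth


def write_raw_csv(entries: Sequence[RawEntry], path) -> None:
    pd.DataFrame(
        {
            "entry_id": [e.entry_id for e in entries],
            "smiles": [e.smiles for e in entries],
            "source_set": [e.source_set for e in entries],
            "solvent_label": [e.solvent_label or "" for e in entries],
        }
    ).to_csv(path, index=False)
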