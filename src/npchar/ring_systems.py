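"""Ring-system extraction with exocyclic double-bond protection; bioactive-ring classification.

A ring system is the cyclic fragment obtained by cleaving every acyclic
single bond of a molecule while protecting exocyclic double (and optionally
triple) bonds, then hydrogen-capping the cut sites.  Unlike a Murcko
scaffold, linkers between cyclic cores are discarded, so biphenyl yields
two (deduplicated) benzene fragments while cyclohexanone keeps its carbonyl.

Bioactivity classification over an external annotation table follows the
"Magic Rings" rules: a ring is active when active reports are at least ten
times the inactive reports (and vice versa for inactive, otherwise
intermediate), and it has a preferred target class when the top class has
at least twice the reports of the runner-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from rdkit import Chem

from .io_curation import MoleculeRecord


def extract_ring_systems(record, protect_triple_bonds: bool = False) -> set[str]:
    """Canonical, stereo-stripped ring systems of one molecule.

    Steps: mark ring atoms; protect multiple bonds from a ring atom to a
    non-ring atom (the exocyclic partner stays with the ring); cleave all
    remaining acyclic single bonds between heavy atoms; keep fragments with
    at least one ring; hydrogen-cap cut sites; canonicalize and deduplicate.
    Acyclic molecules give an empty set.
    """
    if isinstance(record, MoleculeRecord):
        mol = record.mol()
    elif isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
    else:
        mol = Chem.Mol(record)
    if mol is None:
        raise ValueError("invalid structure")
    if mol.GetRingInfo().NumRings() == 0:
        return set()

    cut_bonds = []
    for bond in mol.GetBonds():
        if bond.IsInRing():
            continue
        if bond.GetBondType() == Chem.BondType.SINGLE:
            cut_bonds.append(bond.GetIdx())
        # non-single acyclic bonds (exocyclic C=O, C=C, C#N, ...) are never
        # cut; protection is implicit in cutting single bonds only
    if not cut_bonds:
        frags = [mol]
    else:
        fragmented = Chem.FragmentOnBonds(mol, cut_bonds, addDummies=False)
        frags = list(Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=False))

    keys: set[str] = set()
    for frag in frags:
        try:
            Chem.SanitizeMol(frag)
        except Exception:
            continue
        if frag.GetRingInfo().NumRings() == 0:
            continue
        Chem.RemoveStereochemistry(frag)
        keys.add(Chem.MolToSmiles(frag))
    return keys


@dataclass
class RingSystemTable:
    dataset: str
    rows: pd.DataFrame  # columns: ring_key, count; ordered count desc, key asc

    def keys(self) -> set[str]:
        return set(self.rows["ring_key"])


def ring_system_table(records: Sequence, dataset: str = "") -> RingSystemTable:
    """Count ring systems across a library (each molecule contributes each of
    its distinct systems once)."""
    counts: dict[str, int] = {}
    for r in records:
        for key in extract_ring_systems(r):
            counts[key] = counts.get(key, 0) + 1
    rows = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["ring_key", "count"],
    )
    return RingSystemTable(dataset=dataset, rows=rows)


TARGET_NOT_KNOWN = "not-known"
MULTIPLE_TARGETS = "multiple targets"


@dataclass(frozen=True)
class RingAnnotation:
    ring_key: str
    target_reports: Mapping[str, int]  # e.g. {"GPCR": 40, "kinase": 10, ...}
    active_reports: int
    inactive_reports: int


@dataclass(frozen=True)
class RingClassification:
    ring_key: str
    bioactivity_class: str  # active | inactive | intermediate
    preferred_target: str


def classify_ring(ann: RingAnnotation) -> RingClassification:
    """Apply the 10x bioactivity rule and the 2x preferred-target rule (non-strict)."""
    act, inact = ann.active_reports, ann.inactive_reports
    if act == 0 and inact == 0:
        bio = "intermediate"
    elif act >= 10 * inact:
        bio = "active"
    elif inact >= 10 * act:
        bio = "inactive"
    else:
        bio = "intermediate"

    targets = {k: v for k, v in ann.target_reports.items() if v > 0}
    if not targets:
        preferred = TARGET_NOT_KNOWN
    else:
        ranked = sorted(targets.items(), key=lambda kv: (-kv[1], kv[0]))
        top_name, top_count = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else 0
        preferred = top_name if top_count >= 2 * runner else MULTIPLE_TARGETS
    return RingClassification(ring_key=ann.ring_key, bioactivity_class=bio, preferred_target=preferred)


def read_annotations_csv(path) -> dict[str, RingAnnotation]:
    """Annotation table CSV: ring_key, active_reports, inactive_reports, plus
    one column per target class."""
    df = pd.read_csv(path)
    fixed = {"ring_key", "active_reports", "inactive_reports"}
    target_cols = [c for c in df.columns if c not in fixed]
    out = {}
    for _, row in df.iterrows():
        out[row["ring_key"]] = RingAnnotation(
            ring_key=row["ring_key"],
            target_reports={c: int(row[c]) for c in target_cols},
            active_reports=int(row["active_reports"]),
            inactive_reports=int(row["inactive_reports"]),
        )
    return out


def magic_ring_report(
    table: RingSystemTable,
    annotations: Optional[Mapping[str, RingAnnotation]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Frequency-ranked potentially bioactive rings.

    Returns ``(classified, unannotated)``: the first frame holds annotated
    rings with bioactivity class in {active, intermediate}, ranked by library
    count; the second holds rings without an annotation.
    """
    annotations = annotations or {}
    classified_rows, unannotated_rows = [], []
    for _, row in table.rows.iterrows():
        key, count = row["ring_key"], int(row["count"])
        ann = annotations.get(key)
        if ann is None:
            unannotated_rows.append({"ring_key": key, "count": count})
            continue
        cls = classify_ring(ann)
        if cls.bioactivity_class in ("active", "intermediate"):
            classified_rows.append(
                {
                    "ring_key": key,
                    "count": count,
                    "bioactivity_class": cls.bioactivity_class,
                    "preferred_target": cls.preferred_target,
                }
            )
    cols = ["ring_key", "count", "bioactivity_class", "preferred_target"]
    classified = pd.DataFrame(classified_rows, columns=cols)
    unannotated = pd.DataFrame(unannotated_rows, columns=["ring_key", "count"])
    return classified, unannotated
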