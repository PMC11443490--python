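"""Structure curation: standardization pipeline, element/valence filtering, audit trail.

The curation protocol applies, in a fixed order: parse, structural
normalization, largest-component selection, element/valence filtering,
neutralization (uncharging), reionization, tautomer canonicalization and
canonical SMILES generation.  Entries failing any step are rejected with
the first failing step recorded; kept entries are single-component
molecules drawn from a 13-element organic subset
(H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Allowed atomic numbers: H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I
DEFAULT_ALLOWED_ELEMENTS = frozenset({1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53})

#: Fixed pipeline step order; CurationReport.steps_applied is always a prefix.
PIPELINE_STEPS = (
    "parse",
    "normalize",
    "largest_component",
    "element_filter",
    "valence_check",
    "uncharge",
    "reionize",
    "tautomer_canonicalize",
    "canonicalize",
)

KEPT = "kept"
REMOVED_ELEMENT = "removed_element"
REMOVED_VALENCE = "removed_valence"
REMOVED_PARSE_ERROR = "removed_parse_error"


@dataclass(frozen=True)
class RawEntry:
    """One as-read library entry, prior to any standardization."""

    entry_id: str
    smiles: str
    source_set: str = ""
    solvent_label: Optional[str] = None


@dataclass(frozen=True)
class MoleculeRecord:
    """A curated library entry.

    ``canonical_smiles`` keeps stereochemistry; ``achiral_key`` is the
    stereo-stripped canonical form used for unique-compound, scaffold and
    ring-system bookkeeping.
    """

    entry_id: str
    canonical_smiles: str
    achiral_key: str
    source_set: str = ""
    solvent_label: Optional[str] = None

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.canonical_smiles)


@dataclass
class CurationReport:
    entry_id: str
    outcome: str
    steps_applied: list[str] = field(default_factory=list)
    original_component_count: int = 0


@dataclass
class CurationSummary:
    initial: int = 0
    curated: int = 0
    removed_element: int = 0
    removed_valence: int = 0
    removed_parse_error: int = 0
    duplicate_achiral_keys: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


_UNCHARGER = rdMolStandardize.Uncharger()
_REIONIZER = rdMolStandardize.Reionizer()
_NORMALIZER = rdMolStandardize.Normalizer()


def _tautomer_enumerator(max_transforms: int = 1000) -> rdMolStandardize.TautomerEnumerator:
    params = rdMolStandardize.CleanupParameters()
    params.maxTransforms = max_transforms
    enumerator = rdMolStandardize.TautomerEnumerator(params)
    # stereochemistry is kept through curation
    enumerator.SetRemoveSp3Stereo(False)
    enumerator.SetRemoveBondStereo(False)
    return enumerator


_TAUTOMERIZER = _tautomer_enumerator()


def _largest_component(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Most heavy atoms; ties by larger exact mass, then smallest canonical SMILES."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        return None

    def key(m: Chem.Mol):
        m.UpdatePropertyCache(strict=False)
        heavy = m.GetNumHeavyAtoms()
        try:
            mass = Descriptors.ExactMolWt(m)
        except Exception:
            mass = 0.0
        try:
            smi = Chem.MolToSmiles(m)
        except Exception:
            smi = ""
        # smallest SMILES wins the final tie -> negate by sorting key trick
        return (heavy, mass, smi)

    scored = [(key(m), i, m) for i, m in enumerate(frags)]
    # heavy desc, mass desc, smiles asc
    scored.sort(key=lambda t: (-t[0][0], -t[0][1], t[0][2]))
    return scored[0][2]


def strip_stereo_smiles(smiles: str) -> str:
    """Canonical SMILES with all stereochemistry markers removed."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def strip_stereo(record: MoleculeRecord) -> str:
    """Achiral key of a curated record: identical for all stereoisomers of one constitution."""
    return strip_stereo_smiles(record.canonical_smiles)


def curate_entry(
    raw: RawEntry,
    allowed_elements: frozenset[int] = DEFAULT_ALLOWED_ELEMENTS,
) -> tuple[Optional[MoleculeRecord], CurationReport]:
    """Run one entry through the fixed standardization pipeline.

    Returns ``(record, report)``; ``record`` is None when the entry was
    rejected, in which case the report carries the rejection reason and the
    steps completed before failure.
    """
    report = CurationReport(entry_id=raw.entry_id, outcome=REMOVED_PARSE_ERROR)

    # parse (sanitization deferred so valence problems are classified later)
    mol = Chem.MolFromSmiles(raw.smiles, sanitize=False)
    if mol is None or mol.GetNumAtoms() == 0:
        report.outcome = REMOVED_PARSE_ERROR
        return None, report
    report.steps_applied.append("parse")
    report.original_component_count = len(Chem.GetMolFrags(mol))

    # structural normalization (functional-group normalization; dialect
    # differences in aromatic perception are unified by the final
    # canonicalization after full sanitization)
    try:
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
        mol = _NORMALIZER.normalize(mol)
    except Exception:
        # normalization only fails on chemistry-level (valence) problems
        report.outcome = REMOVED_VALENCE
        return None, report
    report.steps_applied.append("normalize")

    # largest-component selection
    mol = _largest_component(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        report.outcome = REMOVED_PARSE_ERROR
        return None, report
    report.steps_applied.append("largest_component")

    # element filter (on the parent component only)
    if any(a.GetAtomicNum() not in allowed_elements for a in mol.GetAtoms()):
        report.outcome = REMOVED_ELEMENT
        return None, report
    report.steps_applied.append("element_filter")

    # valence check: full sanitization; any failure is a valence-class removal
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        report.outcome = REMOVED_VALENCE
        return None, report
    report.steps_applied.append("valence_check")

    try:
        mol = _UNCHARGER.uncharge(mol)
        report.steps_applied.append("uncharge")
        mol = _REIONIZER.reionize(mol)
        report.steps_applied.append("reionize")
        mol = _TAUTOMERIZER.Canonicalize(mol)
        report.steps_applied.append("tautomer_canonicalize")
        canonical = Chem.MolToSmiles(mol)
        report.steps_applied.append("canonicalize")
    except Exception:
        report.outcome = REMOVED_VALENCE
        return None, report

    record = MoleculeRecord(
        entry_id=raw.entry_id,
        canonical_smiles=canonical,
        achiral_key=strip_stereo_smiles(canonical),
        source_set=raw.source_set,
        solvent_label=raw.solvent_label,
    )
    report.outcome = KEPT
    return record, report


def curate_library(
    entries: Sequence[RawEntry],
    allowed_elements: frozenset[int] = DEFAULT_ALLOWED_ELEMENTS,
) -> tuple[list[MoleculeRecord], list[CurationReport], CurationSummary]:
    """Curate a full library; duplicates (by achiral key) are flagged, not dropped."""
    records: list[MoleculeRecord] = []
    reports: list[CurationReport] = []
    summary = CurationSummary(initial=len(entries))
    seen_keys: set[str] = set()
    for raw in entries:
        rec, rep = curate_entry(raw, allowed_elements)
        reports.append(rep)
        if rec is not None:
            records.append(rec)
            summary.curated += 1
            if rec.achiral_key in seen_keys:
                summary.duplicate_achiral_keys += 1
            seen_keys.add(rec.achiral_key)
        else:
            setattr(summary, rep.outcome, getattr(summary, rep.outcome) + 1)
    return records, reports, summary


# ---------------------------------------------------------------------------
# readers / writers


def read_smi(path: str | Path, source_set: str = "") -> list[RawEntry]:
    """Whitespace-separated SMILES [id] file; missing ids are numbered."""
    entries = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            entry_id = parts[1] if len(parts) > 1 else f"mol{i}"
            entries.append(RawEntry(entry_id=entry_id, smiles=smiles, source_set=source_set))
    return entries


def read_csv(
    path: str | Path,
    smiles_col: str = "smiles",
    id_col: str = "entry_id",
    solvent_col: Optional[str] = "solvent_label",
    source_set: str = "",
) -> list[RawEntry]:
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader):
            solvent = None
            if solvent_col and solvent_col in row and row[solvent_col] not in ("", None):
                solvent = row[solvent_col]
            entries.append(
                RawEntry(
                    entry_id=row.get(id_col) or f"mol{i}",
                    smiles=row[smiles_col],
                    source_set=source_set or row.get("source_set", ""),
                    solvent_label=solvent,
                )
            )
    return entries


def read_sdf(path: str | Path, id_property: str = "_Name", source_set: str = "") -> list[RawEntry]:
    entries = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            entries.append(RawEntry(entry_id=f"mol{i}", smiles="", source_set=source_set))
            continue
        if id_property == "_Name":
            entry_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        else:
            entry_id = mol.GetProp(id_property) if mol.HasProp(id_property) else f"mol{i}"
        try:
            mol.UpdatePropertyCache(strict=False)
            smiles = Chem.MolToSmiles(mol)
        except Exception:
            smiles = ""
        entries.append(RawEntry(entry_id=entry_id or f"mol{i}", smiles=smiles, source_set=source_set))
    return entries


def read_entries(path: str | Path, fmt: str = "csv", **kwargs) -> list[RawEntry]:
    readers = {"smi": read_smi, "csv": read_csv, "sdf": read_sdf}
    if fmt not in readers:
        raise ValueError(f"unknown format {fmt!r}; expected one of {sorted(readers)}")
    return readers[fmt](path, **kwargs)


def write_curated_csv(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["entry_id", "canonical_smiles", "achiral_key", "source_set", "solvent_label"])
        for r in records:
            writer.writerow([r.entry_id, r.canonical_smiles, r.achiral_key, r.source_set, r.solvent_label or ""])


def read_curated_csv(path: str | Path) -> list[MoleculeRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                MoleculeRecord(
                    entry_id=row["entry_id"],
                    canonical_smiles=row["canonical_smiles"],
                    achiral_key=row["achiral_key"],
                    source_set=row.get("source_set", ""),
                    solvent_label=row.get("solvent_label") or None,
                )
            )
    return records


def write_report_csv(reports: Iterable[CurationReport], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["entry_id", "outcome", "steps_applied", "original_component_count"])
        for r in reports:
            writer.writerow([r.entry_id, r.outcome, "|".join(r.steps_applied), r.original_component_count])
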