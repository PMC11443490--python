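"""Bemis-Murcko scaffolds and scaffold-diversity statistics (SSE, CSR, overlap).

A scaffold is what remains after iteratively pruning all side chains:
ring systems plus the linkers connecting them, with exocyclic
double-bonded atoms retained.  Diversity over the scaffold population is
summarized by the scaled Shannon entropy of the top-N most frequent
scaffolds (0 = one scaffold dominates completely, 1 = uniform spread) and
by the cyclic-system-retrieval (CSR) curve: the cumulative fraction of
cyclic compounds recovered as scaffolds are consumed in decreasing
frequency order (higher area = less diverse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .io_curation import MoleculeRecord


def murcko_scaffold(record) -> str:
    """Canonical, stereo-stripped Bemis-Murcko scaffold; empty string for acyclic molecules."""
    if isinstance(record, MoleculeRecord):
        mol = record.mol()
    elif isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
    else:
        mol = record
    if mol is None:
        raise ValueError("invalid structure")
    if Chem.rdMolDescriptors.CalcNumRings(mol) == 0:
        return ""
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    Chem.RemoveStereochemistry(scaffold)
    return Chem.MolToSmiles(scaffold)


@dataclass
class ScaffoldTable:
    dataset: str
    rows: pd.DataFrame  # columns: scaffold_key, count; ordered count desc, key asc
    n_acyclic: int

    @property
    def n_compounds_cyclic(self) -> int:
        return int(self.rows["count"].sum()) if len(self.rows) else 0

    @property
    def n_scaffolds(self) -> int:
        return len(self.rows)

    def keys(self) -> set[str]:
        return set(self.rows["scaffold_key"])


def scaffold_table(records: Sequence, dataset: str = "") -> ScaffoldTable:
    counts: dict[str, int] = {}
    n_acyclic = 0
    for r in records:
        key = murcko_scaffold(r)
        if key == "":
            n_acyclic += 1
        else:
            counts[key] = counts.get(key, 0) + 1
    rows = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["scaffold_key", "count"],
    )
    return ScaffoldTable(dataset=dataset, rows=rows, n_acyclic=n_acyclic)


def table_from_counts(counts: Mapping[str, int], dataset: str = "", n_acyclic: int = 0) -> ScaffoldTable:
    rows = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["scaffold_key", "count"],
    )
    return ScaffoldTable(dataset=dataset, rows=rows, n_acyclic=n_acyclic)


@dataclass
class SSEResult:
    top_n: int
    entropy_bits: float
    sse: float
    ranked_scaffolds: list[tuple[str, int]]


def scaled_shannon_entropy(table: ScaffoldTable, top_n: int = 15) -> SSEResult:
    """Scaled Shannon entropy over the ``top_n`` most frequent scaffolds.

    Probabilities renormalize over the top-N counts only; SSE = H / log2(N),
    with N reduced to the number of available scaffolds when fewer exist.
    A single-scaffold table has SSE 0 by definition.
    """
    if table.n_scaffolds == 0:
        raise ValueError("scaffold table is empty")
    top = table.rows.head(top_n)  # rows already ordered (count desc, key asc)
    n_eff = len(top)
    counts = top["count"].to_numpy(dtype=float)
    total = counts.sum()
    probs = counts / total
    entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    sse = 0.0 if n_eff <= 1 else entropy / math.log2(n_eff)
    return SSEResult(
        top_n=n_eff,
        entropy_bits=entropy,
        sse=sse,
        ranked_scaffolds=list(zip(top["scaffold_key"], top["count"])),
    )


@dataclass
class CSRCurve:
    points: pd.DataFrame  # columns: fraction_of_scaffolds, fraction_of_compounds
    auc: float


def csr_curve(table: ScaffoldTable) -> CSRCurve:
    """Cyclic-system-retrieval curve; higher area under it means less diversity."""
    if table.n_scaffolds == 0:
        raise ValueError("scaffold table is empty")
    counts = table.rows["count"].to_numpy(dtype=float)
    n_sc = len(counts)
    total = counts.sum()
    xs = [(k + 1) / n_sc for k in range(n_sc)]
    ys = list(counts.cumsum() / total)
    # trapezoid from the origin through the ordered points
    auc = 0.0
    prev_x, prev_y = 0.0, 0.0
    for x, y in zip(xs, ys):
        auc += (x - prev_x) * (y + prev_y) / 2
        prev_x, prev_y = x, y
    return CSRCurve(
        points=pd.DataFrame({"fraction_of_scaffolds": xs, "fraction_of_compounds": ys}),
        auc=auc,
    )


def overlap(key_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Venn-style exclusive/shared counts over named key sets.

    Works for scaffold keys, achiral compound keys, ring keys or fragment
    keys alike.  Returns one row per non-empty subset of datasets with the
    count of keys present in exactly that subset.
    """
    if len(key_sets) < 2:
        raise ValueError("overlap requires at least 2 key sets")
    names = sorted(key_sets)
    rows = []
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            inside = set.intersection(*(key_sets[n] for n in subset))
            outside = set.union(*(key_sets[n] for n in names if n not in subset)) if len(subset) < len(names) else set()
            rows.append({"datasets": "&".join(subset), "n_exact": len(inside - outside)})
    return pd.DataFrame(rows)


def overlap_tables(tables: Sequence[ScaffoldTable]) -> pd.DataFrame:
    return overlap({t.dataset or f"set{i}": t.keys() for i, t in enumerate(tables)})


def write_scaffold_csv(table: ScaffoldTable, path) -> None:
    df = table.rows.copy()
    total = df["count"].sum()
    df["fraction"] = df["count"] / total if total else 0.0
    df.to_csv(path, index=False)
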