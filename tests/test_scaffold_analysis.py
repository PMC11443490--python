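"""Murcko scaffolds, SSE, CSR curves and overlap statistics."""

import math

import numpy as np
import pytest
from rdkit import Chem

from npchar import scaffold_analysis as sa
from npchar import synthetic_library as sl
from npchar.io_curation import curate_library


def _pruning_oracle(smiles: str) -> str:
    """Exhaustively prune terminal atoms that are not ring atoms and not
    double/triple-bonded to a retained atom, until fixpoint."""
    mol = Chem.MolFromSmiles(smiles)
    if Chem.rdMolDescriptors.CalcNumRings(mol) == 0:
        return ""
    em = Chem.RWMol(mol)
    changed = True
    while changed:
        changed = False
        for atom in list(em.GetAtoms()):
            if atom.GetDegree() == 1 and not atom.IsInRing():
                bond = atom.GetBonds()[0]
                if bond.GetBondType() == Chem.BondType.SINGLE:
                    em.RemoveAtom(atom.GetIdx())
                    changed = True
                    break
    out = em.GetMol()
    Chem.SanitizeMol(out)
    Chem.RemoveStereochemistry(out)
    return Chem.MolToSmiles(out)


@pytest.mark.parametrize(
    "smiles",
    [
        "Cc1ccccc1",  # toluene -> benzene
        "c1ccccc1CCc1ccccc1",  # linker retained
        "O=C1CCCCC1C",  # exocyclic C=O retained, methyl pruned
        "CCCCCC",  # acyclic -> empty
        "OCC1OC(O)C(O)C(O)C1O",
        "Cc1ccc(C(=O)NCCN2CCCC2)cc1",
    ],
)
def test_scaffold_matches_pruning_oracle(smiles):
    assert sa.murcko_scaffold(smiles) == _pruning_oracle(smiles)


def test_known_scaffolds():
    assert sa.murcko_scaffold("Cc1ccccc1") == "c1ccccc1"
    assert sa.murcko_scaffold("CCCCCC") == ""
    diphenylethane = sa.murcko_scaffold("c1ccccc1CCc1ccccc1")
    mol = Chem.MolFromSmiles(diphenylethane)
    assert mol.GetNumAtoms() == 14  # both rings plus the 2-carbon linker


def test_scaffold_idempotent():
    for smi in ["Cc1ccccc1", "O=C1CC(c2ccccc2)Oc2ccccc21", "CC1CCC2CCCCC2C1"]:
        scaffold = sa.murcko_scaffold(smi)
        assert sa.murcko_scaffold(scaffold) == scaffold


def test_scaffold_stereo_stripped():
    key = sa.murcko_scaffold("C[C@H]1CC[C@@H](O)CC1")
    assert "@" not in key


def test_scaffold_table_counts():
    records = ["Cc1ccccc1", "CCc1ccccc1", "c1ccccc1", "CCCCCC"]
    table = sa.scaffold_table(records)
    assert table.n_scaffolds == 1
    assert table.rows.iloc[0]["count"] == 3
    assert table.n_acyclic == 1
    assert table.n_compounds_cyclic + table.n_acyclic == len(records)


def test_scaffold_table_empty():
    table = sa.scaffold_table([])
    assert table.n_scaffolds == 0 and table.n_acyclic == 0


def test_scaffold_keys_subset_of_generator_cores():
    entries, truth = sl.generate(sl.GeneratorSpec("np_like", n=80, seed=13))
    records, _, _ = curate_library(entries)
    core_scaffolds = {sa.murcko_scaffold(c) for c in sl.NP_CORES}
    table = sa.scaffold_table(records)
    assert table.keys() <= core_scaffolds


def test_sse_uniform_is_one():
    table = sa.table_from_counts({f"s{i}": 7 for i in range(15)})
    assert sa.scaled_shannon_entropy(table, top_n=15).sse == pytest.approx(1.0)


def test_sse_single_scaffold_is_zero():
    table = sa.table_from_counts({"only": 100})
    assert sa.scaled_shannon_entropy(table, top_n=15).sse == 0.0


def test_sse_brute_force_formula():
    counts = {"a": 8, "b": 4, "c": 2, "d": 1, "e": 1}
    result = sa.scaled_shannon_entropy(sa.table_from_counts(counts), top_n=5)
    probs = [c / 16 for c in counts.values()]
    expected_entropy = -sum(p * math.log2(p) for p in probs)
    assert result.entropy_bits == pytest.approx(expected_entropy)
    assert result.sse == pytest.approx(expected_entropy / math.log2(5))


def test_sse_renormalizes_over_top_n_only():
    counts = {f"s{i}": 10 for i in range(15)}
    counts["tail"] = 1  # 16th scaffold must not affect the top-15 SSE
    res = sa.scaled_shannon_entropy(sa.table_from_counts(counts), top_n=15)
    assert res.sse == pytest.approx(1.0)


def test_sse_majorization_monotonicity():
    """Moving a unit of count from a larger to a smaller bin (more uniform)
    never decreases SSE."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        counts = rng.integers(1, 100, size=8)
        i, j = int(np.argmax(counts)), int(np.argmin(counts))
        if counts[i] - counts[j] < 2:
            continue
        flatter = counts.copy()
        flatter[i] -= 1
        flatter[j] += 1
        t1 = sa.table_from_counts({f"s{k}": int(c) for k, c in enumerate(counts)})
        t2 = sa.table_from_counts({f"s{k}": int(c) for k, c in enumerate(flatter)})
        sse1 = sa.scaled_shannon_entropy(t1, top_n=8).sse
        sse2 = sa.scaled_shannon_entropy(t2, top_n=8).sse
        assert sse2 >= sse1 - 1e-12


def test_csr_hand_computed():
    curve = sa.csr_curve(sa.table_from_counts({"a": 3, "b": 1}))
    pts = list(curve.points.itertuples(index=False, name=None))
    assert pts == [(0.5, 0.75), (1.0, 1.0)]


def test_csr_uniform_is_diagonal():
    table = sa.table_from_counts({f"s{i}": 1 for i in range(50)})
    curve = sa.csr_curve(table)
    assert curve.auc == pytest.approx(0.5, abs=0.02)


def test_csr_single_scaffold():
    curve = sa.csr_curve(sa.table_from_counts({"a": 10}))
    pts = list(curve.points.itertuples(index=False, name=None))
    assert pts == [(1.0, 1.0)]


def test_csr_monotone_and_auc_at_least_uniform():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(2, 30))
        counts = {f"s{i}": int(c) for i, c in enumerate(rng.integers(1, 50, size=n))}
        curve = sa.csr_curve(sa.table_from_counts(counts))
        y = curve.points["fraction_of_compounds"].to_numpy()
        assert np.all(np.diff(y) >= 0) and y[-1] == pytest.approx(1.0)
        uniform = sa.csr_curve(sa.table_from_counts({f"s{i}": 1 for i in range(n)}))
        assert curve.auc >= uniform.auc - 1e-12


def test_overlap_hand_cases():
    df = sa.overlap({"A": {"a", "b"}, "B": {"b", "c"}})
    by = dict(zip(df["datasets"], df["n_exact"]))
    assert by == {"A": 1, "B": 1, "A&B": 1}

    df = sa.overlap({"A": {"x", "y"}, "B": {"x", "y"}})
    by = dict(zip(df["datasets"], df["n_exact"]))
    assert by == {"A": 0, "B": 0, "A&B": 2}


def test_overlap_requires_two():
    with pytest.raises(ValueError):
        sa.overlap({"A": {"x"}})


def test_overlap_three_sets_partition():
    rng = np.random.default_rng(1)
    universe = [f"k{i}" for i in range(60)]
    sets = {name: {k for k in universe if rng.random() < 0.5} for name in "ABC"}
    df = sa.overlap(sets)
    assert df["n_exact"].sum() == len(set.union(*sets.values()))
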