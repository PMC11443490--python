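"""Fingerprints (MACCS, ECFP4/6, MinHashed atom pairs) and sampled Tanimoto diversity profiles.

Library diversity is profiled by pooling pairwise Tanimoto similarities over
repeated random samples (default five samples of 1000 compounds each) and
summarizing the pooled distribution as a cumulative curve: the further left
the curve (lower similarities), the more diverse the library.

The MinHashed atom-pair fingerprint is implemented at the shingle level:
each unordered heavy-atom pair contributes shingles combining the two atoms'
circular environments (radius 1 and 2) with their topological distance,
and the shingle set is MinHashed to 2048 components; Tanimoto on this kind
is the fraction of equal components, an unbiased Jaccard estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors

from ._environments import atom_environment, environment_hash
from .io_curation import MoleculeRecord

FP_KINDS = ("maccs", "ecfp4", "ecfp6", "map4")
#: conventional public bit/component counts per kind
FP_LENGTHS = {"maccs": 166, "ecfp4": 1024, "ecfp6": 1024, "map4": 2048}

_MORGAN2 = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
_MORGAN3 = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=1024)

# MinHash universal-hash family h_i(x) = (a_i x + b_i) mod p with p = 2^31-1;
# parameters are fixed (internal seed) so fingerprints depend on structure only.
_MINHASH_P = np.uint64(2**31 - 1)
_N_MINHASH = 2048
_rng = np.random.default_rng(0xC0FFEE)
_MINHASH_A = _rng.integers(1, int(_MINHASH_P), size=_N_MINHASH, dtype=np.uint64)
_MINHASH_B = _rng.integers(0, int(_MINHASH_P), size=_N_MINHASH, dtype=np.uint64)
del _rng


def _as_mol(record) -> Chem.Mol:
    if isinstance(record, MoleculeRecord):
        return record.mol()
    if isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
        if mol is None:
            raise ValueError(f"cannot parse {record!r}")
        return mol
    return record


def _atom_environments(mol: Chem.Mol, max_radius: int = 2) -> dict[int, dict[int, int]]:
    """atom index -> {radius: environment hash}; environments come from the
    shared rooted-fragment representation so symmetric atoms are never pruned."""
    envs: dict[int, dict[int, int]] = {}
    for idx in range(mol.GetNumAtoms()):
        envs[idx] = {
            r: environment_hash(atom_environment(mol, idx, r)) for r in range(1, max_radius + 1)
        }
    return envs


def atom_pair_shingles(mol: Chem.Mol, max_radius: int = 2) -> set[int]:
    """Integer shingles: (env_i_r, topological distance, env_j_r) for every
    unordered heavy-atom pair and every radius r <= max_radius present at both ends."""
    envs = _atom_environments(mol, max_radius)
    n = mol.GetNumAtoms()
    if n == 1:
        only = envs[0]
        return {_mix3(h, 0, h) for h in only.values()}
    dm = Chem.GetDistanceMatrix(mol)
    shingles: set[int] = set()
    for i in range(n):
        for j in range(i + 1, n):
            dist = int(dm[i, j])
            for r in range(1, max_radius + 1):
                hi, hj = envs[i].get(r), envs[j].get(r)
                if hi is None or hj is None:
                    continue
                a, b = (hi, hj) if hi <= hj else (hj, hi)
                shingles.add(_mix3(a, dist, b))
    if not shingles:  # single-environment degenerate molecules (e.g. methane)
        for d in envs.values():
            for h in d.values():
                shingles.add(_mix3(h, 0, h))
    return shingles


def _mix3(a: int, b: int, c: int) -> int:
    """Deterministic 64-bit mix of a shingle triple (splitmix-style)."""
    x = (a * 0x9E3779B97F4A7C15 + b * 0xBF58476D1CE4E5B9 + c * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    x ^= x >> 30
    x = (x * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x ^= x >> 27
    return x


def minhash(shingles: set[int]) -> np.ndarray:
    """2048-component MinHash signature of an integer shingle set."""
    if not shingles:
        return np.full(_N_MINHASH, int(_MINHASH_P), dtype=np.uint64)
    x = np.fromiter(shingles, dtype=np.uint64) % _MINHASH_P
    # (a_i * x + b_i) mod p, minimized over shingles; a*x < 2^62 fits uint64
    vals = (_MINHASH_A[:, None] * x[None, :] + _MINHASH_B[:, None]) % _MINHASH_P
    return vals.min(axis=1)


def fingerprint(record, kind: str):
    """Fingerprint one molecule.  Binary kinds return RDKit bit vectors;
    ``map4`` returns a uint64 MinHash signature array."""
    if kind not in FP_KINDS:
        raise ValueError(f"unknown fingerprint kind {kind!r}; expected one of {FP_KINDS}")
    mol = _as_mol(record)
    if kind == "maccs":
        return rdMolDescriptors.GetMACCSKeysFingerprint(mol)
    if kind == "ecfp4":
        return _MORGAN2.GetFingerprint(mol)
    if kind == "ecfp6":
        return _MORGAN3.GetFingerprint(mol)
    return minhash(atom_pair_shingles(mol))


def fingerprint_library(records: Sequence, kind: str) -> list:
    return [fingerprint(r, kind) for r in records]


def tanimoto(a, b, kind: str) -> float:
    """Tanimoto similarity for binary kinds; MinHash Jaccard estimate for map4."""
    if kind == "map4":
        a = np.asarray(a)
        b = np.asarray(b)
        if a.shape != b.shape:
            raise ValueError("MinHash signature length mismatch")
        return float(np.mean(a == b))
    if not isinstance(a, type(b)) or len(a) != len(b):
        raise ValueError("fingerprint kind/length mismatch")
    return float(DataStructs.TanimotoSimilarity(a, b))


def _pairwise_binary(fps: list) -> np.ndarray:
    sims = []
    for i in range(1, len(fps)):
        sims.append(DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i]))
    return np.concatenate(sims) if sims else np.empty(0)


def _pairwise_minhash(fps: list[np.ndarray], block: int = 128) -> np.ndarray:
    mat = np.stack(fps)  # (n, 2048)
    n = mat.shape[0]
    out = []
    for start in range(0, n, block):
        chunk = mat[start : start + block]  # (b, k)
        # similarities of chunk rows against all later rows
        for local_i in range(chunk.shape[0]):
            i = start + local_i
            if i + 1 >= n:
                continue
            eq = (mat[i + 1 :] == mat[i]).mean(axis=1)
            out.append(eq)
    return np.concatenate(out) if out else np.empty(0)


@dataclass
class DiversityProfile:
    dataset: str
    fp_kind: str
    n_samples: int
    sample_size: int
    seed: int
    similarities: np.ndarray  # pooled, ascending
    mean: float
    median: float

    def cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted similarity, cumulative fraction) pairs of the pooled distribution."""
        n = len(self.similarities)
        return self.similarities, np.arange(1, n + 1) / n


def diversity_profile(
    records: Sequence,
    kind: str,
    n_samples: int = 5,
    sample_size: int = 1000,
    seed: int = 0,
    dataset: str = "",
) -> DiversityProfile:
    """Pooled pairwise-similarity profile over repeated random samples.

    When the library has at most ``sample_size`` molecules all pairs are
    computed exactly once; otherwise ``n_samples`` independent samples are
    drawn without replacement (overlap across samples allowed) and their
    pairwise similarities pooled.
    """
    n = len(records)
    if n < 2:
        raise ValueError("diversity profile requires at least 2 records")
    fps = fingerprint_library(records, kind)
    rng = np.random.default_rng(seed)
    pairwise = _pairwise_minhash if kind == "map4" else _pairwise_binary
    if n <= sample_size:
        n_samples = 1
        pooled = pairwise(fps)
    else:
        chunks = []
        for _ in range(n_samples):
            idx = rng.choice(n, size=sample_size, replace=False)
            chunks.append(pairwise([fps[i] for i in idx]))
        pooled = np.concatenate(chunks)
    pooled = np.sort(pooled)
    return DiversityProfile(
        dataset=dataset,
        fp_kind=kind,
        n_samples=n_samples,
        sample_size=min(sample_size, n),
        seed=seed,
        similarities=pooled,
        mean=float(pooled.mean()),
        median=float(np.median(pooled)),
    )


def profile_to_frame(profile: DiversityProfile, max_points: int = 2000):
    """Down-sampled (similarity, cdf) table for plotting/export."""
    import pandas as pd

    sims, cdf = profile.cdf()
    if len(sims) > max_points:
        idx = np.linspace(0, len(sims) - 1, max_points).astype(int)
        sims, cdf = sims[idx], cdf[idx]
    return pd.DataFrame({"similarity": sims, "cdf": cdf})


def fingerprints_to_hex(fps: Iterable, kind: str) -> list[str]:
    if kind == "map4":
        return [np.asarray(fp).astype(np.uint64).tobytes().hex() for fp in fps]
    return [DataStructs.BitVectToBinaryText(fp).hex() for fp in fps]
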