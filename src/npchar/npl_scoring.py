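"""Natural-product-likeness scoring from fragment (atom-environment) frequencies.

The scorer is a Bayesian-flavored log-ratio model: circular atom
environments (radius 2 by default) are counted in a natural-product corpus
and a synthetic-molecule corpus, and each environment f receives a
contribution

    c(f) = log10( (n_NP(f) + k) / N_NP  /  ((n_SYN(f) + k) / N_SYN) )

with pseudocount k.  A molecule's raw score is the mean contribution of its
heavy atoms' environments (unseen environments contribute 0); raw scores are
affinely calibrated so the pooled training scores' 1st/99th percentiles map
to -5/+5 and then clamped to [-5, 5], the conventional reporting range
(-5 = probably synthetic, +5 = natural-product-like).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from ._environments import molecule_environments as _atom_envs
from .io_curation import MoleculeRecord

SCORE_MIN, SCORE_MAX = -5.0, 5.0


def _as_mol(record) -> Chem.Mol:
    if isinstance(record, MoleculeRecord):
        return record.mol()
    if isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
        if mol is None:
            raise ValueError(f"cannot parse {record!r}")
        return mol
    return record


def molecule_environments(mol: Chem.Mol, radius: int) -> list[str]:
    """One circular-environment key per heavy atom (largest neighborhood
    within ``radius`` bonds; never deduplicated across symmetric atoms)."""
    return _atom_envs(mol, radius)


@dataclass
class NPLModel:
    radius: int
    smoothing: float
    contributions: dict[str, float]
    calibration_scale: float
    calibration_offset: float
    trained_on: dict  # {"np": n, "syn": n}

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": 1,
            "radius": self.radius,
            "smoothing": self.smoothing,
            "calibration_scale": self.calibration_scale,
            "calibration_offset": self.calibration_offset,
            "trained_on": self.trained_on,
            "contributions": dict(self.contributions),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "NPLModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            radius=payload["radius"],
            smoothing=payload["smoothing"],
            contributions=dict(payload["contributions"]),
            calibration_scale=payload["calibration_scale"],
            calibration_offset=payload["calibration_offset"],
            trained_on=payload["trained_on"],
        )


@dataclass(frozen=True)
class NPLScore:
    raw: float
    clamped: float


def _corpus_counts(records: Sequence, radius: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    total = 0
    for r in records:
        for env in molecule_environments(_as_mol(r), radius):
            counts[env] = counts.get(env, 0) + 1
            total += 1
    return counts, total


def _raw_score(model_contribs: dict[str, float], mol: Chem.Mol, radius: int) -> float:
    envs = molecule_environments(mol, radius)
    if not envs:
        return 0.0
    return sum(model_contribs.get(e, 0.0) for e in envs) / len(envs)


def train_npl(
    np_corpus: Sequence,
    syn_corpus: Sequence,
    radius: int = 2,
    k: float = 1.0,
) -> NPLModel:
    """Fit contribution and calibration parameters from two labeled corpora."""
    if len(np_corpus) == 0 or len(syn_corpus) == 0:
        raise ValueError("both training corpora must be non-empty")
    np_counts, n_np = _corpus_counts(np_corpus, radius)
    syn_counts, n_syn = _corpus_counts(syn_corpus, radius)
    contribs: dict[str, float] = {}
    for env in set(np_counts) | set(syn_counts):
        p_np = (np_counts.get(env, 0) + k) / n_np
        p_syn = (syn_counts.get(env, 0) + k) / n_syn
        contribs[env] = float(np.log10(p_np / p_syn))

    train_raw = [
        _raw_score(contribs, _as_mol(r), radius) for r in list(np_corpus) + list(syn_corpus)
    ]
    lo, hi = np.percentile(train_raw, [1, 99])
    if hi > lo:
        scale = (SCORE_MAX - SCORE_MIN) / (hi - lo)
        offset = SCORE_MIN - lo * scale
    else:  # degenerate training distribution (e.g. identical corpora)
        scale, offset = 1.0, 0.0
    return NPLModel(
        radius=radius,
        smoothing=k,
        contributions=contribs,
        calibration_scale=float(scale),
        calibration_offset=float(offset),
        trained_on={"np": len(np_corpus), "syn": len(syn_corpus)},
    )


def score_molecule(model: NPLModel, record) -> NPLScore:
    mol = _as_mol(record)
    raw = _raw_score(model.contributions, mol, model.radius)
    calibrated = raw * model.calibration_scale + model.calibration_offset
    return NPLScore(raw=calibrated, clamped=float(min(SCORE_MAX, max(SCORE_MIN, calibrated))))


def score_library(model: NPLModel, records: Sequence) -> tuple[list[NPLScore], dict]:
    """Per-record scores plus a distribution summary (mean/median/sd of clamped scores)."""
    if len(records) == 0:
        raise ValueError("cannot score an empty library")
    scores = [score_molecule(model, r) for r in records]
    clamped = np.array([s.clamped for s in scores])
    summary = {
        "mean": float(clamped.mean()),
        "median": float(np.median(clamped)),
        "sd": float(clamped.std(ddof=1)) if len(clamped) > 1 else 0.0,
        "n": len(clamped),
    }
    return scores, summary


def write_scores_csv(records: Sequence[MoleculeRecord], scores: Sequence[NPLScore], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["entry_id", "raw", "clamped"])
        for r, s in zip(records, scores):
            writer.writerow([r.entry_id, f"{s.raw:.6f}", f"{s.clamped:.6f}"])
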