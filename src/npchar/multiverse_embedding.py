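"""Chemical-multiverse views: property-space PCA and fingerprint-space t-SNE.

The same pooled set of libraries is projected into two complementary 2-D
chemical spaces: a PCA over six pharmacologically central descriptors
(HBA, HBD, MW, TPSA, RB, logP) after z-score standardization, and a t-SNE
over binary 1024-bit circular fingerprints (perplexity 30, 5000 iterations
by default).  Standardization and both fits use the pooled records of all
datasets so panels share one coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.preprocessing import StandardScaler

from .descriptor_panel import DescriptorVector

PCA_DESCRIPTORS = ("HBA", "HBD", "MW", "TPSA", "RB", "logP")


@dataclass
class EmbeddingResult:
    view: str  # pca_properties | tsne_fingerprints
    coords: pd.DataFrame  # entry_id, dataset, x, y
    explained_variance: Optional[np.ndarray] = None
    loadings: Optional[pd.DataFrame] = None
    params: dict = field(default_factory=dict)


def pca_view(
    vectors: Sequence[DescriptorVector],
    datasets: Sequence[str],
    entry_ids: Optional[Sequence[str]] = None,
) -> EmbeddingResult:
    """First two principal components of the standardized six-descriptor space.

    Component signs are fixed by making each loading vector's
    largest-magnitude element positive, so the view is fully deterministic.
    Zero-variance descriptors across the pool are dropped with a warning.
    """
    if len(vectors) < 3:
        raise ValueError("PCA view requires at least 3 records")
    if entry_ids is None:
        entry_ids = [str(i) for i in range(len(vectors))]
    X = np.array([[getattr(v, name) for name in PCA_DESCRIPTORS] for v in vectors], dtype=float)
    # tolerance-based: a numerically constant column is zero-variance
    keep = X.std(axis=0) > 1e-10 * np.maximum(1.0, np.abs(X).max(axis=0))
    names = [n for n, k in zip(PCA_DESCRIPTORS, keep) if k]
    if not all(keep):
        dropped = [n for n, k in zip(PCA_DESCRIPTORS, keep) if not k]
        warnings.warn(f"zero-variance descriptors dropped from PCA: {dropped}")
    X = X[:, keep]
    Z = StandardScaler().fit_transform(X)
    pca = PCA(n_components=2)
    scores = pca.fit_transform(Z)
    components = pca.components_.copy()
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
            scores[:, i] = -scores[:, i]
    coords = pd.DataFrame(
        {"entry_id": list(entry_ids), "dataset": list(datasets), "x": scores[:, 0], "y": scores[:, 1]}
    )
    loadings = pd.DataFrame(components.T, index=names, columns=["PC1", "PC2"])
    return EmbeddingResult(
        view="pca_properties",
        coords=coords,
        explained_variance=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        params={"descriptors": names},
    )


def tsne_view(
    fingerprints: Sequence,
    datasets: Sequence[str],
    entry_ids: Optional[Sequence[str]] = None,
    perplexity: float = 30.0,
    iterations: int = 5000,
    seed: int = 0,
) -> EmbeddingResult:
    """Seeded 2-D t-SNE of binary fingerprints (Euclidean on 0/1 vectors)."""
    n = len(fingerprints)
    if n <= perplexity:
        raise ValueError(
            f"t-SNE with perplexity {perplexity} needs more than {int(perplexity)} records "
            f"(got {n}); reduce the perplexity"
        )
    if entry_ids is None:
        entry_ids = [str(i) for i in range(n)]
    # rdkit bit vectors and plain arrays both support the sequence protocol
    X = np.array([np.asarray(fp, dtype=float) for fp in fingerprints])
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=iterations,
        random_state=seed,
        init="pca",
    )
    emb = tsne.fit_transform(X)
    coords = pd.DataFrame(
        {"entry_id": list(entry_ids), "dataset": list(datasets), "x": emb[:, 0], "y": emb[:, 1]}
    )
    return EmbeddingResult(
        view="tsne_fingerprints",
        coords=coords,
        params={"perplexity": perplexity, "iterations": iterations, "seed": seed},
    )


def write_coords_csv(result: EmbeddingResult, path) -> None:
    df = result.coords.copy()
    df.insert(2, "view", result.view)
    df.to_csv(path, index=False)
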