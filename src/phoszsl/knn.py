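"""Training-free zero-shot k-NN classifier.

For a test phosphosite the k most similar training (site, kinase) pairs are
located in the phosphosite representation space.  A vote over the
neighbours' light-kinase labels picks the most common light kinase; when no
label strictly beats all others, the nearest neighbour's label is used.
The prediction scores for the dark (unseen) kinases are then the cosine
similarities between the chosen light kinase's embedding and each dark
kinase's embedding, i.e. the classifier transfers the light-kinase vote to
the closest dark classes.

The neighbour universe is the list of training pairs (not unique sites), so
a multilabel training site contributes one neighbour per kinase label.
Distance ties at the k-th neighbour are broken by pair index to keep runs
reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataset import AssociationTable, PhoszslError
from .encoders import EmbeddingStore
from .evaluation import ScoreMatrix


class KnnError(PhoszslError):
    """Invalid k-NN configuration or degenerate geometry."""


@dataclass(frozen=True)
class KnnConfig:
    """Neighbourhood size and site-space metric.

    ``k`` is the only real hyperparameter (chosen on validation macro AP,
    conventionally from {3, 5, 7}); ``site_metric`` selects how training
    sites are ranked by similarity to the query.
    """

    k: int = 3
    site_metric: str = "cosine"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise KnnError("k must be >= 1")
        if self.site_metric not in ("cosine", "euclidean"):
            raise KnnError(f"unknown site metric {self.site_metric!r}")


def _unit_rows(matrix: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1)
    if np.any(norms == 0):
        raise KnnError(f"zero-norm vector among {what}; cosine undefined")
    return matrix / norms[:, None]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise KnnError("zero-norm vector; cosine undefined")
    return float(np.dot(a, b) / (na * nb))


def _neighbour_order(
    site_vec: np.ndarray, train_matrix: np.ndarray, metric: str
) -> np.ndarray:
    """Indices of training pairs from most to least similar (stable ties)."""
    if metric == "cosine":
        norm = np.linalg.norm(site_vec)
        if norm == 0:
            raise KnnError("zero-norm query vector; cosine undefined")
        sims = _unit_rows(train_matrix, "training sites") @ (site_vec / norm)
        return np.argsort(-sims, kind="stable")
    dists = np.linalg.norm(train_matrix - site_vec, axis=1)
    return np.argsort(dists, kind="stable")


def _vote(neighbour_labels: Sequence[str]) -> str:
    """Most common label; plurality ties fall back to the nearest neighbour."""
    counts = Counter(neighbour_labels)
    best = max(counts.values())
    winners = [label for label, c in counts.items() if c == best]
    if len(winners) == 1:
        return winners[0]
    return neighbour_labels[0]


def knn_scores(
    site_vec: np.ndarray,
    train_pairs: Sequence[tuple[str, str]] | AssociationTable,
    site_store: EmbeddingStore,
    kinase_store: EmbeddingStore,
    dark_ids: Sequence[str],
    config: KnnConfig = KnnConfig(),
) -> np.ndarray:
    """Score every dark kinase for one test site.

    Returns cosine similarities between the voted light kinase's embedding
    and each dark kinase's embedding, aligned with ``dark_ids``.
    """
    pairs = list(train_pairs)
    if config.k > len(pairs):
        raise KnnError(f"k={config.k} exceeds {len(pairs)} training pairs")
    light_ids = {kid for _, kid in pairs}
    clash = light_ids & set(dark_ids)
    if clash:
        raise KnnError(f"dark kinases appear among training labels: {sorted(clash)[:5]}")
    train_matrix = site_store.matrix([s for s, _ in pairs])
    order = _neighbour_order(np.asarray(site_vec, dtype=float), train_matrix,
                             config.site_metric)
    neighbour_labels = [pairs[i][1] for i in order[: config.k]]
    light = _vote(neighbour_labels)
    phi_light = kinase_store.vectors[light]
    return np.array(
        [cosine_similarity(phi_light, kinase_store.vectors[d]) for d in dark_ids]
    )


def knn_predict_all(
    test_site_ids: Sequence[str],
    train_pairs: Sequence[tuple[str, str]] | AssociationTable,
    site_store: EmbeddingStore,
    kinase_store: EmbeddingStore,
    dark_ids: Sequence[str],
    config: KnnConfig = KnnConfig(),
) -> ScoreMatrix:
    """Score matrix (test sites x dark kinases) for the evaluation suite."""
    pairs = list(train_pairs)
    if config.k > len(pairs):
        raise KnnError(f"k={config.k} exceeds {len(pairs)} training pairs")
    light_ids = {kid for _, kid in pairs}
    clash = light_ids & set(dark_ids)
    if clash:
        raise KnnError(f"dark kinases appear among training labels: {sorted(clash)[:5]}")
    train_matrix = site_store.matrix([s for s, _ in pairs])
    dark_matrix = _unit_rows(kinase_store.matrix(list(dark_ids)), "dark kinases")
    if config.site_metric == "cosine":
        train_unit = _unit_rows(train_matrix, "training sites")
    rows = np.empty((len(test_site_ids), len(dark_ids)))
    light_cache: dict[str, np.ndarray] = {}
    for i, site_id in enumerate(test_site_ids):
        query = site_store.vectors[site_id]
        if config.site_metric == "cosine":
            norm = np.linalg.norm(query)
            if norm == 0:
                raise KnnError(f"zero-norm query vector for site {site_id!r}")
            order = np.argsort(-(train_unit @ (query / norm)), kind="stable")
        else:
            order = np.argsort(
                np.linalg.norm(train_matrix - query, axis=1), kind="stable"
            )
        light = _vote([pairs[j][1] for j in order[: config.k]])
        if light not in light_cache:
            phi = kinase_store.vectors[light]
            norm = np.linalg.norm(phi)
            if norm == 0:
                raise KnnError(f"zero-norm embedding for kinase {light!r}")
            light_cache[light] = phi / norm
        rows[i] = dark_matrix @ light_cache[light]
    return ScoreMatrix(rows, list(test_site_ids), list(dark_ids))


def select_k(validation_macro_ap: Mapping[int, float]) -> int:
    """k with the highest validation macro AP; ties go to the smallest k."""
    if not validation_macro_ap:
        raise KnnError("empty k grid")
    best = max(validation_macro_ap.values())
    return min(k for k, v in validation_macro_ap.items() if v == best)
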