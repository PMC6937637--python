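"""kd-tree nearest-neighbor lookup and the classification protocols on it.

Embedded vectors are stored in an exact kd-tree under Euclidean distance.
On top of single-nearest-neighbor taxonomy assignment this module provides
the top-K candidate pool, per-genome majority voting over chunk votes,
consensus host-genus prediction for phages (labels appearing at least
min_count times among the n nearest bacterial chunks), calibration of the
neighbor count against a target mean number of guesses, and accuracy
reporting.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .embedding import EmbeddedCorpus

logger = logging.getLogger(__name__)


@dataclass
class Neighbor:
    id: str
    labels: dict[str, str]
    distance: float
    index: int


@dataclass
class Prediction:
    """Outcome of one query lookup: ordered neighbors, the top-1 label per
    requested rank, and the distinct top-K candidate label pool."""

    query_id: str
    neighbors: list[Neighbor]
    predicted: dict[str, str] = field(default_factory=dict)
    candidates: list[str] = field(default_factory=list)


class ReferenceIndex:
    """Embedded reference corpus in a kd-tree for exact Euclidean lookup."""

    def __init__(self, corpus: EmbeddedCorpus):
        self.corpus = corpus
        self.tree = cKDTree(np.asarray(corpus.vectors, dtype=float))

    def __len__(self) -> int:
        return len(self.corpus)

    @property
    def r(self) -> int:
        return self.corpus.vectors.shape[1]


def nearest_neighbors(index: ReferenceIndex, q: np.ndarray, K: int) -> list[Neighbor]:
    """The K stored vectors closest to q, in non-decreasing distance order;
    exact (identical to a brute-force scan), ties broken by insertion order.

    K larger than the corpus is clamped with a warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    m = len(index)
    if K > m:
        warnings.warn(f"K={K} exceeds corpus size {m}; clamping", stacklevel=2)
        K = m
    q = np.asarray(q, dtype=float)
    if q.shape != (index.r,):
        raise ValueError(f"query dimension {q.shape} != ({index.r},)")
    dist, idx = index.tree.query(q, k=K)
    dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
    # stable re-order so exact distance ties respect insertion order
    order = np.lexsort((idx, dist))
    return [
        Neighbor(
            id=index.corpus.ids[i],
            labels=index.corpus.labels[i],
            distance=float(d),
            index=int(i),
        )
        for d, i in zip(dist[order], idx[order])
    ]


def classify_nn(index: ReferenceIndex, q: np.ndarray, rank: str) -> str:
    """Label at the requested rank of the single nearest neighbor."""
    nb = nearest_neighbors(index, q, 1)[0]
    if rank not in nb.labels:
        raise KeyError(f"nearest neighbor {nb.id!r} has no label at rank {rank!r}")
    return nb.labels[rank]


def candidate_pool(
    index: ReferenceIndex, q: np.ndarray, rank: str, K: int = 20
) -> list[str]:
    """Distinct labels of the K nearest neighbors, in first-appearance order.

    The top-1 label is always first, so the pool can only improve on the
    single-neighbor guess.
    """
    seen: dict[str, None] = {}
    for nb in nearest_neighbors(index, q, K):
        label = nb.labels.get(rank)
        if label is not None and label not in seen:
            seen[label] = None
    return list(seen)


def majority_classify(
    index: ReferenceIndex, queries: np.ndarray, rank: str
) -> str:
    """Most frequent nearest-neighbor label across one genome's chunk vectors.

    Ties are broken in favour of the label whose best (smallest) neighbor
    distance is smallest, then lexicographically.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if len(queries) == 0:
        raise ValueError("majority_classify needs at least one query vector")
    votes: Counter[str] = Counter()
    best_dist: dict[str, float] = {}
    for q in queries:
        nb = nearest_neighbors(index, q, 1)[0]
        if rank not in nb.labels:
            raise KeyError(f"nearest neighbor {nb.id!r} has no label at rank {rank!r}")
        label = nb.labels[rank]
        votes[label] += 1
        best_dist[label] = min(best_dist.get(label, np.inf), nb.distance)
    return min(votes, key=lambda lab: (-votes[lab], best_dist[lab], lab))


def consensus_hosts(
    index: ReferenceIndex,
    q: np.ndarray,
    n_neighbors: int = 28,
    min_count: int = 2,
    rank: str = "genus",
) -> list[str]:
    """Labels occurring at least ``min_count`` times among the ``n_neighbors``
    nearest neighbors, ordered by count (descending) then best distance.

    The defaults (28 neighbors, consensus of two) give close to three genus
    guesses per phage on the reference corpus the protocol was designed for.
    The returned list may be empty.
    """
    if not n_neighbors >= min_count >= 1:
        raise ValueError("need n_neighbors >= min_count >= 1")
    counts: Counter[str] = Counter()
    best_dist: dict[str, float] = {}
    for nb in nearest_neighbors(index, q, n_neighbors):
        label = nb.labels.get(rank)
        if label is None:
            continue
        counts[label] += 1
        best_dist[label] = min(best_dist.get(label, np.inf), nb.distance)
    kept = [lab for lab, c in counts.items() if c >= min_count]
    kept.sort(key=lambda lab: (-counts[lab], best_dist[lab], lab))
    return kept


def calibrate_neighbor_count(
    index: ReferenceIndex,
    queries: np.ndarray,
    min_count: int,
    target_avg_guesses: float,
    rank: str = "genus",
    n_range: range = range(2, 101),
) -> int:
    """The neighbor count whose mean consensus-set size over the queries is
    closest to ``target_avg_guesses`` (ties resolved toward smaller n)."""
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    best_n, best_gap = None, np.inf
    for n in n_range:
        if n < min_count or n > len(index):
            continue
        sizes = [
            len(consensus_hosts(index, q, n_neighbors=n, min_count=min_count, rank=rank))
            for q in queries
        ]
        gap = abs(float(np.mean(sizes)) - target_avg_guesses)
        if gap < best_gap:
            best_n, best_gap = n, gap
    if best_n is None:
        raise ValueError("no feasible neighbor count in the searched range")
    return best_n


def evaluate(
    predictions: list[Prediction],
    truth: dict[str, dict[str, str]],
    rank: str,
) -> pd.DataFrame:
    """Accuracy report over queries that carry truth at the rank.

    Columns: top-1 accuracy (%), top-K candidate-pool hit rate (%), and —
    where predictions carry consensus sets in ``candidates`` — the consensus
    hit rate coincides with the pool column. Percentages are over the number
    of evaluable queries.
    """
    n = top1 = pool = 0
    for pred in predictions:
        true_label = truth.get(pred.query_id, {}).get(rank)
        if true_label is None:
            continue
        n += 1
        if pred.predicted.get(rank) == true_label:
            top1 += 1
        if true_label in pred.candidates:
            pool += 1
    if n == 0:
        raise ValueError(f"no query has truth at rank {rank!r}")
    return pd.DataFrame(
        [
            {
                "rank": rank,
                "n_queries": n,
                "top1_pct": 100.0 * top1 / n,
                "pool_pct": 100.0 * pool / n,
            }
        ]
    )


def predict(
    index: ReferenceIndex,
    query_ids: list[str],
    queries: np.ndarray,
    rank: str,
    K_pool: int = 20,
) -> list[Prediction]:
    """Run top-1 + candidate-pool prediction for a batch of query vectors."""
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    out = []
    for qid, q in zip(query_ids, queries):
        neighbors = nearest_neighbors(index, q, min(K_pool, len(index)))
        predicted = {}
        if rank in neighbors[0].labels:
            predicted[rank] = neighbors[0].labels[rank]
        pool: dict[str, None] = {}
        for nb in neighbors:
            lab = nb.labels.get(rank)
            if lab is not None:
                pool.setdefault(lab, None)
        out.append(
            Prediction(
                query_id=qid,
                neighbors=neighbors,
                predicted=predicted,
                candidates=list(pool),
            )
        )
    return out


def predictions_to_frame(predictions: list[Prediction], rank: str) -> pd.DataFrame:
    """Tabular form of predictions for TSV export."""
    rows = []
    for p in predictions:
        rows.append(
            {
                "query_id": p.query_id,
                "rank": rank,
                "predicted": p.predicted.get(rank, ""),
                "candidates": ";".join(p.candidates),
                "distances": ";".join(f"{nb.distance:.6g}" for nb in p.neighbors),
            }
        )
    return pd.DataFrame(rows)
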