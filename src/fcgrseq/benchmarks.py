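"""Reusable evaluation protocols over synthetic corpora.

Runs the full FCGR → DCT-IV → SVD → kd-tree pipeline on a labeled corpus
under repeated stratified 75/25 train/test splits (the randomized-trial
protocol: the corpus is fixed, only split membership varies per trial) and
reports per-trial chunk-level accuracy, top-K candidate-pool hit rate and,
when genomes are chunked, genome-level majority-vote accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ReferenceIndex, candidate_pool, classify_nn, majority_classify
from .config import PipelineConfig
from .embedding import EmbeddedCorpus, fit_svd, fit_svd_subsampled, project
from .pipeline import chunk_corpus, feature_matrix
from .seqio import LabeledSequence
from .synth import stratified_split


@dataclass
class CorpusFeatures:
    """Feature matrix for a corpus, one row per (chunk of a) genome."""

    M: np.ndarray
    units: list[LabeledSequence]      # the vectorised units (chunks or genomes)
    genome_ids: list[str]             # parent genome id of each unit
    genomes: list[LabeledSequence]    # the original genomes


def prepare_features(
    corpus: list[LabeledSequence],
    config: PipelineConfig = PipelineConfig(),
    chunk: bool = False,
) -> CorpusFeatures:
    """Vectorise a corpus once (optionally chunking genomes first) so that
    repeated split trials only redo the cheap SVD + lookup stages."""
    if chunk:
        units, genome_ids = [], []
        for s in corpus:
            got = chunk_corpus([s], config.chunk_len, config.max_chunks)
            units.extend(got)
            genome_ids.extend([s.id] * len(got))
    else:
        units, genome_ids = list(corpus), [s.id for s in corpus]
    M = feature_matrix(units, k=config.k, f=config.f)
    return CorpusFeatures(M=M, units=units, genome_ids=genome_ids, genomes=list(corpus))


def split_trial(
    feats: CorpusFeatures,
    split_seed: int,
    config: PipelineConfig = PipelineConfig(),
    rank: str = "species",
    subsample_fraction: float = 1.0,
    train_frac: float = 0.75,
) -> dict[str, float]:
    """One stratified split trial; returns chunk/pool/majority accuracies (%).

    The split is stratified over *genomes* (all chunks of a genome go to the
    same side); the SVD is fitted on the training rows only.
    """
    train_g, test_g = stratified_split(
        feats.genomes, train_frac=train_frac, seed=split_seed, rank=rank
    )
    train_ids = {s.id for s in train_g}
    tr = [i for i, g in enumerate(feats.genome_ids) if g in train_ids]
    te = [i for i, g in enumerate(feats.genome_ids) if g not in train_ids]
    if not tr or not te:
        raise ValueError("degenerate split: empty train or test side")

    M_train = feats.M[tr]
    if subsample_fraction < 1.0:
        model, embedded = fit_svd_subsampled(
            M_train, config.r, fraction=subsample_fraction, seed=split_seed
        )
    else:
        model, embedded = fit_svd(M_train, config.r)
    index = ReferenceIndex(
        EmbeddedCorpus(
            vectors=embedded,
            ids=[feats.units[i].id for i in tr],
            labels=[feats.units[i].labels for i in tr],
        )
    )
    queries = project(model, feats.M[te])

    n = top1 = pool = 0
    genome_queries: dict[str, list[np.ndarray]] = {}
    genome_truth: dict[str, str] = {}
    for row, i in zip(queries, te):
        truth = feats.units[i].labels[rank]
        n += 1
        if classify_nn(index, row, rank) == truth:
            top1 += 1
        if truth in candidate_pool(index, row, rank, K=config.K_pool):
            pool += 1
        gid = feats.genome_ids[i]
        genome_queries.setdefault(gid, []).append(row)
        genome_truth[gid] = truth

    maj = sum(
        majority_classify(index, np.vstack(v), rank) == genome_truth[gid]
        for gid, v in genome_queries.items()
    )
    return {
        "chunk_acc_pct": 100.0 * top1 / n,
        "pool_acc_pct": 100.0 * pool / n,
        "majority_acc_pct": 100.0 * maj / len(genome_queries),
        "n_test_units": n,
        "n_test_genomes": len(genome_queries),
    }


def repeated_trials(
    feats: CorpusFeatures,
    n_trials: int,
    seed: int,
    config: PipelineConfig = PipelineConfig(),
    rank: str = "species",
    subsample_fraction: float = 1.0,
) -> pd.DataFrame:
    """Run ``n_trials`` randomized split trials (split seeds derived from
    ``seed``) and return one row per trial."""
    rows = [
        split_trial(
            feats, split_seed=seed + t, config=config, rank=rank,
            subsample_fraction=subsample_fraction,
        )
        for t in range(n_trials)
    ]
    return pd.DataFrame(rows)


def same_genome_neighbor_rate(
    feats: CorpusFeatures, config: PipelineConfig = PipelineConfig()
) -> float:
    """Fraction of chunks whose nearest non-self neighbor (over the whole
    indexed corpus) comes from the same genome — the self-similarity probe."""
    from .classify import nearest_neighbors

    model, embedded = fit_svd(feats.M, config.r)
    index = ReferenceIndex(
        EmbeddedCorpus(
            vectors=embedded,
            ids=[u.id for u in feats.units],
            labels=[u.labels for u in feats.units],
        )
    )
    same = 0
    for i, vec in enumerate(embedded):
        nbs = nearest_neighbors(index, vec, 2)
        other = next(nb for nb in nbs if nb.index != i)
        same += feats.genome_ids[other.index] == feats.genome_ids[i]
    return same / len(embedded)
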