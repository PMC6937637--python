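"""End-to-end composition of the pipeline stages.

sequence → FCGR image → centred DCT-IV low-frequency block → flattened,
centred feature vector → truncated-SVD embedding → kd-tree reference index.
"""

from __future__ import annotations

import logging

import numpy as np

from .classify import ReferenceIndex
from .config import PipelineConfig
from .embedding import EmbeddedCorpus, EmbeddingModel, fit_svd, fit_svd_subsampled, project
from .fcgr import FCGRParams, fcgr
from .seqio import ChunkSpec, LabeledSequence, chunk_genome
from .spectral import SpectralParams, image_to_feature

logger = logging.getLogger(__name__)


def feature_matrix(seqs: list[LabeledSequence], k: int = 7, f: int = 30) -> np.ndarray:
    """Stack the length-f^2 feature vectors of a corpus into an m x f^2 matrix."""
    fp, sp = FCGRParams(k=k), SpectralParams(f=f)
    return np.vstack([image_to_feature(fcgr(s.sequence, fp).image, sp) for s in seqs])


def chunk_corpus(
    seqs: list[LabeledSequence], chunk_len: int, max_chunks: int
) -> list[LabeledSequence]:
    """Chunk every genome; genomes shorter than one chunk are dropped."""
    spec = ChunkSpec(chunk_len=chunk_len, max_chunks=max_chunks)
    chunks: list[LabeledSequence] = []
    for s in seqs:
        got = chunk_genome(s, spec)
        logger.info("genome %s: %d chunks", s.id, len(got))
        chunks.extend(got)
    return chunks


def fit_reference(
    train: list[LabeledSequence],
    config: PipelineConfig = PipelineConfig(),
    subsample_fraction: float = 1.0,
) -> tuple[EmbeddingModel, ReferenceIndex]:
    """Fit the embedding on a training corpus and index the embedded rows.

    With ``subsample_fraction < 1`` the SVD is fitted on a seeded random row
    subsample and every row is projected through its V (the memory-saving
    variant); the index always covers the full corpus.
    """
    M = feature_matrix(train, k=config.k, f=config.f)
    if subsample_fraction < 1.0:
        model, embedded = fit_svd_subsampled(
            M, config.r, fraction=subsample_fraction, seed=config.seed
        )
    else:
        model, embedded = fit_svd(M, config.r)
    logger.info(
        "embedded %d vectors; leading singular values %s",
        len(embedded), np.array2string(model.singular_values[:5], precision=3),
    )
    corpus = EmbeddedCorpus(
        vectors=embedded,
        ids=[s.id for s in train],
        labels=[dict(s.labels) for s in train],
    )
    return model, ReferenceIndex(corpus)


def save_reference(path, model: EmbeddingModel, index: ReferenceIndex) -> None:
    """Persist model + embedded corpus to one versioned .npz archive;
    reloading reproduces projections bitwise."""
    import json

    np.savez(
        path,
        version=np.array([1]),
        V=model.V,
        singular_values=model.singular_values,
        r=np.array([model.r]),
        vectors=index.corpus.vectors,
        ids=np.array(index.corpus.ids),
        labels=np.array(json.dumps(index.corpus.labels)),
    )


def load_reference(path) -> tuple[EmbeddingModel, ReferenceIndex]:
    import json

    with np.load(path) as data:
        if int(data["version"][0]) != 1:
            raise ValueError("unsupported reference archive version")
        model = EmbeddingModel(
            V=data["V"], singular_values=data["singular_values"], r=int(data["r"][0])
        )
        corpus = EmbeddedCorpus(
            vectors=data["vectors"],
            ids=[str(x) for x in data["ids"]],
            labels=json.loads(str(data["labels"])),
        )
    return model, ReferenceIndex(corpus)


def embed_queries(
    model: EmbeddingModel, seqs: list[LabeledSequence], config: PipelineConfig = PipelineConfig()
) -> np.ndarray:
    """Process query sequences through FCGR + DCT and project via the model's V."""
    for s in seqs:
        if len(s) < 1000:
            logger.warning("query %s is only %d bp; accuracy degrades below ~1 kb", s.id, len(s))
    return project(model, feature_matrix(seqs, k=config.k, f=config.f))
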