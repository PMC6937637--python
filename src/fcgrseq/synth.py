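"""Synthetic multi-species nucleotide corpora with controllable k-mer structure.

Each synthetic "species" is a low-order Markov chain over {A,C,G,T} whose
transition rows are drawn from a symmetric Dirichlet; lower concentration
gives more idiosyncratic rows and therefore more separable species.
Individual genomes are sampled hierarchically: every genome gets its own
slight Dirichlet perturbation of the species transition table (standing in
for strain-level compositional signatures, which is what makes chunks of
one genome mutually more similar than chunks of sibling genomes), and the
sampled sequence additionally receives i.i.d. substitutions at a small
mutation rate. All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import LabeledSequence

_BASES = "ACGT"


@dataclass
class SpeciesModel:
    """A named Markov transition model over {A,C,G,T}.

    ``transition`` has one row per length-``order`` context (contexts are
    enumerated as base-4 integers, A=0..T=3) and one column per next base;
    every row sums to 1.
    """

    name: str
    order: int
    transition: np.ndarray
    seed: int
    genus: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (4 ** self.order, 4):
            raise ValueError(
                f"transition must be {4 ** self.order} x 4 for order {self.order}"
            )
        if (t < 0).any() or not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each context's probabilities must be >= 0 and sum to 1")
        self.transition = t
        if not self.genus:
            self.genus = f"{self.name}_genus"


def make_species(
    n_species: int,
    order: int = 2,
    concentration: float = 1.0,
    seed: int = 0,
) -> list[SpeciesModel]:
    """Draw ``n_species`` Markov models with Dirichlet(concentration) rows.

    Species are named ``sp00, sp01, ...`` and grouped two-per-genus into
    derived genus labels; the same seed always reproduces the same models.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n_species):
        rows = rng.dirichlet([concentration] * 4, size=4 ** order)
        models.append(
            SpeciesModel(
                name=f"sp{i:02d}",
                order=order,
                transition=rows,
                seed=seed,
                genus=f"genus{i // 2:02d}",
            )
        )
    return models


def perturb_model(model: SpeciesModel, concentration: float, seed: int) -> SpeciesModel:
    """A genome-level variant of a species model.

    Each transition row is resampled from Dirichlet(concentration * row),
    so large concentrations stay close to the species profile while still
    giving every genome a reproducible compositional signature.
    """
    rng = np.random.default_rng(seed)
    eps = 1e-6  # Dirichlet parameters must be strictly positive
    rows = np.vstack(
        [rng.dirichlet(concentration * row + eps) for row in model.transition]
    )
    return SpeciesModel(
        name=model.name, order=model.order, transition=rows, seed=seed,
        genus=model.genus,
    )


def _sample_codes(transition: np.ndarray, order: int, length: int, rng) -> list[int]:
    """Sample base codes (A=0..T=3) from the Markov chain; plain-Python
    inner loop over precomputed cumulative rows for speed."""
    cum = transition.cumsum(axis=1)
    # plain floats: python bool arithmetic gives the 0-3 bin index directly
    rows = [(float(r[0]), float(r[1]), float(r[2])) for r in cum]
    mask = 4 ** order - 1
    codes = list(rng.integers(0, 4, size=order))
    c = 0
    for b in codes:
        c = (c << 2 | int(b)) & mask
    us = rng.random(length - order).tolist()
    append = codes.append
    for u in us:
        r = rows[c]
        b = (u > r[0]) + (u > r[1]) + (u > r[2])
        append(b)
        c = (c << 2 | b) & mask
    return codes


def sample_genome(
    model: SpeciesModel,
    length: int,
    mutation_rate: float = 0.0,
    seed: int = 0,
    genome_id: str | None = None,
) -> LabeledSequence:
    """Sample one genome of exactly ``length`` bp from a species model.

    After Markov sampling, each position is independently substituted with
    probability ``mutation_rate`` by one of the three other bases (uniform).
    """
    if length < model.order + 1:
        raise ValueError(f"length must be >= order+1 = {model.order + 1}")
    if not 0 <= mutation_rate < 1:
        raise ValueError("mutation_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    codes = np.array(_sample_codes(model.transition, model.order, length, rng))
    if mutation_rate > 0:
        hit = rng.random(length) < mutation_rate
        # shift by 1..3 mod 4: always lands on a different base
        codes[hit] = (codes[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
    return LabeledSequence(
        id=genome_id or f"{model.name}_g{seed}",
        sequence=seq,
        labels={"species": model.name, "genus": model.genus},
    )


def stationary_distribution(model: SpeciesModel) -> np.ndarray:
    """Stationary base frequencies (A,C,G,T) of the Markov chain."""
    n_ctx = 4 ** model.order
    P = np.zeros((n_ctx, n_ctx))
    for c in range(n_ctx):
        for b in range(4):
            P[c, (c << 2 | b) & (n_ctx - 1)] += model.transition[c, b]
    eigvals, eigvecs = np.linalg.eig(P.T)
    pi = np.real(eigvecs[:, np.argmin(np.abs(eigvals - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    base_freq = np.zeros(4)
    for c in range(n_ctx):
        base_freq[c & 3] += pi[c]
    return base_freq


@dataclass
class Benchmark:
    """A labeled synthetic corpus with one stratified 75/25 split."""

    corpus: list[LabeledSequence]
    train: list[LabeledSequence]
    test: list[LabeledSequence]
    species: list[SpeciesModel] = field(default_factory=list)


def stratified_split(
    corpus: list[LabeledSequence],
    train_frac: float = 0.75,
    seed: int = 0,
    rank: str = "species",
) -> tuple[list[LabeledSequence], list[LabeledSequence]]:
    """Seeded stratified split: per class, floor(train_frac * size) genomes
    go to training and the rest to test; a new seed permutes membership only."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[LabeledSequence]] = {}
    for s in corpus:
        by_class.setdefault(s.labels[rank], []).append(s)
    train, test = [], []
    for label in sorted(by_class):
        members = by_class[label]
        perm = rng.permutation(len(members))
        n_train = int(train_frac * len(members))
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return train, test


def make_benchmark(
    n_species: int = 6,
    genomes_per_species: int = 12,
    genome_length: int = 20000,
    seed: int = 0,
    order: int = 2,
    concentration: float = 0.5,
    genome_concentration: float = 300.0,
    mutation_rate: float = 0.01,
    train_frac: float = 0.75,
) -> Benchmark:
    """Build a labeled multi-species corpus with a stratified 75/25 split.

    Defaults model a compact multi-species recognition task: six species,
    twelve genomes each, 20 kb genomes, order-2 chains with
    Dirichlet(0.5) rows (clearly distinct species, as across real genera),
    genome-level perturbation at concentration 300 (tight within-species
    strain variation) and 1% substitution noise.
    """
    species = make_species(n_species, order=order, concentration=concentration, seed=seed)
    rng = np.random.default_rng(seed + 1)
    corpus = []
    for model in species:
        for g in range(genomes_per_species):
            gseed = int(rng.integers(0, 2**31 - 1))
            genome_model = perturb_model(model, genome_concentration, gseed)
            corpus.append(
                sample_genome(
                    genome_model,
                    genome_length,
                    mutation_rate=mutation_rate,
                    seed=gseed,
                    genome_id=f"{model.name}_g{g:02d}",
                )
            )
    train, test = stratified_split(corpus, train_frac=train_frac, seed=seed + 2)
    return Benchmark(corpus=corpus, train=train, test=test, species=species)
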