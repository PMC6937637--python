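# Methods

## Pipeline model and assumptions

The package treats a nucleotide sequence purely as a bag of overlapping
k-mers with positional structure discarded beyond the length-k window.
The premise is that oligonucleotide composition is a stable, taxon-
specific signature: two fragments of the same genome, or two genomes of
the same species, have more similar k-mer spectra than fragments of
unrelated taxa. All downstream machinery — spectral compression, linear
embedding, metric lookup — preserves that signal while shrinking each
sequence to a vector of a few dozen numbers. Nothing requires input
sequences to share a common length.

### FCGR stage

Corners follow Jeffrey's convention: A=(0,0), C=(0,1), G=(1,1), T=(1,0),
purines diagonally opposed, matrix row 0 at the top of the square. Any
valid corner assignment merely permutes pixels consistently and leaves
all distances unchanged; one is fixed for determinism. The pixel of a
k-mer is computed bitwise (column bit from {G,T}, y bit from {C,G}), with
the **last** base contributing the most significant bit — this is exactly
the pixel in which the chaos-game midpoint iteration lands, and the
equivalence is asserted against a literal midpoint-iteration oracle in
the tests. Windows containing any IUPAC ambiguity code contribute to no
pixel; the skipped fraction is logged. Inventing fractional counts for
ambiguous windows was rejected as it biases spectra at no benefit. Counts
are integers; the displayed image is (counts/max)^(1/5), a nonlinear
stretch that keeps typical pixels away from black/white. The count
matrix, not the stretch, is what carries information; the fifth root
compresses the dynamic range so that rare and common k-mers both
contribute to the spectral stage.

The default pixelation level is k=7 (128×128 images). Levels 1–12 are
supported; beyond ~10 the memory cost grows with no accuracy return.

### Spectral stage

The orthonormal DCT-IV is used because it is involutive (its own
inverse), which makes truncation/reconstruction reasoning trivial, and
empirically concentrates FCGR spectral energy well. The image is first
centred by its global mean — DCT-IV has no pure DC basis vector, so
centring is what actually removes the flat component — then transformed
along rows and columns (order immaterial by separability; both passes are
applied before slicing) and cut to the top-left f×f low-frequency block,
f=30 by default. Truncating before or after the second pass is
mathematically identical for this block. All spectral arithmetic is in
double precision.

### Embedding stage

Feature vectors are the row-major flattened blocks, each centred by its
own mean (queries are centred the same way; no training mean is stored).
The rank-r truncated SVD (r=40 default; 20–50 behaves similarly, r=80 is
exposed in configuration for experiments that benefit from a richer
embedding) is computed densely below 2000 rows and with a Lanczos-type
iterative solver above. Embedded coordinates are stored as MV rather than
UW computed separately: the two are equal at full rank, and using MV
keeps the training and query paths bit-identical under truncation, which
is what makes a stored vector its own exact nearest neighbor. Each column
of V is sign-fixed so its largest-magnitude entry is positive; SVD signs
are otherwise arbitrary and fixing them makes the gram and subsampled
variants directly comparable and all outputs reproducible. The gram
variant clamps negative round-off eigenvalues of MᵗM to zero before the
square root.

### Lookup and protocols

Lookup uses Euclidean distance in the embedded space via an exact
kd-tree; results are asserted identical to a brute-force scan. Distance
ties are broken by insertion order; majority votes break ties by the
label with the smallest best neighbor distance, then lexicographically —
the protocols themselves do not prescribe tie-breaks, so deterministic
ones are imposed for reproducibility. The top-20 candidate pool does not
deduplicate chunks originating from the same training genome. Host
consensus retains labels seen at least `min_count` times (default 2)
among `n_neighbors` (default 28) nearest reference chunks, a setting that
targets roughly three genus guesses per query on realistic reference
sets; `calibrate_neighbor_count` searches the neighbor count whose mean
guess-set size is closest to a requested target.

### Chunking and stitching

Genomes are split into non-overlapping chunks of `chunk_len` (20 kb
default), at most `max_chunks` (37), placed at
floor(i·(L−chunk_len)/(c−1)) — approximately equally spaced, guaranteed
non-overlapping, and deterministic. Short-read emulation stitches
equal-length fragments by arranging them row-wise into a matrix with
`group_size` columns and transposing, so each composite samples fragments
spread across the genome rather than one contiguous region. The spacing
of sampled fragments is exposed as a parameter since no single rule is
canonical.

### Trees, MDS, Robinson–Foulds

Trees are built on one vector per whole input sequence (no chunking),
with cosine distance and average linkage by default; linkage is a flag
because reasonable agglomeration rules differ and topologies can vary
modestly between them. Newick branch lengths are parent merge height
minus child height. Classical MDS is the Torgerson construction
(double-centred squared distances, top eigenpairs, negative eigenvalues
clamped); Euclidean-embeddable inputs are reproduced to machine
precision. Robinson–Foulds is the size of the symmetric difference of
non-trivial bipartition sets under the unrooted interpretation of both
trees; the package's own bipartition enumeration is cross-checked in the
tests against dendropy's independent implementation.

## Synthetic corpus generator

Each species is an order-2 Markov chain over {A,C,G,T} with transition
rows drawn from a symmetric Dirichlet(0.5) — rows that different, species
are separated roughly as real genera are in 7-mer space. Genomes are
sampled hierarchically: every genome perturbs its species' rows through
Dirichlet(300·p) (a tight, strain-like compositional signature) and then
receives i.i.d. substitutions at 1%. The hierarchical layer is what makes
chunks of one genome mutually more similar than chunks of sibling
genomes, mirroring the genome self-similarity seen in real corpora; the
self-similarity probe fixture uses a stronger jitter, Dirichlet(10·p), to
test that the pipeline picks up genome-level signal when it is present.
The default benchmark is 6 species × 12 genomes × 20 kb with stratified
75/25 splits (training side rounded down), evaluated over 20 randomized
split trials of the fixed corpus; multi-chunk protocols use 100 kb
genomes chunked to 20 kb. These sizes keep a full evaluation under a
minute while leaving no stage untested.

What the generator does *not* emulate: repeats, GC skew along the
replichore, indels, horizontal transfer, shared ancestry between species
(species are drawn independently, so there is no meaningful "true tree"
beyond species monophyly). Passing tests therefore demonstrate that the
pipeline recovers compositional structure when it exists and that every
algorithmic contract holds exactly; they do not by themselves certify
accuracy levels on real taxonomic corpora, which must be evaluated with
the CLI on downloaded data.

## Numerical choices

- All floating-point work in double precision; FCGR counts as int64.
- Involution, orthonormality and exact-match assertions use absolute
  tolerances of 1e-8–1e-10, reflecting accumulation over ≤ 16384-element
  transforms.
- Degenerate inputs: all-zero count matrices map to all-zero images
  (no 0/0); genomes shorter than one chunk yield zero chunks with a log
  warning rather than an error; empty consensus sets are valid output;
  queries under 1 kb trigger a warning since short fragments degrade.
- `K` larger than the corpus is clamped with a warning rather than
  rejected, since protocol defaults (e.g. 28 neighbors) can exceed small
  reference sets.
- Dirichlet perturbation adds 1e-6 to its parameters because zero
  parameters are undefined; transition rows must sum to 1 within 1e-12.

## Known limitations

- The kd-tree's tie handling beyond the returned K neighbors follows the
  tree's internal order; with continuous-valued embeddings exact ties are
  measure-zero and this never matters in practice.
- The subsampled SVD requires the subsample to be at least the rank r, so
  very small corpora cannot use small fractions.
- No out-of-core SVD: the m × f² matrix must fit in memory (about 7.2 kB
  per sequence at f=30).
- GenBank fetching is not built in; provide FASTA (plus an optional
  two-column label TSV) obtained by any external means.
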