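# fcgrseq

Alignment-free comparison of nucleotide sequences via Frequency Chaos Game
Representation (FCGR) images, DCT-IV low-frequency truncation, and a
truncated-SVD embedding. Genomes, genome fragments, and mitochondrial
sequences of *any* length are turned into short numeric vectors that
support:

- exact kd-tree nearest-neighbor taxonomy lookup (species/genus/…),
- majority-vote classification of whole genomes from their chunks,
- consensus host-genus prediction for phage genomes against a bacterial
  reference,
- distance-based phylogenetic trees (hierarchical clustering, Newick
  output, Robinson–Foulds comparison), and
- classical MDS visualisation.

It is aimed at people who need fast, scalable, coarse-grained genomic
lookup or phylogeny sketches — metagenomics triage, reference-set
screening, "which genus is this contig" questions — where alignment is
too slow and a k-mer signature carries enough signal.

## Method

For a sequence *s* and pixelation level *k* (default 7):

1. **FCGR.** The chaos game places A, C, G, T at the corners of the unit
   square (purines diagonal to purines) and iterates "move halfway toward
   the next base's corner". Binning the iterates at resolution 2^k gives a
   2^k × 2^k matrix whose pixel (i, j) counts one specific k-mer. The
   count matrix is normalised so its maximum is 1 and stretched by the
   elementwise fifth root, giving an image in [0, 1]^(2^k × 2^k).
2. **DCT-IV.** The image is centred by subtracting its global mean
   (removing the DC component) and transformed separably with the
   orthonormal type-IV discrete cosine transform
   X_j = √(2/N) Σ_i x_i cos(π(i+½)(j+½)/N), which is its own inverse.
   Only the top-left *f* × *f* block of low frequencies is kept
   (default *f* = 30), a compression factor of 128²/30² ≈ 18.2.
3. **SVD.** The blocks are flattened row-major, centred by their own mean,
   and stacked into M (m × f²). From the factorization M = U W Vᵗ we keep
   the *r* largest singular values (default *r* = 40). Because UW = MV,
   training rows and query vectors are embedded through the identical
   path — right-multiplication by V — so a training vector looked up in
   the kd-tree matches itself exactly, up to machine arithmetic. Two
   scalability variants are provided: fitting the SVD on a random row
   subsample, and the Gram-matrix route via eigen-decomposition of MᵗM.
4. **Lookup / trees.** Embedded vectors go into an exact kd-tree
   (Euclidean distance) for classification protocols, or into a cosine
   distance matrix for average-linkage hierarchical trees and classical
   (Torgerson) MDS.

## Worked example

Generate a small labeled synthetic corpus (three Markov "species", four
genomes each, 20 kb), embed it, classify, and build a tree:

```
$ fcgrseq synth --n-species 3 --genomes-per-species 4 \
      --genome-length 20000 --seed 7 -o corpus.fa --labels-out labels.tsv
wrote 12 genomes -> corpus.fa

$ python -c "from fcgrseq.config import PipelineConfig; \
             PipelineConfig(r=8, seed=7).to_yaml('config.yaml')"
$ fcgrseq embed corpus.fa --no-chunk --config config.yaml -o ref.npz
embedded 12 vectors at rank 8 -> ref.npz

$ fcgrseq classify ref.npz corpus.fa --config config.yaml \
      --rank species -o pred.tsv
wrote 12 predictions -> pred.tsv

$ head -2 pred.tsv
query_id  rank     predicted  candidates      distances
sp00_g00  species  sp00       sp00;sp02;sp01  0;4.16042;4.68528;...
```

Each query's nearest neighbor is itself at distance 0 (the exact-match
property of the MV embedding); `predicted` is the nearest neighbor's
label and `candidates` the distinct labels among the top-20 pool, in
first-appearance order. The tree command recovers the three species as
clades:

```
$ fcgrseq tree corpus.fa --config config.yaml -o tree.nwk
wrote tree over 12 leaves -> tree.nwk
$ cat tree.nwk
((sp01_g00:0.0582,(sp01_g03:0.0482,(sp01_g01:0.0206,sp01_g02:0.0206)...
```

(`r=8` here only because the demo corpus has 12 sequences; the default
r=40 applies to realistically sized reference sets.)

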