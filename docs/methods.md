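# Methods

## The prediction problem

Given a bacteriophage genome, identify its bacterial host among a set of
candidate host genomes. `comphi` combines two complementary sources of
evidence:

* **Alignment-free**: a random-forest (RF) classifier scores a
  (phage, host) pair from fixed-length composition features of both
  genomes and both proteomes. This works even when phage and host share no
  alignable sequence.
* **Alignment-based**: best-hit local-alignment bit scores exploit shared
  genetic material left by phage–host co-evolution (prophages, acquired
  genes) and the fact that related hosts are attacked by related phages.

## Feature encodings

Each organism contributes a 340-dimensional DNA vector and a
162-dimensional protein vector; a pair is their concatenation,

```
phage DNA(340) | phage protein(162) | host DNA(340) | host protein(162)  = 1,004
```

DNA layout: `Kmer(64) | RCKmer(32) | CKSNAP(96) | PseEIIP(64) | NAC(4) |
DNC(16) | TNC(64)` with k = 3 throughout. All encodings are frequencies,
so the vector length is independent of genome length.

Denominator conventions are deliberate and worth spelling out:

* **Kmer/RCKmer** divide counts by the full sequence length N rather than
  the window count N−k+1. This matches the formula the encodings are
  defined by here; the conventional window-count denominator is available
  via `length_denominator=False`. The two differ by the factor
  (N−2)/N ≈ 1 at genome scale.
* **NAC/DNC/TNC** use N, N−1, N−2 (their exact window counts).
* **CKSNAP** counts base pairs separated by g = 0…5 intervening bases
  (6 × 16 = 96 features), each gap block normalized by its own number of
  positions L−g−1. Reading the gap parameter as "0 through 5 inclusive"
  is what makes the total pair dimensionality come out at 1,004.
* **PseEIIP** weights trinucleotide frequencies (windows, denominator
  L−2) by the summed electron–ion interaction potentials of the three
  bases (A 0.1260, C 0.1340, G 0.0806, T 0.1335 — the standard published
  constants).
* Ambiguous bases: windows containing `N` are dropped from numerators
  only; denominators keep the full length/window count.

Protein side: each protein yields molecular weight
(`MW = Σw_t − (m−1)·18.01`, free-residue weights, one water per peptide
bond), C/H/O/N/S atom counts (condensed-chain by default, mirroring the
MW water subtraction; free-residue totals via `condensed=False`), and
amino-acid composition over 21 symbols (20 residues + `*`; `X` counts
toward length only). Because organisms carry many proteins, six operators
(mean, median, std, var, max, min) aggregate the 27 per-protein
descriptors columnwise into 27 × 6 = 162 features. Variance is
population-form so a single-protein organism yields 0, not NaN.

All features are min–max normalized to [0,1] with statistics learned on
training rows only; test values are clipped. Constant columns map to 0.
`reshape_to_image` provides the n×n zero-padded square layout
((n−1)² < N ≤ n²) for external image-based models; nothing in this
package consumes it.

## Alignment bit scores

Three best-hit structures, all from nucleotide local alignment at
e-value ≤ 1e-4:

* `bit_pp[p]` — best score of phage p against every other phage, plus
  `nearest_phage[p]`, the argmax (ties → lexicographically smallest id).
* `bit_ph[p, h]` — phage × host matrix; 0 where nothing passes the cutoff.
* `bit_hh[a, b]` — pairwise host × host matrix, symmetrized by the
  elementwise max of the two search directions. A full matrix is kept
  (rather than one score per host) because the composite equation needs
  the similarity of *every* candidate host to one particular reference
  host.

Backends: NCBI BLAST+ (`makeblastdb`/`blastn`, tabular output) for genome
scale, or a built-in affine-gap Smith–Waterman (numba-jitted; match +1,
mismatch −2, gap open 5, gap extend 2, a length-L gap costing
open + L·extend) with the Karlin–Altschul conversion
bits = (λS − ln K)/ln 2 and e-value K·m·n·e^(−λS) (defaults λ = 0.625,
K = 0.41; all configurable). `backend="auto"` picks BLAST+ when on PATH.

Because raw bit scores are unbounded while RF probabilities live in
[0,1], `bit_ph` and `bit_hh` are min–max scaled to [0,1] before entering
the composite equation (statistics from training rows, clipped at test
time). `bit_pp` feeds only an argmax and stays raw.

## Composite scoring

For query phage *pt* and candidate host *H*:

```
Pra     = BitPH(pt, H)·(1 − a)  +  BitHH(hs, H)·a
Prfinal = Prm(pt, H)·(1 − r)    +  Pra·r
```

where *Prm* is the RF probability, *hs* is the host of *pt*'s nearest
phage, *r* weighs alignment-based vs alignment-free evidence and *a*
weighs the host–host term inside the alignment side. Prfinal is a convex
combination of [0,1] inputs, hence a valid score in [0,1]; r = 0
reproduces the RF ranking exactly and r = 1, a = 0 ranks by `bit_ph`
alone. The top-ranked host (ties → lexicographic id) is the prediction.

The RF uses 100 trees, max depth 20, min samples split 10, min samples
leaf 4, `sqrt` feature sampling, random state 42. Weights default to
r = 0.9, a = 0.4 but are re-derived in every experiment by an 11 × 11
grid search at 0.1 increments on a validation split of training phages
that the classifier never saw (ties → smallest r, then smallest a). Both
grid metrics are available: pair AUC for binary-metric experiments and
top-1 host accuracy for ranking experiments — the metric is matched to
the quantity the experiment reports. Feature attribution uses the RF's
impurity importances, summed per feature group and per encoding.

## Evaluation designs

Splits are always by **phage**, never by pair: each phage has one true
host, and pair-level splits would leak a test phage's features into
training. Negatives follow their phage's side of the split. A no-leakage
assertion runs inside every evaluation. Designs: 5-fold CV, repeated
70–30 splits (pipeline fully refit per repeat), mask-driven feature/
alignment-mode ablations on identical splits for paired comparison, and
taxon holdout (exclude or restrict named taxa at a rank on the training
side only; an ESKAPEE family preset ships as a constant).

Two metric framings are reported side by side: binary pair metrics
(Acc/Sen/Spe/AUC, threshold 0.5, rank-based AUC with 0.5 tie credit) and
per-phage top-1 accuracy resolved at each taxonomic rank. Rank accuracies
are nested by construction (a species match implies a genus match, and so
on), so accuracy(species) ≤ … ≤ accuracy(phylum) on every report.

## Synthetic data

The generator plants exactly the signals the method exploits:

* hosts descend a 6-rank taxonomy tree with per-rank substitution rates
  (defaults 0.10/0.08/0.06/0.04/0.02 for class→species), so sequence
  identity mirrors taxonomic proximity;
* a fraction *h* (`homology_strength`) of each phage genome is 250-bp
  segments copied from its true host at 2% substitution (the `bit_ph`
  signal); a backbone shared within each 4-phage family fills up to 30%
  (the `bit_pp` signal); the remainder is random;
* proteins are sampled from genus-specific residue-frequency profiles,
  phage proteins following the true host's genus (the alignment-free
  signal).

Defaults are desk-scale: 4 phyla × 1 × 2 × 2 × 2 × 2 = 64 hosts, 200
phages, 5 kb host and 1 kb phage genomes, h = 0.5, balanced negatives,
one fixed seed ⇒ byte-identical output. Mutation is substitution-only (no
indels), which keeps the alignment oracle exact and cheap.

What the generator does **not** emulate: codon usage, GC skew, CRISPR
spacers, tRNAs, genome rearrangement, uneven host abundance, multi-host
phages. Passing tests therefore demonstrate that the machinery is correct
and that the composite design recovers planted signal — not that the
published real-data accuracy transfers to any particular genome
collection.

## Numerical and test-design choices

* Problem sizes in the test suite: unit tests run on a 16-host/36-phage
  bundle with the internal aligner; pipeline-level properties run at the
  default desk-scale conditions (64 hosts, 200 phages) over 10 fixed
  seeds with the BLAST backend, one split per seed.
* Homology monotonicity: mean top-1 species accuracy over the grid
  h ∈ {0, 0.25, 0.5, 0.75, 1} rises from ~0.08 to ~0.98 and saturates by
  h = 0.25; beyond saturation, adjacent-step differences are smaller than
  seed-to-seed sampling noise. The property test therefore requires each
  step not to decrease by more than twice the paired standard error of
  the per-seed differences, plus a large overall rise — the statistically
  meaningful form of "non-decreasing on average".
* Degenerate inputs: single-protein organisms (zero variance), all-zero
  bit matrices (normalize to zeros), constant feature columns (map to 0),
  zero-score nearest-phage ties (lexicographic id) are all defined
  behaviours with tests.
* Exact-duplicate genome removal stands in for identity-threshold
  clustering; true 95%-identity clustering belongs to an external
  redundancy-reduction step ahead of this package.

## Known limitations

* The nearest-phage host (*hs*) is only as good as the phage–phage
  signal; with no related phage in the reference set the host–host term
  is noise, which the grid search then down-weights via *a*.
* RF probabilities are used uncalibrated.
* Protein-level alignment is out of scope; the bit scores are nucleotide
  only.
* With very small validation splits the (r, a) surface is noisy; the
  implementation widens the split until both pair labels are present but
  cannot remove the variance itself.
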