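# Methods

## Problem

In a haplotype-resolved diploid assembly every gene locus should appear
twice — once per haplotype — and the pair of copies is an allele pair.
Naive cross-haplotype homology search conflates allele pairs with
paralogs left by whole-genome, segmental or tandem duplication: paralogs
can be nearly as similar in sequence and may even retain synteny with
the ancestral locus.  The pipeline separates the two classes with a
statistical argument rather than a fixed similarity cutoff: allelic
divergence is set by heterozygosity and is therefore small and tightly
distributed, while paralog divergence reflects the (much older)
duplication age.  Synonymous-site divergence (Ks) is the cleanest
readout of that difference, and gene-order colinearity supplies an
independent positional constraint.

## Identification pipeline

Stages, in order:

1. **Reciprocal best hits (RBH).**  All-vs-all protein similarity
   between haplotypes; (a, b) is a candidate iff b is a's unique best
   hit by bit score and vice versa.  Ties break by longer alignment,
   lower e-value, then lexicographically smaller subject id, making
   the selection deterministic.  Hits can be imported (BLAST
   outfmt-6) or computed by the builtin scorer: candidate pairs share
   at least one protein 6-mer and are scored by local alignment
   (BLOSUM62, gap open −11, extend −1, one best score per ordered
   pair).  The builtin scorer exists so the pipeline is testable and
   runnable with no external aligner; its raw alignment score plays
   the role of the bit score (it is used only for ranking).
2. **Chromosome correspondence.**  RBH is computed genome-wide and
   pairs whose chromosomes are not a corresponding pair are flagged
   and rejected, keeping them visible in the report and dot plot.
3. **Colinearity.**  Anchors live in gene-order (rank) space: the
   ordinal position of each gene's start on its chromosome.  Ranks
   make the slope of a true 1:1 colinear run ±1 regardless of local
   gene density; base-pair midpoints are kept for plotting only.
   Blocks are maximal chains under a longest
   increasing/decreasing-subsequence dynamic program in which anchor
   j may follow i iff 0 < Δrank_a ≤ max_gap (default 25) and
   0 < |Δrank_b| ≤ max_gap with consistent sign.  The best chain
   (forward or inverted) is peeled off, its anchors removed, and the
   scan repeated; chains shorter than min_block_size (default 5) are
   dropped and their anchors marked non-colinear.  Inverted blocks
   are retained — haplotypes really do differ by inversions — and the
   slope filter, not orientation, decides removal.
4. **Divergence.**  Each surviving pair is codon-aligned (global
   protein alignment, BLOSUM62, affine gaps, back-translated; columns
   with gaps, ambiguity or stops dropped) and Ka/Ks estimated by
   Nei–Gojobori (1986) with Jukes–Cantor correction.  Site counts
   exclude mutations to stop codons from the per-position
   denominator; observed differences average over all stop-free
   minimal substitution pathways.  If every pathway is blocked by a
   stop, differing positions are scored independently from both codon
   contexts (symmetric; vanishingly rare).  p ≥ 3/4 leaves the
   corresponding estimate undefined ("saturated"): such pairs cannot
   pass a Ks filter and are set aside, counted separately.
5. **Ks outlier layer.**  Either the 3σ rule (flag Ks outside
   μ ± kσ, sample standard deviation, k default 3) or Tukey's fences
   (flag outside [Q1 − m·IQR, Q3 + m·IQR], m = i for the inner fence,
   2i for the outer; i default 1.5).  Quantiles use linear
   interpolation at rank 1 + (n−1)p.  The mask is computed over
   colinear, unsaturated pairs only — the population still in play —
   and applied once (no iterative re-estimation).  Degenerate cases:
   σ = 0 flags nothing; IQR = 0 flags values different from Q1.
6. **Slope layer.**  The same mask, with the same parameters, applied
   to the vector of block slopes; anchors of flagged blocks are
   rejected.  With fewer blocks than the mask needs (2 for sigma, 4
   for tukey) the layer logs a warning and removes nothing.

By default the Ks layer runs before the slope layer; a configuration
switch (`ks_before_slope=False`) swaps them, changing which rejection
status a doubly-outlying pair receives and the population the Ks mask
sees.  Ka is reported but never filtered on — the filtering criteria
are synonymous divergence and position only.

On near-normal Ks data the two rules are ordered: the i = 1.5 inner
fences sit at ≈ μ ± 2.70σ (Q3 + 1.5·IQR → 0.6745σ + 1.5·1.349σ),
inside the 3σ fences, so Tukey filtering is stricter and its retained
set nests within sigma's.  Smaller i narrows the window further.  The
sigma rule suits simple genomes with near-normal Ks; the tunable
Tukey rule suits genomes whose duplication history fattens the Ks
tail.

## ASE classification

Counts are normalized by median-of-ratios size factors (reference =
per-gene geometric mean over samples; error, with an optional
positive-part fallback, when no gene is positive everywhere).  For
each allele pair and condition the two alleles are two groups of
replicate counts under a negative binomial model.  The Wald statistic
is ln FC / SE with FC = (m̄_A + ½)/(m̄_B + ½) and
SE² = Σ_groups (1/(m̄ + ½) + α)/n, two-sided normal p.

Dispersion α is estimated per pair by method of moments,
α̂ = (s² − m̄)/m̄², pooled over the two groups.  At three replicates
this estimate has ≈ 4 degrees of freedom; plugging it into a Wald
variance as if known is anti-conservative (measured type-I ≈ 0.11 at
nominal 0.05).  The default therefore moderates it by flooring at the
across-pair mean of the non-negative per-pair estimates —
α_i = max(α̂_i, ᾱ, 10⁻⁸) — which shares information across pairs in
the spirit of DESeq2's dispersion shrinkage and is slightly
conservative (measured ≈ 0.033).  Raw per-pair and fixed-α modes
remain selectable (`DispersionConfig`).  Numerical agreement with
DESeq2 itself is not claimed.

P values are Benjamini–Hochberg adjusted within each condition across
all tested pairs.  Categories, per condition:

* **No_expression** — both alleles have zero raw counts in every
  replicate (strict rule; the threshold is configurable).
* **Diff00** — adjusted p > 0.05, or the pair untestable (fewer than
  the replicate minimum, default 3).
* **Diff0 / Diff2 / Diff8** — adjusted p ≤ 0.05 with linear
  fold-change magnitude |FC| = 2^|log2FC| in (‥, 2], (2, 8), [8, ‥)
  respectively.  Boundaries: exactly 2 → Diff0, exactly 8 → Diff8.

|FC| is the linear magnitude max(FC, 1/FC); thresholds 2 and 8
correspond to |log2FC| 1 and 3.  Classification is per condition; the
summary helpers (divergence by category, |TPM_A − TPM_B| gaps,
haplotype-bias counts with a two-sided sign test) consume the
per-condition table.  TPM uses the standard length-rate
normalization; every nonzero column sums to 10⁶.

## Synthetic data generator

The generator emulates exactly the structure the filters assume:

* Ancestral genes are uniform random sense-codon sequences of 250–550
  codons (typical plant CDS lengths; long enough that a gene's
  realized Ks, a ratio of small counts, keeps |skew| < 0.5 and the
  3σ premise of near-normality holds).
* Haplotype B derives from A codon-wise.  Per-gene target Ks is drawn
  from N(0.03, 0.01²) (heterozygosity scale); Ka = 0.3·Ks.
  Synonymous and non-synonymous single-base changes are placed at
  distinct codon positions with per-position probabilities inverted
  through the Jukes–Cantor relation, so realized NG86 estimates track
  the targets (verified within ±20%).
* 100 paralog decoys: a donor A gene is copied, mutated to Ks uniform
  in [0.3, 1.0] (WGD scale, below saturation), inserted at a random
  position on a random B chromosome, and the donor's true B allele is
  deleted.  Replacement is the point: RBH then genuinely mis-pairs
  donor and decoy, which is the failure mode the filters must catch —
  merely adding a decoy would be rejected by RBH uniqueness already.
* One 50-gene inversion (order and strand reversed) exercises
  inverted-block handling.
* Expression: NB counts (dispersion 0.1) with shared base mean 100
  per pair; 20% of pairs get the A allele scaled by 2^±4; optional
  silent pairs are zero on both alleles.

What the generator does *not* emulate: intergenic sequence and
introns, tandem arrays with more than two copies, GC/codon-usage
bias, expression mean–dispersion trends, or library-size imbalance
(size factors are ≈ 1 by construction; the normalization path is
exercised by unit tests instead).  Passing recovery tests therefore
demonstrates the statistical machinery under the stated assumptions,
not performance on any particular real genome, where upstream
annotation quality and duplication history dominate.

## Numerical and design choices

* Coordinates are externally 1-based inclusive everywhere; gene rank
  is the ordinal of the start coordinate.
* One sequence per gene; haplotype membership comes from which file a
  gene was loaded from, never parsed out of identifiers.
* The NG86 engine is validated exhaustively against an independent
  brute-force enumerator (all 61 × 61 sense-codon pairs to 10⁻⁹), and
  RBH against exhaustive mutual argmax on random matrices with
  deliberate ties.
* Chaining is greedy best-chain-first; with anchors of equal chain
  length the forward chain wins.  The dynamic program is O(n²) per
  chromosome pair, adequate to a few thousand anchors.
* Problem sizes in the test and acceptance runs (2 × 1000-gene
  chromosome pairs, 400-pair ASE panels, 10 × 100 000-draw
  calibration samples) were chosen so each property is measured with
  comfortable statistical margin while the whole suite stays quick on
  a single CPU.
* Degenerate branches (σ = 0, IQR = 0, < 4 blocks, untestable pairs,
  empty survivor sets) are defined behaviours with warnings, not
  errors.

## Known limitations

* NG86 + Jukes–Cantor underestimates divergence relative to
  maximum-likelihood codon models at high Ks and ignores
  transition/transversion bias; for the allelic regime (Ks ≪ 0.1)
  the difference is negligible, and results on real data will differ
  slightly from pipelines built on other Ka/Ks engines.
* The builtin similarity scorer is quadratic per candidate pair and
  intended for testing and small genomes; production users should
  import a precomputed hit table.
* The NB Wald test with moderated method-of-moments dispersion is
  deliberately simple; it is slightly conservative at three
  replicates and does not implement DESeq2's trended shrinkage or
  outlier handling.
* Cross-chromosome allele pairs (translocations between haplotypes)
  are rejected by design; genomes with real haplotype translocations
  need the chromosome map adjusted accordingly.
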