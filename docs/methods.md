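# Methods

## Problem and model

`metkern` treats metabolic network completion as supervised link
prediction.  The known part of the enzyme graph Γ = (V, E) supplies labeled
examples — edges are positives, sampled non-edges negatives — and per-gene
genomic data supply the features, always through kernels, so heterogeneous
data types live in one framework.  Two estimators are implemented on top of
the same kernel layer.

### Gene-level kernels

* **RBF** (expression, phylogenetic): `K(x,y) = exp(−‖x−y‖²/2σ²)`.  The
  bandwidth σ defaults to the median pairwise Euclidean distance of the
  input table (median heuristic): it is scale-free, deterministic, and
  reproducible without any reference to unpublished parameter choices.  It
  can be overridden per kernel.
* **Linear** (localization): plain dot products of binary indicator
  vectors; the value is the number of shared localizations.
* **Spectrum** (n = 3 by default): dot products of overlapping n-gram
  count vectors.  n-grams containing a non-standard residue (X, B, Z, `*`,
  U, O) are skipped; sequences shorter than n contribute a zero vector.
* **Motif**: dot products of per-sequence motif match counts.  The motif
  syntax is a deliberately small eMotif-like subset — literal residues,
  `[bracket]` classes over the 20 standard amino acids, and `.` as a
  single-position wildcard.  Matches are counted at every start position
  (overlaps included); ambiguity codes never match, including under `.`.
* **Log-E** (Pfam-style): features are `max(0, −log₁₀ E)` per domain model
  (absent hits = 0), kernel = dot product.  Smaller E-values mean stronger
  hits and larger features, and nonnegativity keeps the dot products
  interpretable as shared domain content.

All six kernels are cosine-normalized (`K'_ij = K_ij/√(K_ii K_jj)`) before
any combination or pairwise lifting.  Without a common scale a weighted sum
of kernels is meaningless (a raw spectrum kernel has entries in the
thousands, an RBF kernel in [0,1]).  Normalization preserves PSD and is
idempotent.  PSD is validated via the spectrum (`assert_psd`); matrices
failing the tolerance `λ_min ≥ −1e−8 · λ_max` are repaired by clipping
negative eigenvalues, and the repair is reported.

### Pairwise lift

A gene kernel k′ induces the symmetrized Kronecker kernel on unordered
pairs, `K((a,b),(c,d)) = k′(a,c)k′(b,d) + k′(a,d)k′(b,c)`, implemented
exactly in this form (no ½ factor; some authors include one, which only
rescales the Gram matrix and leaves SVM solutions and rankings essentially
unchanged).  Gram blocks are assembled from four indexed submatrix
products, so memory is |rows|·|cols| and the n²×n² Kronecker product never
exists.  Because the lift is multiplicative, kernel combination must happen
at the gene level *before* lifting — the test suite asserts that lifting a
sum is not the sum of the lifts.

### PKMR

Penalized kernel matrix regression regresses a graph-derived target kernel
G on the genomic kernel K over training genes:

    B = (K + λI)⁻¹ G (K + λI)⁻¹,    score(u,v) = kᵤᵀ B k_v

with `k_u` the similarities of gene u to the training genes (transductive
columns for held-out genes).  At λ = 0 with invertible K this reconstructs
G exactly on the training set; λ (default 1.0) trades reconstruction
against shrinkage, and ‖B‖ is non-increasing in λ.  Three targets are
available: raw 0/1 adjacency, ±1 adjacency, and the graph diffusion kernel
`expm(β(A − D))` (default, β = 1), which is PSD by construction; adjacency
targets are PSD-repaired before the solve.  The default target is the
diffusion kernel because it needs no repair and encodes graph proximity
smoothly.

A consequence worth knowing: with a diffusion target, PKMR can rank
held-out pairs above chance *even with an uninformative genomic kernel*,
because reconstructing the target amounts to common-neighbor link
prediction from the training edges alone.  This is legitimate use of the
graph prior, not leakage (only training-fold edges enter the target), but
it means per-kernel AUC under PKMR measures kernel + graph prior, whereas
under pSVM it measures the kernel alone.  The null checks in the test
suite therefore use pSVM.

### pSVM

A soft-margin SVM on pairs with precomputed Kronecker Gram matrices; the
pair feature map is never materialized.  The dual is solved by libsvm
(scikit-learn `SVC(kernel="precomputed")`), but the module's contract is
the dual solution itself: signed coefficients αᵢdᵢ with |αᵢdᵢ| ≤ C,
Σαᵢdᵢ = 0, bias b, and decision `f(p) = Σ αᵢdᵢ K(pᵢ,p) + b`.  The tests
verify KKT conditions and agreement of the dual objective with an
independent SLSQP solver on small instances.  Defaults C = 1.0 and
KKT tolerance 1e−3 are library-typical and recorded in every report row.

### Evaluation protocol

* **Balanced datasets**: all edges (or a uniform subsample) as positives,
  an equal number of uniformly sampled non-edges as negatives; an odd
  budget gives the extra unit to the positives (5149 → 2575/2574).
  Negatives are drawn once per experiment with a recorded seed, so folds
  are comparable.
* **Stratified k-fold CV** (k = 10): each pair is scored exactly once by a
  model trained without it; the pooled out-of-fold scores give one AUC and
  one error count per cell.  Pooling (rather than averaging per-fold AUCs)
  gives the confidence interval a single well-defined error count.
* **AUC**: Mann–Whitney form via midranks; ties credited ½.
* **Weighted combination**: Wₙ = cross-validated AUC of the method with
  kernel Kₙ alone.  In combined-kernel cells the weights are recomputed on
  each outer-fold training set from an inner CV (default 3-fold) and
  frozen before the fold is scored — nested CV, so no information from
  held-out pairs reaches the weights.
* **Confidence intervals** (Cortes–Mohri style, distribution-independent):
  the variance of the AUC is computed over the uniform ensemble of
  (ranking, threshold) classifications of m positives and n negatives with
  exactly k errors.  With x false negatives and y = k − x false positives
  the allocation weight is `C(m−x+y, y)·C(n−y+x, x)`; within the two
  threshold blocks the interleavings are uniform, so the conditional AUC
  mean is `[(m−x)(n−y) + ((m−x)y + x(n−y))/2]/mn` and the conditional
  variance is the null Mann–Whitney variance `pq(p+q+1)/12` of each block.
  Mean and variance are obtained by exact summation over x (log-space
  binomials), avoiding any closed-form transcription; the implementation
  reproduces the closed-form expectation identity exactly and, at
  m = 2575, n = 2574, k = 902, yields [0.934, 0.946] at AUC 0.940 — the
  published interval width at exactly this operating point, with k inside
  the published 750–1851 error range.  The interval is AUC ± 1.959964·σ,
  clipped to [0, 1].  k is counted at decision threshold 0 for pSVM and at
  the median score for the ranking-only PKMR.

  Coverage: the interval's guarantee is tied to its error-count ensemble,
  not to a sampling model.  Empirically (binormal scores, 100 + 100
  examples), nominal 95% intervals cover the true AUC ~92% of the time at
  an operating accuracy of AUC 0.94 and over-cover above it, but
  under-cover at moderate accuracies (~75% at AUC 0.76).  The coverage
  check therefore simulates the high-accuracy regime in which these
  intervals are actually used.

## Synthetic studies

The generator emulates the *shapes and statistical structure* of the
classic yeast data, not its biology.  Per gene, a latent vector
z ∈ R⁶ drives everything:

* **Graph**: edge (i,j) with probability `logistic(a − b‖zᵢ−zⱼ‖)`,
  b = 4.0; the intercept a is calibrated by bisection so the expected
  density is 0.06.  b = 0 degenerates to Erdős–Rényi (used as a
  degree-homogeneous control).
* **Feature tables**: expression (157-dim numeric), localization (23-dim
  binary), phylogenetic (145-dim binary) are noisy linear /
  thresholded-linear maps (noise σ = 0.8) of *channel-specific 4-of-6
  dimensional views* of z.  The rotating views make the channels
  complementary: no single kernel sees the whole geometry, so the weighted
  combination genuinely beats each single kernel rather than merely
  matching the best one.
* **Sequences**: i.i.d. uniform residues (length 60–120), k-means clusters
  of z (k = 8) each own a random signature motif (length 4–6) inserted
  twice into a carrier's sequence with probability 0.8; the log-E table is
  a noisy readout of per-gene motif-hit strengths.  Interacting genes are
  latent-close, hence often share a cluster and its planted n-grams.

Everything is bit-reproducible: each stage has its own generator seeded
from (seed, stage-tag).

Default sizes are desk-scale by design: 120 genes give ~430 edges, ~860
balanced pairs, and pair Grams below 1000×1000, so the complete ten-seed
default study (both methods, all kernels, nested weighting, permuted null)
runs in a few minutes on one CPU.

What passing tests on these data do **not** show: robustness to real
sequence evolution, domain architecture, annotation noise, or the extreme
degree heterogeneity of real metabolic networks.  One protocol-level
caveat carries over to real data: pairwise CV shares genes between folds,
so on degree-heterogeneous graphs any method (even with an uninformative
kernel) can score above chance by recognizing hub genes.  The permuted-
label null and the Erdős–Rényi control both isolate this effect in the
test suite.

## Numerical and design choices

* Symmetry tolerance 1e−10 (inputs re-symmetrized as (K+Kᵀ)/2); PSD
  tolerance `λ_min ≥ −1e−8·λ_max`, repair by eigenvalue clipping.
* Kernel files are written with 17 significant digits and parsed with
  round-trip float precision, so write→read is bit-faithful.
* Canonical pair order is lexicographic on opaque string gene ids;
  self-pairs are valid for the Kronecker formula but excluded from
  datasets (enzyme self-interaction is out of scope).
* Gene-level kernels are combined *before* the pairwise lift (the lift is
  multiplicative, so the order matters).
* λ grid {0.01, 0.1, 1, 10} is available for inner-CV selection; the
  default λ = 1 is used throughout the reported studies for
  reproducibility.
* The interaction graph container is a small dedicated dataclass rather
  than a general graph library: the only operations needed are canonical
  edge storage, membership and non-edge enumeration, and the container
  enforces the canonical-pair and no-self-loop invariants directly.
* Known limitations: PKMR's closed form is O(n³) in training genes and is
  applied transductively (the kernel must already contain candidate
  genes); the pSVM path materializes per-fold pair Grams, which bounds
  practical dataset sizes at a few thousand pairs; the motif language is a
  subset of full eMotif syntax; no probability calibration, only rankings
  and decision signs.
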