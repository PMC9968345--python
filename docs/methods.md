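# Methods

This note documents the models and numerical choices behind `scnavar`,
what the synthetic benchmark does and does not emulate, and the known
limits of the approach.

## Signal model

The input is an m × n matrix D of log₂(count + 1) expression, cells on
rows, genes ordered by genomic coordinate (chromosomes 1–22 and X; Y and
MT are excluded because expression-based copy-number inference on them is
unreliable). A cell's profile along the gene axis is treated as a noisy
sampling of a piecewise-constant copy-number function: amplifications
raise expression of the genes they span, deletions lower it, and all
cells in a copy-number clone share the same breakpoints. That shared-
breakpoint assumption is what makes the segmentation *joint*: every
cell's profile is one channel of evidence for a single breakpoint set.

## Preprocessing and baseline

Cells with fewer than 200 detected genes (count > 0) and genes expressed
in under 1% of the remaining cells are removed; genes without a
coordinate and cell-cycle genes (packaged list) are dropped; genes are
sorted by (chromosome, start). The 200-gene threshold presumes a full
transcriptome panel; for reduced panels (e.g. the synthetic benchmark's
2000-gene genome) it should be scaled down proportionally (the benchmark
driver uses n_genes/100).

Confident non-malignant cells are seeded with a one-sided single-sample
Mann–Whitney–Wilcoxon test of each packaged stromal/immune signature
against the rest of the cell's genes. The enrichment score is the logit
of the common-language effect size, NES = log₂(pU/(1−pU)) with
pU = U/(n₁n₂); a cell qualifies when its best signature has P < 10⁻¹⁰
and NES > 1 (i.e. pU > 2/3), and at most 30 cells are kept. The exact
Mann–Whitney null is used when n₁n₂ ≤ 10⁴ and the profile has no ties; a
tie-corrected normal approximation otherwise.

The copy-number baseline b is the per-gene **mean** over the confident
normals, and the relative matrix is D_r = D − bᵀ. The mean rather than
the median is deliberate: with droplet-sparse data (>90% zeros) the
median of up to 30 mostly-zero profiles collapses to zero for most
genes, leaving each gene's composition bias in every cell; those shared
offsets masquerade as breakpoints shared by all channels and measurably
destroy segmentation precision. The median remains available
(`baseline_statistic="median"`) for deeply sequenced plate-based data.
When no confident normal is found the sample is assumed pure: cells are
Ward-clustered (k chosen by the Calinski–Harabasz index over k = 2..10)
and each gene is shifted by an N(0, sd) draw with its within-cluster sd.

For the segmentation track only, each gene of D_r is divided by its sd
across cells, floored at 0.3. This makes every gene contribute
comparable evidence to the multichannel merge cost — otherwise a handful
of highly expressed, high-variance genes dominate it — while damping
near-silent genes instead of amplifying them. Segment means, CNV calls
and all reported values stay on the unstandardized log-ratio scale.

## Edge-preserving smoothing

Each cell's signal is regularized by T explicit descent steps on the
discontinuity-adaptive functional Σ φ(u_{i+1} − u_i), φ(x) = log cosh(x),
plus an optional quadratic fidelity term:

    u_i ← u_i + dt·[tanh(u_{i+1} − u_i) − tanh(u_i − u_{i−1})]
              − dt·γ·(u_i − u⁰_i)

with Neumann boundaries, independently per chromosome. Defaults:
T = 100, dt = 0.1 (dt ≤ 0.5 enforced for stability), γ = 0.01. Because
tanh saturates, large jumps diffuse much more slowly than small-scale
noise. With γ = 0 the scheme is in discrete divergence form and
conserves the per-chromosome mean exactly. The iteration count is kept
moderate on purpose: stronger smoothing (or exact 1-D TV denoising, which
was evaluated) erases the weak per-cell steps of sparse data faster than
it erases noise, because per-cell smoothing is incoherent across cells
while the signal only becomes significant in the joint statistics.

## Joint segmentation

Greedy hierarchical merging of adjacent regions, starting from one
region per gene. The merge cost
λ̃ = |R₁||R₂|/(|R₁|+|R₂|)·‖u₁ − u₂‖² equals exactly the increase of the
energy's data term caused by the merge (verified to 1e−9 against brute
force in the tests), so the dynamically raised λ schedule is monotone.
Stopping: merging continues while the λ jump is ≤ β·ν and stops at the
first larger jump, where ν is the sum over cells of the per-cell sd of
the smoothed matrix. Larger β therefore yields coarser segmentations by
construction. Merging never crosses chromosome ends; the λ schedule and
ν are global across the genome so all chromosomes stop on a common
scale. ε (the λ bump) is 1e−9·max(ν, 1): strictly positive, negligible
against real costs. Ties in the minimal cost are broken leftmost. The
implementation is a doubly-linked region list plus a lazily invalidated
heap, O(n log n) per chromosome with O(m) per merge.

β defaults: 0.5 for the sample-level segmentation, 3.0 for per-clone
re-segmentation.

## Classification and CNV calling

The CNA matrix substitutes every value with its cell's mean over the
containing region. Cells are Ward-clustered into two groups on CNA rows;
the group with more confident-normal seeds is non-malignant (ties go to
the group with smaller mean |CNA|; cluster vote overrides seed identity
for individual seeds). With no seeds the sample is labelled pure, all
cells malignant. The final CNA matrix subtracts the per-gene mean of the
identified normals.

Per-segment per-cell means are modelled as a five-component truncated-
normal mixture (deletion 0, loss 1, neutral 2, gain 3, amplification 4).
Initial parameters: means (−1, −0.4, 0, 0.4, 1), sds 0.15, weights
(0.05, 0.1, 0.7, 0.1, 0.05), truncation bounds at midpoints between
adjacent means (±∞ at the extremes), all configurable. EM fits means,
sds (floored at 0.02) and weights; the M-step maximizes the expected
complete-data log-likelihood exactly per component from the sufficient
statistics (Σr, Σrx, Σrx²) with a bounded 2-parameter solve, falling
back to the current parameters when no improvement is found — this keeps
the observed log-likelihood monotone, which naive moment updates do not
guarantee under truncation. Cells get max-posterior states; segments get
the majority vote across cells, ties resolved toward neutral.

## Subclones

Malignant CNA rows are clustered with Louvain communities (seeded, via
networkx) on a shared-nearest-neighbor graph: mutual-kNN edges weighted
by Jaccard overlap of neighbor sets, k = 20 by default (with hundreds of
malignant cells, k = 10 fragments the graph into many small communities
and degrades assignment accuracy). Each community is re-segmented with
β = 3.0 and called with a mixture fitted on the pooled malignant segment
means. Same-state segments closer than 10 Mb are merged; alterations in
different clones match when a start or end is within 10 Mb, sizes differ
by under 40% and the state is identical; matching is closed transitively
across clones. Groups present in all clones are clonal, in one clone
specific, otherwise shared. Clones with no specific alteration are
dissolved smallest-first, their cells reassigned to the surviving clone
with the highest Pearson correlation of mean CNA profile, and categories
recomputed. The clone tree is neighbor joining on Manhattan distances
between gene-level consensus state vectors, rooted at an all-neutral
pseudo-clone, serialized as Newick.

## Synthetic benchmark

The generator emulates droplet scRNA-seq of a tumor with planted truth:

* **Base counts**: negative-binomial (Gamma–Poisson) with dispersion
  0.5 and a two-component gene-mean population — 13% expressed genes
  with log-normal(1.0, 1.2) means and a silent majority with
  log-normal(−5.5, 1.5) means — giving ~92% zeros overall. The two-
  component shape mirrors real transcriptomes, where sparsity comes from
  a silent gene majority rather than from extreme noise on every gene; a
  single log-normal calibrated to the same sparsity on a 2000-gene panel
  leaves counts so low that planted deletions disappear entirely under
  integer rounding.
* **Genome**: one chromosome per ~1000 genes, gene starts 100 kb apart,
  so benchmark-sized alterations fit inside a chromosome.
* **Alterations**: an aneuploid fraction of cells (default 0.6), 1–10
  non-overlapping alterations of 50–1000 genes; each scales counts by
  (1+ρ) (amplification) or 1/(1+ρ) (deletion) with ρ ~ U(0, α), rounded
  back to integers. Scenario I is purely clonal; scenario II assigns the
  first ⌈n/3⌉ alterations to both subclones (truncal) and alternates the
  rest, so clonal and subclone-specific events always exist. Planted
  breakpoints flush with a chromosome end are excluded from the recorded
  truth (no observable step exists there). Diploid cells are bit-
  identical to the base matrix.
* **Dropout**: gene g's non-zero counts are zeroed with probability
  p_g = 1/(1 + exp(−k(x0 − ln(μ_g + 1e−8)))), μ_g the raw mean count,
  k = 1; at x0 = 0 this replaces roughly a third of non-null values.

What the generator does **not** emulate: cell-type-specific expression
programs, library-size gradients, doublets, ambient RNA, or correlated
gene modules. Passing benchmarks therefore demonstrates the machinery
recovers planted copy-number structure under realistic sparsity and
noise — not performance on any particular real dataset.

## Evaluation harness

Breakpoints are scored with greedy one-to-one matching within a gene
tolerance (default 20): a prediction cannot absorb two truths, and
empty-vs-empty is a perfect score. The DP pruner finds the exactly
RSS-optimal size-k subset of any candidate set (verified against
exhaustive search up to 12 candidates); sweeping k yields a
precision–recall curve summarized by the trapezoidal AUC over achieved
points. Inferred profiles are compared with external references by
sampling the containing segment value at every 1-Mb reference position
and computing Pearson correlation over shared positions.

## Known limits

On 200-cell, 2000-gene matrices at ~92% sparsity, per-cell regional
steps are ~0.1 log₂ units against per-gene noise of ~1. Amplifications
with ρ ≳ 1 are recovered reliably; deletions are much harder (deleting a
mostly-zero signal barely moves it, and ρ ≲ 0.3 alterations are erased
by integer rounding already in the generator). The greedy merge also
freezes boundary positions at small region sizes where the local
signal-to-noise ratio is far below one, which displaces some boundaries
by tens of genes. Under these study conditions mean breakpoint F1 at
tolerance 20 plateaus around 0.6–0.7, and two-subclone recovery succeeds
in most but not all runs — the per-clone β = 3.0 re-segmentation can
return no breakpoints for ~50-cell clones, dissolving a true clone.
Richer data (more cells, deeper counts, or stronger alterations) moves
all of these numbers up sharply, as the acceptance script's classification
scores (≈0.99) and the 5σ-step segmentation tests (F1 = 1.0) show.
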