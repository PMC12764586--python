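# Methods

## Pipeline model

`graphtad` calls TADs on one chromosome at a fixed resolution. The
input is a symmetric, non-negative `n × n` contact matrix; bin *i*
covers the bp interval `[i·res, (i+1)·res)` and all interval output is
0-based half-open (BED convention). The pipeline has five stages.

**1. Windowing.** High-resolution chromosomes produce matrices too
large to embed whole, so the matrix is processed in `ns = ⌈n/t⌉`
windows (threshold `t = 5000` bins) with core width `p = ⌈n/ns⌉`.
Cores tile `[0, n)` disjointly; the last core absorbs the remainder
when `n` is not divisible by `ns`. Every window after the first is
extended left/top by `q = 3 Mb` (`q_bins = ⌈q/res⌉`, clamped at bin 0)
so a domain straddling a core boundary is seen whole by at least one
window. The extension is square: the matrix is symmetric, so the
"top and left" extension is the principal sub-block over the extended
bin range.

**2. Smoothing.** Each extracted sub-matrix is denoised with an
isotropic 2-D Gaussian filter, σ = 1 bin by default, kernel truncated
at 4σ, reflect boundary. One bin of smoothing removes shot noise
without blurring boundaries at 5–40 Kb resolutions; σ is configurable
and 0 disables the filter. Reflect boundaries preserve constants and
total mass for interior features, and the output is re-symmetrized to
remove floating-point skew.

**3. Embedding (NetMF).** The smoothed sub-matrix becomes a weighted
graph: bins are nodes, entries edge weights. The diagonal is zeroed by
default — a self-contact carries no pairwise proximity and would
otherwise dominate node degrees and the graph volume (a
`keep_diagonal` flag retains it). Zero-degree bins cannot be embedded
(the walk transition matrix is undefined there); they bypass embedding
and are forced to the noise label downstream.

For context window `T` (default 2) and negative-sampling constant `b`
(default 1) the exact path computes the DeepWalk matrix
`χ = vol(G)/(b·T) · (Σ_{r≤T} P^r) D⁻¹` with `P = D⁻¹A` by dense
powers, then symmetrizes `(χ+χᵀ)/2`. The large-window path instead
takes the top-`h` eigenpairs (largest |λ|, default `h = 256`) of the
normalized adjacency `D^(−1/2) A D^(−1/2)` and forms
`χ̂ = vol(G)/b · D^(−1/2) U_h (T⁻¹ Σ_r Λ_h^r) U_hᵀ D^(−1/2)`; with a
full eigenbasis this reproduces the exact matrix to ≤ 1e−8. The
`auto` variant uses the exact path for ≤ 4000 active nodes and
`T ≤ 4`, the eigen path otherwise.

The embedding is the rank-`a` factorization of `L = log max(χ, 1)`
(the shifted-PPMI floor keeps the log finite and non-negative), node
vectors `U_a √Σ_a` with `a = e_eff = min(e, rank(L), m_active − 1)`
and target width `e = 455`. Because `L` is symmetric, its SVD is
computed from the symmetric eigendecomposition (singular values |λ|,
left vectors the eigenvectors) — fully deterministic, no randomized
solver. Magnitude ties order positive eigenvalues first, and each
retained vector's largest-|entry| component is made positive, fixing
the column signs across platforms; sign flips are reflections, so
downstream Euclidean distances — and therefore the clustering — are
unaffected. A sub-matrix whose χ is entirely ≤ 1 yields a zero
embedding with a warning.

**4. Clustering and candidate intervals.** Embedded bins are
clustered with HDBSCAN (Euclidean metric, `min_cluster_size = 5`,
`min_samples = min_cluster_size` unless set) via scikit-learn's
implementation; the mutual-reachability stage it relies on — core
distance to the k-th nearest other point, pairwise value
`max{core_p, core_q, d(p,q)}` — is also implemented directly as a
testable contract and validated against it on small inputs. HDBSCAN
is deterministic for fixed input, so the whole call path is seedless.
Windows with fewer active bins than `min_cluster_size` are all noise;
coincident embeddings (zero spread) form a single maximally dense
cluster.

Clusters live in embedding space and need not be genomically
contiguous, but a TAD is an interval: each maximal run of consecutive
bins with the same non-noise label becomes one candidate, noise
breaking runs. Candidates are then size-filtered to the closed range
[100 Kb, 5 Mb], the typical mammalian TAD span; the filter changes
membership only, never coordinates. `min_cluster_size = 5` keeps a
100 Kb domain (10 bins at 10 Kb) able to survive run-splitting at
common resolutions.

**5. Stitching.** Window `i+1` re-embeds the `q` region it borrows
from window `i`, so both windows may call domains there. For each
overlap region the TAD Quality score decides: TQ = mean contact over
intra-domain bin pairs minus mean contact over pairs lying in two
different domains, computed after clipping the competing calls to the
region (the comparison stays local to the disputed bins; pairs
touching unassigned bins are ignored; an empty pair class contributes
0). The side with the higher TQ keeps its full, unclipped intervals;
the loser's region-intersecting intervals ("intersecting" = overlap by
≥ 1 bin) are dropped; an exact tie keeps the newer window's calls, so
duplicated identical calls survive exactly once. Any residual overlap
after the pairwise passes drops the later interval — the earlier one
has already been validated — giving a deterministic, sorted,
non-overlapping final set.

## Evaluation statistics

**MoC.** For partitions P, Q with domain counts N_P, N_Q and bp
overlaps F_ij: `MoC = (Σ_ij F_ij²/(|P_i||Q_j|) − 1)/(√(N_P N_Q) − 1)`,
defined as 1 when both partitions are a single domain. Symmetric, in
[0, 1], 1 iff identical.

**Adjusted R² profile.** At each genomic distance `d` (1 bin to
1.5 Mb by default) the contacts `X_i = cm[i, i+d]` are grouped by the
domain containing both endpoints; pairs straddling a domain edge or
outside every domain form one background group. With `N` pairs and
`N_t` domains of bp span ≥ d,
`r² = 1 − [SS_res/(N − N_t − 1)]/[SS_tot/(N − 1)]`. Of the two
possible readings of the group mean we use the mean over pairs *at
the same distance* within a region — this makes a matrix that is
constant within each true domain score exactly 1 at every defined
distance, and an empty domain set score exactly 0, which are the
limits the statistic is meant to have. Distances with zero total
variance or `N − N_t − 1 ≤ 0` are reported missing (NaN), never 0.

**Boundary profiles.** Mean piecewise-constant signal per offset bin
over ±250 Kb around each boundary (odd bin count centers one bin on
the boundary), averaged over boundaries; uncovered bp count as 0,
offset bins truncated by the chromosome start are averaged over their
covered part only.

**Recovery rate** counts a reference domain as recovered when some
detected domain reaches bp-Jaccard ≥ 0.5 with it; **split/merge
events** require each fragment to lie ≥ 80 % of its length inside the
parent and the fragments jointly to cover ≥ 80 % of the parent. Both
thresholds are package defaults for a criterion the literature leaves
unspecified; they are exposed as parameters.

## Synthetic generator

`simulate_hic` emulates the block-plus-decay phenotype of real
single-chromosome maps: ground-truth domains with sizes uniform in
250 Kb – 1.75 Mb (the bulk of the mammalian TAD size distribution)
tile the chromosome, optionally separated by short unorganized gaps
(`gap_prob = 0.2`); the mean contact is
`μ_ij = β·exp(−|i−j|/L)·γ^[same domain]` with background scale
`β = 10`, decay length `L = 100` bins and intra-domain boost `γ = 4`;
observed counts are `Poisson(μ) + ν·|N(0,1)|` with additive noise
scale `ν = 1` by default, symmetrized, fully deterministic per seed.
Increasing ν mimics graded benchmark noise levels and provably
shrinks the intra/inter contrast.

What the generator does *not* emulate: loops and compartments,
unmappable-bin dropout, coverage biases that matrix balancing
normally removes, nested (hierarchical) domains, and the specific
noise-level semantics of any published benchmark — it is a synthetic
stand-in. Passing end-to-end tests therefore demonstrate that the
pipeline recovers clean block structure under decay and moderate
noise, not performance on real tissue Hi-C.

`perturb_partition` produces controlled split / merge / boundary-shift
variants of a truth partition as fixtures for the rearrangement and
concordance metrics.

## Numerical and design notes

- Matrices are stored dense; the windowing bound (5000 bins) caps the
  largest object at ~200 MB, and the test and verification scales are
  hundreds to thousands of bins.
- Asymmetric dense input is stored as `(M + Mᵀ)/2`; Hi-C maps are
  symmetric by construction and residual asymmetry is dump rounding.
  NaN becomes 0 on read (unmappable bins are conventionally empty and
  downstream degree math needs finite values).
- COO input treats `(j,i)` records as duplicates of `(i,j)` and sums
  them; upper-triangle dumps are the expected dialect.
- The end-to-end call path contains no randomness: the
  eigendecomposition-based factorization and HDBSCAN are
  deterministic, so repeated runs are byte-identical. Only the
  simulator takes a seed.
- Degenerate inputs: a matrix below the window threshold runs as a
  single window with no extension; an edgeless window yields no
  domains; overlap regions shorter than 2 bins skip TQ adjudication
  (the residual-overlap rule still applies).
- Known limitations: no hierarchical/nested domain output, no matrix
  balancing (ICE/KR) — input is taken as-is, single chromosome per
  call, no `.hic`/`.cool` binary readers.

## Verification scales

The oracle suites run on graphs of ≤ 12 nodes (dense brute-force
DeepWalk powers), point sets of ≤ 50 (mutual reachability), matrices
of ≤ 40 bins (per-pair adjusted-R² and TQ oracles); the end-to-end
and stitching checks use 600- and 1200-bin simulated chromosomes at
10 Kb — sizes at which every stage, including the full 455-dim
embedding, runs in seconds while exercising multi-window stitching.
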