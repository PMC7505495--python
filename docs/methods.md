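# Methods

This note documents the models, numerical choices, and limitations behind
`scretina`. Notation: `M` is the cell × gene unique-transcript count
matrix, `|Ci|` and `|Gj|` its row/column totals, `κ` the grand total,
`κ̄ = κ/n_cell` the average library size, and `N` the cluster × gene
contingency table induced by a clustering `T`.

## Synthetic data: what it emulates and what it does not

The generator is the test bed for every stage, so its defaults encode the
study conditions the statistics assume.

* **Counts.** Each cell's per-gene means are its cluster's profile
  renormalized to a library size drawn log-normally (median ≈ 2,000
  transcripts, log-sd 0.35 — typical of 10x v2 chemistry). Counts are
  gamma–Poisson (negative binomial) with dispersion 0.1, the usual
  magnitude of UMI overdispersion.
* **Mitochondrial structure.** A beta-distributed share of each cell's
  expected library is reallocated to mitochondrial genes: Beta(2, 38)
  (mean 5%) for healthy cells, Beta(8, 12) (mean 40%) for a configurable
  "damaged" subpopulation. This gives the rank-size filter a real
  subpopulation to remove, with ground-truth labels.
* **Doublets.** A fraction of cells (the `doublet_rate`) absorb the full
  counts of a second parent drawn from a different cluster — sums, not
  averages, matching droplet physics — so their libraries are
  stochastically larger and they co-express two classes' markers.
* **Regional shifts.** A designated gene set gets log2 fold-changes
  (defaults ±1–2) applied to the foveal copy of each profile.
* **Developmental drift.** Cluster proportions change linearly with age
  (progenitors giving way to neurons), and trajectory genes follow
  **linear** monotone trajectories between a baseline (log-uniform on
  2–30, TPM-like units) and a 4–12× higher or lower level, half rising
  and half falling, with Gaussian noise of sd = 5% of each gene's range.
  Linear trajectories with a baseline spread wider than the typical
  movement reproduce the banded Spearman self-correlation structure of
  real developmental bulk series (adjacent ages ≈ 0.8–0.95, decaying over
  weeks) while letting every trajectory gene clear the `dnr > 0.5`
  selection; log-linear trajectories with fold-changes large enough for
  selection scramble the rank structure and were rejected for that
  reason.
* **Embedding.** Each cluster is an isotropic 2D Gaussian (sd 0.8)
  whose center lies on a circle of radius 8.5 inside the density grid;
  draws falling outside the grid are resampled.

One `numpy` generator seeded from `SimConfig.seed` drives all draws in a
fixed order, so outputs are bit-reproducible.

Not emulated: ambient RNA, chemistry/batch effects, spliced/unspliced
counts, nested subtype structure within classes, and realistic gene-gene
correlation beyond the cluster means. Passing tests therefore show that
the statistics behave correctly **under their own model assumptions**, not
that they are robust to artifacts the generator omits.

## Cell filtering

For detected-gene counts (low tail) and mitochondrial fraction (high
tail), a LOESS curve is fit to the sorted rank-size distribution and
evaluated at 10,000 evenly spaced relative positions. The cutoff sits at
the first point past the 5th / 95th percentile where the discrete second
difference of the smoothed curve changes sign — the inflection marking
the start of a distinct subpopulation. Implementation notes:

* Local-**linear** LOESS (statsmodels) at span 0.3; curvature below
  `max(1e-8·range(curve), 1e-12·max|curve|)` counts as flat, so constant
  or near-constant features never trigger noise inflections.
* When no inflection exists, the cutoff falls back to the percentile
  itself with a warning. A consequence accepted deliberately: re-running
  the filter on already-filtered data (where no damaged subpopulation
  remains) trims up to ~5% per criterion via the fallback, so strict
  two-pass idempotence is not attainable with this fallback rule; the
  test suite asserts the achievable bound instead.
* Survivors split into high/low expression pools at `|Ci| >` 800
  (adult-like) or 400 (organoid-like); mitochondrial and ribosomal genes
  are excluded from embedding/clustering gene views but never from
  library totals.

## Normalization and gene scores

Row scaling by `κ̄/|Ci|` exactly conserves per-cell sums (checked to
rel. 1e-9); `σ` in the CoV score is the population standard deviation and
`μ` the plain mean, with no small-sample correction. `dnr` operates on
gene × sample bulk tables; `cov`/`mnr` on cell × gene counts. PCA is
mean-centered with a deterministic sign convention (largest-magnitude
loading positive) and truncates with a warning when components exceed the
data rank.

## Clustering

Exact KNN (Euclidean on PCA scores) below 20,000 cells, seeded
approximate search (pynndescent) above; the directed KNN relation is
symmetrized by union into a simple graph. Infomap (python-igraph) runs 10
trials at a fixed seed and keeps the lowest-codelength two-level
partition. Merging recomputes cluster-mean profiles over the
mnr-selected genes at every step; at each θ (0.99 down to 0.90 in 0.01
steps) the above-threshold pair graph is replaced by its connected
components — the inclusive rule — until stable. Purity of a cluster under
an 85% resample is the mean fraction of its members landing in the
best-overlapping re-clustered community; stability is the mean fraction
of member pairs still co-clustered. Both operationalizations are this
package's choices (the originals defer to prior literature).

## Density maps and divergence

The KDE uses a separable Gaussian product kernel with per-axis Scott
bandwidths (`n^(-1/6)·sd`), evaluated on the fixed 341 × 341 grid; the
bandwidth from the full fit is reused for every subset or
transcript-weighted density so that densities are comparable. Points
outside the grid raise rather than clamp. `D_KL` uses base 2 so the
Jensen–Shannon divergence lands exactly in [0, 1]; cells where both
probability masses vanish contribute zero. The isodensity contour at
`Ŝ = 2×10⁻⁴` is plotting-only and enters no statistic.

## Developmental age

Features are Spearman correlations on `log2(1+x)` over the shared
dnr-selected genes (ranks make the scale nearly irrelevant; ties get
average ranks). Because features outnumber reference samples the design
is always singular: the final model takes the minimum-norm least-squares
solution (so a noise-free reference is interpolated exactly), while
leave-one-out refits use a light ridge (α = 1e-4), which stabilizes
prediction at the held-out sample without affecting in-sample behavior.
LOO removes the held-out sample's row but keeps its feature column by
default (`loo_drop_column=True` switches to dropping both). Replicate
averaging is an explicit preprocessing flag. Predictions outside the
reference age range are returned but flagged as extrapolations.

## Multiplets

Scores are raw count sums (a normalized mode exists for sensitivity
analysis). Thresholds sit at the minimum-density valley between the two
main modes of a KDE of `log2(1+score)`, constrained above the lower mode;
unimodal distributions fall back to the 99th percentile with a warning,
and manual overrides win. All threshold comparisons are strict. The
packaged marker table carries ten retinal cell-class sets; sets with no
genes in a matrix are skipped by the estimator but error when supplied
explicitly.

## Regional statistics and classifier

Foveal (and organoid) cells are rescaled to the peripheral library size
before comparison. Half of each region's cluster cells are held out; on
the rest, overexpression requires `log10(μ_Tk/μ_To) > 0.1`, `μ_Tk > 1`
and `μ_To < 10` (library-normalized units). Mann–Whitney U p-values are
computed from a tie-corrected normal approximation with continuity
correction directly in log space, so values below the double-precision
underflow (~1.8×10⁻³⁰⁷) remain meaningful log10 bounds; Bonferroni
adjustment is an addition in log space.

The classifier `r = tanh((1/d)Σβ_j x_j)` is fit by L-BFGS (gradient
based; max 5,000 iterations, ftol 1e-6) on standardized expression of the
overexpressed genes, equal region samples of at most 1,000 cells,
squared-error loss with L2 weight 1e-3, β initialized at 10% of the
specificity index. The verdict's χ² test is a goodness-of-fit of the
(peripheral-overlapping, foveal-overlapping) counts against an even
split — the construction is under-determined in the source description
and chosen here.

## Closeness and z-distance

`dge` ranks genes with ε = 0.5 inside the logs; PCA is fit on all adult
cells of the type plus an equal-size random organoid subsample, remaining
organoid cells are projected. The adult (PC1, PC2) Gaussian is fit by
graphical lasso (α = 0.01 — mild shrinkage; the self-closeness of a
10,000-cell reference reproduces the χ²₂ tail 1−e^(−4.5) ≈ 98.9% within
0.1 points). The robust z-distance standardizes Euclidean distances to
the reference mean profile by 1.4826·MAD of the reference's own
distances; the same routine serves time-course references.

## Entropy statistics and permutation testing

`spg` follows the printed joint-term sum
`H(T|Gj) = −Σ_k P(Tk,Gj) log2 P(Tk,Gj)` by default; this is not the
standard conditional entropy (which would renormalize by `P(Gj)`), so a
`variant="conditional"` flag provides the renormalized form. Values are
clamped into [0, 1] with a warning when the as-printed form strays. For
gene sets, the distribution is restricted to the set's transcripts and
renormalized before computing `U = I/H(T)` — otherwise `H(G′)` is not an
entropy of a probability distribution.

The permutation null shuffles transcript-level cell labels with gene
labels fixed. Equivalently — and as implemented — a single gene's column
is a multivariate hypergeometric draw conditioned on the cluster totals
(vectorized across iterations), and a gene set's columns are drawn by
Patefield sampling of a contingency table with the set's gene totals plus
a remainder column. Both preserve every `P(Gj)` and `P(Tk)` exactly.
With `b` = number of permuted statistics strictly exceeding the observed:
`p = (1+b)/n_iter` when `b > 10`; otherwise a generalized Pareto
distribution (MLE, location fixed at 0) is fit to exceedances over the
threshold at the 250th-largest draw, the fit is tested by
Kolmogorov–Smirnov at 0.05, the exceedance count is lowered in steps of
10 until the fit passes, and `p = (n_exceed/n_iter)·(1−F(stat−φ))`. If no
fit passes down to 10 exceedances the bound `1/n_iter` is reported with
an explicit method tag. Very discrete permutation distributions (tiny
tables) typically take this fallback; quasi-continuous ones (a 30-copy
gene in a ~3,000-transcript pool) agree with 10⁶-draw brute-force
p-values well within a factor of 3.

## Pipeline determinism and problem sizes

One global seed fans out to per-stage child seeds at fixed offsets, so
toggling a stage never shifts another's randomness; two runs with the
same seed produce byte-identical JSON summaries (no timestamps in the
summary; elapsed times go to the log). Test and acceptance problem sizes
— 900–5,000 cells, 300–2,000 genes, 1,000 permutation iterations, a
10⁶-draw brute-force check — were chosen so the full suite and the
acceptance script each complete in well under a minute on one CPU while
keeping every statistical check comfortably powered.

## Known limitations

* The scVis/UMAP embeddings, MNN correction, and Scrublet are consumed as
  external inputs (or stand-in simulations), never reimplemented.
* LOESS here is locally linear; a locally quadratic fit would track
  curvature at wide spans better, and the span (0.3) is a package choice,
  not an established constant.
* The KDE-valley multiplet threshold and the purity/stability formulas
  are explicit operationalizations of loosely specified procedures.
* The inclusive merge rule can chain transitively at θ-floor; on data
  with a continuum of profiles this may over-merge.
* GPD tail p-values inherit the usual extreme-value caveats: far beyond
  the fitted support (negative shape) they can collapse to the smallest
  positive double, which should be read as "below resolution".
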