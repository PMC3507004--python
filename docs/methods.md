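# Methods

## The model

An expression compendium is a genes × samples matrix `X` (log-scale values,
already normalized upstream, e.g. by RMA). We model it as a linear
combination of a small number of latent biological programs:

    X = S A

* `A` (k × n_samples) holds k latent **activation signals**: how strongly
  each program is switched on in each array. These are the statistically
  independent, non-Gaussian variables of the ICA model — pathway programs
  are silent in most conditions and strongly induced in a few (sucrose
  stress, regulator over-expression), giving heavy-tailed, super-Gaussian
  activation profiles.
* `S` (n_genes × k) is the **gene signature matrix**: gene *g*'s row says
  how much each program contributes to its profile. Co-regulated genes have
  parallel signature rows, so clustering the rows of `S` groups pathway
  members.

The statistical observations are the *samples*: each array is one draw of an
m-dimensional gene vector. This matters for two reasons. First, it is how
the standard R/scikit-learn fastICA call on a samples × genes matrix is set
up. Second, fastICA centers its observations — centering per gene (across
samples) leaves the gene-to-gene structure of `S` intact, whereas centering
across genes would force every signature column to zero mean over genes and
destroy exactly the shared-response structure the downstream uncentered
correlation is designed to exploit.

## fastICA

Estimation is the classic fixed-point scheme:

1. center each gene; whiten the sample observations to the top-k principal
   subspace. Whitening is an eigendecomposition of the gene-space sample
   covariance (divisor n, i.e. ddof 0); when samples < genes the
   eigenproblem is solved on the equivalent n × n Gram matrix. Eigenvalues
   below `1e-12 ×` the largest count as numerical zeros for rank detection;
   asking for k beyond the achievable rank is an error that reports the
   rank.
2. symmetric (parallel) fixed-point iteration on an orthonormal k × k
   unmixing matrix `W`, initialized from seeded standard normals:
   `W ← E[g(WZ) Zᵀ] − diag(E[g′(WZ)]) W`, followed by symmetric
   decorrelation `(WWᵀ)^{-1/2} W`. Iteration stops when
   `max |abs(diag(W_new W_oldᵀ)) − 1| < tol`. A deflation (one-component-
   at-a-time) mode is available behind a flag.
3. contrasts: `logcosh` (g = tanh(αu), α ∈ [1,2], default α = 1 — the
   robust default for super-Gaussian sources) and `exp`
   (g = u·exp(−u²/2)). Defaults `max_iter = 200`, `tol = 1e-4` follow the
   R fastICA defaults.

Afterwards the activations are `A = WZ` and the signature is the regression
of the centered data on them, `S = X_c Aᵀ/n`; then `S` columns are scaled to
unit variance over genes (the scale moves into `A`, leaving `S·A`
unchanged) and sign-fixed so each column's largest-magnitude entry is
positive. Both conventions exist purely to make runs reproducible and
comparable; `S·A` always equals the rank-k principal projection of the
centered input, and non-convergence sets a flag and warns rather than
raising. The default k is 8, the value commonly used for metabolism-scale
compendia; every analysis here passes k explicitly.

ICA leaves component order and sign undefined; all recovery scoring is
therefore up to permutation and sign, and the rotation-scan oracle used in
the tests compares angles modulo 90°.

## Clustering

Signature rows are clustered with the Cluster 3.0 recipe: similarity =
**uncentered correlation** (cosine of the angle, no mean subtraction;
Pearson is also available), distance = 1 − similarity, **average linkage**
(UPGMA, implemented with the exact Lance–Williams update). Rows are
clustered as-is — no re-standardization — matching Cluster 3.0's default.
Ties between equal-distance candidate merges are broken by the
lexicographically smallest (min node id, max node id) pair, which makes the
merge sequence deterministic and permutation-stable; merge records carry the
similarity at each merge, and the CDT/GTR writer emits the Java TreeView
dialect. Average linkage cannot produce inversions; the dendrogram
constructor asserts monotone merge similarities.

Flat clusters come from either cutting to a requested cluster count
(undoing the last n−1 merges) or keeping merges at or above a similarity
threshold. How many sub-clusters a published heat map "contains" is a
judgment call; the recovery analyses use planted modules + 1 (the +1 being
the background) and say so.

## Guide-gene screen

For every non-guide gene, Pearson r against every guide over the full
sample set; a candidate passes with ≥ `min_links` (default 2) strictly
positive links r > `threshold` (default 0.525 — the conventional cutoff for
ATTED-II-scale Arabidopsis compendia; configurable since its derivation
belongs to that resource, not to this package). No multiple-testing
correction: the procedure is a fixed-cutoff screen, not hypothesis testing;
a t-approximation p-value is written for orientation only.

## The synthetic compendium

The generator plants k* modules (defaults: 8/6/10 genes — typical pathway
sub-cluster sizes) driven by Laplace (scale 1) or sparse-spike activation
signals, at 1000 genes × 200 samples by default (a desk-scale stand-in for
a ~1900-gene × ~1400-array compendium; full scale remains supported).
Module members load 1.0 on their module's signal; noise is i.i.d. Gaussian
(sd 0.3) on every gene; background genes additionally vary with an
idiosyncratic baseline (sd 0.3).

**Background coupling.** Background genes are not idle: each loads
`0.12 × u` on *every* module signal, with a gene-specific sensitivity
u ~ U[0.9, 1.1]. This emulates a robust feature of real compendia — the
conditions that induce a pathway (stress, nutrient shifts, regulator
over-expression) also move general metabolism a little, so most genes share
a weak positive response. The shared response is what gives the uncentered
correlation its meaning: background signature rows then agree in direction
with each other (forming their own cluster) while module members point
along their component's axis. A fully idle background would have
direction-free signature rows — cosine similarity is scale-free — and *no*
flat cut could separate it from the modules; a planted-recovery benchmark
is only well-posed in the coupled regime.

The three free levels (coupling 0.12, its ±10 % spread, baseline sd 0.3)
were fixed once from the signal-to-noise requirements of the three analyses
run on the same data, and not revisited: (i) the screen must stay specific —
the strongest background–member correlation is
`c·u·var(s) / (σ_bg σ_member) ≈ 0.34`, about 3 sampling standard deviations
(1/√200 ≈ 0.07) below the 0.525 cutoff; (ii) signature-row directions must
be stable — the per-component estimation noise `σ_resid/√n ≈ 0.03` is small
against the coupling signal `c·sd(s) ≈ 0.17`; (iii) signature columns must
correlate ≥ 0.95 with the planted loading columns, which bounds the
baseline sd from above. Raising the coupling improves (ii) but breaks (i);
raising the baseline improves (i) but breaks (ii) and (iii); the defaults
sit in the window satisfying all three.

A **dual-membership gene** (a bifunctional enzyme serving two pathway
branches) loads 1.0 on its primary module and `cross_loading` (default 0.8)
on a secondary one. In the demonstration fixture the primary is the
*weaker* module (anthocyanin modification, 6 members): at k = 2 that module
does not get a component of its own, so the gene's signature is dominated
by its secondary loading and it sits in the flavonol cluster; from k = 3 on
the modification component exists and the gene moves (or, right at the
boundary, falls between the module clusters). That is the mechanism by
which the cluster membership of a bifunctional gene depends on the number
of extracted components, and it is deterministic on the fixture.

The random stream is consumed in a fixed order (sources, sensitivities,
baseline, unit noise, row shuffle), so changing one level rescales the same
realization rather than redrawing; within-module correlation is then
monotone in the noise level at fixed seed. Gene/sample IDs are synthesized
(`G0000…`, `S0000…`) and row order is shuffled under the seed so nothing
downstream can exploit placement.

What the generator does *not* emulate: probe-level noise, batch structure,
repressed (negative) modules, and the long-tailed module-size distribution
of real pathway databases. Passing the recovery benchmarks therefore shows
the pipeline is correct and well-conditioned at realistic SNR, not that any
particular biological compendium will yield clusters this clean.

## Evaluation

Module recovery is scored by (a) the adjusted Rand index between the flat
clustering and the planted partition, with background as its own class
(pair-counting formula under the permutation null; degenerate pairs where
max = expected score 0), and (b) per-module best-match Jaccard, ties toward
the smaller cluster label. Excluding background from the ARI is available
behind a flag but off by default: at compendium scale the background
dominates, and a clustering that shreds it should score badly. The
benchmark experiments run seeds 0–9 at k = 3 with a 4-way cut; the
IC-number sweep runs k ∈ {2, 3, 4, 6, 8} with the decomposition seed held
fixed so that differences across k are attributable to k alone.

## Numerical conventions

* Variances and covariances use ddof 0 throughout (whitening, signature
  scaling).
* Floats are serialized with `repr`, the shortest round-tripping form;
  write→read is bit-exact, and same-seed runs are byte-identical.
* TSV dialect: tab delimiter, UTF-8, `.` decimal, no quoting. Missing
  values are rejected unless row-mean imputation is requested explicitly.
* Similarities are clipped to [−1, 1] before distances are formed;
  zero-norm (uncentered) or constant (Pearson) rows are errors naming the
  offending gene.
* Sample excess kurtosis is the biased fourth standardized moment minus 3
  (so an alternating ±1 vector scores exactly −2). Small-sample kurtosis of
  Laplace draws is noisy; non-Gaussianity checks in the tests run on the
  frozen fixture rather than across arbitrary seeds.

## Known limitations

* Uncentered-correlation clustering of ICA signatures is only informative
  when genes share response structure (see background coupling above);
  on data without it, use Pearson similarity or cluster loading magnitudes.
* k is taken as given; no model-order selection is attempted (the sweep
  module exists precisely because the interesting biology can live in the
  k-dependence).
* The screen's r cutoff is resource-specific; 0.525 is a sensible default
  for large Arabidopsis array compendia, nothing more.
* Whitening at full compendium scale eigendecomposes a matrix of side
  min(genes, samples); fine to a few thousand, not tuned beyond that.
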