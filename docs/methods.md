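# Methods

`decograd` implements a complete framework for segmenting macroscale
functional-connectivity gradients and functionally decoding the segments
against labelled meta-analytic map sets, together with the synthetic data
needed to exercise every stage with known ground truth. This note records
the models, the parameter choices that matter, and the places where the
design was genuinely open.

## Gradient decomposition

A dense connectome (vertex-by-vertex, symmetric) enters as Fisher z values
or correlations. Processing follows the standard chain for connectivity
gradients: the inverse Fisher transform (`tanh`) maps z back to r; each
row keeps its strongest `density` fraction of connections (default 0.10,
exactly `ceil(density * n)` entries per row, ties at the cutoff resolved
to the lowest column index); cosine similarity between the sparsified
rows forms the affinity matrix; and a diffusion-map embedding of that
affinity yields the gradients.

The diffusion operator uses anisotropic normalisation with `alpha = 0.5`,
the conventional choice that removes the influence of sampling density.
Negative cosine values are clipped to zero before normalisation so the
operator stays non-negative and row-stochastic after scaling. The
eigenproblem is solved through the symmetric conjugate of the
row-stochastic operator (dense `eigh` up to 800 vertices, ARPACK with a
seeded start vector beyond). The trivial eigenvector is identified by its
near-zero coefficient of variation and discarded wherever it lands.
Components are weighted by `lambda / (1 - lambda)` (diffusion time 0, the
automatic multi-scale convention); a fixed diffusion time `t` weights by
`lambda**t` instead. Each component's sign is fixed by making the vertex
with the largest absolute loading positive, so repeated runs are
bit-identical.

Explained variance is reported as `lambda_i / sum(lambda)` over the
retained non-trivial components. Whether eigenvalues or their squares are
the right variance analogue for a non-linear embedding is convention-
dependent; the linear ratio is used here and stated explicitly so
downstream comparisons are unambiguous.

## Segmentation of the gradient axis

Three 1-D approaches split the principal gradient into k segments, k from
2 to 32 by default (93 solutions across the three approaches):

* **PCT** — boundaries at the j·(100/k)-th percentiles (linear
  interpolation). Labels are assigned by rank so that populations differ
  by at most one even with ties; the reported boundaries are the
  percentile values.
* **KMeans** — 1-D k-means (k-means++ initialisation, 10 restarts,
  tolerance 1e-6, seeded), clusters relabelled in ascending centroid
  order; anchors are the centroids.
* **KDE** — a Gaussian kernel density estimate of the gradient axis is
  evaluated on a 1024-point uniform grid spanning the data ± 3 bandwidths;
  boundaries are the interior local minima of the curve. The bandwidth is
  tuned by bisection on the log scale over [1e-3, 1] × data range (60
  iterations) until exactly k − 1 interior minima exist; minima are strict
  sign changes of the discrete derivative, with plateau minima taking the
  plateau midpoint. If no bandwidth in the range achieves k − 1 minima the
  tuner raises and reports the achievable counts. Anchors are the density
  maxima between consecutive minima, which exist for a continuous density
  on a closed interval.

Quality is scored per (method, k) with the mean silhouette coefficient,
the variance-ratio (Calinski–Harabasz) score and the cluster-separation
(Davies–Bouldin) score; the per-vertex silhouette doubles as a confidence
map. Members of singleton clusters score silhouette 0 (common
convention). These metrics are delegated to scikit-learn but are verified
against brute-force direct-formula oracles in the test suite at 1e-9.

Multidimensional clustering (joint space of up to 9 gradients) uses the
same k-means machinery; only k-means generalises cleanly beyond 1-D.
Clustering similarity across dimensionalities is measured with NMI
normalised by the arithmetic mean of the entropies.

## Pseudo-activation maps

Each segment becomes a continuous decoding target through a Gaussian
radial-basis transform: `A(v, p) = exp(-D(v, p)^2 / (2 sigma^2))`, with D
the Euclidean distance in gradient space between vertex v and the
segment's peak point p. Peak points: terminal segments anchor at the
extreme data value on the side away from their neighbour (1-D only);
interior segments use the method's natural anchor (median for PCT,
centroid for KMeans, KDE density maximum for KDE); multidimensional
clusters use their centroids.

"Average distance within the segment" admits two readings for sigma; the
default is the mean distance of segment members to the peak (O(n), and
peak-centred like the kernel itself), with the mean pairwise distance
available behind `sigma_mode="pairwise"`. Vertices outside the segment
are set to 0 rather than masked, so all maps share a fixed full-cortex
support and decoding correlations are computed over the same vertex set;
a within-segment flag is unnecessary under that convention.

## Meta-analytic maps

Term route: studies whose TFIDF feature weight for a term exceeds 0.001
form the selected sample. Study-level modeled-activation maps place a
binary sphere of radius 10 mm at each peak coordinate and max-combine
(duplicate coordinates are idempotent). Per cell, a 2×2 Pearson
chi-square (no continuity correction) of selected/unselected ×
active/inactive yields the statistic, reported both raw and as a signed
z-like value `sign(P(act|sel) − P(act|unsel)) * sqrt(chi2)`; cells with a
zero margin are set to 0 rather than NaN. Maps can be rasterised on a
configurable isotropic volume grid (default 4 mm spacing over a ±80 mm
box) or evaluated directly at surface-vertex coordinates; out-of-grid
coordinates are clipped with a warning.

Topic route: latent Dirichlet allocation (scikit-learn, batch variational
inference, seeded) of the document-term counts provides `p(word|topic)`
and `p(topic|article)`; studies with `p(topic|article) > 0.05` form each
topic's sample, fed through the same chi-square meta-analysis. Topic maps
are labelled with the top three `p(word|topic)` words (ties broken
lexicographically); three words carry most of a topic's probability mass
and keep labels readable.

Externally supplied map sets (for example topic-by-voxel probability maps
from a spatially constrained topic model) decode through the same
interface; fitting such models is out of scope.

## Correlation decoding and spatial inference

Every pseudo-activation map is Pearson-correlated with every meta-analytic
map over cortex vertices. Significance uses spin permutations: a uniform
random rotation (QR of a seeded Gaussian matrix, determinant +1) is
applied to the spherical mesh coordinates of the cortex — mirrored across
hemispheres when two are present — and vertices are reassigned to their
nearest rotated positions bijectively, without replacement, processing the
worst-served vertices first; the medial wall never moves. This preserves
each map's value multiset and, up to the fixed-wall rim, its spatial
autocorrelation. The meta-analytic maps are the spun member of each pair,
matching the framing of rotating their spherical projection;
target-spinning is available and used for calibration tests.

The permutation p-value is the literal fraction of null correlations at
least as large as the observed one (one-sided; negative correlations can
therefore never reach significance). Because that estimator can return
exactly 0, the unbiased `(k+1)/(n+1)` variant is available behind a flag.
Benjamini–Hochberg FDR is applied across all (segment × map) pairs of one
decoding run — the natural simultaneous-inference family for a single
decoded solution — and significance is `q < 0.05`.

## Semantic evaluation

Information content of term t in document d is `-ln(f(t,d)/N(d))`;
map-level IC averages over the meta-analytic sample, skipping documents
where the term is absent (selection thresholds make presence typical, and
an infinite IC from one zero count would otherwise dominate; add-one
smoothing is available). TFIDF uses `tf = f(t,d)` and the smooth-idf
convention `idf = ln((1+D)/(1+d_t)) + 1`, matching the standard
transformer; a topic's IC and TFIDF are the sums over its top words.
Natural logarithms are used throughout.

Category annotations (Anatomical / Functional / Clinical / Non-specific)
yield `p(category|word)` by vote counting; a word is classified by the
category strictly exceeding 0.5, else Non-specific. Topics classify by
`sum_w p(c|w) p(w|topic)` under the same strict rule. The decoding SNR is
the ratio of Functional to non-functional top labels across a segment
solution (counted per segment occurrence, not per unique label), with the
normalised variant defined as the Functional fraction. Word-cloud report
weights apply Bayes with a uniform prior over the retained (significant,
functional) topics: `weight(w) = sum_t p(t|w) r_t`.

## Strategy grid

`evaluate_grid` benchmarks the Cartesian product of segmentation
approaches × map sources × databases across the k range: mean top
correlation, mean IC, mean TFIDF and normalised SNR of the top labels,
plus clustering quality per (method, k). Benchmarking needs only
correlation ranks, so it skips permutation inference. Cells at or above
the 90th percentile (correlation, SNR, silhouette) or 70th percentile
(IC, TFIDF) are marked, and the overall score is the sum of the five
binary indicators (max 5).

## Synthetic data

The generators are pure functions of (parameters, seed) and emulate the
four real inputs:

* **Sphere mesh** — Fibonacci lattice (quasi-uniform; nearest-neighbour
  spacing CV < 0.2) with a contiguous spherical cap (default 10% of area,
  centred on +x, perpendicular to the latent axis) as the medial wall.
* **Connectome** — `r_ij = exp(-|t_i - t_j| / lengthscale)` over a latent
  axis t in [0, 1], plus symmetric Gaussian noise (default sd 0.05),
  clipped to [-1, 1] with unit diagonal. Lengthscale 0.2 gives the
  graded, long-range-decaying structure a functional connectome shows
  while keeping the principal gradient identifiable.
* **Study database** — topics own disjoint-leaning Dirichlet word
  distributions (most mass on a signature block of the vocabulary) and
  spatial focus centres; each study draws a dominant topic (mass uniform
  in [0.7, 0.9], remainder Dirichlet), multinomial word counts (150
  tokens), and 8 peak coordinates from mixture-sampled topics. Features
  are l2-normalised TFIDF weights of the counts.
* **Annotations** — each word gets a true category (Functional with a
  configurable fraction) and 10 raters vote it with a configurable
  agreement probability.

The coupled scenario (`synth_world`) ties everything together: the latent
axis blends the normalised z coordinate of the cortex vertices with a 15%
per-vertex random component, rank-normalised — like a real gradient, it
follows cortical geometry only approximately and carries fine topography
of its own. Topic 0 sits at the south pole (t = 0 end), topic 1 at the
north pole, other centres away from the poles (|z| < 0.5). Study
coordinates are sampled at cortex vertices weighted by a spatial kernel
around the topic centre times a latent-axis kernel around the topic's
nominal t (width 0.12), so activation topography follows function rather
than pure geometry — the property that lets a correctly aligned
meta-analytic map beat every rotated null, as real task topographies do.

What the generator does **not** emulate: cortical folding and true
geodesic distances, empirical spatial autocorrelation spectra of fMRI,
hemispheric asymmetries, vocabulary Zipf tails, and annotation biases.
Passing tests therefore demonstrate the correctness and calibration of
the machinery under a controlled planted model, not performance on any
real connectome or literature database.

## Problem sizes

Default generator sizes (2000 vertices, 500 studies, 20 topics, 400
words) run the full pipeline in minutes on one core. The test suite and
the reproduction script use smaller instances chosen to keep the
brute-force O(n²) oracles and the 20-seed replications quick: 1000
vertices for gradient recovery, a 500-vertex world with 300 studies and
10 planted topics (12 fitted — fitting a few more topics than the truth
absorbs occasional LDA merges, as over-provisioned topic counts do in
practice) for the end-to-end check, 200 spin permutations × 50 targets
for calibration, and 1000 permutations for end-to-end inference.

## Known limitations

* The spin null's greedy bijection distorts autocorrelation near the
  medial-wall rim; with 10% wall and a few hundred vertices this is a
  visible fraction of the sphere (the pure-rotation case is exact).
* The one-sided fraction p-value floors at 1/n_perm below which BH
  granularity, not signal, limits detection.
* KDE bandwidth tuning assumes the minima count is monotone in the
  bandwidth, which can fail on adversarial samples; the tuner then
  reports the achievable counts instead of guessing.
* LDA identifiability at small corpora is imperfect; fitted topics can
  merge or split planted ones, which is why topic labels rather than
  topic indices are the unit of interpretation.
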