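# Methods

This note records the statistical model, its assumptions, the defaults
and why they were chosen, and the places where the implementation had to
make a genuine design choice.

## Suite geometry

A *suite* is the sugar-to-sugar unit spanning two adjacent, covalently
bonded residues, named by the second residue's (author) number. Two
residues count as bonded when the O3′(i−1)–P(i) distance is at most
2.5 Å (the covalent bond is ≈ 1.6 Å; the margin tolerates poorly
refined models; configurable). Its high-detail shape is the ordered
7-tuple of backbone torsions

| name | atoms |
| --- | --- |
| δ(i−1) | C5′–C4′–C3′–O3′ of residue i−1 |
| ε | C4′(i−1)–C3′(i−1)–O3′(i−1)–P(i) |
| ζ | C3′(i−1)–O3′(i−1)–P(i)–O5′(i) |
| α | O3′(i−1)–P(i)–O5′(i)–C5′(i) |
| β | P–O5′–C5′–C4′ of residue i |
| γ | O5′–C5′–C4′–C3′ of residue i |
| δ(i) | C5′–C4′–C3′–O3′ of residue i |

measured with the standard sign convention (cis = 0°, agreeing with
Biopython's `calc_dihedral` to 1e-13°) and wrapped to [0°, 360°) — a
point on the 7-torus.

**Pucker.** Two routes are provided. The low-detail route is the Pperp
criterion: the distance from the next-in-sequence P to the infinite
line through C1′ and the glycosidic nitrogen; ≥ 2.9 Å ⇒ C3′-endo,
< 2.9 Å ⇒ C2′-endo, with the boundary value itself classified
C3′-endo. The high-detail route is cutoff-free ring geometry: the
signed heights of C3′ and C2′ over the oriented plane spanned by the
C4′–O4′ and C1′–O4′ bond vectors decide the endo atom (C3′-endo iff
C3′ sits on the positive — C5′/base — side and higher than C2′). The
5′ sugar's Pperp uses the suite's own P; the 3′ sugar needs the
*following* residue's P, so chain-terminal suites are un-gateable at
low detail and are reported as such.

## MUCCSS coordinates and their geometry

Low-detail data is the landmark quintuple (N1/N9(i−1), C1′(i−1), P(i),
C1′(i), N1/N9(i)). After centring on P and building the canonical
frame (e₁ along w−v, e₂ the in-plane normal component of v, e₃ =
e₁×e₂ — so both pseudo-bonds share one positive y-projection and the
later C1′ has the larger x-projection), the suite is

W = (d₂, d₃, α, s₁, s₂) ∈ ℝ₊² × (0, π) × (S²)².

The glycosidic bond lengths are treated as a known constant: each
measured bond vector is normalised to unit length rather than asserted
to equal 1.47 Å, so noisy inputs can never violate the constraint —
only the directions carry information. All arccos arguments are
clamped to [−1, 1]; spherical arcs are computed in the atan2 form,
which stays accurate for nearly parallel directions (a plain arccos
loses ~8 digits there).

**Metric.** The product metric with every factor entering once,
unweighted: squared differences in d₂, d₃, α plus squared great-circle
arcs on the two spheres. A ½-weighted sphere variant was considered
and rejected; the unweighted product is the canonical metric of the
direct product and is what the uniqueness argument for means relies
on.

**Fréchet means.** The flat factors take arithmetic means (exact
closed form). Each sphere factor takes the intrinsic mean by
fixed-point iteration of tangent averaging: initialise at the
normalised chordal mean, iterate exp/log until the gradient norm drops
below 1e-10 (at most 1000 iterations, which concentrated per-cluster
samples never approach; non-convergence raises with diagnostics).
Per-cluster samples are concentrated well inside a geodesically convex
region, so the mean is unique.

**Tangent coordinates.** At a base point W\*, the coordinates are
(Δd₂, Δd₃, Δα, s̃₁, s̃₂) ∈ ℝ⁷. For each sphere the 2-D residual s̃ᵢ is
the orthogonal projection of the data direction onto the tangent plane
at the *base* direction sᵢ\*, expressed in a deterministic basis: the
helper axis is the standard basis vector least aligned with sᵢ\*
(lowest index on ties), b its normalised orthogonal component, c =
b × sᵢ\*. This "robustified residual coordinates" chart is bijective
exactly on the open hemisphere around the base; points outside it
(sᵀ s\* ≤ 0) raise a chart error rather than silently folding over.
The base point maps to the zero vector. The per-cluster covariance is
the uncentred estimator S = (n−1)⁻¹ Σ TᵀT at the Fréchet mean.

## Training-side clustering

Per pucker-pair set, high-detail points are clustered in three stages.

**Average linkage** under the flat torus metric (root sum of squared
minimal wrapped differences, degrees); the tree is scipy's, checked in
the tests against an O(n³) re-agglomeration oracle.

**AGE cut.** Walking the tree from the root, a merge node splits into
its two children when the vertical gap between its merge height and
its taller child exceeds q × (root height): branches that join only
across a large stretch of empty merge heights are separated groups,
and the loosest ones detach first. Groups smaller than κ become
outliers; the outlier fraction is compared against d_max and warned
about, never enforced by deletion. Defaults: q = 0.09 / 0.05 / 0.07 /
0.05 and d_max = 1.1 % / 0.34 % / 1.4 % / 0.7 % for P33 / P32 / P23 /
P22, κ = 3 everywhere — q is a per-data-set tuning parameter, and for
the synthetic gold standard (whose clusters are broader relative to
their separations than curated suite data) the same tuning procedure
gives q = 0.15, d_max = 2 % (`SYNTHETIC_AGE_PARAMS`), chosen from the
dendrogram gap structure at generator-design time.

**Circular mode hunting (MINT stage).** Each precluster is reduced to
one circular coordinate: unwrap every coordinate about its circular
mean (valid for concentrated clusters), project onto the dominant
eigenvector of the unwrapped covariance (sign fixed deterministically),
and wrap the centred scores. This principal-geodesic-style reduction
deliberately replaces stratified-sphere torus PCA; it preserves the
role of a 1-D circular reduction feeding the mode test and is exact
for single-direction variation. The scores are then tested unimodal
vs bimodal: a likelihood ratio of the best two-component Gaussian
mixture (hand-rolled EM, 10 deterministic restarts from sorted-split
initialisations, component scales floored at 0.5° — the scale below
which suite geometries are indistinguishable — and component weights
at 2/n so a component always carries at least two points) against a
single Gaussian. The null distribution comes from a parametric
bootstrap (default 200 replicates); when the full 7-D points are
available the bootstrap replicates the *entire* projection pipeline —
matched multivariate Gaussian clusters re-projected through the
principal-circle step — because selecting the dominant-variance
direction systematically inflates apparent bimodality. A cluster is
split, at the antimode of the fitted mixture, only when three
conditions hold: the bootstrap p-value is below α (default 0.05), the
fitted mixture density is genuinely bimodal (an interior density
minimum below both component peaks — the alternative is a *bimodal*
Gaussian, not an arbitrary mixture), and the observed statistic
exceeds 1.5 × the bootstrap null's 95 % quantile (practical
significance: a split must clear the null envelope with a margin, not
scrape past it). Splitting recurses on parts of at least 4 points;
subclusters as small as 2 can emerge. Clusters are finally numbered by
decreasing size with deterministic tie-breaks, and every input point
ends in exactly one cluster or the outlier set.

## The classifier

Each trained cluster contributes its size |Cᵢ| (the unnormalised prior),
Fréchet mean and tangent covariance Sᵢ of its low-detail members. Small
clusters cannot fill all 7 dimensions, so every covariance is
regularised towards the dominant cluster: RSᵢ = λSᵢ + (1−λ)S₁ with
λ = 0.5 by default and S₁ the covariance of the single largest P33
cluster (the A-form-dominated one); if training data contains no P33
clusters the pooled covariance substitutes, with a warning. All RSᵢ
must pass a Cholesky factorisation — a non-positive-definite matrix is
an error naming the cluster and its smallest eigenvalue, never a silent
pseudo-inverse. The endpoints λ = 1 (RS = S, valid only for full-rank
clusters) and λ = 0 (RS = S₁ everywhere) are admitted for their exact
identities.

Prediction gates a suite by the Pperp pair and scores only that pair's
clusters with log p̃ = log|Cᵢ| − ½ log det RSᵢ − ½ d²ᴹ, where d²ᴹ is
the Mahalanobis distance of the tangent coordinates at the cluster
mean — the only term depending on the test suite. Normalisation is
done on the log scale with max-subtraction (mathematically identical
to normalising the raw p̃ values, but immune to underflow when a suite
is far from every cluster). Clusters whose hemisphere chart cannot hold
the suite are excluded from the sum — a cluster more than 90° away in a
glycosidic direction cannot be the answer — and if every cluster is
excluded the suite gets an explicit no-prediction result. Ties in the
argmax break to the lowest cluster index. Because of the
regularisation, reported posteriors carry "regularised" credibility;
the summary output says so.

**Evaluation** is three-way per suite: *prediction match* if the
winning cluster's label multiset intersects the probable-answer set
(clusters holding several conformers match any of them, and any one of
several probable answers suffices); *pucker mismatch* if no answer
conformer belongs to the gated pair's set; otherwise *prediction
mismatch*, flagged `unclustered-answer` when the answer conformer was
never clustered during training (such answers can only mismatch).

## Synthetic data: what it emulates and what it does not

The generator draws cluster mixtures on the 7-torus (wrapped-Gaussian
noise, σ = 8° per dihedral by default — comparable to the within-class
spread of rotameric suites), rebuilds each sample into 3-D atoms by
sequential internal-coordinate placement (NeRF) with ideal bond
lengths/angles (real backbones deviate by ~0.01 Å and ~2°), closes
each ribose from a pseudorotation template (phase 18° for C3′-endo,
162° for C2′-endo, amplitude 38°), applies a uniform random rigid
motion, and emits both representations plus ground-truth labels. The
default study conditions are 4 pucker pairs × 4 classes × 40 training
suites (10 test suites per class). Default class centres are
A-form-like and three strongly distinct rotamer-like alternatives,
separated by ≥ 60° in at least two torsions *and* well separated in
MUCCSS space — deliberately no crankshaft-related twins (α/γ rotations
that low-detail coordinates genuinely cannot see; real data contains
such pairs, and there the classifier inherits that ambiguity).

Consequences for interpreting green tests: passing the end-to-end
recovery criteria shows the pipeline is correct and self-consistent,
not that real RNA reaches those match rates — real suites carry
unbalanced class frequencies (A-form dominance), boundary cases between
classes, heterogeneous coordinate error, and crankshaft ambiguity, none
of which the default generator reproduces. The ribose template closes
the ring only approximately (C1′–C2′ within ~0.06 Å of ideal); the
7 backbone torsions and both pucker calls are exact by construction,
which is what the round-trip contracts require.

## Numerical and degenerate-input policy

Collinear torsion quadruples, zero-length bonds, parallel pseudo-bonds,
planar riboses, and antipodal sphere points all raise typed geometry
errors rather than returning values. Altloc policy on file input:
blank or "A" wins, highest occupancy on ties; suites touching alternate
conformations can be dropped with a flag. Only the first model of
multi-model files is read; residue numbering is taken verbatim
(insertion codes preserved). All randomness flows through explicit
seeds or `numpy.random.Generator` objects; two runs with one seed are
bit-identical.

## Known limitations

- The stratified-sphere torus PCA of the original clustering recipe is
  replaced by the principal-geodesic reduction described above; on
  clusters whose dominant variation is strongly curved across several
  torsions the 1-D scores are a poorer summary.
- The AGE cut rule is this package's reading of "adaptive iterative
  cutting"; the original is specified elsewhere and may differ in
  detail.
- Gaussian likelihoods per cluster are a simplification; heavy-tailed
  or skewed clusters are summarised only through mean and covariance.
- The 1a/1c crankshaft ambiguity of real data is intrinsic to
  low-detail coordinates; no d₃-based disambiguation heuristic is
  implemented.
- Suites at chain ends lack the next phosphorus and cannot be gated or
  predicted at low detail.
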