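# Methods

This note documents the models, numerical choices and limitations behind
`enamelgmm`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Shape capture

A digitized tooth is 8 fixed landmarks plus 8 curves, one between each pair
of consecutive landmarks, read from the tpsDig text dialect (`LM=`,
`CURVES=`/`POINTS=`, `ID=`, `IMAGE=`, `SCALE=`; coordinates are multiplied
by `SCALE` on read). Right-sided specimens are mirrored to the left
convention by reflecting x about the configuration centroid — an isometry,
so centroid size and all inter-point distances are preserved exactly.

Each curve is resampled to a fixed number of semi-landmarks equally spaced
in arc length along the digitized polyline, flanking landmarks excluded
(positions k/(m+1) of the total arc). The protocol fixes only the total of
178 semi-landmarks; the per-curve split is configurable with default
(22, 22, 22, 22, 22, 22, 23, 23). Point order is landmarks 0–7 then curves
in anatomical order, enforced by `SemiLandmarkScheme` so datasets are
interoperable.

## Superimposition

Generalized Procrustes analysis: center, scale to unit centroid size,
rotate each configuration to the current consensus by the rotation-only
(det +1) orthogonal least-squares solution, update the consensus, iterate
to tolerance (default 1e-6). Reflections are excluded because side is
standardized by mirroring first. Because the Procrustes solution is defined
only up to a global rotation, the output is pinned to a canonical frame
(consensus principal axis on x, sign fixed by the third moment), which
makes alignment idempotent and invariant to similarity transforms of the
inputs (asserted to 1e-8 in the tests).

### Semi-landmark sliding

Semi-landmarks are slid along their local tangent (the chord between the
two neighbouring points on the curve chain) to minimize the thin-plate-
spline bending energy of the displacement from the consensus. The TPS
system uses kernel U(r) = r² log r² (a constant multiple of the classical
r² log r, which changes only the absolute energy scale, not minimizers or
the affine null space); the bending-energy matrix L_k is the upper-left
p×p block of the inverse of [[K, Q], [Q', 0]] with Q = [1, x, y]. The
slide magnitudes solve the induced linear system (a convex quadratic;
least-squares solve, minimum-norm on the singular directions). Fixed
landmarks never move; degenerate tangents hold the point fixed with a
warning.

Two numerical safeguards matter in practice:

- **Trust region.** The tangent linearization is local; an unconstrained
  optimum can move a point past its neighbour, after which repeated passes
  let points "crawl" and bunch up along the outline. The whole slide vector
  is therefore scaled so no point moves more than 45% of the gap to its
  nearest neighbour; a common scaling of the optimal step of a convex
  quadratic still strictly decreases the energy, so the no-energy-increase
  guarantee survives.
- **Fixed base.** Each GPA+slide cycle (default 5, interleaved with
  re-superimposition, re-centering and re-scaling) re-solves the slide from
  the *unslid* aligned configuration rotated into the current frame, rather
  than accumulating slides on previously slid shapes. Accumulation is the
  other route to unbounded crawling; with a fixed base the procedure
  converges (the consensus is stationary well within the default cycles on
  the synthetic data, verified in the tests).

## Shape-space statistics

**PCA** by SVD of the centered coordinate matrix; the retained dimension is
the smallest m whose cumulative variance fraction reaches the threshold
(default 0.99).

**Factorial shape-ANOVA**: sequential (type-I) sums of squares of the
multivariate linear model with terms A, B, A:B, computed via nested hat
matrices (ranks from QR, so empty cells are handled). F = MS_term /
MS_residual of the full model. p-values come from residual randomization:
for each term, the residuals of the reduced model (all earlier terms) are
row-permuted, and the proportion of permuted F at or above the observed F
(observed counted, add-one) is reported. Z is the standardized position of
the observed F in its permutation distribution, (F_obs − mean F*)/sd F*;
note that other implementations report effect sizes on a log-F scale, so Z
magnitudes are not comparable across software. With a single factor the
same machinery yields Goodall's F. Sums of squares and F match
vegan::adonis2 on Euclidean distances exactly (cross-checked in the
tests). Term order defaults to (anatomical position, taxa, interaction)
and is configurable; this is a sequential decomposition, so order matters
under imbalance.

**MANOVA** is Pillai's trace on retained-PC scores with the standard
approximate F; it requires m < n − g and raises an instructive error
otherwise.

**CVA** solves the generalized eigenproblem between × within (covariance
normalizations B/(g−1), W/(n−g)); eigenvectors are W-normalized, so every
canonical variate has unit pooled within-group variance. During
cross-validation, training groups reduced to one member are admitted: they
contribute a centroid but no within-group variance (the smallest feasible
twofold split of a two-specimen group places 1 in training, 1 in testing).

**Cross-validated classification (CCV)**: per round, a stratified random
half-split per group (training size alternates ceil/floor of n_g/2 across
attempts, every group keeps ≥1 training row), CVA fit on the training half,
and each testing row assigned to the group with minimum Mahalanobis
distance in canonical space (equal priors; ties break to the lowest group
index for determinism). Splits with a singular training covariance are
redrawn with a logged warning; more than half untrainable is an error. Two
summaries are reported: the per-round mean correct percentage (designated
CCV in the outputs, since the per-specimen averaging happens first) and
the percentage of specimens whose modal assignment is correct. When the
99%-variance retention exceeds what a half-split can support
(m ≥ n_train − g), the pipeline caps the retained dimension and logs it.

**Predictive assignment** of unknowns: one orthogonal Procrustes fit onto
the training consensus, projection onto the retained PCs, squared
Mahalanobis distance to each group centroid in canonical space, posterior
∝ exp(−D²/2) with equal priors.

**Shape along an axis**: the multivariate regression of coordinates on an
axis score, evaluated at a chosen score; for PCA this reduces exactly to
mean + score × eigenvector.

## Phylogenetic comparative layer

The phylogeny is consumed as rooted newick with branch lengths (dendropy);
polytomies are allowed, missing lengths are an error unless a unit-length
flag is set. The Brownian covariance C has C[i,j] = shared root-to-MRCA
path length. Species means are computed after a fresh superimposition of
just the selected specimens; full Procrustes coordinates are the default
input to K (the statistic is invariant to orthogonal changes of basis, so
retained PCs give the same value — asserted in the tests).

**Multivariate K**: with the GLS phylogenetic mean â = (1'C⁻¹1)⁻¹1'C⁻¹Y
and D = Y − 1â,

K = [tr(D'D) / tr(D'C⁻¹D)] ÷ [(tr C − N/(1'C⁻¹1)) / (N − 1)],

expectation 1 under Brownian motion. The permutation test shuffles species
mean rows across tips (1000 permutations by default; the alternative of
permuting specimen-level data is not implemented), with the add-one
p-value convention so p is never 0. The univariate case equals Blomberg's
K to 1e-10, and matches phytools::phylosig in a cross-check.

**Squared-change parsimony** minimizes Σ_edges ‖Δ‖²/length with tips fixed,
by solving the exact sparse stationarity system (each internal node is the
inverse-length-weighted average of its neighbours). This equals the
GLS/maximum-likelihood reconstruction under Brownian motion at the root
(asserted to 1e-8, and against ape::ace). Zero-length internal edges are
treated as near-zero (1e-8) with a warning.

**Phylomorphospace**: PCA of the species means, squared-change parsimony on
the retained scores (linearity makes this identical to projecting
coordinate-space reconstructions), tips + internal nodes + edges on
PC1/PC2, plus per-species shape differences against the reconstructed root
for outline plots.

Species present in the data but not the tree (or vice versa) are
intersected with a log message; the pipeline prunes the tree to the species
with data before K and the phylomorphospace.

## Synthetic studies

The generator emulates the structure of the real study, not its anatomy.
The template outline is an ellipse (semi-axes 1.6 × 1.0) radially modulated
by 1 + A sin(8θ) (default A = 0.12), landmarks at the fold maxima and ~60
polyline points per curve; any |A| < 1 keeps the outline simple. Group
mean-shape effects are applied as smooth low-frequency displacement fields
(five fixed radial/tangential modes of the outline, unit RMS), not iid
per-landmark offsets, so group differences are anatomically coherent.
Taxon effects for the 10 tree species are Brownian draws of the mode
coefficients along the default tree (caballine horses sister to the
ass/hemione + zebra clades, ultrametric, arbitrary unit-scale lengths);
other taxa get independent draws of comparable magnitude. Tooth-position
and interaction effects are independent coefficient draws. Noise has two
parts: isotropic per-landmark noise (applied per curve as a coherent shift
so that arc-length resampling does not average it away) and per-point
digitization jitter.

Default conditions: the 15 × 4 sample-size layout of the study (including
the two-specimen group that stresses the twofold split), and effect scales
(taxon 0.016, tooth 0.017, interaction 0.013, noise 0.020, jitter 0.002 in
template units) chosen once so that the factorial decomposition of the
generated data roughly reproduces the study's variance partition (taxa ≈
0.22, position ≈ 0.14, interaction ≈ 0.14 of total SS, about half
residual). Individual seeded realizations scatter around that partition
because the Brownian taxon draws are themselves random.

What passing tests on synthetic data do *not* show: the generator has no
real dental anatomy, no wear/age structure, no allometry, no correlated
digitization error between neighbouring specimens, and its taxon effects
are exactly Brownian — so success on synthetic data demonstrates the
statistical machinery, not field performance on real enamel outlines.

## Problem sizes and runtime choices

The analysis drivers use 1000 cross-validation rounds, 999 ANOVA
permutations and 1000 K permutations (the `RunConfig` default for CV
rounds is 10 000; the drivers choose 1000 so each script completes in
about a minute). Calibration tests use 500 Brownian replicates for the K
expectation, 200 null datasets at 199 permutations for the ANOVA type-I
error, and 1000 rounds for the chance-level classification check.

## Known limitations

- Sliding is tangent-linearized and trust-region damped; points are not
  re-projected onto the digitized polylines, so slid semi-landmarks sit on
  tangent lines, as in standard relax-against-consensus implementations.
- The sequential ANOVA is order-dependent under imbalance (by design);
  there is no type-II/III option.
- Classification uses equal priors; group-size priors are configurable
  only through the posterior formula in predictive assignment.
- K assumes the branch lengths as given (substitutions or time); no
  calibration or rate model beyond Brownian motion is attempted, and no
  Ornstein–Uhlenbeck alternative is provided.
- The CVA ordination and Mahalanobis classification agree in rankings only
  when the CVA is full rank; the pipeline classifies in canonical space.
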