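# Methods

`cantokit` asks a comparative question: do the stylistic features of a
society's songs carry the same historical signal as its language and its
genes?  The package implements each stage of that comparison as a testable
unit and ships a synthetic-world generator so that every stage has a known
ground truth to recover.  This note documents the models, the defaults, the
numerical choices, and what the synthetic evidence does and does not show.

## The measurement model

Song-style codings arrive as ordinal features (~24 per song, coded on
non-consecutive integer scales of up to 13 levels).  Preparation maps each
feature's codes to [0, 1] by rank within the declared code set — rank, not
the raw integer, because code values are arbitrary labels on an ordinal
scale — reversing scales whose high codes mean *less* of the measured trait.
Cells carrying several codes are resolved to one code uniformly at random
under a fixed seed; because only a few percent of cells are affected,
downstream latent scores are nearly invariant to the seed (the suite asserts
per-song score correlations above 0.95 across re-preparations).

The latent structure is a confirmatory factor model with five correlated
dimensions of song style (Articulation, Tension, Ornamentation, Rhythm,
Dynamics): x = Λη + ε with Σ(θ) = ΛΦΛ′ + Θ.  Each indicator loads on exactly
one dimension; Θ is diagonal plus an explicit list of residual covariances.
Identification fixes latent variances to 1 (the completely standardized
convention on the latent side).  The ML discrepancy

    F_ML = ln|Σ(θ)| − ln|S| + tr(S Σ(θ)⁻¹) − p

is minimized by L-BFGS-B with residual variances log-parameterized and Φ
parameterized through a row-normalized Cholesky factor, which keeps Σ
positive definite along the search path.  Convergence tolerance is 1e-8 on
F_ML with 10 random restarts by default; the deterministic start (loadings at
0.7·sd, uniquenesses at half the observed variance) reaches the global
optimum in every well-conditioned case we simulate, so heavy recovery runs
use fewer restarts.  Ordinal 0–1 indicators are treated as continuous
(Pearson covariances); a polychoric mode is out of scope, so loadings carry
the usual mild attenuation from discretization — at 13 code levels this is
well under the 0.05 recovery tolerance the tests use.

Fit indices follow the standard formulas: χ² = (N−1)·F_min; RMSEA =
√(max(χ²−df, 0)/(df(N−1))) with a 90% interval from noncentral-χ²
inversion; CFI against the independence baseline (closed form: F_b =
Σln s_ii − ln|S|); SRMR as the RMS of correlation-metric residuals over the
p(p+1)/2 unique elements.  Per-song latent scores use the regression method
η̂ = ΦΛ′Σ⁻¹(x − x̄).  A dimension reduced to a single indicator (as happens
after aggressive reliability filtering) is a passthrough: loading fixed at
the indicator's sd, zero uniqueness, so the score is the standardized
indicator itself.

## Variance decomposition and fixation

AMOVA decomposes squared Euclidean distances among songs into within-society,
among-society(-within-group) and among-group components with the standard
unequal-n coefficients; Φ statistics are ratios of the components.  Negative
components are reported raw and a Φ with a non-positive denominator is NaN —
clamping would silently bias comparisons with other AMOVA software.
Permutation nulls move songs across societies (within groups for the nested
level; whole societies across groups for Φ_CT), 999 permutations by default.
Pairwise Φ_ST runs the two-population decomposition for every society pair
and requires at least two songs per society.

Genetic differentiation uses the Weir–Cockerham (1984) θ from biallelic
dosages: per-SNP components a (among populations), b (among individuals
within), c (within individuals) from allele frequencies, sample sizes and
observed heterozygosity, combined across SNPs as Σa/Σ(a+b+c) — the ratio of
averages, never the average of per-SNP ratios (a test pins this against the
biased variant).  Missing dosages drop out per SNP per population; SNPs
monomorphic across both populations, or with fewer than two called
individuals on either side, are skipped and counted.  Populations under five
individuals trigger a warning but are allowed from two.

## Spatial structure

The variogram computes, for each geographic distance class (default 500 km
bands to 20,000 km, i.e. 40 classes), the coefficient

    r_h = Σ_{(i,j)∈h} c_ij / Σ_{(i,j)∈h} (c_ii + c_jj)/2

where C is the Gower-centered squared trait-distance matrix.  The
denominator convention — each pair contributes both its diagonal entries,
halved, once per pair involvement — is pinned by a brute-force oracle in the
tests, because published implementations differ in this detail.  Pairs at
exactly zero distance land in the first class.  Significance permutes the
society-to-location assignment (two-tailed, 999 by default); confidence
intervals bootstrap pairs within a class.  Under the null the coefficient
has the usual small negative bias (≈ −1/(n−1)), so "no autocorrelation"
means r near that value, not exactly zero.  The significant range walks
classes outward and reports the last distance before the run of positive,
significant classes breaks.

## Treelikeness

For four taxa the three pairings of pairwise distances give sums m1 ≥ m2 ≥
m3; the quartet's delta is (m1−m2)/(m1−m3), zero when m1 = m3 (the fully
degenerate quartet — by the convention in the delta-score literature, ties
count as treelike).  The score of a matrix is the mean over all C(n,4)
quartets, enumerated exactly up to 10⁶ quartets and subsampled (default
10⁵, seeded) beyond that; taxa themselves can be subsampled first, which is
the standard way to make regional comparisons affordable.

One degeneracy deserves emphasis: distances derived from a *scalar* per-taxon
value are always additive (any four collinear points satisfy the four-point
condition), so a per-dimension delta computed from 1-D differences of mean
scores is identically zero.  Per-dimension treelikeness is therefore
meaningful only on distances that aggregate within-society spread — the
per-dimension Φ_ST matrices — and `delta_by_region` accepts those through
`variable_matrices`; the pipeline wires them in by default.  The joint
("All") row uses Euclidean distance over all dimensions and has no such
degeneracy.

## Association

Distance matrices are embedded by principal coordinates (eigendecomposition
of −½JD⁽²⁾J); negative eigenvalues are dropped from both the coordinates and
the variance denominator, with no Cailliez/Lingoes correction; axes
explaining more than 10% of the positive-eigenvalue variance are retained
(always at least the first).  Mantel correlations are Pearson r over
upper-triangle entries with simultaneous row/column permutations of one
matrix (two-sided); the partial variant residualizes both matrices on the
third, entrywise, and permutes the residualized response as a matrix.  When
the conditioning matrix fully explains one side (e.g. controlling a matrix
for itself) the partial correlation is reported as 0 — nothing remains to
correlate; only when *both* sides are exhausted is it an error.

Redundancy analysis regresses the response axes on the explanatory axes
(both residualized on conditioning axes when present) and reports R² as the
explained share of total response variance, adjusted by Ezekiel's formula
1 − (1−R²)(n−1)/(n−m−1) with m the number of explanatory axes.  A
semipartial alternative (difference of adjusted R² between full and
conditioning-only models) is available; Ezekiel on the residualized fit is
the default.  The permutation p for RDA shuffles rows of the explanatory
axes and is upper-tailed, the statistic being nonnegative.

## The synthetic worlds

A world hangs everything off one Yule tree rescaled to unit depth:
latent means evolve by Brownian motion (rate 1/unit depth per dimension);
coordinates diffuse along the same tree (30° per unit depth, longitude
wrapped, latitude clamped), so geography mirrors ancestry as it does in real
data; songs add within-society noise (sd 0.5 on the latent scale), map
through a known loading matrix (0.7 per indicator, round-robin over the five
dimensions) with unique noise sd √(1−0.7²), and are binned to 13 ordinal
levels with 3% of cells duplicated as multi-coded; allele frequencies drift
down the same tree under Balding–Nichols with per-branch F = 1−exp(−f·ℓ)
(default f = 0.05) and dosages are binomial draws (10 individuals per
society).  Defaults are 30 societies × 10 songs and 500 SNPs, which runs the
full pipeline in seconds; a single seed fans out to independent per-layer
streams, so changing one layer's parameters never perturbs another.

Horizontal transmission is modeled as per-dimension borrowing: with
probability h, a society's value on a dimension is replaced by that
dimension's value in a random one of its five nearest geographic neighbors.
We deliberately did not model borrowing as neighbor *averaging*: averaging
is a smoother — it shrinks local differences and in our experiments
systematically *lowered* delta scores (0/20 seeds showed the expected
ordering), because the h=0 baseline (independent Brownian dimensions) is
already far from additive and smoothing reduces that conflict faster than it
adds reticulation.  Dimension-wise borrowing, by contrast, gives different
dimensions different donors — the classic signature of conflicting
histories — and raises delta in 19–20 of 20 replicate worlds at h = 0.8.

What the synthetic evidence shows: the estimators recover their generating
parameters (loadings to ±0.05 at 2000 songs; θ tracking drift with rank
correlation > 0.9; delta ordering under borrowing; partial-Mantel power
≥ 80% when music and genes share a tree and false-positive rate ≤ 10% when
they do not).  What it does not show: robustness to the things real song
corpora add — unbalanced sampling, coder disagreement beyond a scalar kappa,
non-Brownian trait change, genre structure within repertoires, and
ascertainment in SNP panels.  Conclusions about real data rest on the
estimators being correct (the oracle tests), not on the generator being
realistic.

## Problem sizes and tolerances

Oracle-equivalence tests run 100 random instances per statistic at n ≤ 12;
permutation-uniformity checks use 80–100 replicate null datasets at 99
permutations; the recovery experiments use the world sizes quoted above.
Symmetry of distance matrices is enforced to 1e-8 and then averaged;
eigenvalues below 1e-9 of the spectral radius count as zero in PCoA;
permutation p-values use the add-one convention (b+1)/(m+1).  The Matérn
correlation follows the geostatistical (κ, φ) parameterization, ρ(u) =
2^(1−κ)/Γ(κ) (u/φ)^κ K_κ(u/φ), with ρ(0) = 1; at κ = ½ it reduces to
exp(−u/φ) exactly, which the tests assert.  Earth radius is fixed at
6371.0 km and configurable.

## Known limitations

- Ordinal indicators are treated as continuous; no polychoric correlations,
  standard errors, or robust corrections.
- AMOVA handles at most three hierarchy levels and trait (not
  haplotype-frequency) data.
- The F_ST layer reads dosage tables, not binary PLINK or VCF; convert
  upstream.
- The GenAlEx-style variogram implements one pinned denominator convention;
  a strict-compatibility toggle for other variants is future work.
- Matérn conversion of fixation matrices to correlations is exposed as an
  optional transform but enters no downstream stage by default.
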