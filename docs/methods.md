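# Methods

## The analysis

`mirnet` implements a rank-based association screen linking miRNA
expression in post-mortem cortex to per-subject variables in a small
autopsy cohort, and the downstream artifacts that make the screen
interpretable: signed phenotype-hub networks, group-comparison tables,
and target-prediction "connectivity" scores.

### The screen

Raw miRNA counts are first normalized per subject (each column divided
by the subject's total miRNA count), then miRNAs detected (count > 0)
in fewer than `min_present` subjects (default 11 of 26) are removed.
Every retained miRNA is correlated with every phenotype using
tie-corrected Spearman rank correlation: both variables are converted
to ranks across subjects, tied values receive their mean rank, and rho
is the Pearson correlation of the ranks.  Higher expression, higher
pathology stage, older age and better test performance all receive
higher ranks, so a positive rho always reads "more expression goes with
more of the phenotype".  Chromosomal sex is the one exception: it is
binary, so the screen uses the point-biserial coefficient — Pearson R
of the 0/1-coded sex (male = 0, female = 1) against the normalized
expression values — meaning a positive R is higher expression in
females.

Two-sided p-values come from the t approximation
t = rho·sqrt((n−2)/(1−rho²)) on n−2 degrees of freedom, which is the
standard default at this sample size and remains serviceable under
ties.  |rho| = 1 reports p at the machine floor rather than zero.
Associations with uncorrected p < 0.05 survive; p < 0.0005 flags a
record for emphasis.  Inverting the t relation at n = 26 gives the
screening bound |rho| ≥ 0.388: no weaker correlation can be significant
in the full cohort.  An optional Benjamini–Hochberg mode (conventional
boundary q ≤ 0.1) computes q-values across the full pre-filter record
set and additionally requires q below the boundary; it is off by
default because the primary screen is deliberately uncorrected.

All subjects enter every correlation, with zero counts ranked (tied) at
the bottom — ranks always span the whole cohort, and sparsity is
handled by the presence filter alone.  Missingness in a *phenotype*
(the default simulation hides pathology loads for two stage-III
subjects, mirroring the source cohort) is handled pairwise: the
affected correlations drop those subjects and record the n actually
used.

### Composites

The 19-test neuropsychological battery maps onto five cognitive
domains (episodic memory 6 tests, semantic memory 4, working memory 4,
perceptual orientation 3, perceptual speed 2).  A domain composite is
the mean of the per-test z-scores (z computed across subjects within
each test, sample SD) over the subject's non-missing mapped tests; the
global composite (GCS) is the mean over all 19 z-scored tests.  A test
may carry a dual display label (e.g. a fluency test shown as "sem/lan")
but contributes to exactly one scoring domain.

### Ordinal encodings

Fixed once, everywhere: Braak I–VI → 1–6 (group I–II / III / IV derived
from stage), CERAD No AD < Possible < Probable < Definite → 0–3,
NIA-Reagan Low < Intermediate < High → 0–2, pathology loads 0–5 as
scored.  Ordinals are ranked with mean-rank tie correction like any
other variable.

### Networks

Each (phenotype, sign) pair with at least one significant record
becomes a hub node (`age_pos`, `perc.sp_neg`, ...); each significant
miRNA becomes a miRNA node linked to its hubs with edge weight
100·|rho|.  The graph is bipartite by construction and node degree
(number of connections) drives node size in plots.  Layout is a
two-phase force loop — weighted linear attraction along edges plus
inverse-distance repulsion, then a radial gravity pull toward the
origin scaled by (1 + degree) — iterated until the maximum displacement
falls below tolerance, a rounded-position digest repeats (limit cycle),
or the iteration cap.  Coordinates are presentation-only: seeded,
deterministic, exported to GEXF/GraphML, and never feeding any
statistic.  A fully connected four-node test graph with equal weights
settles into a square-like equilibrium (four equal sides, longer
diagonals), which is what this force law admits in two dimensions.

### Group comparisons

Categorical variables are compared across Braak-stage groups with the
Pearson chi-square test on the contingency table, no continuity
correction (the tables are larger than 2×2; this choice reproduces the
published p-values exactly: sex 0.84, ApoE 0.28, CERAD 0.16,
NIA-Reagan < 0.01).  Expected counts below 5 log a warning but never
block computation — small cells are a fact of autopsy cohorts.  Numeric
and ordinal variables use tie-corrected Kruskal–Wallis; post hoc
contrasts use Dunn's z approximation with the tie-corrected pooled
variance, reported raw and Bonferroni-adjusted side by side because the
adjustment convention is lab-dependent.

### Connectivity scores

Predicted miRNA–mRNA interactions enter as a file (no live database
queries, for reproducibility).  Curated records must carry a validation
score ≥ 0.8 (inclusive); sequence-prediction records pass through and
are instead screened on their logit probability.  Multiple predicted
sites of one miRNA on one transcript collapse to a single hit, so a
gene's hit count is its number of distinct predicted regulator miRNAs.
The category connectivity score is the mean hit count over the
category's panel genes, zero-hit genes included in the denominator —
the most literal reading of "adjusted by the number of genes in each
category and averaged".  The minimum logit probability is a required,
exposed parameter (default 0.5) because no canonical value exists; all
reported scores state the threshold used.  The packaged 16-gene panel
spans amyloid processing (7 genes), tau (5), cytokines (3) and the REST
transcription factor (1); the packaged resilience set lists the 12
differentially expressed miRNAs (8 up, 4 down), each named cluster
counted once.

## The synthetic cohort

No raw sequencing data ships with the package, so a generator supplies
cohorts and count matrices with the structure the screen assumes.

**Cohort.**  26 subjects split 8/8/10 across Braak groups I–II/III/IV.
Sex, ApoE, CERAD and NIA-Reagan composition per group follow the
published contingency tables exactly when sizes match (shuffled within
group by seed; proportional sampling otherwise).  Ages, education and
MMSE are uniform within published per-group ranges — medians therefore
only loosely match the published ones, but the significant age–Braak
gradient is preserved.  Pathology loads are rounded clipped normals
around the published group means; loads for two stage-III subjects are
hidden to exercise pairwise-complete handling.  Each subject draws five
independent standard-normal domain latents; a test score is its
domain's latent plus N(0, sd²) noise (default sd 0.6, chosen so
within-domain test correlations land in a plausible 0.6–0.8 band); GCS
is the mean of the 19 z-scored tests.

**Counts.**  Per-miRNA negative-binomial marginals with log10 means
uniform on [0.5, 3] and dispersion α = 0.3 (Var = μ + αμ²; α = 0 is the
Poisson limit) — conventional RNA-seq choices, not claims about the
source data.  Per-subject lognormal library-size factors (CV 0.3)
scale the means.  Presence rates: each miRNA gets a target rate uniform
on [0.42, 1.00]; cells are zeroed with a probability shrunk by the
NB's own zero mass so the *population* presence rate hits the target
(realized rates add binomial noise at n = 26).

**Planted effects.**  A planted (miRNA, phenotype, ρ) triple couples
the miRNA's latent Gaussian to the phenotype's normal scores with
Pearson correlation r = 2·sin(πρ/6), then quantile-transforms to the NB
marginal — the classical relation making the population Spearman
correlation equal ρ.  Planted miRNAs are exempt from zero-inflation
(presence 1) so the planted ρ is the population value the screen
estimates.  The default simulation plants 12 effects with |ρ| 0.45–0.6
echoing the observed pattern: positive with age and the perceptual
domains, negative with semantic/episodic memory, mixed with Braak
stage.

**What the simulation does not emulate.**  Real miRNA count matrices
have correlated miRNAs (families, clustered loci, shared regulation);
here non-planted miRNAs are mutually independent, so the null
calibration tests speak to marginal type-I control, not to the
effective number of independent tests in real data.  Cognitive tests
load on a single latent per domain with no cross-domain correlation,
no floor/ceiling effects and no practice effects.  Library-size
variation is lognormal and independent of group.  Passing tests
therefore demonstrate that the machinery recovers known structure at
the study's scale — not that the published effect sizes would replicate.

## Numerical choices

- All written numbers use 6 significant digits; file row orders are
  fixed (hub then miRNA, lexicographic), so identical inputs give
  byte-identical outputs.  The GEXF modification date is pinned.
- Normalized columns must sum to 1 within 1e-9; presence-filtered
  subsets of a normalized matrix may sum to less, never more.
- Zero-variance phenotypes are skipped with a logged warning;
  zero-variance miRNA rows yield no record for that phenotype.
- The Spearman/point-biserial p floors at the smallest positive double
  rather than reporting 0.
- Monte-Carlo problem sizes: power uses 500 replicate matrices, each
  one planted miRNA among 60 nulls at n = 26, measured through the
  normalize-then-correlate path the screen actually takes (normalizing
  against a null-dominated total, as in real data, removes library-size
  noise; a matrix made *only* of planted rows would instead cancel its
  own signal in the totals); type-I uses 10,000 null miRNAs against one
  phenotype; copula
  calibration uses 1,000 replicates at n = 500 per target.  These sizes
  put the Monte-Carlo standard errors well inside the asserted margins
  (e.g. ±0.02 on a mean Spearman at n = 500 is ~14 SE).

## Known limitations

- The t-approximation p-value is asymptotic; exact permutation p-values
  are not implemented (scipy's implementation serves as a test oracle
  only).
- The layout is a documented approximation of a two-step gravity loop;
  it makes no attempt to reproduce any specific external tool's
  geometry.
- The connectivity score's averaging step and logit threshold follow
  this package's stated convention; other reasonable readings exist.
- Chi-square p-values on small tables are asymptotic; the package
  reports them (with a warning) for comparability rather than switching
  to exact tests.
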