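# Methods

## Design and model

The experiment is a 2 x 2 x 2 factorial: selection history (`line_type`:
control vs. resistant), herbicide treatment (`treatment`: unsprayed vs.
sprayed) and sampling time (`timepoint`: 8 or 32 h after spray). Expression
is modelled with one coefficient per occupied cell of the factorial
(group-means parameterization) rather than main effects plus interactions.
Pooling over timepoints is then simply a contrast that averages the two
timepoint cells; this keeps per-timepoint and pooled comparisons mutually
consistent without assuming additivity of time. The six standard contrasts
are the spray response within control lines (8 h, 32 h, pooled), the spray
response within resistant lines (pooled), and the resistant-vs-control
difference in each environment (unsprayed and sprayed).

Family, block and breeding-design structure below the line level is not
modelled: samples within a cell are treated as exchangeable replicates,
and no random effects or duplicate-correlation adjustment is applied.

## Normalization and filtering

Genes are kept when their CPM reaches `cpm_min` (default 10) in at least
k samples, k being the smallest design-cell size (inclusive boundary), so
genes expressed in only one group survive. Library sizes of a filtered
matrix deliberately retain the pre-filter column totals: CPM remains
defined against sequencing depth, and the filter becomes idempotent.

Between-sample factors use the trimmed mean of M-values. Against a
reference sample (the one whose 75th-percentile CPM is closest to the
mean of those percentiles; lowest index on ties), each gene nonzero in
both samples contributes a log-ratio M and log-abundance A; genes in the
upper/lower 30% tails of M and 5% tails of A are discarded (ranks are
positional on ties, for determinism on small fixtures) and survivors are
averaged with inverse-variance weights, the delta-method variance of M
being (N_k − y_k)/(N_k y_k) + (N_r − y_r)/(N_r y_r). Factors are scaled
to unit geometric mean. The implementation reproduces edgeR's
`calcNormFactors` to at least six decimals on test fixtures, and is
cross-checked against it (via Rscript) in the test suite.

## Precision weights and moderation

Log2-CPM uses a 0.5 prior count: log2((y + 0.5)/(N·f + 1)·10⁶). Per-gene
OLS residual standard deviations are square-root transformed and smoothed
against average log2 count with lowess (tricube weights, span 0.5, two
robustness iterations); the trend is evaluated at each observation's
fitted log2 count, extrapolated flat beyond the fitted range and floored
at 10⁻⁶, and the weight is the predicted value to the power −4 (an
inverse-variance weight). Because weights come from the trend, a gene
with zero residual variance still receives finite weights.

Moderation moment-matches a scaled inverse-χ² prior on the gene
variances: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of
var(e) over the mean of ψ′(d_g/2) identifies d₀ through the trigamma
inverse (monotone Newton iteration), and s₀² = exp(ē + ψ(d₀/2) −
log(d₀/2)). When the observed spread does not exceed χ² sampling noise,
d₀ = ∞ and all variances collapse to s₀² (p-values from the normal
distribution). Zero variances are excluded from prior estimation but
still squeezed. Tests are two-sided throughout; FDR is Benjamini–Hochberg
within each contrast, matching how per-comparison significant counts are
reported. The prior is estimated once per fitted design and shared across
contrasts, since it is a property of the residual variances, not of the
contrast.

## Classification and concordance

Calls at level α (default 0.1, on the BH-adjusted p-values): a gene
significant in both the plastic and evolved contrasts is adaptive when
the two LFCs share a sign, maladaptive when they oppose; an exactly zero
LFC among doubly significant genes is "unclassifiable" and is excluded
from the binomial count with a warning (measure-zero in practice). The
evolved input must be the unsprayed contrast — contrast metadata is
checked and a sprayed evolved table is refused unless explicitly
overridden — because selection measured under spray confounds the evolved
response with plasticity. The two-sided binomial test uses the
minimum-likelihood convention (all outcomes no more probable than the
observed one), which at p₀ = 0.5 equals doubling the smaller tail. With
zero doubly significant genes the test result is undefined (reported as
such), not p = 1.

Plasticity amplification compares |LFC| per gene between the resistant
and control spray responses over all shared genes; exact ties count as
*not* greater, conservative for any "majority amplified" claim.
Timepoint concordance is the Pearson correlation of LFCs over all shared
genes (not only significant ones) plus the count of doubly significant
genes whose direction flips. Term enrichment is a one-sided
hypergeometric (Fisher) test per term over a user-supplied gene→term map,
BH-adjusted across terms.

## The synthetic-data generator

Counts are negative binomial, Var = μ + φμ², with a dispersion trend
φ_g = a1 + a0/μ̄_g (defaults a1 = 0.04, a0 = 2: squared biological CV
~0.04 for abundant genes, inflated for rare ones — typical bulk RNA-seq
magnitudes). Baseline abundances are log2-normal (mean 5, sd 2 log2-CPM
units) and renormalized to sum to 10⁶, so "CPM" in the generator is a
proper composition; library sizes are log-normal around 28 million reads,
the depth scale of the motivating experiment. The default design has
eight replicates per factorial cell (the motivating experiment had 15–16
plants per line x treatment group split over two timepoints); unequal
cells are available through a per-cell override.

Effects are planted on the log2 scale: plastic effects shift sprayed
samples (times `amplification` in resistant lines, so amplification = 1
means selection left plasticity unchanged), evolved effects shift
resistant samples, and both are identical at the two timepoints (the
motivating data showed strongly correlated 8 h and 32 h responses).
Effect magnitudes are |N(mean, sd)| with random signs; genes carrying
both effects are sign-concordant with probability `prob_concordant`.
Class labels (adaptive / maladaptive / plastic_only / evolved_only /
null) follow deterministically from the planted signs and are validated
on construction.

What the generator does *not* emulate: family/pedigree structure within
lines, batch or lane effects, gene length and GC biases, outlier samples,
and correlated expression between genes (genes are independent given the
design). Passing tests therefore demonstrate correctness of the
statistical machinery under the model's own assumptions, not robustness
to those real-data complications.

## Study conditions used by the acceptance script and heavy tests

Simulation experiments are desk-scale by design: 2,000–5,000 genes and
4–8 replicates per cell, 20 independent seeds per experiment.

- Concordance recovery: 5,000 genes, 8 per cell, effect mean 2, 5% of
  genes with both effects, planted concordance 0.72 — strong effects so
  the doubly significant set is large and the recovered fraction is
  dominated by bookkeeping, not power. The recovered fraction sits
  slightly below the planted value because a few single-effect genes leak
  into the doubly significant set with a random second sign.
- Null calibration: all effect fractions zero; any FDR < 0.1 call is a
  false call.
- Amplification detection: amplification 2 with effect mean 1.0, sd 0.5
  and 4 replicates per cell. Marginal effect sizes are essential here:
  the significant-gene *count* comparison between lines only responds to
  amplification when part of the effect distribution sits near the
  detection boundary; with uniformly strong effects both lines saturate
  and the comparison is uninformative by construction.
- Variance-prior recovery: 50,000 variances drawn exactly from the
  scaled inverse-χ² prior with d₀ = 4, s₀² = 2, d_g = 10.

## Numerical choices and edge cases

- Lowess trend: statsmodels implementation; duplicate abscissae are
  deduplicated before interpolation; trend values floored at 10⁻⁶.
- Trigamma inverse: Newton iteration with the closed-form guards
  1/√y (y > 10⁷) and 1/y (y < 10⁻⁶); relative convergence 10⁻¹⁰.
- TMM: a sample identical to the reference (max |M| < 10⁻⁶) gets factor
  1 before rescaling; a sample sharing no nonzero gene with the reference
  is an error, as is any zero library size (reported by sample name).
- Weighted fits use batched normal equations; a singular per-gene
  weighted design is reported by gene id.
- All tables are tab-separated UTF-8 with mandatory headers, floats at 6
  significant digits; the summary JSON keeps full precision; the run
  manifest records SHA-256 checksums of all outputs, and identical
  configs reproduce identical checksums.

## Known limitations

- The moderated model assumes independent genes; correlated genes make
  the binomial concordance test anti-conservative in real data.
- TMM assumes a majority of non-differential genes; simulations that
  plant effects in most of the transcriptome show a compositional shift
  that normalization cannot remove (visible in the test suite, where one
  recovery test deliberately uses a mostly-null transcriptome).
- No quasi-likelihood or exact negative-binomial tests, no batch/surrogate
  variable correction, no random effects.
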