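# Methods

`xburden` implements a gene-based rare-variant collapsing ("burden")
association analysis for X-linked recessive disease in hemizygous males, of
the kind used to detect depletion-intolerant genes enriched for very rare
deleterious variants in case/control sequencing cohorts. This note documents
the statistical model, the filters, the synthetic-cohort generator used as
test bed, and the numerical and design choices that were genuinely open.

## Burden model and test

For each gene, sample *i* contributes a binary carrier indicator
$g_i \in \{0,1\}$ — 1 iff the sample carries at least one *qualifying*
variant of the gene (non-synonymous: predicted loss-of-function, missense, or
in-frame indel; population MAF strictly below $10^{-4}$; variants absent from
the reference population qualify). Carrying two qualifying variants counts
once; an allele-count (CMC-style) collapse is available via
`collapse_carriers(mode="count")` but is not the default, because the
comparison of interest is the proportion of carriers. The outcome
$y_i \in \{0,1\}$ (1 = case) is modelled by logistic regression

$$\operatorname{logit} \Pr(y_i = 1) = \beta_0 + \beta_g g_i +
\sum_{k=1}^{5} \gamma_k \mathrm{PC}_{ik} + \delta\,\mathrm{age}_i ,$$

with age in years, untransformed, and the first five genotype principal
components as ancestry covariates.

Rare-variant tables are sparse — a gene may have carriers only among cases —
so maximum likelihood diverges under separation. We use Firth's bias-reduced
estimator: maximize the penalized log-likelihood
$\ell^*(\beta) = \ell(\beta) + \tfrac12 \log\det I(\beta)$ with
$I(\beta) = X^\top W X$, $W = \mathrm{diag}(\pi_i(1-\pi_i))$ (a Jeffreys
prior), which keeps all estimates finite. For an intercept+carrier design
this estimator coincides with the log odds ratio of the 2×2
carrier-by-status table after adding 0.5 to every cell; the test suite pins
this equivalence to $10^{-6}$, including on separated tables.

### Penalized profile likelihood-ratio test

The per-gene p-value comes from a likelihood-ratio test referred to
$\chi^2_1$. The null fit pins $\beta_g = 0$ and re-maximizes the remaining
parameters **under the full design's penalty** (a penalized profile
likelihood, as in `logistf`). The alternative construction — refitting the
null on the reduced design with its own, lower-dimensional penalty — adds
$\log\det I_{\text{full}}/\det I_{\text{null}}$, a systematically positive
$O(\log n)$ term, to the statistic: measured type-I error was 0.16 at
nominal 0.05 over 2,000 null genes, versus 0.049 for the profile
construction. The profile LRT is therefore the only construction offered.

### Multiple testing and eligibility

Genes with at least `min_case_carriers` (default 5) case carriers form the
eligible set; the family-wise threshold is $\alpha / n_{\text{eligible}}$
and eligible genes get $p_{\text{corr}} = \min(1, p \cdot n_{\text{eligible}})$.
Ineligible genes are still fitted and reported with raw p-values but are
excluded from the Bonferroni denominator (with 226 eligible genes and
$\alpha = 0.05$ the threshold is $2.2\times10^{-4}$ to two significant
figures). A synonymous-variant negative-control analysis (`control_mode`)
applies the identical machinery to rare synonymous variants, where no
enrichment should appear.

## Quality control

Genotype-level filters (failing calls become missing, GATK-style masking,
not dropped rows): depth < 8 reads; GQ < 20; minor read ratio
$\mathrm{MRR} = \min(\mathrm{ref}, \mathrm{alt}) / (\mathrm{ref} +
\mathrm{alt})$ below 20% **when minor-allele reads are present**. All
inequalities are strict: DP = 8, GQ = 20 and MRR = 0.20 pass. The
minor-reads qualifier is a deliberate adaptation for haploid calls: a
confident hemizygous call has *zero* minor reads (MRR = 0), and an
unqualified "< 20%" rule would discard every clean call on the male X; the
filter as implemented rejects exactly the calls whose minor allele has read
support too weak to be believed and too strong to ignore. The MRR
denominator is informative reads (ref+alt), not DP; `mrr_denominator="dp"`
switches to total depth. Calls with a non-missing genotype but zero
informative reads are flagged malformed and masked.

Site-level filters, applied after genotype masking (so masked calls count
toward cohort missingness) and reported by first failing reason in this
order: reference-population call rate < 50%; non-PASS flag in the reference
database; overlap with user-supplied low-complexity/decoy BED intervals;
more than four alleles at the site; more than 20% missing genotypes in the
cohort; span above 20 nucleotides. Boundary values pass. Whether site
filters run before or after genotype masking is switchable
(`site_filters_first`); genotype-first is the default and the missingness
filter is re-evaluated after masking in either order. QC is idempotent and
every removal is attributed to exactly one reason; the report reconciles
input = removals + retained at both levels.

## Ancestry PCA

Covariates come from an in-cohort genotype PCA rather than projection onto
an external reference panel: the covariate's job is to absorb case/control
frequency differences due to ancestry, which in-cohort structure captures,
and a reference panel is external data this package does not ship.
Externally computed scores can be supplied as a TSV
(`sample_id, PC1..PCk`) to reproduce a reference-projected setup. Variants
enter the PCA if in-cohort MAF > 0.01 and call rate > 0.99 (strict);
residual missing entries are mean-imputed. Columns are centered and scaled
by $\sqrt{p(1-p)}$ at the estimated allele frequency (hemizygous ploidy 1 by
default; `scale=False` gives unscaled PCA). Scores are top-k left singular
vectors scaled by singular values, sign-fixed so each component's
largest-magnitude loading is positive; a fully degenerate matrix (identical
rows) yields all-zero scores rather than an error, while k above the rank of
a non-degenerate matrix is an error.

## Numerical details of the Firth fit

Newton iteration on the modified score
$U^*_j = \sum_i (y_i - \pi_i + h_i(\tfrac12 - \pi_i)) x_{ij}$, with $h_i$
the hat diagonals, update $I^{-1}U^*$, initialized at $\beta = 0$, up to 100
iterations with up to 25 step-halvings whenever $\ell^*$ would decrease
(with a tolerance of a few ulps of $\ell^*$, since near the optimum a full
Newton step's true improvement falls below float64 resolution). The design
is internally reparameterized to centered, unit-variance columns through an
exact invertible transform — a pure change of coordinates that leaves
estimates, hat values and LRT statistics unchanged while making the Newton
system well-conditioned for covariates on arbitrary scales (ages in years,
raw PC scores).

Convergence requires step norm below `tol` = 1e-8 **and** max modified
score below `gtol` = 1e-5. The two tolerances differ deliberately: a design
containing a single-observation indicator (a gene with exactly one carrier)
gives that observation hat value exactly 1 and $\ell^*$ extreme higher-order
curvature; the analytic score then plateaus near $2\times10^{-6}$ while the
estimate itself is stable to below $10^{-9}$ (central-difference gradients
confirm the true gradient is ~0 at the plateau). Log-likelihoods are
evaluated in log space (`logaddexp`), the penalty via `slogdet`.

## Synthetic cohort generator

The generator exists so every stage is testable without protected data. It
emulates, at reduced gene count, a male-only X-chromosome case/control
sequencing study:

* **Cohort**: 1,202 cases (age ~ truncated normal, mean 52.9 y, SD 16.4,
  lower bound 0.5 y) and 331 controls (mean 38.7 y, SD 17.2); three
  discrete ancestry strata with weights (0.60, 0.25, 0.15), assigned
  independently of phenotype.
* **Rare-variant architecture**: per-gene variant counts
  Poisson(`variants_per_gene_rate`, default 200); population MAF
  log-uniform on $[10^{-6}, 10^{-2}]$; consequence classes with
  probabilities (LOF 0.08, missense 0.55, in-frame indel 0.04, synonymous
  0.25, other 0.08). The default of 40 genes (rather than the 731 X-linked
  genes of a real exome) keeps a full pipeline run in seconds; the per-gene
  rate is a placeholder for an unpublished distribution and is exposed in
  `CohortSpec`.
* **Ancestry-informative common variants**: 200 sites with
  Balding–Nichols stratum frequencies ($F_{st} = 0.05$) supply the PCA.
  They are generated cleaner than the rare background (missingness 0.3%,
  contamination 0.4%) because the analysis selects call-rate > 0.99
  variants, which in real capture data exist in abundance only among
  well-behaved common sites.
* **Planting**: the planted gene's qualifying sites carry exactly
  `planted_case_carriers` (21) case carriers and
  `planted_control_carriers` (0) control carriers — exact counts, not
  expectations; carriers are chosen by a seeded shuffle, each assigned one
  qualifying site uniformly, and background carriers at those sites are
  cleared. Planted carrier calls are generated clean (DP ≥ 20, GQ ≥ 40, no
  minor reads, never missing) so the counts survive QC exactly. Planted
  case carriers draw ages from a younger law (mean 34.4 y, SD 16) matching
  the observed carrier ages; this is what makes age adjustment sharpen,
  rather than dilute, the planted signal, and it is why the planted gene's
  adjusted p lands at $10^{-6}$–$3\times10^{-4}$ where the marginal 2×2
  test alone gives only ~$3\times10^{-3}$.
* **Genotype noise**: depth negative-binomial (mean 40, shape 8); GQ
  rounded normal (mean 70, SD 18) clipped to [0, 99]; with probability 0.03
  a call receives minor-allele reads with Beta(1.5, 6) fraction
  (contamination); 2% of calls missing outright. Each QC filter removes
  records on the default cohort.

What the generator does **not** emulate: linkage disequilibrium, relatedness
and cryptic kinship, sequencing-batch and capture-kit effects, admixture
continua (strata are discrete), genotype-calling error correlated with
variant type, and the true per-gene distribution of rare-variant counts.
Passing tests therefore demonstrate correctness of the statistical machinery
under the stated sampling assumptions, not robustness to those real-data
phenomena.

## Reporter-activity classification and cumulative frequency

Alleles assayed in an NF-κB luciferase reporter (activity as % of stimulated
wild type, stimulated conditions R848/imiquimod/CL264, replicates aggregated
by mean and re-anchored to the wild-type mean so raw luminescence units
cancel) are classified: loss-of-function if activity ≤ 5% of wild type
(indistinguishable from empty vector — the 5% default is a modelling choice,
exposed in `ClassificationRule`), hypomorphic if strictly below 25%, neutral
otherwise (25.0% is neutral; the bound is strict). The cumulative male MAF
of a deleterious allele set (LOF ∪ hypomorphic, or strict-LOF) is the plain
sum of per-allele male frequencies; on the male X this approximates the
hemizygote frequency, i.e. the population frequency of the at-risk genotype.
Proportions in reports are rounded to one decimal of percent; underlying
values keep full precision.

## Problem sizes used in checks

The test suite runs most checks on a scaled-down cohort (120/40 samples, 8
genes); power and calibration checks use the full simulated study scale
(1,202/331) with 20 seeded replicates for power and 2,000 null genes for
type-I error. `scripts/acceptance.py` runs one full-scale planted cohort,
the printed-count descriptive statistics, the separated-table Firth
estimate, and a 1,000-gene null calibration; all randomness derives from
its `--seed`.

## Known limitations

* The burden test treats the carrier indicator as fixed; uncertainty from
  genotype calling and QC masking is not propagated.
* χ²(1) calibration degrades for genes with very few carriers (the test is
  conservative there); eligibility filtering keeps the corrected analysis on
  genes where the approximation is adequate.
* In-cohort PCA can absorb true signal if case/control sampling is strongly
  confounded with ancestry; the reference-projection hook exists for that
  situation.
* The synonymous negative control shares QC and collapsing code with the
  primary analysis, so it checks calibration of the statistics, not of
  annotation quality.
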