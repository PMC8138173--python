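# Methods

## Data model

The analysis unit is a β-value matrix (probes × samples) per prandial
state, with aligned per-sample metadata: subject, BMI and BMI class
(N 18.5–24.9, Ow 25–29.9, Ob > 30 kg/m², half-open bins), age, fatty-acid
percentages, and six leukocyte proportions.  Each subject contributes one
pooled sample per state; there is no draw-level structure.  β is clipped to
`[1e-6, 1 − 1e-6]` at load (the logit diverges at the boundary; the clip
constant is configurable), and probes with any missing value are removed
rather than imputed.  Genomic coordinates are 0-based half-open everywhere,
BED-native, so island geography has a single off-by-one-free convention.

## Statistical procedure

All hypothesis tests operate on M = log2(β/(1−β)); β is used for effect
sizes.  Per-probe covariate testing is normality-adaptive: Shapiro–Wilk at
α = 0.05 on both vectors selects Pearson (both normal) or Spearman
(otherwise).  The gate is configurable (`both`/`either`/`y_only`); `both`
is the default because Pearson's null theory assumes joint normality and a
single non-normal margin is enough to violate it.  Spearman uses average
ranks and the t-approximation p-value, adequate at n = 12 (empirical size
0.050 over 40,000 null simulations).

A probe is called a dmCpG under the dual rule: nominal p < 0.05 (no
genome-wide correction, mirroring small-cohort EWAS practice) **and**
|Δβ| > 0.10 between extreme groups.  For BMI the extreme groups are the
obese and normoweight classes; for fatty-acid covariates the top and bottom
covariate tertiles of size ⌊n/3⌋ — in the 12-subject design the BMI
tertiles coincide exactly with the N and Ob classes, so the two readings
agree where both apply.  Saturation-group covariates (SFA, MUFA, PUFA) are
the per-sample sums of member fatty-acid percentages; fatty-acid values are
always percent-normalized per sample.  Glucose and the incompletely
determined C18:3 are rejected as covariates at construction.

Paired FS-vs-PS testing within a BMI class uses the subject-paired
difference of M-values: paired t when the differences pass Shapiro–Wilk,
otherwise Wilcoxon signed-rank with the exact null for n ≤ 25 (tie-free),
a continuity-corrected normal approximation above or under ties, and zero
differences dropped before ranking (p = 1 when fewer than 3 remain).  With
four pairs the exact two-sided Wilcoxon minimum is 2/16 = 0.125, so calls
at that class size can only come from the t branch; the code warns to make
this visible.  An `approx` flag forces the asymptotic p throughout.

Cell-composition adjustment is an OLS fit of M on intercept + covariate +
cell proportions (one column dropped for identifiability, constant columns
dropped), with the covariate's two-sided t-test p-value reported.  Both the
unadjusted and adjusted p-values are carried in every result row, since
either may be the quantity of interest; `adjust_cells` selects which one
the dmCpG rule consumes.  The per-probe fit is vectorized across the matrix
(the design is shared), and is verified against statsmodels in the tests.

The probe filter removes, in fixed order: SNP-affected probes (user-supplied
list), chrX/chrY probes, probes with detection p > 0.01 (quantifier
configurable `any`/`all`/`mean`, strictest default), probes with missing
values, and probes whose M-values associate with age at p < 0.05 using the
same normality-adaptive correlation.  When both states are filtered
together, the union of age-associated probes is removed from both so FS and
PS share a single probe universe.  Reattributing a probe to a different
removal reason never changes the retained set, only the bookkeeping.

Island geography: positions inside a merged island interval are `island`;
the 2,000 gap bases outside either boundary are `shore`; the next 2,000 are
`shelf`; everything else `open_sea`.  Distances count gap bases (a probe at
an island's `end` coordinate is the first shore base).  Set-level context
tests use chi-square goodness-of-fit of the called set's category counts
against probe-universe proportions (not a 2×k contingency table: the
universe is orders of magnitude larger than any called set, so its
proportions are effectively fixed); categories with expected count < 1 are
merged into their neighbour.  Gene-set over-representation is a one-sided
hypergeometric tail with Benjamini–Hochberg FDR, against an explicit,
user-supplied universe.

## Synthetic cohorts

The generator draws, in fixed order from one seeded RNG: subjects (BMI
uniform within class bins, ages N(35, 8) clipped to 20–60), fatty-acid
profiles, cell proportions, the genome layout, baseline β, per-state noise,
and planted effects.  Defaults are the study conditions the package is
built for: 12 subjects (4 per class), 20,000 probes, noise SD 0.15 on the
M scale, 200 BMI-linked and 60 per-saturation-group planted probes with
target r = 0.9 and Δβ = 0.2, and 150 prandial-shift probes (Δβ = 0.2)
planted in the overweight class only.

Baseline β is a three-component Beta mixture (Beta(2,20), Beta(5,5),
Beta(20,2) with weights 0.4/0.2/0.4) reproducing the array's bimodal shape.
Fatty-acid percentages are log-normal around typical blood values, with
correlation 0.5 within a saturation group and subject-level correlation 0.9
between states — blood FA composition is subject-characteristic, so a meal
perturbs rather than replaces it; profiles are percent-normalized to 100.
Cell proportions are Dirichlet around realistic leukocyte means.

Covariate-linked effects are injected on the M scale where the tests
operate, with targets specified on the β/r scales the results are read on:
the slope is solved by root finding so the β-scale extreme-group contrast
hits its target at the realized covariate values, and the noise SD follows
from the target correlation.  The effect is present in both prandial
states with independently realized noise, so covariate-planted probes do
not masquerade as prandial differences.  Planting targets outside the
reachable β range raises an error naming the probe.  Prandial-shift probes
add a β offset postprandially in the configured class only, with the
hypermethylating fraction (default 0.6) placed on low-baseline
island/promoter probes and the rest on mid/high-baseline probes.

The confounded preset models strong cell-composition confounding: the
granulocyte mean tilts with BMI (0.015 per kg/m², about 0.50→0.80 across
the cohort) and shifts +0.08 postprandially, realized 1:1 in the Dirichlet
mean (the remaining cell types are rescaled); a tight concentration (400)
keeps sampling scatter below the drift, and probes load on the granulocyte
fraction with SD 4 on the M scale.  These values were set by power
analysis so that the confounding path, not 12-subject sampling noise,
drives the naive tests, which is the preset's purpose.

The synthetic genome places islands 12 kb apart (600–1,500 bp long) so
shores, shelves and open sea are populated at construction-known distances;
every probe's stored relation is recomputable from coordinates, giving the
classifier a generator-independent cross-check.

What the generator does **not** emulate: Infinium I/II probe-type chemistry,
batch and position effects, LD/SNP structure, correlated neighbouring CpGs,
and realistic genome-scale probe density.  Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
stated generative model, not that real-array artefacts are handled.

## Problem sizes and numerics

Calibration and recovery checks run at 20,000 probes — large enough that
the ±3-binomial-SE band around a 5% rate is ±0.46 points — with 12
subjects; unit tests use 2,000–4,000-probe cohorts.  The planted-recovery
threshold (sensitivity ≥ 0.95) is the oracle sensitivity (0.999, by direct
simulation of the generative model before implementation) minus five
points; specificity on unplanted probes must be ≥ 0.99.  Tolerances:
β↔M round trips to 1e-12; Spearman vs rank-then-Pearson and exact
Wilcoxon/Mann–Whitney vs enumeration to 1e-12.  Tie handling: average
ranks everywhere; stable argsort for tertile membership; constant probes
are excluded from testing with a logged count; constant vectors are
rejected by Shapiro–Wilk and correlation with explicit errors.

## Known limitations

* With 4 subjects per class, the Wilcoxon branch cannot reach p < 0.05;
  paired calls at that size rest entirely on the t branch and its normality
  gate.
* The nominal-p policy means called sets on real-scale data contain an
  expected 5% false-positive rate before the Δβ filter; an FDR option
  exists but is off by default to mirror the small-cohort design the
  package targets.
* Cell adjustment is a linear covariate adjustment; it does not estimate
  proportions (deconvolution is out of scope — proportions are inputs).
* The generator's planted effects are probe-independent; spatially
  correlated differentially methylated regions are not modelled.
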