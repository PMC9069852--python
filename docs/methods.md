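# Methods

This note documents the statistical model behind `btmbkit`, the conventions
and numerical choices the implementation commits to, and what the synthetic
cohorts used for validation do and do not capture about real trial data.

## The biomarker

Blood tumor mutational burden (bTMB) counts somatic mutations detected in
plasma cell-free DNA (cfDNA) per megabase of panel territory. Because most
cfDNA is leukocyte-derived, the tumor-derived fraction (ctDNA) cannot be
weighed directly; its input mass is estimated from the mean somatic variant
allele fraction (AF):

    ctDNA input mass (ng) = cfDNA input mass (ng) × mean AF
    adjusted bTMB         = bTMB / ctDNA input mass      [muts/(Mb·ng)]

The point of the adjustment is confounding: variant detectability in plasma
rises with ctDNA shedding, which rises with tumor burden, so raw bTMB mixes
mutational load with disease bulk. Dividing by the estimated ctDNA mass
removes the shedding term in expectation, leaving a quantity driven by the
per-genome mutation density and the sample's cfDNA mass.

Scoring conventions (all knobs on `EligibilityPolicy`):

- bTMB counts somatic SNVs and indels with AF ≥ `af_floor` (default 0.5%),
  germline-flagged calls excluded, driver mutations included. Published bTMB
  assays differ in these rules; every choice is explicit and configurable.
- mean AF uses **all** somatic calls, not only the bTMB-eligible subset
  (default `mean_af_variant_set="all_somatic"`), since the mass estimate
  should reflect overall tumor content rather than the counting rules.
- A patient with zero mean AF (no detected somatic variants) or missing
  plasma has an **undefined** adjusted score. The default policy excludes
  such patients downstream, with the reason recorded; an
  `epsilon_floor` policy (score = bTMB/ε) exists for sensitivity analysis.
- The score's dimension is muts/(Mb·ng); report labels print the
  conventional "muts/Mb × ng".

Durable clinical benefit (DCB) is progression-free survival of at least 6
months (boundary inclusive, event or censored); progression or death within
6 months is no durable benefit (NDB); censoring before 6 months is
indeterminate and excluded from benefit labeling by default (configurable to
count as NDB).

## Cutoff selection

ROC curves classify DCB with the rule *score ≥ threshold → benefit*; one
operating point per attained score value. AUC is the trapezoid area, which
equals the tie-corrected Mann–Whitney concordance exactly (asserted as an
identity in the tests). The operating cutoff maximizes Youden's
J = sensitivity + specificity − 1; ties are broken toward the smallest
qualifying score (maximizing sensitivity). Correlated AUCs for two scores on
the same patients are compared with DeLong's placement-value test. Cutoffs
are derived on the immunotherapy arm by default (the question is who benefits
from the drug), on all patients optionally; derivation and evaluation on the
same cohort is flagged as optimistic in the report, and a split-sample option
is provided.

## Survival inference

Kaplan–Meier curves use the product-limit estimator with Greenwood standard
errors; the survival factor at each event time is computed as (n−d)/n, and
the median is the earliest time with S(t) ≤ 0.5 (step-function convention,
undefined if never reached). The log-rank test uses the
observed-minus-expected statistic with the conventional hypergeometric
variance (including the (n−d)/(n−1) factor under ties).

Cox proportional-hazards models are fit by Newton–Raphson on the exact log
partial likelihood, Efron tie handling by default (Breslow available, e.g.
for cross-checks against tools defaulting to it). Numerical choices:

- covariates are centered and scaled internally (estimates are equivariant,
  so results are unaffected);
- convergence when the score max-norm falls below 1e-9 per event, at most 50
  iterations, with step-halving on likelihood decreases (tolerating
  float-noise-level decreases of relative size 1e-10);
- rank-deficient design matrices are rejected with the collinear columns
  named;
- monotone likelihoods (perfect separation) are detected by their signature —
  a large standardized coefficient whose Wald standard error dwarfs it — and
  raised as errors rather than returned as fits. The log-rank/Cox-score
  identity holds exactly only for untied event times, which is how the suite
  asserts it.

Predictiveness is the Wald test on the product term of a Cox fit with
(treatment, marker, treatment × marker); the report also carries the
within-stratum treatment hazard ratios that a forest plot displays. P-values
are two-sided, 95% Wald intervals, no multiplicity adjustment.

Restricted cubic splines use Harrell's truncated-power basis with linear
tails, normalized by (t_k − t_1)²; default 4 knots at the 5/35/65/95th
percentiles of the score, reference at the median (hazard ratio there is 1
by construction). The linearity probe is a Wald chi-square test that all
k−2 nonlinear coefficients vanish; curves carry delta-method 95% bands.

## Group comparisons

Mann–Whitney U (exact enumeration up to n·m = 400 without ties, otherwise
tie- and continuity-corrected normal approximation), Kruskal–Wallis
(tie-corrected; an all-tied sample returns H = 0, p = 1), Spearman rank
correlation (exact permutation p for n ≤ 9, t approximation beyond), Pearson
chi-square without continuity correction, and Fisher's exact test with the
point-probability two-sided rule (doubling rule available). "χ² or Fisher as
appropriate" is operationalized as Fisher whenever any expected cell is
below 5.

## The synthetic cohort generator

The simulator emulates a randomized two-arm trial (immunotherapy vs.
chemotherapy comparator) with the confounding structure the adjustment
targets. Per patient: tumor burden B ~ lognormal (sum of longest diameters,
mm); true panel mutation count M ~ negative binomial; cfDNA mass C ~
lognormal; mean shed AF a = min(af_cap, s·B·ε) with lognormal noise ε; each
mutation detected independently with probability min(1, κ·a); detected
variant AFs scatter lognormally (mean-one) around a. Raw bTMB therefore
rises with burden while the expected adjusted score, M·κ/(panel·C) in the
sub-saturation regime, does not. The latent marker-high group is defined by
the realized adjusted score against `true_cutoff`; patients with no detected
variants keep an undefined score and fall in the latent-low group.

OS and PFS are exponential with log-hazard
β_T·T + β_X·X + β_TX·T·X + β_B·z(log B) (endpoint-specific interaction),
baseline medians set by `baseline_median_os/pfs`, administrative censoring
uniform on [censor_lo, censor_hi]. Best response is logistic in T·X;
responders are floored at 2 months of PFS so response and benefit labels
cannot contradict (a simulator convention; as a side effect a responder's
PFS may exceed a very short OS, which the readers accept with a warning).
Defaults (e.g. β_TX = log 0.5 for OS) give a strongly predictive marker so
end-to-end runs at a few hundred patients have power; sample sizes in the
validation suite (n = 300 for null calibration, n = 600 for recovery,
n = 2000 for structure checks) were chosen so each check's Monte-Carlo error
is small relative to its tolerance band.

All randomness flows from one seed through per-patient substreams (spawn
keyed by patient index), so identical (config, seed) pairs are byte-identical
and growing a cohort never reshuffles earlier patients.

**Known limitation — finite-count residual correlation.** The decorrelation
of the adjusted score is exact only in expectation. Two small-sample effects
leave a residual *negative* rank correlation with burden when detected
counts are low (median ≈ 3–4 under the default mutation load): conditioning
on ≥ 1 detected variant inflates scores preferentially at low burden, and
detection saturation (κ·a capped at 1) deflates them at high burden.
Conversely, the AF eligibility floor removes low-AF variants from the bTMB
count preferentially at low burden, pushing the scored correlation
*positive*. At detected counts typical of clinical panels (≳ 10 mutations)
both effects are negligible and |ρ| < 0.05 holds, which the suite asserts in
that regime; under the low-count defaults the residual is of magnitude ≈ 0.1
and the corresponding structure check fails honestly rather than being
tuned away.

What the simulator does **not** model: read-level sequencing error, clonal
hematopoiesis contamination (config hook only), panel composition,
non-proportional hazards, dependent censoring, or serial sampling. Passing
tests therefore validate the statistical machinery and the confounding
logic, not assay chemistry.

## Problem sizes

The validation suite runs the null-interaction calibration at 2000
replicates of n = 300 (Wald rejection rate within [0.03, 0.07]), interaction
recovery at 500 replicates of n = 600 (mean error ≤ 0.1 on the log scale,
CI coverage within [0.92, 0.98]), RCS linearity calibration at 1000
replicates of n = 200, and oracle identities on 1000 random instances each.
The reproduction script simulates one cohort of n = 2000 and runs the full
pipeline on it.
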