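# Methods

## Scope and data model

`icpday` analyzes the first 24 hours of invasive intracranial-pressure
monitoring after ICU admission in subarachnoid-hemorrhage cohorts. Inputs
are two tables: timestamped ICP chart events (`subject_id, charttime,
icp_mmHg`) and a subject-level covariate/outcome table (age, gender,
GCS_min, APS III, OASIS, SOFA, first-day fluid balance, ICU death indicator
and follow-up time in hours). The day window is anchored at ICU admission
and divided into 24 hour slots indexed 0–23.

## Preprocessing

Events are assigned to the nearest hour (ties at the half hour round up;
events in the last half hour clamp to slot 23) and duplicates within a slot
are averaged, so every event contributes to exactly one slot. A subject is
excluded when monitoring is absent altogether or when any run of
consecutive missing slots — including runs touching the day's edges —
exceeds 6 hours; a run of exactly 6 is retained (the exclusion threshold is
read strictly). Remaining gaps are completed by linear interpolation
between observed neighbours; leading/trailing gaps carry the nearest
observed value flat, since linear interpolation is undefined beyond the
observed range. Observed slots are never altered and the completion is
idempotent.

ICP_mean is the arithmetic mean and ICP_variance the sample variance
(denominator 23) of the completed series; the raw (mmHg) scale is used for
summaries, not the normalized one. For clustering, each time-point column
is z-scored across the cohort (sample sd; zero-variance columns map to
zeros); min–max scaling to [0, 1] is available as a config option for
sensitivity analyses. The normalization stores its affine parameters so the
transform inverts to 1e-10.

## Trajectory clustering

K-medoids is run on Euclidean distances between normalized 24-point rows.
The implementation is classical PAM: a deterministic greedy BUILD seeding
followed by the swap phase (apply the single medoid/non-medoid exchange
with the largest cost reduction until none improves). Because greedy swap
can stall in local optima on small inputs, the swap phase is additionally
restarted from four random seedings (drawn from the run seed) and the
lowest-cost local optimum is kept; on instances small enough to enumerate,
this lands within 5% of the exhaustive optimum over all medoid subsets.

The cluster count is selected over k = 2..7 by minimizing the
Davies–Bouldin index with the classical centroid-based dispersion
(Sᵢ = mean member distance to the cluster centroid, Mᵢⱼ = centroid
separation); a medoid-based variant is selectable. Coincident cluster
centers make the ratio undefined and raise an error; in the k-selection
loop such degenerate partitions score +inf. Ties in the DB minimum break
toward smaller k for parsimony. Reported cluster labels are Roman numerals
ordered by descending cluster size.

## Cut-point survival analysis

Survival time is hours from ICU admission to ICU death, censored at ICU
discharge. Kaplan–Meier estimation is delegated to lifelines; the
two-group log-rank statistic (observed-minus-expected events under the
hypergeometric null with matching variance, chi-square with 1 df) is
implemented in-package and cross-checked against lifelines and a
permutation null in the tests.

The cut-point scan tries every distinct rounded marker value (integers by
default, matching how such cut-offs are reported) as a threshold c, keeps
candidates whose groups `≤ c` / `> c` each hold at least 5% of the cohort
(`min_group_frac`; the reference software's internal constraint is not
documented, so this is a package choice), and selects the candidate with
the smallest log-rank p (ties: larger chi-square, then smaller c). The
boundary value itself belongs to the low group. Because a minimum over m
correlated tests is anti-conservative, a Šidák-style corrected p,
1 − (1 − p_min)^m, is reported alongside; the raw minimum still drives cut
selection, mirroring the field procedure. Simulations in the test suite
show the raw minimum-p rejects a true null far above nominal while the
corrected p stays near 5%.

## Causal weighting

The high/low split at the chosen ICP_mean cut defines a binary "treatment".
Candidate confounders (age, gender, GCS_min, APS III, OASIS, SOFA) are
screened in when their univariable logistic association with the outcome
has p < 0.1 **or** when adjusting for them moves the treatment coefficient
by more than 10%. The change-in-estimate criterion is relative; when the
base treatment coefficient is within 0.1 of zero the absolute change is
used instead, because a relative criterion divides by approximately zero
there and admits noise covariates.

The propensity model is logistic; continuous covariates (more than ten
distinct values) enter through B-spline bases (df = 4) when the smoother is
on, approximating a generalized additive fit. Scores are clipped to
[0.01, 0.99] (configurable); perfect separation falls back to an L2-ridge
logistic fit with a warning. Stabilized weights are: ATE — treated
P(T=1)/e, controls P(T=0)/(1−e); ATT — treated 1, controls e/(1−e); ATU —
treated (1−e)/e, controls 1 (e the propensity score). With an
intercept-only propensity model the three estimands coincide exactly.

The effect is the odds ratio from a weighted logistic regression of the
outcome on treatment. The default interval is a nonparametric bootstrap
(1000 resamples by default) that refits the propensity model and weights
inside every resample; a robust HC1 sandwich interval is available as
`ci_method="robust"` and is used for large replicate studies where
thousands of bootstrap refits would be wasteful. If an arm has no
(weighted) events, a continuity-corrected weighted 2×2 odds ratio is
returned with a warning. Balance is reported as absolute standardized mean
differences before and after weighting.

The effect scale is an interpretation choice: the field's reports of such
treatment effects are often unlabeled; a weighted-logistic odds ratio is
implemented because the outcome is binary ICU death. Note the marginal
(population-averaged) odds ratio is not collapsible: with a planted
conditional OR of 3 and outcome-associated covariates, the true marginal
ATE odds ratio is ≈ 2.7; recovery tests compare against that marginal
truth computed from the potential-outcome probabilities.

## Cohort statistics

Continuous table-one rows use a Lilliefors-corrected Kolmogorov–Smirnov
normality check per group (the correction because the moments are
estimated); all-normal rows get t-test/ANOVA, otherwise Wilcoxon rank-sum /
Kruskal–Wallis. Categorical rows use chi-square without continuity
correction, switching to Fisher's exact on 2×2 tables with any expected
cell below 5. All p-values in a table are corrected jointly by
Benjamini–Hochberg step-up. Summaries are mean ± sd or n (%) with
percentages to one decimal. The multivariable logistic model for ICU
mortality screens covariates at univariable p < 0.1 with age always
retained (a reconstruction of common practice; the upstream entry rule is
not documented), and reports Wald ORs; separation falls back to ridge
point estimates with CIs marked missing.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with defaults
fixed to the reference cohort description: archetype proportions
(0.62, 0.03, 0.10, 0.25), means (9, 19, 19, 9) mmHg and within-day
fluctuation scales (1, 6, 1.5, 1.5) mmHg, the second archetype being the
strongly fluctuating one. Per subject, the latent trajectory is

    value(t) = m_i + shape_z(t) + drift_i(t) + noise,

where m_i is the archetype mean plus a between-subject jitter of
0.05·sd_z, `shape` is an archetype template (flat for I and III, a coherent
12-hour oscillation of amplitude 1.5·sd for II, a within-day ramp spanning
±2.5·sd for IV), `drift` is two random sinusoids of amplitude 0.05·sd, and
the measurement noise sd is 0.06·sd_z. Every term scales with the archetype
sd, so a zero-sd configuration degenerates to a constant series. The
within-archetype dispersion is deliberately kept well below the
between-archetype separation so that the planted four-group structure is
unambiguous — passing recovery tests therefore demonstrates that the
clustering machinery finds well-separated structure, not that real ICP
data are this clean. Pulse/respiratory waveform physiology, multi-day
dynamics and treatment feedback are out of scope.

Sampling is a Poisson stream of 1.5 measurements/hour at uniform within-
hour times; with probability 0.1 a subject loses a contiguous block of 4–9
hours, so gaps beyond the 6-hour exclusion rule occur. ICU death is
Bernoulli with log-odds −3.2 + 0.15·ICP_mean + 0.02·age − 0.10·GCS_min
(≈ 20% cohort mortality, strongly increasing in ICP), with an optional
threshold jump term used by the cut-point recovery study. Death times are
uniform on (0, 240 h); survivors are censored at discharge, 24 h plus an
exponential tail (mean 96 h), capped at 240 h. The 240-hour horizon keeps
event and censoring times on a common scale — if deaths are spread far
beyond the discharge distribution, the log-rank risk sets degenerate and
the test loses its power against proportion differences. Covariates are
simple parametric draws (age N(58.8, 14.5²) clipped to [18, 95]; 58%
female; GCS_min banded toward severe grades; APS III, OASIS, SOFA normal
with cohort-typical moments; fluid balance increasing weakly with latent
ICP mean); they are convenience distributions, not fits to any database.

The cut-point recovery study uses archetype means (12, 16, 16, 12) with
unit jitter fraction instead of the defaults: a planted threshold can only
be localized if the marker has density around it, and the default bimodal
design leaves the 10–18 mmHg range empty. A separate confounded-binary
simulator (`simulate_confounded_binary`) provides treatment/outcome data
with known propensity scores and potential-outcome probabilities for the
weighting studies.

## Problem sizes and numerical choices

Recovery studies run at n = 400 (clustering), n = 1000 (cut-point) and
n = 2000 (weighting; bias averaged over 15 replicates in the acceptance
script, null coverage over 200 replicates with sandwich intervals). PAM
uses 4 random restarts beyond BUILD; bootstrap intervals default to 1000
resamples (tests and the acceptance script use 40–200). The per-stage seeds
of a run fan out from one master seed via `numpy.random.SeedSequence`, so
every output table is bit-reproducible at a fixed seed. Degenerate inputs
are handled explicitly: empty event sets yield fully-missing series (an
exclusion, not an error), constant covariates are skipped with warnings,
coincident cluster centers raise, and a scan with no admissible candidate
returns an explicit "no cut-point" result.

## Known limitations

The generator's archetypes are far cleaner than clinical ICP; recovery
results bound what the machinery can do under its stated conditions, not
its behavior on real monitoring data. The bootstrap does not re-run
confounder screening inside resamples (the screen is treated as fixed
design). Cut-point inference after minimum-p selection remains biased even
with the Šidák report — the corrected p addresses the null calibration,
not the optimism of the selected effect size. The causal estimands assume
no unmeasured confounding, which chart data cannot guarantee.
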