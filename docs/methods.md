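# Methods

## Scope and data model

The pipeline operates on parcellated resting-state BOLD data: for each
subject, one or more runs of `volumes × networks` time series (TSV with a
header of network labels), a matching `volumes × 6` rigid-body motion trace
(translations in mm, rotations in rad), and a phenotype row carrying the
diagnostic group (ordinal severity 0 = cognitively intact, 1 = amnestic
MCI, 2 = mild AD), one or more cognitive index scores on the standard-score
scale (M = 100, SD = 15; higher = better), and the nuisance covariates:
age (years), sex (0/1), total brain volume (mm³), and education (years;
carried but deliberately excluded from the default models, since education
proxies cognitive reserve and adjusting for a potential mediator risks
overadjustment bias).

## Motion QC

**Framewise displacement.** "RMS head motion" is not uniquely defined in
the field; we use the per-transition root-mean-square over the six
differenced parameters, with rotations first converted to arc displacement
on a 50 mm sphere: FDᵢ = √(mean₆(Δ²)). Both the radius and the pooling rule
(`rms` or the summed-absolute Power convention) are options; the RMS/50 mm
default is the dominant scrubbing convention. Note that under RMS pooling a
single-channel jump of amplitude A pools to A/√6, so a 1.22 mm jump is the
smallest single-channel step that trips a 0.5 mm threshold.

**Censoring.** A transition i with FDᵢ strictly greater than the threshold
(default 0.5 mm; exactly-at-threshold is kept) censors its two flanking
volumes {i, i+1} plus `half_width` neighbors on each side (default 1, i.e.
{i−1, …, i+2}), clipped at the run boundaries. "Volumes before and after" a
motion spike is ambiguous about window width, hence the option.

**Exclusion.** A run keeping strictly less than `min_retention` (default
50%) of its volumes fails; a subject is excluded if **any** run fails
("for each scan" semantics). Exactly 50% retained passes. The
mean-head-motion covariate is the mean FD over all transitions of all runs,
computed **before** censoring, and is invariant to the censoring itself.

## Connectivity

Edge values are Fisher-z transformed Pearson correlations over kept
volumes, averaged entrywise across runs in z-space, then flattened to the
canonical upper-triangle edge vector (row-major; labels `netA__netB` with
A before B in parcel order; 17 networks → 136 edges). Correlations are
clipped to |r| ≤ 1 − 1e−7 before atanh so degenerate perfect correlations
give a large finite z rather than ±∞. A zero-variance network over the kept
volumes is an error naming the network. A subject with a single usable run
is analyzed with a warning rather than dropped — two-run averaging is the
intended design, but single-run behavior must be defined. Censoring is
applied per run before correlation (masked correlation), then averaged.

## Edge-wise association (primary analysis)

The estimand per edge is the partial correlation between Fisher-z
connectivity and the cognitive score given the covariates, computed as the
Pearson correlation of the two least-squares residual series
(intercept + covariates removed from each). This equals the classical
precision-matrix definition, which the test suite checks to 1e−10.

* **p-value:** t = r·√((n−k−2)/(1−r²)) on df = n−k−2, two-sided. The
  source analysis states only the CI construction; the t test is the
  classical choice and is consistent with the reported p < .001 at
  r = −.35, n = 108. A Fisher-z Wald p is available via
  `AssocSpec(p_method="fisher")`.
* **CI:** tanh(atanh r ± z₁₋α/₂/√(n−k−3)). The SE formula is a
  reconstruction (the original renders it as an image); it reproduces every
  decodable printed interval at 2 decimals (r = −.35 → [−.51, −.17],
  −.38 → [−.53, −.20], −.31 → [−.47, −.12] at n = 108, k = 4).
* **Multiplicity:** Benjamini–Hochberg across the 136 edges, separately per
  cognitive score (no cross-score correction); `q ≥ p` elementwise, capped
  at 1, step-up monotone. Implemented via statsmodels' `fdr_bh` and checked
  against a direct step-up enumeration oracle.
* **Missing data:** listwise deletion per score; the complete-case n is
  recorded on every row.

## Group contrasts (exploratory analysis)

Per edge, OLS of connectivity on treatment-coded group (reference = least
severe level present) plus the covariates; residual df = n − (1 + (G−1) + k)
(108 subjects, 3 groups, 4 covariates → 101). All unordered pairwise
contrasts are linear contrasts of the dummy coefficients from a single fit,
which equals the re-leveled-fit coefficient t exactly (tested to 1e−10);
positive t means the **more severe** group has higher connectivity.

The standardized effect size is r = t/√(t² + df) and its CI is
tanh(atanh r ± z₁₋α/₂/√df). Both formulas are reconstructions of equations
rendered as images in the source: the effect size reproduces all five
printed values (t = 4.38, 3.36, 4.03, 4.55, 3.68 at df = 101 →
.40, .32, .37, .41, .34), and the CI reproduces the printed intervals for
the t = 3.68 and t = 4.03 contrasts at 2 decimals (the t = 4.55 interval's
lower bound lands at .24 vs the printed .25, consistent with the original
rounding t before back-computing). BH-FDR is applied within contrast across
the 136 edges; the full uncorrected table is always emitted.

## Synthetic cohort generator

The generator emulates the study conditions, not raw scanner physics: no
voxel images, hemodynamics, or physiological waveforms.

**Signal model.** Volumes are i.i.d. zero-mean multivariate Gaussian with
population correlation matrix tanh(Z_subject), projected to the nearest
positive-definite correlation matrix (eigenvalue clipping at 1e−8, then
renormalization to unit diagonal — deterministic and idempotent on PD
inputs). Because the downstream pipeline only uses Pearson correlation,
i.i.d. sampling leaves the estimand untouched and makes the measurement
variance of a run-averaged Fisher z analytic: ≈ 1/(n_runs·(n_volumes−3)).
Temporal autocorrelation is deliberately not modeled; with autocorrelated
data, effective df would shrink and real-data CIs would be somewhat
anti-conservative relative to the simulation — a limitation of what
passing tests demonstrate.

**Subject connectivity targets.** Every edge has a cohort-level baseline
z ~ N(0.25, 0.08²), small deterministic age and brain-volume drifts, and
between-subject noise (SD 0.08). For each planted effect (edge, ρ) the
target gains b·s̃ᵢ, where s̃ᵢ is the score residualized on the covariates
under the **population** linear projection (computed analytically from the
group-mixture moments; only age and brain volume correlate with the score
by construction), and

  b = ρ·σ_tot / (σ_s̃·√(1−ρ²)),  σ_tot² = subject-noise² + measurement var.

Using the population rather than the per-cohort empirical residual is what
gives each simulated cohort's sample partial correlation the full sampling
variability the Fisher interval assumes; calibrating against the realized
cohort would pin the sample signal-to-noise and produce ≈99% empirical
coverage of a nominal 95% interval.

**Phenotypes.** Scores per group: N(100/85/70, 15²). Age: N(74.1, 5.7²)
with the AD group +3 years; sex ~ Bernoulli(0.583) (1 = female); total
brain volume: N(1.10e6, 1.0e5²) mm³ with −4e4/−6e4 mm³ offsets for MCI/AD;
education: N(16.1, 2.5²) with MCI −1 year. These match the reported cohort
moments where available and are otherwise plausible for an ADNI-style
dementia-spectrum sample; all are configurable.

**Motion.** Each run's parameters follow a random walk whose step SD is
drawn per subject from a log-normal around 0.06 mm (sub-threshold floor);
spike count ~ Poisson(5 per run); each spike adds 2.0 mm to one translation
channel of a single interior volume (pooling to ≈0.82 mm FD on the two
adjacent transitions, safely supra-threshold), never the first or last
volume by default. Default rates censor ≈2% of volumes, so no subject is
excluded under defaults; exclusion behavior is exercised by tests with
inflated motion.

**Determinism.** Everything derives from a single `numpy` Generator seeded
by `CohortSpec.seed`; reruns are bit-identical.

## Validation sizes and numerical choices

The Monte-Carlo suites run at the study's subject count (n = 108) with run
length and (for the recovery study) parcel count reduced, which the
generator supports explicitly since the estimators' behavior depends on
subject n while run length only sets the (analytically accounted)
measurement noise: FDR control under the global null uses 500 cohorts of
108 subjects × 136 edges × 2 runs of 120 volumes; planted-effect recovery
and CI coverage use 1000 cohorts of 108 subjects with a 5-network
parcellation and 2 runs of 200 volumes. Observed: mean false-discovery
proportion ≤ .05 + 3 MC-SE; recovery bias of a planted −0.38 well under
0.05; empirical CI coverage ≈ 96% (the slight over-coverage is real: the
group-structured score mixture is platykurtic, which shrinks correlation
sampling variance relative to the bivariate-normal Fisher approximation).

Other numerical conventions: correlation clip 1 − 1e−7 before atanh;
symmetry tolerance 1e−10 when flattening matrices; rank deficiency detected
by incremental column rank and reported with the offending covariate's
name; |r| = 1 yields p = 0 by convention; outputs are stored at full
precision (rounding only in display).

## Known limitations

* i.i.d. volumes: no autocorrelation, scanner drift, or physiological
  noise; real-data df are effectively smaller than nominal.
* The generator's covariate→connectivity drifts are linear and global; no
  edge-specific atrophy topography.
* Group is treated as categorical in the contrast analysis and enters the
  association analysis only through the score and covariate distributions;
  ordinal trend tests are out of scope.
* The positive-definite projection slightly perturbs extreme target
  matrices; with the default noise scales this shifts planted effects by
  far less than the recovery tolerance, but very dense strong effects could
  interact with the projection.
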