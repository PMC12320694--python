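# Methods

## Transport-index scoring

A lymphoscintigraphy study of one limb is summarized by five ordinal
components, each on the scale {0, 3, 5, 9} (higher = worse):
transport kinetics K (no delay / mild / marked / missing), dermal
backflow D (normal / partial / diffuse / transport stop), node visibility
N and main-vessel visibility V (clearly / mildly / hardly / not
visualized), plus the time T (minutes) at which the ilio-inguinal nodes
first appear on the serial images and a collateral-flow flag C. The
composite severity score is

    TI = K + D + 0.04·T + N + V.

Conventions and invariants:

- **Not-visualized time scores 9.** If the nodes never appear, the time
  term is 9 and N must be 9; a read with a numeric appearance time and
  N = 9 (or vice versa) is rejected as inconsistent at construction.
- **Time-term cap at 9.** The latest acquisition frame is 240 min and
  0.04·240 = 9.6 would exceed the never-seen score; the term is capped at
  9 so the achievable TI range is exactly [0.6, 45] (verified by
  exhaustive enumeration of all 4³·(6·3+1) = 1216 valid reads). No
  observed cohort has a 240-min first appearance, so the cap is a
  boundary convention rather than an operative rule.
- **C never enters the sum**; it is used only in the dichotomized profile.

### The 120-min window

The shortened protocol uses only the 15-, 60- and 120-min images (the
30-min image is deliberately omitted). `censor_read` restricts a full
read: a node time on a retained frame is unchanged; a time on an omitted
frame within the window snaps forward to the next retained frame (the
first image on which the shortened study actually shows the nodes); a
first appearance after 120 min — or never — becomes not-visualized with
N = 9. K, D and V are carried over unchanged: this is the weakest
assumption about what a reader of the shortened study would conclude, and
it is the rule under which the observed extremes of the TI₁₂₀ − TI₂₄₀
difference (1.2 from a 30→60 min snap; 5.8 from a 180-min/N=5 read
becoming not-visualized) are both realized exactly. Under this rule
TI₁₂₀ ≥ TI₂₄₀ for every valid read. Whether K could legitimately be
re-graded within two hours is unknowable from a full-protocol read; we
hold it fixed.

### Dichotomization

The six binary criteria used for group comparisons: K ∈ {5,9} (marked
delay or missing transport), D > 0 (any backflow), node time > 60 min or
never, N = 9, V = 9, and C. The 60-min boundary itself is *not* late.

## Volumetry

LELI = (Σᵢ cᵢ²)/BMI over five sites (superior patella edge, ±10 cm from
the patella, lateral malleolus, foot dorsum), circumferences in cm, BMI
in kg/m². The squared form is used (an alternative linear-sum phrasing
circulates, but only the squared form matches the magnitude of reported
cohort values, ~250 for affected limbs, and the index literature).
%ΔLELI = 100·(pre − post)/pre, so reduction is positive; pre-operative
burden is the affected-minus-contralateral LELI difference. Units are
fixed; no auto-detection.

## Nonparametric statistics

Self-contained implementations with fixed exact/approximate switch
points, all two-sided at α = 0.05 with no multiplicity correction by
default (a Holm step-down switch exists for the binary-parameter family):

- **Spearman**: Pearson correlation of mid-ranks (tie-corrected). Exact
  permutation null for n ≤ 9, else the t approximation with n−2 df.
- **Mann-Whitney**: exact enumeration of all C(n, n_a) labelings for
  combined n ≤ 10 (ties enumerate naturally); otherwise the tie-corrected
  normal approximation without continuity correction, so the two-group
  case satisfies H = z² against Kruskal-Wallis.
- **Wilcoxon signed-rank**: zero differences dropped; exact 2ⁿ sign
  enumeration for n ≤ 15, else the normal approximation with variance
  Σrᵢ²/4 (exact under mid-ranks).
- **Kruskal-Wallis**: tie-corrected H with a χ²(k−1) tail; an all-tied
  pooled sample degenerates to H = 0, p = 1 by convention.
- **ICC**: two-way mixed-effects, absolute-agreement, *single-measure*
  coefficient from the ANOVA mean squares,
  (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)). The variant is a
  package choice — stated prominently because different ICC forms differ
  materially — and is the one cross-checked against pingouin's ICC(A,1).

Two-sided exact p-values use the symmetric criterion
P(|T − E T| ≥ |T_obs − E T|), so perfectly balanced configurations give
p = 1 and every p lies in (0, 1].

## Synthetic cohorts

The generator emulates the structure of the 45-patient series the method
was reported on; defaults are the study conditions, not tuning knobs.

**Severity copula.** One latent severity z ~ N(0,1) per patient. Each
ordinal component thresholds `link·z + √(1−link²)·ε` at its marginal
quantiles (Gaussian copula), giving exact marginals — K: 1/16/16/12 of
45, D: 2/7/34/2, N: 8/6/8/23, V: 3/13/22/7, collateral present 26/45 —
and positive inter-component correlation. `severity_link` defaults to
0.6, chosen so stage-conditional TI separation and the TI–excess
correlation are of the observed order; at link = 0 components become
independent draws from the marginals. The Campisi stage is z thresholded
at the 5/45, 35/45, 5/45 quantiles (stages 2/3/4), so stage-conditional
mean TI rises with stage by construction.

**Node time.** N is drawn first; a numeric time is drawn only for
visible nodes (N < 9) from the conditional distribution 6/5/6/5/2 over
15/30/60/120/180 min. The published component table is internally
inconsistent here (23 limbs with N = 9 but 21 with no appearance time);
the generator honours the read-validity constraint by conditioning on N.
Because the time latent shares z with the visibility latent, the raw
copula uniform is tilted among visible limbs; it is mapped through its
exact conditional CDF given visibility (Gauss-Hermite quadrature), which
restores the conditional marginals exactly while preserving the severity
ordering of appearance times. Consequently the generator's closed-form
expected TI is ≈ 26.4 — the sum of the component expectations with the
time term mixed over visibility — slightly above the ≈ 26.1 implied by
treating the published table rows as independent, and above the published
cohort mean of 25.5; the generator matches the table structure, not the
printed mean.

**Volumes.** Contralateral LELI ~ N(200.2, 18.8²); affected pre-op LELI
adds an excess 51.1 + 10·z + N(0, 20²) (LELI units), making the affected
SD ≈ 28 and the TI–excess Spearman correlation ≈ 0.3-0.5. Circumferences
are synthesized backwards from the target LELI: the implied Σc² is split
across the five sites in fixed proportions (base circumferences
37/45/36/24/23 cm) with per-limb log-normal jitter (σ = 0.05) held
constant across timepoints, so volumetrics round-trip exactly. BMI, age
and duration are truncated normals matching the reported mean ± SD and
range (25.3 ± 3.5 in [19, 33]; 56 ± 10 in [25, 78]; 6.4 ± 5.8 in
[0.3, 21]).

**Outcomes.** %ΔLELI at month t is `μ_t − slope_t·zTI + σ_t·ε` with
μ = (6.5, 7.9, 5.6) and σ = (4.9, 5.0, 6.8); zTI is TI₁₂₀ standardized by
the calibration-population moments. Slopes are calibrated by monotone
bisection on a 100 000-patient sample (common random numbers; run to
bracket convergence to avoid early-stopping bias) so the population
Spearman correlation between TI₁₂₀ and the outcome hits the targets
(0 at 1 month, −0.366 at 3 months, −0.370 at 6 months) within ±0.01.
Calibrations are cached per configuration; everything is deterministic
given (config, seed), with seeds handled through numpy `SeedSequence`.

**Contralateral limbs** are normal reads (TI 0.6) except a 4/45 fraction
assigned one of four fixed mild-impairment patterns (TIs 4.2, 6.6, 7.2,
8.4), mirroring the subclinical contralateral elevation seen in
cancer-related LEL. An optional second reader pass regrades each ordinal
component to an adjacent category with a small probability (default off;
0.03 yields an intra-rater ICC ≈ 0.99).

**What the generator does not emulate.** Outcomes at different months are
correlated only through their shared TI term, so the strong observed
3-vs-6-month outcome correlation (~0.7, suggesting a patient-level
response effect) is understated; lymphangitis history, cancer site and
radiotherapy are not modelled; circumference site proportions are
essentially fixed rather than anatomically varying. Passing tests
therefore demonstrate the pipeline's correctness and the attainability of
the reported association strengths under the stated cohort structure —
not clinical validity on real patients.

## Pipeline

`load_cohort` joins reads.csv, volumetry.csv and patients.csv with
row-level diagnostics (every malformed row reported; duplicates and
orphan limb rows are errors); records missing post-op timepoints are kept
with gaps, and each analysis reports its own n. Outcome analyses exclude
bilateral-flagged patients by default and never include contralateral
limbs (their TIs are reported descriptively). Dual reader passes are
never auto-reconciled — the first pass is analysed and the second used
only for the ICC. Reports store full precision (JSON + CSVs); only the
rendered `summary.txt` rounds (TI to 1 decimal, rho and p to 3).
Degenerate inputs (constant TI, empty comparison groups, n < 3) mark the
affected block `computed: false` with a reason and the run continues.

## Problem sizes and tolerances

Enumeration checks cover all 1216 valid reads (instant). Marginal
goodness-of-fit uses 10⁵–2·10⁵ draws (±1% tolerance). Link calibration
uses 10⁵ patients (±0.01 on rho); the recovery check averages 500 cohorts
of n = 45, where the sample Spearman at n = 45 carries a small bias
toward zero, hence the ±0.05 band around the target. Exact-test oracles
enumerate all labelings/signs/permutations up to combined n = 8.
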