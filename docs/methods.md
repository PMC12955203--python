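# Methods

## Scoring schemes

Both schemes are instances of one primitive: an ordered list of items, each
a positive integer deduction triggered when any of its segments carries
thrombus, subtracted from a fixed maximum of 10.  Partial and complete
thrombi count alike; scoring is unilateral (one anterior-circulation
territory), and a patient with any missing segment flag is reported as
unscorable rather than guessed.

**CBS** items: infraclinoid ICA 1, supraclinoid ICA 2, proximal M1 2,
distal M1 2, ACA 1, M2 superior 1, M2 inferior 1 (sum 10).

**mCBS** raises the intracranial-ICA deduction to 3.  A design choice was
forced here: keeping a separate 1-point infraclinoid item alongside a
3-point supraclinoid item would make the deductions sum to 11, contradicting
the scheme's stated 0–10 range.  We therefore merge both carotid flags into
a single 3-point item triggered by thrombus in either segment.  Under this
merge the two schemes are related pointwise by

    CBS − mCBS = 1  (supraclinoid only),  2  (infraclinoid only),  0  otherwise,

which the test suite verifies by exhaustive enumeration of all 2^7 segment
statuses, along with monotonicity (adding thrombus never raises a score) and
attainment of both endpoints.  A consequence worth knowing: mCBS ≤ CBS for
every patient, so a cohort cannot have a higher mCBS median than CBS median
under this reading; published summaries that show otherwise must rest on a
different (unstated) item table.

## Evaluation statistics

All statistics are implemented here from first principles, with scipy used
only for probability distributions; scipy's and pingouin's equivalents serve
as independent cross-checks in the tests.

- **Dichotomization.** mortality = [mRS90 = 6]; disability = [mRS90 ≥ 2];
  severity = [NIHSS ≥ 15].  (Some published tables split disability at
  mRS ≤ 2 vs > 2; we follow the ≥ 2 convention consistently, including in
  the contingency section.)
- **Spearman correlation** is the Pearson correlation of midranks (exact
  under ties).  p-values: t-approximation with n − 2 df for n ≥ 10; exact
  permutation over all n! orderings for n ≤ 8; seeded Monte Carlo (20 000
  draws, add-one correction) at n = 9.  Two-sided throughout, with a 1e−12
  tolerance when counting permutations as extreme as observed.
- **ROC/AUC.** Low score predicts the adverse outcome, so operating points
  use positivity `score ≤ c` over all distinct observed values.  The AUC is
  the Mann–Whitney statistic with half-weight ties; it equals the
  trapezoidal area of the empirical ROC polygon (asserted to 1e−12).  Its
  variance comes from DeLong's structural components with ddof = 1; this
  estimator is algebraically identical to the two-sample delete-one
  jackknife, which is how the tests verify it (brute-force leave-one-out
  AUC recomputation, agreement to 1e−6 on random fixtures).  95 % CIs are
  normal-theory, clipped to [0, 1].
- **Paired AUC comparison** uses the paired DeLong covariance of the two
  schemes' components; identical score vectors short-circuit to z = 0,
  p = 1, and a zero-variance contrast with non-identical scores raises an
  explicit error rather than dividing by zero.
- **Youden criterion**: J = sens + spec − 1 maximized over operating points;
  ties resolve to the smallest criterion (the more specific cutoff, matching
  the convention of reporting 100 %-specificity criteria).
- **ICC(2,1)** — two-way random effects, absolute agreement, single rater —
  from the two-way ANOVA mean squares, with the McGraw–Wong F-based 95 % CI.
  Interpretation bands: poor ≤ 0.20 < fair ≤ 0.40 < moderate ≤ 0.60 <
  good ≤ 0.80 < very good ≤ 1.  (The conventional band table leaves the
  interval (0.20, 0.21) unspecified; we close it by treating the printed
  upper bounds as inclusive.)  The model choice is deliberate where the
  convention is often left implicit: raters are treated as a random sample,
  and systematic rater offsets count against agreement.
- **Wilcoxon rank-sum**: exact enumeration over all C(N, n_x) assignments
  when N ≤ 12 without ties, else normal approximation with tie correction
  and 0.5 continuity correction.  **Fisher exact**: two-sided by summing
  hypergeometric probabilities not exceeding the observed table's (relative
  tolerance 1 + 1e−7); the odds ratio is the sample cross-ratio with the
  usual ∞/0 conventions.
- **Post-hoc power** for an AUC difference uses the Hanley–McNeil variance
  for each AUC and a user-supplied correlation between them (default 0.5),
  in a two-sided normal test.  This operation is exploratory by
  construction: published power figures rarely state their variance model or
  correlation assumption, so no particular printed value should be expected
  to reproduce.  At zero difference it returns exactly the test size α.
- No multiplicity correction is applied anywhere; every p-value is raw.
- Missing outcomes are handled by complete-case exclusion with per-row
  quarantine accounting (strict mode aborts instead).

## Synthetic cohort generator

No public dataset pairs per-segment thrombus flags with NIHSS, ASPECTS and
90-day mRS, so the simulator creates cohorts with that joint structure.  Per
patient: an occlusion origin is drawn from {ica, m1, m2, none}; involvement
propagates distally (ICA → proximal M1 → distal M1 → each M2 branch), each
step with probability `p_extend_distal`; ICA origins resolve a sub-pattern
(supraclinoid only / infraclinoid only / both) and involve the ACA with
probability `p_aca`.  A latent severity

    L = Σ_s w_true[s]·X_s + N(0, σ_latent)

drives everything clinical: NIHSS = clamp(round(8.7 + 1.1·L + N(0, 2)), 0, 42);
ASPECTS = clamp(round(10 − 0.8·L + N(0, 0.8)), 0, 10); mRS90 is the ordinal
category of L + N(0, 1.8) against six increasing thresholds (category 6 =
death); admission mRS uses the same thresholds shifted down by 1 and capped
at 5.  The default weights are proportional to the mCBS deductions (one
ICA-heavy item over the union of the carotid flags) — in the simulated
world, carotid occlusion really is disproportionately harmful, which is the
hypothesis the weight-sweep experiment manipulates.  Age (N(64.85, 14.14²))
and sex (male with p = 0.531) are generated for realism only and enter no
outcome model; treatment labels (APT/TPA/EVT with expected stratum sizes
57/20/53 of 130) are assigned at random and carry no effect.

Defaults were calibrated once with `scripts/calibrate_defaults.py` against
the target marginals — mean NIHSS 14.83 (SD 3.74), disability 83/130,
deaths 29/130, CBS median 4, ASPECTS mean 5.56 — and then frozen.  The
frozen defaults reproduce, averaged over 200 cohorts of n = 130: NIHSS mean
14.85 (SD 3.90), disability fraction 0.637, death fraction 0.229, CBS
median 4.0.  The mCBS median lands at ≈ 4, not above the CBS median: that
is forced by the merge identity above, not a calibration failure.

What the generator does **not** emulate: real TOF-MRA misclassification
structure (rater noise is an i.i.d. per-segment flip, probability
`rater_noise`, used only for the reliability experiments); treatment
effects; survival time (death is only mRS90 = 6); bilateral or
posterior-circulation disease; and realistic score–outcome effect sizes —
because the latent severity shares its functional form with the score, the
simulated AUCs (~0.90 for disability) and correlation magnitudes are
stronger than any real cohort's.  Passing recovery tests therefore shows
that the pipeline detects an ICA-weighting advantage when one truly exists
and reports none when the schemes coincide; it does not certify effect
sizes on patients.

Every operation is reproducible bit-for-bit from (config, seed); replicate
seeds derive from `numpy.random.SeedSequence.spawn`.

## Experiment sizes and numerical conventions

The recovery experiments use 200 replicates of n = 130 (the null arm uses
configurations with no isolated-ICA patterns, where both schemes coincide
pointwise and the paired difference is exactly zero); the reliability null
uses 100 replicates of 500×2 standard-normal matrices; module-level sweep
tests use 10–60 replicates.  Report JSON rounds statistics half-even to 4
decimals and percentages to 2, sorts keys, and is byte-identical across
runs.  Score ties in ROC criteria, rank ties in all rank statistics, and
Youden ties are all resolved by the explicit rules above, so no result
depends on sort stability.

## Known limitations

- The mCBS item table is reconstructed from prose (the merge decision
  above); a variant that keeps a separate infraclinoid item on an 0–11
  scale is expressible as a custom `ScoringScheme` but is not built in.
- ICC model choice (2,1) is a convention; reliability studies that used a
  different model (e.g. consistency, or average of k raters) will not match.
- The post-hoc power method is labelled exploratory (see above).
- Bilateral carotid disease and A2/M3 segments are out of scope.
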