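# Methods

## Model and procedure

The pipeline treats a person's stream of max-deviation accelerometer
magnitudes as draws from a *slowly drifting* Gamma distribution, and
measures the person by how fast that distribution moves.

1. **Magnitudes.** The (X, Y, Z) maximum deviation from the mean
   acceleration is reduced to its Euclidean norm. Timestamps are used only
   to validate within-session ordering; the statistics are indexed by
   acquisition order (the trajectory's clock is the entry index, not
   wall-clock time — an interpretation choice, since the upstream
   summarisation cadence differs across devices). Device units pass
   through unconverted: the Gamma shape is scale-invariant and the scale
   parameter is equivariant under unit rescaling, so units only rescale
   the plane (tested).

2. **Entries.** Disjoint consecutive blocks of `window = 100` values.
   Disjoint rather than overlapping windows, so each reading contributes
   to exactly one trajectory point and speed statistics are not
   double-counted. A trailing remainder shorter than the window is
   discarded. 100 readings keeps 95% CIs tight while giving a dense
   trajectory.

3. **Unimodality screen.** Hartigan's dip test on the raw samples of each
   entry; entries with p < `dip_alpha = 0.01` are discarded as
   contaminated (in real streams the second mode sits at extreme values —
   sensor artefacts). The test runs on raw samples, not binned counts:
   the dip is defined on the empirical CDF and binning loses information.
   The histogram bin-width rule W = 3.49·σ̂·N^(−1/3) is kept for
   reporting/plotting only. P-values are Monte-Carlo calibrated against
   `n_boot = 500` uniform-null replicates of the same size, cached per
   sample size, with `p = (1 + #{null ≥ obs}) / (1 + n_boot)`; the
   uniform is the asymptotically least-favourable unimodal null, giving a
   conservative test (observed false-rejection ≲ 1% at α = 0.01 under
   Gaussian and Gamma nulls).

4. **Gamma MLE.** Location fixed at 0 (the density has no location term;
   magnitudes are non-negative, zeros are dropped with a logged count
   before fitting). 95% CIs are Wald intervals on (log a, log b) from the
   observed Fisher information `I(a,b) = n·[[ψ′(a), 1/b], [1/b, a/b²]]`,
   exponentiated back — a standard asymptotic construction that keeps
   intervals positive; empirical coverage at n = 100 is 93–97% (tested
   over 200 replicates).

5. **Trajectory and speed.** The ordered (a, b) points are pieced
   together across sessions and days into one longitudinal trajectory.
   Speed is the Euclidean shift between consecutive points on the raw
   (a, b) plane (not log-transformed — the published per-person shift
   ranges, e.g. a cohort maximum of 83.69, identify raw-plane
   magnitudes). Shifts below `speed_cutoff = 0.002` are stochastic rest
   and excluded from peak and median statistics; the cutoff is the
   published minimum step across participants.

6. **Per-person signature.** All shifts strictly above
   `peak_threshold = 1` (the Exponential boundary a = 1 of the plane;
   all supra-threshold shifts, not just local maxima) are pooled over the
   person's whole longitudinal trajectory and Gamma-fitted. The Fano
   factor of that fit is variance/mean = (a·b²)/(a·b) = b, an algebraic
   identity the code preserves to machine precision. Participants with
   fewer than 20 surviving entries or 10 peaks are excluded (too little
   data for the distributional estimate — the same rule that excluded one
   control in the reference study).

7. **Cohort stage.** Power law y = a·x^b fitted by nonlinear least
   squares *in original coordinates*, initialized from the log-log OLS
   line. The original-space objective is identified by the published SSE
   (20.44 on the cohort fit), which is on the raw y scale; a pure log-log
   fit would weight the low-scale controls differently. CIs use the
   Jacobian asymptotics with t(n−2). Clustering is k = 2 Lloyd iteration
   with city-block assignment and component-wise-median centroid updates
   (the stated metric; the medians make the L1 cost non-increasing per
   iteration, asserted in tests), best of `restarts = 50` seeded
   initializations — with 15 points in 2-D the optimum is stable. The
   "NC" cluster is named post hoc as the one holding the majority of
   veridical controls. Distances to that centroid are city-block, for
   metric consistency with the clustering (Euclidean is available via
   argument). Rank-sum comparisons use full enumeration over rank
   assignments when both groups have ≤ 10 members (mid-ranks under ties,
   so identical samples give p = 1) and the tie-corrected normal
   approximation otherwise. Adjusted R² uses (n−1)/(n−2) with 2
   parameters throughout, matching the published goodness-of-fit
   conventions. No multiple-testing correction is applied across the
   report, mirroring the original analysis.

## Synthetic cohort

The generator emulates exactly the structure the method assumes, with
known ground truth per entry:

- (log a, log b) follow a reflected random walk (step sd `drift_sd`)
  inside [a₀/10, 10a₀] × [b₀/10, 10b₀] — positivity plus bounded drift;
- regime jumps with probability `jump_prob` per entry multiply (a, b) by
  log-uniform factors in [1/jump_scale, jump_scale], producing the speed
  spikes the signature measures;
- with probability `contamination_prob` an entry receives a far second
  mode (20% of samples moved to ~10× the entry's 99th percentile),
  mimicking the discarded multimodal histograms whose second bump sat at
  extremely large values.

Presets anchor the two phenotypes to the reference cohort's fitted
endpoints: NC-like (a₀ = 3.5, b₀ = 0.64, jump_prob 0.04, jump_scale 3)
and late-PD-like (a₀ = 0.75, b₀ = 13.4, jump_prob 0.10, jump_scale 8).
One global seed spawns per-persona sub-seeds, so cohorts are bit-identical
across runs.

What the generator does **not** emulate: biomechanics of real movement,
circadian structure, device noise models, or serial correlation within an
entry (samples are i.i.d. given the entry's parameters). Passing recovery
tests therefore demonstrates the estimation machinery is correct under
the model's own assumptions, not that real accelerometry satisfies them.

## Numerical choices and degenerate inputs

- Gamma MLE via the profile closed form (b̂ = x̄/â with â from the digamma
  equation, as implemented in scipy's fixed-location fit); verified
  against a 1-D profile-likelihood grid to 3 decimals.
- Dip statistic: the classic GCM/LCM iterative algorithm on the sorted
  sample; verified against an independent linear-programming brute force
  (best sup-norm unimodal CDF fit per candidate mode) at small n, and
  against the closed-form floor 1/(2n) for equally spaced samples.
- k-medians assignment ties go to the lower cluster index; an emptied
  cluster is reseeded with the point farthest from its nearest centroid.
- Constant samples: bin-width rule raises a degenerate-input error.
- Sessions supplied out of order are reordered by (day, session);
  mixed-participant input is an error, as are non-finite components.
- Entries whose dip test cannot run (< 10 samples) are a precondition
  error rather than silently passed.

## Problem sizes

The test suite and the replication script run on the 15-person reference
signature table (cohort stage, deterministic) and on synthetic cohorts of
2–6 personas with 2,400–7,200 readings each — enough for 24–72 trajectory
points per person, which already yields stable peak distributions for the
phenotype contrast the tests assert. Parameter-recovery tests pool 10,000
stationary readings, the regime where the 5% MLE tolerance is the
expected sampling error.

## Known limitations

- The entry-index clock ignores gaps between sessions and days; a person
  with sparse recording has the same trajectory resolution as a dense
  recorder per entry, but fewer entries.
- Wald-on-log CIs undercover slightly for very small shape values at
  n = 100; profile-likelihood intervals would be more accurate there.
- The speed-peak Gamma fit conditions on peaks > 1, but fits an
  untruncated Gamma, as the original procedure does; the (shape, scale)
  signature is therefore a descriptive summary of the exceedances, not a
  calibrated tail model.
- With 15 people, the cluster structure and regressions are illustrative;
  the package applies no multiplicity control.
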