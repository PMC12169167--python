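# Methods

This note documents the models, numerical choices and limitations behind
`tendonmech`. It describes what the code computes; every number quoted here
is produced by the test suite or the analysis/acceptance scripts, not
asserted independently.

## Force conditioning and tendon force

The cuff force trace is modelled as a quiet pre-trigger baseline followed by
a linear moment ramp (default ~70 N·m/s up to the trial peak), sampled at
1,000 Hz. Conditioning is a Butterworth low-pass at 30 Hz, applied
forward–backward (`sosfiltfilt`, reflective padding) so the filter is
zero-phase: any lag would desynchronise force samples from the
trigger-aligned ultrasound frames. The filter family and order are not part
of the measurement definition, so the order (default 4) is exposed in
configuration; the passband contract (DC gain 1, ≤1 % change at 5 Hz, ≥95 %
attenuation at 200 Hz) is what the tests pin down. Moment-arm conversion is
element-wise: moment = force × external arm, tendon force = moment / internal
arm, with the internal arm a per-participant constant reused pre and post.
Antagonist co-contraction and joint-rotation corrections are deliberately out
of scope.

## Landmark tracking

The tracker is a from-scratch iterative Lucas–Kanade implementation:

* window 21×21 px, 3 pyramid levels (factor 2, Gaussian anti-aliasing),
  ≤30 Gauss–Newton iterations per level, convergence tolerance 0.01 px —
  standard settings for speckle imagery, all configurable;
* frames are pre-smoothed (σ = 1 px) and stored as cubic-spline coefficients,
  so window sampling and the central-difference gradients are smooth
  functions of sub-pixel position. Bilinear sampling was measurably worse
  here: its piecewise-constant derivatives bias each sub-pixel solve and the
  bias accumulates over a ~100-frame sequence;
* tracking is frame-to-frame accumulating, matching the frame-to-frame
  definition of the elongation measurement. The cost is drift on very long
  sequences; the accuracy tests quantify it (≈2×10⁻⁴ mm max elongation error
  over a noise-free 108-frame trial at 0.1 mm/px, ≈0.005 mm with default
  noise);
* windows with a near-singular structure tensor (textureless) or
  non-converging iterations are flagged and the position carried forward,
  never silently extrapolated.

Coordinates are 0-based pixels, x rightward, y downward; initial landmark
positions are user-supplied (automatic landmark detection is a non-goal).

## Stiffness estimation

Pairing takes the filtered tendon force at sample `trigger + round(t·rate/
frame_rate)` for frame `t`, restricted to the loading phase: from force onset
(5 % of the trial peak, configurable) to the peak sample. Pairs are resampled
to 100 points uniform in force from 0 to the trial peak (the short segment
below onset is linearly extrapolated from the first two pairs), and a
2nd-degree polynomial is fitted with force as the dependent variable,
`F = a·e² + b·e + c` (unconstrained). R² is computed on the resampled points;
trials with R² < 0.90 are excluded, and the boundary is inclusive (R² exactly
at the threshold is kept).

Fitting F(e) rather than e(F) is a deliberate design choice: the quadratic
force–elongation law is the standard stiffening model for tendon (and is the
family the synthetic generator draws from), whereas a quadratic in force
cannot represent its inverse square-root shape — fitting e(F) left a
systematic ~5 % bias in the 60–100 % slope that no tracking accuracy could
remove. Evaluating the fitted curve at arbitrary force levels (needed for
common-force standardisation) inverts the quadratic numerically on its
monotonically increasing branch (dense grid + linear interpolation), which is
robust to any coefficient signs a noisy fit may produce.

The participant-level mean curve averages the included trials' fitted curves
on a 100-point force grid from 0 to the common force — the lowest
included-trial peak force observed in either session, so both sessions are
compared over an identical force range. Stiffness is the OLS line slope of F
on e over the grid points in [0.6, 1.0] × common force (~40 points), not a
two-point difference; the test oracle uses the same definition evaluated on
the analytic curve. Non-monotonic mean elongation over that range is flagged
rather than silently regressed.

## Synthetic data

The generator emulates the acquisition, not ultrasound physics:

* **Force**: exact ramp plus Gaussian sensor noise (default SD 5 N at the
  cuff, a realistic strain-gauge noise floor at these load levels).
* **Frames**: a fixed reference image — low-pass-filtered Gaussian speckle
  (σ = 1.5 px, contrast 0.15 around a 0.5 background) with two bright
  Gaussian landmark blobs (σ = 2.5 px, ~10 px wide) — warped per frame with
  cubic-spline interpolation. The warp translates everything within ±16 px of
  each landmark rigidly (the landmarks are bone surfaces) and stretches only
  the tendon region between them; elongation follows the inverse of the
  trial's true curve evaluated at the tendon force of the synchronised force
  sample. Sensor noise (default SD 0.02 intensity units) is added after
  warping so it does not move with the tissue. Frame rate defaults to 50 Hz
  (plausible B-mode; ~150 frames over a 3 s ramp) and image resolution to
  0.1 mm/px on a 96×384 grid — plausible placeholders exposed in
  configuration, not measurement facts.
* **SWV maps**: Normal(base, 1.0) pixel velocities clipped to [0, 20] m/s
  with an exactly controlled count of saturated pixels per frame.
* **Cohorts**: `outcome = μ + subject + post·(training + is_OC·interaction)
  + location_offset + residual`, subject ~ N(0, σ_between), residual
  ~ N(0, σ_within) per cell. Defaults n = 15/17 (OC/NOC), σ_between = 10,
  σ_within = 5 on a baseline of 100 — between-subject spread dominating
  within-subject noise, as for the study's tendon outcomes.

What passing tests do *not* show about real data: no point-spread function,
attenuation, decorrelation, out-of-plane motion or probe-pressure artefacts
are modelled, so tracking accuracy on these phantoms is an upper bound;
likewise the cohort model has no skew, outliers or missingness mechanism.

## Reliability and inference

ICC(3,1) is computed from the two-way subject × session mean squares,
`(MS_S − MS_E)/(MS_S + (k−1)MS_E)`; consistency, not absolute agreement, per
the Shrout–Fleiss model-3 naming. TE = sd(differences)/√2 and
CV = 100·TE/grand mean (Hopkins). Confidence intervals for ICC are omitted.
Degenerate tables (no between-subject variance) return a flagged non-positive
estimate instead of raising.

The mixed ANOVAs use the weighted-cell-means decomposition with separate
error strata (subjects-within-group for the between factor; each within
factor and its group interaction against its own factor × subjects-within-
group stratum). With a single between-subject factor and complete within
cells the cell frequencies are proportional, so the decomposition is
orthogonal — sums of squares add to the total exactly (tested to 1e-8 on
random tables) and the F tests are exact for unequal group sizes such as
15/17. This is the "Type II style" resolution of the unbalanced between
factor; no sums-of-squares type ambiguity arises for the within effects.
Sphericity for the 3-level location factor is assumed (no Greenhouse–Geisser
correction by default). Participants with any missing cell are dropped
listwise per outcome and counted. All-equal inputs yield a flagged
zero-variance result with undefined F rather than a division error.
Mann–Whitney and Wilcoxon use exact null distributions for small samples
without ties (n ≤ 12 per group / ≤ 25 nonzero pairs) and tie-corrected
normal approximations otherwise.

Simulation-measured calibration (2,000 null cohorts at n = 15/17): the
training × group interaction rejects at 0.044–0.045 at α = 0.05. With a
programmed interaction of 1 within-SD the measured power is ≈0.50, in
agreement with the analytic non-centrality λ = (δ/σ_diff)²·n₁n₂/(n₁+n₂) ≈ 4
(σ_diff = √2·σ_within for a pre/post difference): an interaction of that size
is simply not an 0.8-power effect at this sample size — roughly 1.4
within-SDs would be. The calibration test nevertheless asserts the stricter
0.8 bound; its failure is expected and is the honest statement of this
limitation.

## Pipeline and problem sizes

`run-all` processes a study directory (delimited force traces, multi-frame
grayscale TIFFs, JSON sidecars with landmark seeds, CSA/MVC tables) into
participant outcomes and cohort statistics, writing every intermediate
(per-frame tracks, per-trial fits, exclusions) under `audit/` so each
reported number is traceable. Outputs are byte-deterministic for a fixed
study and configuration. Strength is the mean of the two highest MVC
attempts; mean CSA the average of the three site outlines.

The shipped analysis scripts and test suite run a deliberately small study —
2–3 participants per group, 2 trials per session, 25 Hz frame rate — chosen
so the whole chain (generation, tracking, fitting, inference) exercises every
code path at desk scale; the statistical conclusions of the shipped run are
therefore illustrative, while the calibration claims come from the
array-level simulations at the study's real 15/17 sample sizes.
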