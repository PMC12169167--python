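# tendonmech

Analysis pipeline for ultrasound-based patellar tendon (PT) mechanics in
pre/post resistance-training studies: force-signal conditioning, Lucas–Kanade
landmark tracking, force–elongation stiffness estimation, shear-wave-velocity
(SWV) quality control, test–retest reliability statistics, and mixed-design
group × training inference. A synthetic-data generator emulates every input
the pipeline consumes — ramped knee-extension force traces, speckle-textured
B-mode frame stacks, SWV pixel maps and pre/post cohorts — with known ground
truth, so every stage is testable without access to raw participant data.

It is written for musculoskeletal biomechanics researchers who process
dynamometer + ultrasound acquisitions into tendon stiffness and related
outcomes, and for anyone who wants a fully simulated testbed for such a
pipeline.

## The measurement model

**Tendon force.** The raw cuff force (sampled at 1,000 Hz) is low-pass
filtered (4th-order zero-phase Butterworth, 30 Hz cut-off), converted to knee
extension moment by the external moment arm, and to PT force by the internal
moment arm: `F = force · r_ext / r_int`.

**Elongation.** The patella apex and tibial plateau are tracked through the
frame stack with an iterative, pyramidal Lucas–Kanade solver: per frame pair
the local displacement `d` minimises `Σ_w (J(x+d) − I(x))²`, solved by
Gauss–Newton steps `d ← d + G⁻¹ b` with `G` the gradient structure tensor.
Elongation is the change in inter-landmark distance,
`e(t) = (‖apex_t − plateau_t‖ − ‖apex_0 − plateau_0‖) · pixel_scale` (mm).

**Stiffness.** Per trial, the loading-phase (F, e) pairs are resampled to 100
points evenly spaced in force and fitted with a 2nd-degree polynomial; trials
with R² < 0.90 are excluded. Included curves are standardised to a common
force (the lowest included-trial peak across a participant's pre and post
sessions), averaged to a mean curve, and stiffness `k = dF/de` (N/mm) is the
least-squares line slope over 60–100 % of the common force.

**SWV QC.** A recording is discarded when more than 5 % of pixels (averaged
across frames) exceed 90 % of the 20 m/s instrument ceiling; passing
recordings are summarised per side and as the mean of both sides.

**Reliability.** ICC(3,1) (two-way mixed, consistency, single measure),
typical error `TE = sd(diff)/√2`, and `CV = 100·TE/mean`.

**Inference.** Mixed two-way (training × group) and three-way
(training × group × location) ANOVAs from the classical weighted-cell-means
decomposition with separate error strata, partial η² per effect, Bonferroni
post hocs, plus Student's t, Mann–Whitney U, Wilcoxon signed-rank and Pearson
correlation.

## Worked example

Simulate a small two-group study (20 % programmed training gain in stiffness,
no group × training interaction) and run the whole pipeline:

```sh
python analysis/01_simulate_study.py --seed 7     # writes scratch/study
python analysis/02_track_stiffness.py             # writes results/stiffness.tsv
python analysis/05_cohort_inference.py            # writes results/anova.tsv, report.txt
```

which prints (abridged):

```
wrote results/stiffness.tsv
  6 participants, 24/24 trials included
  stiffness recovery error vs generating curve: median 1.11%, worst 2.23%

stiffness: n=6 (0 dropped), training p=1.992e-06, interaction p=0.7432
csa: n=6, training p=0.001605, time:location p=0.7411
```

Read: tracked stiffness agrees with each participant's generating curve to
~1 % under default image/sensor noise; the programmed training effect is
detected (p < 10⁻⁵) and the absent interaction is correctly not (p = 0.74).
`analysis/03_swv_qc.py` and `analysis/04_reliability.py` cover the SWV rule
and the ICC/TE/CV statistics the same way. The same steps are available as a
CLI (`tendonmech synth|stiffness|swv|reliability|stats|run-all`).

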