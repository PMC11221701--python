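# Methods

## Task designs

Eight group designs across four center-out reaching experiments are encoded
as trial schedules (4 radial targets at 10 cm, 90° apart, pseudo-random
order with each direction appearing once per 4-trial window; a single fixed
order is shared by all simulated participants via a default seed).

| Design | Blocks (trials) | Perturbation | SPE | TPE |
|---|---|---|---|---|
| E1 Hit | 20+20 / 240 / 20+20 | +10° jump, clamp at 0°, jumped target 4.6 cm | yes | no |
| E1 Miss | 20+20 / 240 / 20+20 | +10° jump, clamp at 0°, target 0.98 cm | yes | yes |
| E2 J10/J20 | 20+20 / 240 / 20+20 | 10°/20° jump, clamp at 0°, ignore instruction | no | yes |
| E3 Clamp | 40 / 200 / 40+120 | 30° clamp, stationary target | yes | yes |
| E3 ClampJump | 40 / 200 / 40+120 | 30° clamp + 30° jump | yes | no |
| E4 J10CCW | 20+20 / 240 / 20+20* | 10° jump, veridical cursor | no | yes |
| E4 J30CW | 40 / 200 / 40+120 | 30° CW jump, veridical cursor | no | yes |

\* E4 group 1 washes out with feedback first, then without — the reverse of
E1/E2.

TPE presence on learning cycles is decided geometrically: the cursor
endpoint and jumped-target centre both lie on the 10-cm circle, so their
separation is the chord `2R·sin(|jump − clamp|/2)`, and a hit requires it
not to exceed the target radius (the cursor is treated as a point; a cursor
radius can be supplied and is added to the target radius).  SPE presence is
a design property (clamped-cursor experiments only), not inferred from
trajectories.  All angles are counterclockwise-positive and every design is
sign-normalized on construction so compensation is positive; the E4 30° CW
group is mirrored on load (and the synthetic generator emits its
trajectories physically mirrored so the pipeline's normalization restores
them).

## Models and update conventions

All three learners run at one update per 10-trial cycle, matching the
resolution of the fitted data (a per-trial mode is available through drive
expansion but is not used for the reference fits).  Traces record the
post-update state of each cycle, starting from 0 before the first baseline
cycle (the data are baseline-corrected).  Lumped drives are constant during
learning and zero elsewhere; both drives are also zeroed on no-feedback
washout cycles — without a cursor there is neither a visual error nor
outcome information.  In the Independent model each process retains its own
state; a variant in which the SPE process retains the net state is
available behind a flag (`retention_on_net`) but is not the default, since
it makes the two processes non-separable and breaks the additive
decomposition.  In the Interaction model the gains apply only on cycles
without a TPE and are pinned at 1 where a TPE is present.

## Fitting

Loss is the unweighted sum of squared residuals between the model's net
trace and the group-mean cycle series over the masked cycles (baseline,
learning, no-feedback washout).  Box constraints: retention factors in
[0, 1]; lumped drives in [0, d] where d is the design's maximum error angle
(10° for the 10°-jump designs, 20° for the 20° jump, 30° for the 30° clamp
— the bound generalizes the "maximum possible error per trial" rationale);
gains in [0, 3], wide enough to contain all plausible estimates and their
CIs.

Every protocol has exactly two free parameters, and the trace is affine in
the drive/gain parameter once the retention/gain-on-retention parameter is
fixed.  The optimizer exploits this: the affine parameter is profiled out
in closed form (clipped least squares) and the remaining axis is searched
with a coarse grid plus seeded random probes and a bounded Brent polish.
This is deterministic given the seed, immune to local-minimum traps in the
profiled 1-D objective, and validated against an exhaustive grid search
(steps 0.01 / 0.05) on short problems.  Goodness of fit (R², RMSE) is
computed over the fitted (masked) cycles by default; a switch computes it
over all cycles instead.

Sequential protocols follow the two-stage logic: the SPE-only process fit
to the TPE-free group, frozen, then the TPE process fit to the TPE group
(Independent); or the full dynamics fit with unit gains to one group,
frozen, then the gains fit to the other (Interaction).  Bootstrap 95% CIs
resample participants with replacement (the conventional unit for
group-mean fits), recompute the mean cycle series and refit, holding
stage-1 frozen parameters at their full-sample values; percentile intervals
are reported and are deterministic given the seed.

## Kinematic preprocessing

Hand paths are low-pass filtered (Butterworth, 10-Hz cutoff; order 4 —
unstated in the source analyses, chosen as the field convention — applied
forward-backward for zero phase), speeds come from central differences,
movement onset is the first sample at or above 5% of peak speed, and RT is
onset minus go cue.  Hand deviation is the signed angle between the
start-to-original-target line and the start-to-hand line at peak velocity,
with the peak searched from onset to the first 10-cm crossing (the cursor
froze at 10 cm), falling back to the whole trial.  Exclusions: no movement
(peak speed below 2 cm/s — the floor itself is a package choice), stylus
lift, and |deviation| strictly greater than 85°.  Baseline bias is the mean
deviation over all valid baseline trials (both sub-blocks) and is
subtracted per subject.  Cycle means use valid trials only (a cycle with no
valid trials propagates as missing).  Phase metrics are means over the
defining 10-trial windows: first/last 10 learning trials, first 10
no-feedback washout trials (early after-effect), first 10 feedback washout
trials (sustained after-effect), last 10 washout trials, and the RT change
from the last 10 baseline to the first 10 learning trials.

## Synthetic cohorts

The generator emulates the behavioural structure the analysis assumes, at
two resolutions.  At cycle level, each subject is the noiseless model trace
plus independent Gaussian cycle noise (default SD 1.5°).  At trajectory
level, each trial is a straight-line reach at the intended angle plus
Gaussian angular noise (default SD 3°), with a minimum-jerk speed profile
(smooth, with a unique interior speed maximum) over 14 cm in 0.6 s at
100 Hz sampling.  The intended angle is the strategic aim (original target,
or jumped target when re-aiming, which engages 2 trials after the first
jump by default) plus the implicit state of that trial's cycle.  Programmed
RTs are 400 ms baseline plus 100 ms on strategic re-aiming trials plus
additive lognormal jitter (median 20 ms); movement start is placed so the
5%-of-peak-speed crossing — the onset definition the pipeline measures —
falls exactly at the programmed RT.  The noise defaults are calibrated only
to produce group-level variability comparable to published cycle plots and
are not claims about the real data's noise structure.

What the generator does **not** emulate: within-trial feedback corrections,
curved or segmented trajectories, biomechanics, trial-varying error
sensitivity, subject-level parameter heterogeneity, or genuinely missing
data.  Passing recovery tests therefore shows that the estimation chain is
correct and well-conditioned under the stated noise model at the study's
group sizes — not that real data meet those assumptions.

## Problem sizes and numerical choices

The recovery and coverage studies use the study's group size (n = 15),
100 recovery replicates, 50 coverage cohorts and 1000 bootstrap refits per
cohort; these sizes give Monte-Carlo error comfortably below the margins
they are checked against.  Optimizer tolerance is 1e-10 on the profiled
axis; grid/probe counts are configurable (41-point grid + 20 probes for
point fits, 21 + 5 for bootstrap refits, where the profiled objective is
smooth and the polish does the precision work).  Ties in the profiled
search resolve to the first-found minimum.  Degenerate inputs are handled
explicitly: a zero-variance observed series flags R² as undefined; an
all-zero drive profile yields a zero drive estimate; a cycle with no valid
trials propagates NaN and is ignored by masked means.

## Known limitations

* The deposited behavioural dataset is not bundled, so fits to the real
  group data require supplying the trial table; the loader resolves column
  names through an explicit alias map rather than guessing a layout.
* Bayes factors use a default JZS prior and are informational only.
* The mid-reach timing of the target jump is a schedule attribute only;
  within-trial dynamics of the jump are not simulated.
* Per-subject fitting is available but the reference protocols operate on
  group-mean series, as in the analyses they mirror.
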