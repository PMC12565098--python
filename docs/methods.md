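# Methods

This note documents the models, numerical choices and limitations behind
`crossgaze`: a pipeline that reproduces a VR pedestrian-crossing study's
head–eye movement analysis on synthetic data with known ground truth.

## Traffic scenario

The scene lasts 45 s. Each car pass is reduced to the azimuth at which the
car appears in the participant's view, a piecewise-linear, monotonic function
of time. A car blocks crossing while its azimuth lies within the hazard zone,
±45° of straight ahead; the zone half-width is a modelling choice (the
geometry of the crossing is not otherwise constrained) fixed so that the
default 10-car schedule yields exactly the two published car-free windows,
[16, 25] s and [34, 45] s. Car speeds and spacing are unconstrained
otherwise; the default schedule chains hazard-zone dwells so the occupied
intervals tile [0, 16] and [25, 34] with small overlaps. Three of the ten
cars are red; the rest take colours from a fixed seven-colour palette purely
for reproducibility.

`find_safe_windows` recovers maximal car-free intervals of length ≥ `min_gap`
(default 3 s, a shortest plausible crossing; it only matters for non-default
schedules). Windows are closed intervals: a verbal response exactly on a
boundary counts as inside. Scenario JSON round-trips losslessly to six
decimal places.

## Synthetic behaviour generator

The generator defines the study conditions; everything downstream is
validated against its injection logs.

**Cohort.** Group sizes default to 19 controls, 26 central, 6 peripheral and
8 combined-impairment patients. Age, MoCA, decimal acuity and field radius
are drawn from piecewise-uniform distributions whose population median and
range match the study's demographics table; every draw classifies back into
its own group under the functional criteria. Two of the eight combined
patients are "dual severe" (acuity ≤ 0.1 and field radius ≤ 7°) and, with the
default failure flag, produce no responses and report zero red cars — the
phenotype that failed both tasks.

**Gaze stream (120 Hz).** A viewing is the sum of:

* *Fixational drift* — an Ornstein–Uhlenbeck velocity process (RMS 3 °/s,
  time constant 0.25 s; configurable) integrated into position with a weak
  positional leak (1.5 s), giving a bounded slow wander of ~1–2°.
* *Macrosaccades* — Poisson-timed, log-normal amplitudes (per-group median,
  log-sd 0.45, truncated to [2.5°, 60°]), directed toward the azimuth of a
  currently visible car (or a random scene point when no car is visible),
  with direction flipped toward centre when the target would exceed ±65°.
  The velocity profile is a raised cosine; duration follows the saccadic
  duration law 2.2 ms/deg + 21 ms, which together imply a saturating
  main-sequence peak velocity v_p = 2A/dur ≈ 909·A/(A + 9.55°) °/s
  (≈ 100 °/s at the 1.2° boundary, ≈ 440 °/s at 15°). We derive peak
  velocity from the duration law rather than fixing an independent
  exponential main sequence, because amplitude, duration and peak velocity
  cannot all be chosen freely once the profile shape is fixed.
* *Microsaccades* — Poisson-timed single-interval steps (one 8.3 ms sample
  period), log-normal amplitudes truncated to [0.92°, 1.13°]. The lower
  bound enforces that the sampled central-difference peak velocity
  A/(2·dt) = 60·A °/s clears the 50 °/s detection threshold; the upper bound
  leaves headroom below the 1.2° classification boundary for measurement
  noise. Real microsaccades extend well below 0.9°, but events smaller than
  ~0.85° are mathematically invisible to a 50 °/s velocity threshold at
  120 Hz, so only the detectable part of the distribution is emulated — a
  sampling-rate limitation, not a property of the underlying behaviour.
* *Tracker noise* — isotropic Gaussian, sd 0.5° per axis, with AR(1)
  temporal correlation (lag-1 ≈ 0.99 at 120 Hz). The correlation matters:
  white 0.5° noise would contribute ~20 °/s of velocity noise and flood a
  50 °/s threshold with false events, whereas video eye-tracker error is in
  fact dominated by slowly wandering offsets. About 0.1% of samples are
  flagged invalid (tracking dropouts).

All saccadic events (both kinds) are scheduled jointly with ≥ 80 ms
onset-to-offset separation and 0.25 s clear margins at the trace ends, by
distributing the free time between events uniformly at random. If a Poisson
draw cannot fit, the count is truncated to the maximal feasible number;
infeasible *rates* raise an error up front.

**Head stream (90 Hz).** Yaw is baseline drift plus discrete raised-cosine
ramps (log-normal amplitudes, median 25°, truncated [8°, 60°]; peak yaw
velocity drawn uniformly from 60–110 °/s). Ramp direction points toward the
current gaze azimuth when gaze is eccentric (> 20°), otherwise random, with
a centre-flip keeping yaw within ±45°. Head-turn counts are drawn
under-dispersed relative to Poisson (Gaussian with sd 0.35·√λ around the
rate): scanning is paced by the ten car arrivals, so per-viewing counts
cluster around a scene-determined number. Gaze is generated directly in
world coordinates; vestibulo-ocular stabilisation is implicit (head motion
does not add gaze-in-world velocity outside gaze shifts).

**Responses.** One response per safe window at
`window start + group delay + N(0, 0.6 s)`, clipped into the window; the two
windows carry separate delay medians because the published per-window group
medians differ. The red-car report is 3 minus a binomial miss count with a
small per-group miss probability.

**Seeding.** A single master seed feeds documented
`numpy.random.SeedSequence` keys: `(seed, 0)` for the cohort,
`(seed, 1, i, task)` for participant *i*'s trace on a task, `(seed, 2, i)`
for responses. Identical inputs give bit-identical output.

## Event detection

Angular velocity is the central difference of the great-circle angle between
gaze directions (unit-vector dot products; no small-angle shortcut):
`v[i] = angle(x[i-1], x[i+1]) / (t[i+1] - t[i-1])`. Invalid samples make the
velocity missing and break events; an event whose support touches an invalid
sample is discarded.

Saccades are maximal runs with v > 50 °/s; runs separated by < 20 ms merge;
runs shorter than `min_event_duration` (default 1 sample) are dropped. Event
amplitude is measured between the samples one before onset and one after
offset — the support of the central difference — so a single-interval step is
recovered in full. Mean velocity is amplitude/duration with duration floored
at one sample period; for a single-interval microsaccade this equals
A/8.3 ms ≈ 120·A °/s, the quantity reported as average microsaccade
velocity. Events with amplitude ≥ 1.2° are macrosaccades (the boundary is
inclusive on the macro side), below are microsaccades.

The default `smoothing_window` is 1 (no smoothing beyond the two-interval
central difference). This is deliberate: at 120 Hz a 3-sample centred mean
caps the measurable velocity of a displacement A at 40·A °/s, so a 50 °/s
threshold would require A > 1.25° and every microsaccade would be invisible.
Wider windows remain available for low-rate, low-noise regimes.

Fixations are the complement of the macrosaccade intervals, including the
leading and trailing stretches (configurable at summary level);
microsaccades do not interrupt them, so fixations and macrosaccades
partition the trace to within one sample period.

Head turns — the study reports them without an operational definition — are
defined here as runs of consistent-sign yaw velocity above 10 °/s whose net
yaw change is at least 5°. Both thresholds are configurable and this
definition is the package's own; matching published head-turn counts is
achieved through generator calibration, not definitionally.

## Clinical classification

logMAR = −log10(decimal acuity), rounded half-up to two decimals only for
reporting. Non-concentric field constriction averages the temporal and nasal
radii. Functional types follow the study's entry criteria exactly; the gaps
in that scheme (e.g. acuity 0.7 with a full field) are labelled
`unclassified` rather than forced into a group. WHO categories evaluate the
acuity-based and field-based rows separately and assign the more severe —
the tie-breaking is inferred from the study's own worked example (acuity
0.20 with a 5° field → category 4) — with the table's top row mapped to
`not_categorized` for ordering.

## Statistics

All endpoints are compared nonparametrically, two-sided, α = 0.05, mid-ranks
for ties. Shapiro–Wilk only annotates endpoints. Mann–Whitney uses exact
enumeration when n_a·n_b ≤ 400 and the data are tie-free, otherwise the
tie-corrected normal approximation without continuity correction (so the
two-group case agrees with Kruskal–Wallis). The Bonferroni family is the
three subgroup-vs-control contrasts per endpoint. Covariate adjustment is
OLS with explicit dummy coding (controls reference) and predictors limited
to group, age and MoCA; both a binary patient indicator and a categorical
group coding are fitted. scipy.stats and statsmodels supply the numerics;
tests validate them against brute-force enumeration, permutation oracles and
closed-form cases.

## Calibration

The shipped `default_behaviour.yaml` was calibrated once, by coarse
iterative search, so that the *detected* group medians of the full
simulate → detect → summarize pipeline land on the published values:
crossing times (CT1 17.8 s controls / 19.1 s patients), macrosaccade counts
(195 controls safe-crossing, 226 central), microsaccade counts (119 / 86 /
65 controls / central / combined in car counting), head turns (35 / 20
controls / combined in car counting), and total macrosaccade amplitude
(3098° controls vs 2353° combined in safe crossing). Unreported quantities
(car-counting macrosaccade counts, safe-crossing microsaccade counts,
per-event amplitude distributions) were chosen once at plausible values
consistent with the reported totals. The published average microsaccade
velocities (115–125 °/s) pin the otherwise-unreported microsaccade amplitude
medians at velocity/120 ≈ 0.96–1.04°, since a single-interval step's mean
velocity is 120·A °/s.

Calibration measurements used 150 simulated participants per group×task
cell; the acceptance checks run the study-sized cohort (19 controls), where
sample medians scatter a few percent around the calibrated values.

## What passing tests do and do not show

The generator emulates the *statistical* structure of visually guided
scanning: event rates, amplitude scales, main-sequence kinematics, response
delays and group contrasts. It does not emulate smooth pursuit of moving
cars, vestibulo-ocular gain, blinks, pupil dynamics, binocular disparity,
sub-0.9° microsaccades, or any cognitive strategy beyond "look near cars".
Detector validation against injection logs therefore demonstrates
correctness of the segmentation logic under realistic noise, not performance
on real recordings; and calibration closure demonstrates that the pipeline
is internally consistent, not that the generator is a generative model of
patients.

## Known limitations

* At 120 Hz the central difference bounds measurable event velocity by
  A/(2·dt); detected peak velocities of microsaccades are therefore ~55–70
  °/s even though their notional (continuous-time) peaks exceed 100 °/s.
* Micro/macro classification within ~0.1° of the 1.2° boundary is
  noise-limited; the generator avoids the band just below the boundary, and
  exact count equality between detection and injection is only guaranteed in
  the low-noise oracle regime.
* The head-turn definition is operational, not taken from the study; counts
  are comparable only under this package's definition.
* The simulated cohort reproduces medians and ranges of the demographics
  table but not its joint correlation structure (e.g. age–acuity).
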