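# Methods note

This note records the modelling assumptions, parameter defaults and
numerical conventions behind `vrepm`, and the boundaries of what the
synthetic cohort generator does and does not emulate. Every quantitative
statement here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted about real human data.

## Maze geometry and zone model

The maze is a plus of four arms, each 175 cm long and 30 cm wide
(350 × 350 cm overall). In the maze frame the x-axis runs along the
closed arms and the z-axis along the open arms; the vertical coordinate
is ignored for scoring. A sample is classified by a 15-cm threshold:

* `|z| > 15` → OPEN arm (sign of z selects the arm),
* else `|x| > 15` → CLOSED arm,
* else CENTER.

If both coordinates exceed the threshold (possible only with
out-of-maze positions, which the reader does not reject) the larger
coordinate wins, with exact ties resolved to OPEN. The classification is
a total partition — verified by property tests over the whole plane.
"End exploration" is reaching `|z| ≥ 160` cm, i.e. within 15 cm of an
open-arm end.

Recorded head poses may be in an arbitrary tracking frame; a
`CalibrationTransform` (rigid rotation + translation, determinant +1
enforced) maps them into the maze frame before scoring.

## Behavioural markers

Sampling is 5 Hz; each task sample contributes Δt = 0.2 s of dwell time.
The task segment is `t ≥ 0`; a 30-s baseline precedes it at negative
times. Markers per session:

* **time_open / time_closed / time_center** — Δt per classified sample;
  the three always partition the task duration to within one sample.
* **entries** — transitions from *not-in-zone* to *in-zone*, pooled over
  both arms of a kind; re-crossing between the two open arms through the
  center counts as a new entry.
* **latency_first_open** — task time of the first OPEN sample; censored
  at the task duration if no open visit occurs.
* **latency_end_exploration** — first sample with `|z| ≥ 160`; censored
  likewise.
* **total_distance** — sum of horizontal Euclidean step lengths over the
  task segment, reported in meters.
* **mean velocity (open/closed)** — mean of step speeds whose *both*
  endpoints lie in the zone; `NaN` if no such step exists.

All markers are validated against independent brute-force per-sample
scans on random trajectories (exact agreement, 100 trajectories × 1500
samples in the acceptance suite).

## Occupancy maps

Maps are 35 × 35 grids of dwell seconds at 10-cm resolution: bin index
`floor((c + 175)/10)` clipped to `[0, 34]`, i.e. half-open bins over
`[−175, 175)` with boundary samples clamped. An unnormalized map sums to
the tracked task time (conservation is an acceptance criterion). Cohort
maps are means over participants' unnormalized maps; a difference map is
`second − first` of two cohort means and requires both inputs to be
cohort-normalized. The dwell mask marks bins with ≥ 0.5 s occupancy
(inclusive).

## Physiological intervals

Continuous channels (SCL, HR, RESP) are summarised as 11 interval means:
one 30-s baseline plus ten 30-s task windows, each half-open `[a, b)`.
Empty windows yield `NaN` and are listed as missing. SCL interval means
are natural-log transformed *at the interval-mean level* (not per
sample); non-positive means raise an error naming the interval, and a
second transform of already-transformed data is refused. Salivary
alpha-amylase is handled as T0/T1/T2 triplets with change scores
(T1−T0, T2−T0) and a 25 U/mL detection limit flag.

## Reliability statistics

**ICC(3,1)** (two-way mixed, consistency, single measures):
`(MS_B − MS_E)/(MS_B + (k−1) MS_E)` from the subjects × occasions mean
squares, with the exact F-bound 95% confidence interval
(`FL = F/F_{.975}(n−1,(n−1)(k−1))`, `FU = F·F_{.975}((n−1)(k−1),n−1)`,
CI endpoints `(FL−1)/(FL+k−1)` and `(FU−1)/(FU+k−1)`). At least 5
subjects are required. Cross-checked against `pingouin` (ICC(C,1)) and,
asymptotically, against the Pearson correlation.

**Split-plot ANOVA.** Implemented by the multivariate regression
approach: the between design matrix is effect-coded (so unbalanced
groups are handled by Type III / unweighted-means conventions), within
effects are spanned by orthonormal Helmert contrasts, and two within
factors are combined by Kronecker products. Sums of squares are traces
of the hypothesis and error SSCP matrices projected through the
contrasts. The Greenhouse–Geisser epsilon is
`tr(M)²/(q·tr(M²))` with `M = C'SC` and `S` the *pooled within-group*
covariance — the SPSS convention; `pingouin` pools differently in mixed
designs, so the cross-check oracle is applied only to pure
within-subject and balanced designs, where the two agree exactly
(including epsilon and corrected p-values). A 2-level within factor
gives epsilon = 1 and reproduces the paired t (F = t²) to 1e-6.

**Paired t and power.** Two-sided paired t with a degenerate-difference
guard (zero or numerically-zero variance). Power for the paired design
uses the noncentral t with noncentrality `d·√n`; the required sample
size is found by bisection on the smallest integer n achieving the
target. Defaults d = 0.5, α = .05 two-sided: n = 38 at power .85, n = 34
at power .80. Empirical type-I error of the paired onset test on
simulated null physiology is 5% ± 2% over 2000 replicates, and empirical
power matches the noncentral-t prediction within 3 percentage points
(acceptance criteria).

No correction for multiple comparisons is applied anywhere in the
package; this is a deliberate reporting convention.

## Synthetic cohort generator

The generator is a *segment-based arm-visit walker*, not a biomechanical
model. An agent repeatedly chooses an arm (open arms weighted
`w = 1/(1+anxiety)` against 1 per closed arm, with probability 0.2 of
repeating the previous arm), walks there at a lognormally varying speed,
dwells for a Poisson-distributed number of samples, and returns. Open
visits are shallower and shorter for anxious agents: depth fraction
`0.9·u^(1/w)` with probability `0.5·w` of a full end-exploration visit
(`U(0.92, 1)`), and open dwell scaled by `0.2 + 0.8·w`.

Cohorts draw a latent anxiety trait per participant from a bivariate
normal across the two exposures (sd 2.0, retest correlation 0.8,
`anxiety = exp(trait)`), plus *stable* per-participant locomotor traits
(`speed_factor = exp(N(0, 0.3))`, `dwell_factor = exp(N(0, 0.4))`)
applied identically to both exposures. The default design is 39
participants, first exposure always on the "Sea" maze, second exposure
split 18 "Desert" / 21 "VideoGame".

These defaults were calibrated — before the acceptance tests were
frozen — so that cohort-level behaviour lands on a realistic scale
(mean open-arm time of order one minute out of 300 s) and so that the
reliability structure is interesting: the latent retest correlation of
0.8 is *attenuated* by within-session dwell-choice noise to a realized
behavioural reliability of ≈ 0.36 for open-arm time (pooled over 200
simulated cohorts in the acceptance suite), while locomotor measures,
driven by the stable factors, stay highly reliable (ICC ≈ 0.8–0.9).
The acceptance criterion checks that per-cohort ICC confidence intervals
cover this implied (attenuated) truth in ≥ 90% of cohorts and that mean
open-arm time is monotone decreasing in the anxiety parameter.

The physiological generator is piecewise-deterministic plus white noise:
a baseline level, a step onset response at task start, an additive
anticipation shift and a multiplicative sensitization factor on the
second exposure.

**What the generator does not emulate:** head orientation dynamics
beyond a heading-from-gradient yaw, postural sway, freezing or
risk-assessment micro-behaviours, habituation within a session, any
coupling between behaviour and physiology, circadian or endocrine
dynamics (amylase triplets are not simulated), tracking dropout or
sensor noise (ingestion handles those, the generator does not produce
them), and any questionnaire or self-report layer.

## Numerical conventions

* Trajectory CSVs round-trip through `%.17g`, so pipeline outputs are
  bit-identical across runs with the same seed (tested).
* Resampling interpolates linearly on a uniform grid, unwraps angles,
  and flags gaps longer than 1 s; non-finite rows are dropped and
  counted in the quality report.
* All randomness flows through `numpy.random.Generator` seeded
  explicitly; no global state.
* Half-open windows/bins everywhere (`[a, b)`), with the single
  exception of the inclusive dwell-mask threshold (≥).

## Limitations

* The ICC confidence interval assumes normality of subject and error
  effects; markers with floor effects (e.g. latency censored at task
  end) violate this, and censored latencies are returned as the task
  duration with an explicit censoring flag rather than modelled
  survival-style.
* The mixed ANOVA's sphericity handling follows one (SPSS-style)
  convention among several; mixed unbalanced designs therefore need not
  match other software that pools covariances differently.
* The generator's attenuation of latent reliability is a property of its
  own noise structure, not an empirical claim about human retest
  behaviour.
* Velocity means require both step endpoints in-zone, which drops
  boundary-crossing steps; very brief visits can yield `NaN`.
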