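# Methods

## The measurement principle

The package models a tonometer that never touches the eye: it watches
the pupil. After dark adaptation, a short blue flash constricts the
pupil; when the flash ends the pupil redilates toward its dark baseline.
If the anterior-chamber fluid resists iris movement in proportion to the
intraocular pressure, redilation is slower at higher IOP, so the
redilation *rate* carries a pressure signal. Iris mechanics differ
between people, so the rate-to-pressure map must be anchored per eye
with one simultaneous reference tonometer reading.

No published equation exists for a real device of this kind (the
hardware and estimation algorithm are proprietary), so the package
declares its own minimal surrogate model and is explicit about it.

## Pupil light-response model (`dynamics`)

Area as a fraction of the dark-adapted baseline, piecewise exponential:

- dark phase (t < t_on): f = 1;
- flash (t_on ≤ t < t_off): f(t) = m + (1 − m)·e^(−(t−t_on)/τ_c), where
  m is `min_frac` and τ_c the constriction time constant;
- recovery (t ≥ t_off): f(t) = r − (r − f_off)·e^(−(t−t_off)/τ_d), where
  r is `recovery_frac` and f_off the flash-offset value, making the
  curve continuous across the boundary by construction.

IOP enters only through the redilation time constant,
τ_d(IOP) = τ_ref · IOP / IOP_ref. Linear coupling is the simplest law
under which a single calibration reading determines the whole map; it
also makes the estimator a one-parameter power law (IOP ∝ τ_d). A
sustained post-illumination response (r < 1) is exposed but not default:
full recovery keeps the asymptote equal to the baseline, which the
redilation fit exploits.

Defaults (population-typical values for a healthy adult in darkness):
baseline area 38 mm² (≈ 7 mm diameter), min_frac 0.35, τ_c 0.35 s,
τ_ref 2 s at IOP_ref 16 mmHg. The protocol is 10 s dark, 1.5 s flash
(480 nm, metadata only), 8 s recovery at 13 frames/s — recovery length
chosen so the 6-s post-illumination readout always exists; total 254
samples. Measurement noise is multiplicative i.i.d. Gaussian per frame,
since segmentation error scales with pupil size.

## Imaging and segmentation (`imaging`, `segmentation`)

Rendering follows the dark-pupil NIR convention: pupil (gray 20) inside
an iris disk (120) on sclera (200), 240×320 px at 0.05 mm/px, optional
centre jitter and Gaussian sensor noise, 8-bit multi-page TIFF with a
JSON sidecar (protocol, scene, timestamps). Monocular frames; a
binocular instrument is represented by two independent sequences.

Segmentation per frame: 3×3 median filter → threshold → connected
components → largest dark component (≥ 50 px) → hole filling →
area = pixel count × (mm/px)². The default threshold is a **three-class
multi-Otsu taking the darkest class**: the scene histogram is trimodal
and a plain two-class Otsu splits iris from sclera, merging pupil and
iris into one dark component. Multi-Otsu is offset-invariant (adding a
constant gray shifts all class boundaries equally), which the tests
assert. Pixel counting is used rather than an ellipse fit because the
target quantity is area and counting is unbiased on rendered disks.

Missing-frame policy: a frame with no adequate dark component yields a
NaN, interpolated linearly when flanked by valid frames and dropped (with
a warning) at the edges; a recording with > 20 % missing frames is
rejected outright. The policy is a declared contract so that dropout
behaviour is deterministic and testable.

## Features (`features`)

- baseline: mean area over the final 3 s of the dark phase;
- constriction amplitude: 100·(1 − min area / baseline);
- redilation fit: one-parameter nonlinear least squares of
  A(t) = A∞ − (A∞ − A_off)·e^(−(t−t₀)/τ) over the first 6 s of
  recovery, with A∞ fixed to the baseline (consistent with full
  recovery) and (t₀, A_off) anchored at the first recovery *sample* —
  for an exponential approach this re-anchoring is exact, so noiseless
  recordings are recovered to machine precision. The starting τ comes
  from a log-linear fit of ln(A∞ − A) on the samples below the
  asymptote; τ is optimized in log space (positivity built in) with a
  Levenberg–Marquardt step. Failure modes (recovery already at/above
  baseline; non-convergence) raise a dedicated error carrying the
  log-linear fallback value.
- 6-s PIPR: area at the sample nearest t_off + 6 s as % of baseline;
  at 13 fps the worst-case timing error is 38 ms. Exact halfway ties
  resolve to the earlier sample.

The fit window of 6 s matches the standard post-illumination readout
interval and is configurable.

## Calibration and estimation (`estimator`)

k = IOP_calib · rate_calib (units mmHg/s), then IOP̂ = k / rate. Under
the linear τ_d–IOP coupling this closed loop is exact: calibrating at
any IOP₁ and measuring at any IOP₂ returns IOP₂, which the tests verify
to ≤ 0.1 mmHg across 9–23 mmHg on noiseless recordings. Output is
reported at 0.1 mmHg resolution by default (rebound-tonometer style),
with integer (Goldmann-dial) rounding as an option. Calibration is per
eye and per study sitting (the first sitting measurement).

## Study simulator (`study`)

Cohort defaults encode the validation-study structure: 20 recruited, 3
unable to cooperate, 1 with no data, 1 further participant contributing
one eye, and 4 included participants unable to lie with legs raised —
drawn only from two-eyed participants, which the accounting forces
(31 − 23 = 8 = 4×2 eyes). That yields 16 participants / 31 eyes and the
pair accounting 116 = 31 calibration + 85 compared (31 supine + 23
raised-legs + 31 second-sitting).

Per eye, a true sitting IOP is drawn from N(18.25, 2.2²) clipped to
[9, 23] mmHg — chosen to reproduce an overall ~18.2 mmHg mean and the
observed clinical range. Reference readings add N(0, 0.5²) instrument
noise; GAT and iCare are treated as interchangeable up to the position
biases. Compared prototype readings are reference + bias(position) +
deviation, with deviations from a two-component Gaussian mixture:
N(0, 0.5²) with probability 0.8, N(0, 4²) otherwise. A single Gaussian
cannot put ~80 % of mass within ±1 mmHg while keeping ~10 % beyond
±3 mmHg; the mixture CDF gives P(|d| ≤ 1) = 0.803 and
P(|d| ≤ 3) = 0.909. Default biases are −1 mmHg supine and +1 mmHg with
legs raised (sitting unbiased), matching ~1 mmHg group-level offsets
and a 2 mmHg spread of prototype group means; they are set to zero for
pure-noise experiments. Simulated tables keep full float precision —
device-style rounding before differencing would bias the within-±1
fraction upward by ~0.8 points relative to the mixture law.

Calibration-session prototype rows equal their reference reading: the
one-point calibration defines the prototype to agree there, and those
rows are excluded from all comparisons.

## Statistics (`stats`)

Written from scratch (scipy supplies only ranking and the normal/χ²
CDFs; scipy's own tests serve as independent cross-checks in the test
suite, alongside brute-force sign-vector and hand-computed oracles):

- **Wilcoxon signed-rank**: zero differences dropped (classic
  convention; Pratt's method available), midranks for ties, statistic
  W⁺ = sum of positive-difference ranks. Exact mode builds the null
  distribution of W⁺ by dynamic programming over doubled (integer)
  midranks — correct conditional on the observed tie pattern; two-sided
  p = 2·min(tails), capped at 1. Approximate mode uses the exact
  conditional variance Σr²/4 (equivalent to the textbook tie-corrected
  variance) with a continuity correction. Auto mode is exact to n = 25.
- **Friedman** (the repeated-measures comparison across supine /
  raised-legs / second-sitting deviations): midranks within each eye,
  tie-corrected χ² statistic on k−1 degrees of freedom; incomplete eyes
  excluded and counted. Chosen as the nonparametric instantiation of a
  repeated-measures analysis, consistent with the Wilcoxon-based
  pairwise comparisons on non-normal differences.
- **Laterality check**: OD vs OS paired Wilcoxon within two-eyed
  subjects for each instrument-role × position cell — the guard against
  fellow-eye correlation (multicollinearity) when both eyes enter the
  analysis.
- **Agreement report**: per-group and overall n, means ± SD, Wilcoxon W
  and p; |deviation| histogram binned at the nearest integer mmHg from
  0 to 6 (mass beyond 6.5 mmHg stays as residual, so fractions sum to
  ≤ 1); fractions within ±1 and ±3 mmHg (inclusive thresholds, signed
  continuous deviations); pairwise intergroup median differences of
  prototype readings with Wilcoxon p; the laterality table. Two-sided
  p-values throughout; no multiple-testing correction is applied, and
  the report metadata says so.

## Pipeline (`pipeline`, `io`, `cli`)

`full_run` composes everything: cohort → per-eye physiology (baseline
area, τ_ref etc. drawn with modest inter-individual spread) → one
recording per session, where the study table's prototype value acts as
the device-effective pressure the recording is simulated at → features →
first-sitting calibration → estimates → agreement report. `series-only`
mode skips rendering/segmentation so the statistical surface does not
require image processing; `imaging` mode runs the full optical chain and
agrees with the fast path within the 2 % segmentation round-trip bound.
All randomness flows from one root seed via named substreams; every run
directory embeds the seed and a config hash, and re-running reproduces
byte-identical measurement tables.

## Problem sizes used in the test and acceptance suites

Deviation-distribution checks pool ≥ 5000 (tests) / ≥ 20000 (acceptance
script) compared deviations over repeated default studies; the overall
IOP level pools 30–50 studies; τ-recovery runs a 5 × 3 grid of
(τ, noise) cells at 100 seeds per cell; the segmentation sweep renders
full-length stacks at IOP ∈ {9, 12, 16, 20, 23} mmHg, which brackets
the whole pupil-area range of the clinical interval; Wilcoxon
calibration uses 2000 simulated null studies of 31 pairs. These sizes
give Monte-Carlo standard errors comfortably below the tolerances they
are checked against.

## What the generator does and does not emulate

The synthetic data reproduces the *structure* of a real comparative
study — cohort accounting, paired design, calibration/comparison split,
deviation mixture, position biases — and a physically plausible but
declared-surrogate optical chain. It does not model melanopsin vs
rod/cone pathways, consensual binocular coupling, blinks or eyelid
occlusion beyond the missing-frame policy, accommodation, diurnal IOP
variation, postural IOP physiology beyond fixed biases, or glaucomatous
(high-IOP) eyes. Passing tests therefore demonstrate internal
consistency of the method and faithful reproduction of the declared
study conditions — not clinical accuracy on real eyes.

## Known limitations

- Whether a real prototype's "dilatation rate" is a time constant, an
  initial slope, or a fixed-interval area change is unknown; the
  time-constant reading is this package's declared surrogate, and the
  area (not diameter) percentage convention is assumed.
- The linear τ_d–IOP law is the weakest-assumption model compatible with
  one-point calibration, not a validated biomechanical result.
- The exact repeated-measures test and the SPSS tie/zero conventions
  behind a real study's printed p-values are unknowable; the
  conventions here are declared and tested against independent oracles
  instead.
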