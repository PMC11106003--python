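# Methods

This note documents the models behind `peptrack`, the parameters that
matter, the numerical choices, and what the synthetic-data studies do and
do not demonstrate.

## Scanner model and coordinates

The detector is a cylinder of `n_rings × n_transaxial` crystal centres:
right-handed frame, scanner axis = z, azimuth counter-clockwise from +x,
millimetres throughout. Crystal `(ring, transaxial)` maps to
`(R cos θ, R sin θ, z₀ + ring·pitch)` with
`θ = θ₀ + 2π·transaxial/n_transaxial`. Vendor crystal-numbering schemes are
proprietary, so the mapping is entirely config-driven
(`radius_mm, n_transaxial, n_rings, axial_pitch_mm, axial_origin_mm,
angular_origin_rad`); reprocessing real scanner exports requires the
vendor's index convention in that config. The default desk-scale geometry —
radius 120 mm, 480 crystals/ring, 80 rings at 1.2 mm pitch, axially centred
— is a plausible small-animal-scanner scale for tests, not a model of any
particular instrument. `nearest_crystal` rounds azimuth and z
independently; exact half-way ties go to the lower index, so
position→index→position round-trips are stable. Block gaps,
depth-of-interaction and time-of-flight are not modelled.

## List-mode dialects

Events are `(t, crystal pair)` or `(t, endpoint pair)`. Two CSV dialects
(headers `t_s,ring1,cry1,ring2,cry2` and
`t_s,x1_mm,…,z2_mm`, gzip accepted by extension, optional boolean
`rejected` column whose flagged rows are dropped — the hook for upstream
delayed-window randoms rejection) and one binary dialect (8-byte magic
`PEPTLM01`, uint64 count, then little-endian float64 t + 6×float32
endpoints per record; round-trips are byte-identical). Readers sort stably
by timestamp and validate bounds, finiteness and — when a geometry is
attached — that endpoints lie on the detector cylinder (relative tolerance
1e−6, generous enough for float32 binary records).

## Emission simulator

The generator's defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| `a0_bq` | 1500 | initial activity (a ~1.5 kBq single particle) |
| `half_life_s` | 4062.6 | ⁶⁸Ga (67.71 min), overridable |
| `sensitivity` | 0.09 | P(emission → recorded true coincidence) |
| `positron_sigma_mm` | 1.2 | isotropic Gaussian positron-range blur |
| `scatter_fraction` | 0.10 | share of detected events with one endpoint displaced ≥2° in azimuth (exponential tail, scale 5°) |
| `randoms_fraction` | 0.02 | share replaced by two independent uniform crystals |
| `intrinsic_rate_cps` | 0.5 | homogeneous background of uniform crystal pairs (LYSO-type intrinsic coincidences, small because a 400 keV energy threshold suppresses them upstream) |
| `discretize` | on | endpoints snapped to nearest crystal centres |

True event times come from thinning a homogeneous Poisson process at the
t = 0 rate `A0·sensitivity` against the decay law `2^(−t/T½)`, so the
recorded count is Poisson with mean
`A0·sensitivity·(T½/ln 2)·(1 − 2^(−T/T½))` — the calibration the count
tests check. Each event annihilates at the trajectory position plus the
positron blur; the LoR direction is uniform on the sphere, resampled until
both cylinder crossings land inside the axial extent. That resampling
*shapes* the axial acceptance while `sensitivity` *scales* the rate — one
interpretable count-rate knob, at the cost of not modelling the true
solid-angle dependence of detection efficiency on axial position.
Annihilations radially outside the bore are silently undetected.
Coincidence-window physics is not simulated (randoms are injected as a
fraction), nor are attenuation, energy spectra, dead time, or
tissue-inhomogeneity positron-range bias (the lung–tissue interface effect
that could bias real in vivo MDPs is explicitly out of model). One seeded
`numpy` Generator drives everything; identical seed ⇒ byte-identical
stream.

The particle motion model is piecewise-linear waypoints (clamped outside
their span) plus an optional sinusoid on one axis — breathing. Defaults:
±2 mm at 1.2 Hz (72 cycles/min, the middle of the 60–80 range typical for
anaesthetised mice).

## Tracking (Birmingham method)

`mdp` solves the 3×3 normal equations of the least-squares
point-to-lines problem in closed form; a bundle whose normal matrix has
condition number above 1e12 (all lines near-parallel) raises a
degenerate-geometry error naming the condition number. Perpendicular
distances use `|w × d̂|`, not `√(|w|² − (w·d̂)²)` — the subtractive form
loses ~6 digits for points near a line with distant anchors, which matters
because exact-recovery tests assert micro-millimetre agreement.

`locate` trims iteratively: compute the MDP of the survivors, drop the
`discard_per_iteration` (default 20%) farthest LoRs — never below
`⌈f·n_initial⌉`, truncating the last removal to land exactly there — and
repeat until the f-factor target is reached. Distance ties break stably
(earlier event survives), making the algorithm deterministic for a given
input order. The published description fixes the *termination* (the
f-factor) but not the per-iteration discard distance; fractional trimming
is scale-free, deterministic and reproduces the "loop terminates when the
set fraction remains" semantics, so it is the package's chosen discard
rule, with the fraction configurable. The tracked-point timestamp is the
mean timestamp of the *surviving* LoRs (default) — self-consistent with
the trimmed position when the source moves — with a window-midpoint
alternative. `error_estimate = rms_residual/√n_final` is a naive
uncertainty; the quantity compared against breathing and precision claims
is always the scatter of tracked points, not this estimate.

`partition_stream` groups the time-ordered stream greedily with no
overlap; the sample size in force is that of the schedule interval
containing each event, so a sample straddling a schedule boundary closes at
the *later* size. A trailing partial sample is kept only if it still holds
at least `⌈min_lors/f⌉` events. With the study-condition rate
(1.5 kBq × 0.09 ≈ 135 cps), 150-LoR samples give ~1.1 s points early in a
scan and 1000-LoR samples stretch from ~7.5 s towards ~30 s after two
half-lives — the adaptive-schedule behaviour the partition tests pin down.

## Kinematics

Velocities are forward differences between consecutive tracked points
(sparse, uneven sampling argues against central differences); speed is the
Euclidean norm; `mean_speed` weights segment speeds by segment duration and
selects segments by midpoint. Static precision is the per-axis sample SD
(ddof = 1) over a window; the breathing envelope is half the peak-to-peak
of the window-mean-subtracted coordinate — an envelope, deliberately not a
sinusoid fit, because the observable of interest is "confined to ±X mm".
Axis naming is anatomical only per fixture (the lung fixtures oscillate
along z); nothing hard-codes animal orientation.

## Reference studies and their parameter choices

* **Transit speed** — constant 48 mm/s along a two-segment, nearly straight
  path (total ≈147 mm, bend cosine 0.9985) inside the default bore;
  acquisition covers the ~3 s transit. A straight 144 mm line cannot fit
  the 96 mm axial extent, and the near-straight dog-leg keeps chord speeds
  between tracked points within 0.2% of the set speed. At 135 cps a
  150-LoR sample spans ~1.1 s, giving 2–3 tracked points per transit; the
  0–30 s mean-speed window therefore contains only moving segments, which
  is what an injection-transit speed estimate means.
* **Breathing envelope** — static lung position, ±2 mm z-sinusoid at
  1.2 Hz, 180 s at sensitivity 0.4 (~600 cps), ~1-s samples. A 1-s window
  spans a whole breathing cycle, so a plain least-squares centre would
  average the motion away (the sinc attenuation at 1.2 Hz × 1 s is ≈0.16).
  The locator instead exploits the dwell-time density of a sinusoid, which
  peaks at the turning points: gentle (10%/iteration), deep (f = 0.05)
  trimming converges onto the momentary extreme cluster, so tracked points
  alternate near ±amplitude and the max–min envelope recovers it. This is
  a mode-seeking use of the trimming loop and the package's own choice for
  oscillation analysis; aggressive 20% trimming undershoots the envelope.
* **Static precision** — 20 min lung-rest acquisition at study conditions
  under the adaptive schedule; reports mean per-axis SD for the 150-LoR
  regime (first minute) versus the 1000-LoR regime, the early-noisy /
  late-steady contrast inherent to adaptive PEPT sampling.
* **Robustness** — single 150-LoR samples around a fixed point with 30%
  uniform-random LoRs; f = 0.1 versus f = 1.0 paired over seeds.
  Quantifies what the trimming buys (sub-millimetre versus ~tens of mm).
* **Fractionation** — the four-tube serial transfer (50 → 37.5 → 25 →
  12.5 µl, 12.5 µl left per tube) makes each tube's capture probability
  exactly ¼ for a well-mixed particle; free activity splits ¼ each
  deterministically, and each further step re-fractionates the
  highest-activity tube after notional re-dilution to 50 µl (the re-dilution
  is implied, not stated, by the protocol; tube-wall adsorption of free
  activity is ignored). Classification thresholds — `single` ≥ 0.90 of
  total in one tube, `colloid_or_free` ≤ 0.40 — are package choices
  sharpening a qualitative rule, both configurable.

Because the simulator omits attenuation, realistic acceptance profiles,
tissue-dependent positron range and vendor crystal maps, passing these
studies demonstrates the *algorithmic* correctness and robustness of the
pipeline under controlled statistics — not the accuracy achievable on a
specific physical scanner, which additionally depends on the real
sensitivity, background and geometry.

## Numerical conventions

Degenerate inputs raise typed errors (`DegenerateLoRError`,
`DegenerateGeometryError`, `InsufficientDataError`, …) rather than
returning sentinels; empty streams partition to nothing and tracking an
empty result raises. All tolerances asserted in tests are stated inline
with their reasons; seeds are explicit everywhere, and the acceptance
script derives all sub-seeds (kept below 2³¹) from its single `--seed`.
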