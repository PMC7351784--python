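# Methods

This note documents the models behind `gaitsynth`: what the synthetic
gait generator emulates and what it does not, the numerical choices in
signal synthesis and peak detection, and the design decisions taken
where more than one reasonable option existed.

## Synthetic gait generator

### What it stands in for

The package's scientific object is the *mapping* from sensor position
and algorithm choice to gait-marker estimation error.  Driving that
mapping requires articulated-body motion.  Instead of motion capture
plus musculoskeletal simulation, `gaitsynth` generates motion from a
rigid 12-segment kinematic chain (pelvis root; thorax; upper/lower arms;
upper/lower legs; feet) driven by parametric joint waveforms.  This is a
deliberate trade: the generator is seed-reproducible, runs in
milliseconds, and exercises every downstream stage (synthesis, peak
detection, matching, scoring) with known ground truth — but it is not a
biomechanically validated human model.

### Stride timing

Gait is driven by a global stride phase, piecewise linear in time:
stride *k* of duration *T_k* occupies phase `[k, k+1)`.  Durations are
drawn i.i.d. from a normal distribution truncated below at 0.25 x mean
(the studies being emulated report only mean ± SD, so a truncated
normal is the minimal model).  Inside the motion builder each drawn
duration is snapped to the nearest sampling-grid multiple (10 ms at
100 Hz): stride boundaries then fall exactly on samples, noiseless
motion is exactly periodic, and the treadmill-frame property (zero net
pelvis displacement over whole strides) holds to machine precision.
`sample_stride_durations` itself returns unsnapped values.

Scenario presets carry the emulated study conditions: treadmill running
at 2/3/4/5 m/s with per-speed stride duration mean/SD of 814.6/96.4,
794.0/93.4, 772.3/94.4 and 743.7/101.3 ms; hemiparetic treadmill
walking before an intervention (0.3 m/s, 1447.4/397.7 ms, affected-side
irregularity 0.3 vs 0.05) and after (0.5 m/s, 1243.6/376.9 ms,
irregularity 0.15 vs 0.05).

### Joint waveforms

Joint angles are truncated Fourier series of the fractional stride
phase *u* (left limbs offset by half a stride):

- hip flexion: `A_hip (cos 2πu + 0.06 cos(4πu + 1.2))`, with
  `A_hip = 6 deg x speed [m/s]` — the documented linear speed-to-
  amplitude mapping (doubling speed doubles the hip fore–aft
  amplitude);
- knee flexion: `A_knee (0.5 − 0.5 cos 2π(u − 0.25))²` (a two-harmonic
  form), extended through stance and maximal mid-swing, so the
  calcaneus has a single vertical minimum per stride (ground contact at
  u ≈ 0.25);
- ankle, shoulder, elbow: small two-harmonic series (defaults 8, 12,
  18 deg, config-overridable);
- pelvis: vertical oscillation at twice the stride frequency (3 mm
  amplitude) and zero-mean fore–aft sway (8 mm per m/s), both periodic
  in the phase so the treadmill frame is exact.

Defaults were chosen so the calcaneus vertical excursion falls in the
plausible 5–15 cm range across scenarios; all amplitudes are exposed
through `GaitParameters.amplitudes_deg`.

### Ground-contact impact transient

Real accelerometer data contain a heel-strike shock; a smooth Fourier
chain does not.  Each leg therefore carries a raised-cosine pulse in
its hip (7.4 deg) and knee (3.4 deg) angles, centred at the contact
phase (u = 0.28), 0.14 strides wide.  Near contact the leg is nearly
vertical, so the pulse moves a thigh sensor *vertically* in proportion
to its fore–aft (ventral/dorsal) offset from the bone axis and barely
at all for lateral offsets.  This single modelling element produces the
spatial structure of the error maps: ventral/dorsal positions see one
strong acceleration transient per stride and segment cleanly; lateral
positions see mostly the twice-per-stride smooth components and
mis-segment.  At high running speeds the smooth harmonic content grows
quadratically with the hip amplitude while the pulse does not, so
estimation errors increase with speed — the qualitative behaviour the
methodology is designed to expose.

### Per-stride amplitude normalisation

Waveform amplitudes are scaled per stride by `(T_k / mean T)^1.5`
(clipped to [0.5, 2.0], smoothstep-blended across stride boundaries so
the angle series stays C¹).  Without this, acceleration amplitude would
scale as `1/T_k²` and — at the high duration variability of hemiparetic
gait (CoV ≈ 27 %) — the loudest stride would dominate every
range-relative detection threshold.  The normalisation encodes the
observation that short strides in slow pathological gait are *smaller*
movements, not proportionally faster ones.

### Hemiparetic irregularity

A per-side irregularity factor `f ≥ 0` adds two seeded per-stride
effects to the affected leg, with draws independent of `f` (common
random numbers, so effects scale monotonically in `f`):

1. *shape modulation*: smooth waveforms are multiplied by
   `1 + f r_k sin²(πu)` with `r_k ~ N(0,1)` per stride (the envelope
   vanishes at boundaries, preserving continuity);
2. *contact-timing jitter*: the impact-pulse centre shifts by
   `0.35 f q_k` stride fractions (`q_k ~ N(0,1)` clipped to ±2),
   modelling incoordination between the limb trajectory and the
   foot-strike shock.

The calcaneus reference tracks the smooth limb geometry while sensor
events track the shock, so jitter degrades sensor-vs-reference
agreement on the affected side — the mechanism by which simulated
hemiparesis raises affected-side nRMSE and shrinks the region of
sensors with nRMSE ≤ 10 %, and by which lowering `f` ("post"
intervention) enlarges it again.

### What the generator does not model

No muscle dynamics, ground-reaction forces, inverse kinematics, or
anthropometric scaling; no overground progression (treadmill frame
only); no soft-tissue wobble in the kinematics themselves (that is
modelled downstream as additive signal noise); the two legs share one
stride clock (phase-offset by 0.5) rather than having independent step
timing.  Passing tests therefore demonstrate that the *pipeline*
behaves correctly and that its comparative conclusions (algorithm
ordering, side asymmetry, position structure) hold on a controlled
motion model — not that absolute error levels transfer to any real
cohort.

## Sensor layouts

Ring sensors sit at 16 angular positions per ring (22.5° steps, S1 on
the ventral midline, increasing toward the lateral side; left-side
offsets mirror right-side ones in z).  Rings span a fixed 15–85 % of
the bone length, so the dense 12-ring upper-leg grid covers the same
extent as the 6-ring full-body grid at twice the density.  Radial
offsets are per-segment constants (3.5–6 cm).  The foot convention —
two 36-sensor perimeter rows around an elliptical shoe outline plus a
5 x 5 instep grid — is a documented geometric convention on a rigid
shoe surface; only the counts (72 + 25) are externally fixed.  The
upper-arm (64) and lower-leg (96) per-side counts follow uniquely from
the full-body total of 834 together with the printed per-segment counts
and 16 sensors per ring.

## Signal synthesis

Acceleration is the second-order central difference
`a[i] = (p[i−1] − 2p[i] + p[i+1]) fs²` with endpoints replicated from
the nearest interior value (a cubic-spline derivative is available
behind the same interface).  No gravity term is added: the synthesised
signal is a pure kinematic derivative, which is worth stating because a
physical accelerometer would additionally measure the gravity
projection.  The soft-tissue noise model is
`N = A sin(2πft + φ)` with defaults A = 10 % of the signal's maximal
absolute value, f = 2 Hz, φ = 180°.  A sinusoidal carrier is the
natural reading of a "continuous noise at frequency f" specification;
whether the original formulation intended sin, cos or another carrier
is unknowable from its printed form, and only the sine variant is
implemented.

## Peak detection and marker extraction

The detector keeps local maxima whose topographic prominence exceeds a
threshold — by default one quarter of the signal range — then applies a
greedy minimum-distance filter in descending peak height (ties broken
by earlier time).  The default minimum distance is 0.25 x the expected
stride period (supplied, or estimated from the dominant non-DC spectral
peak).  Both knobs are in `PeakDetectorConfig`.  The pipeline departs
from the defaults in two documented places:

- *reference detection* (calcaneus minima, via the negated series) uses
  prominence fraction 1/8 and minimum distance 0.5 x the expected
  period: the position signal is clean, the lower threshold keeps edge
  minima whose prominence is clipped by the start of the recording, and
  the stride-scale distance discards the shallow secondary dip the
  rigid leg geometry produces late in swing;
- *sensor detection* inside `score_layout` widens the minimum distance
  to 0.6 x the reference stride period, since exactly one marker event
  per stride is expected.

`smpl` runs the detector on the raw acceleration; `cmplx` first applies
a Savitzky–Golay filter (polynomial order 5, window 25 samples,
mirror-padded boundaries).  Maxima polarity is the implemented
convention (the ventral heel-strike transient is negative-going, so its
smoothed trough's taller shoulder serves as the per-stride event
there).  Stride markers: count = number of inter-event intervals, mean
duration in ms, cadence = 60000 / mean duration.

## Matching and scoring

Sensor and reference events are paired greedily by increasing time
difference within a window of half the median reference stride period,
each event used at most once; per-stride durations are recomputed
between consecutively matched reference events.  nRMSE divides the RMS
of paired duration differences by the mean reference duration — the
natural multi-stride extension of a scalar relative-error formula.
Population maps average per-subject nRMSE cell-wise (`agg="median"` is
available); affected/less-affected regrouping mirrors left-side
circumferential indices about the ventral midline so anatomical
directions align.  Error levels use the conventions [0, 1) %, [1, 5] %,
(5, ∞) %, and ≤ 10 % inclusive.  Best/worst sensors are the argmin /
argmax with (segment, ring, Sx, side) lexicographic tie-breaking.

The Wilcoxon rank-sum test enumerates all rank assignments exactly when
both groups have ≤ 8 observations and otherwise uses the normal
approximation with tie correction; significance is judged at α = 1 %.
Spearman correlation is the Pearson correlation of mid-ranks (delegated
to scipy, with a brute-force oracle in the tests).

## Problem sizes and determinism

The test suite and the acceptance script run desk-scale problems: 6–10
strides per trial, 8 synthetic subjects for the asymmetry analysis, 20
seeds for the spike-robustness family, the 384-sensor upper-leg grid
for per-sensor scoring.  These sizes give stable medians and
vanishingly small rank-sum p-values while keeping a full run in the
seconds range.  Every random draw flows from a single integer seed
through `numpy` `SeedSequence` spawning; identical configurations
produce byte-identical outputs.

## Known limitations

- The smpl algorithm frequently yields no matchable events on slow
  hemiparetic signals (weak transients under a range-relative
  threshold); such sensors are flagged missing rather than scored,
  which understates smpl's error relative to a forced score.
- Stride-count comparisons at recording edges can differ by one event
  (a contact falling exactly at the first or last sample).
- The contact-phase constant (u = 0.28) couples the generator and the
  reference detector: moving it without revisiting the reference
  configuration can re-introduce edge losses.
- Absolute nRMSE levels depend on generator constants (pulse amplitude,
  pelvis oscillation); only orderings and spatial structure should be
  interpreted.
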