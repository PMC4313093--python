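# Methods

## The model

`quadgait` simulates a planar (sagittal-plane) quadruped of 7.0 kg: a rigid
torso of 4.0 kg with a hip at each end carrying two legs (fore and hind legs
overlap in the plane but contact the ground independently), each leg a
rotary hip plus a prismatic "knee" with lumped segment masses (upper 0.5 kg,
lower 0.2 kg, foot 0.05 kg per leg).  A stance leg held at its natural
length by a stiff PD controller behaves as a spring-loaded inverted pendulum
(SLIP) limb; a swing leg is retracted and swung forward to a target angle.
The generalized coordinates are torso (x, z, pitch) plus a hip angle and a
leg length per leg (11 DOF).  Pitch is positive nose-down throughout the
package.

Each leg is driven by one Matsuoka half-center oscillator (extensor and
flexor rate units with mutual inhibition `gamma`, self-adaptation `b`, tonic
drive `s0`).  Corresponding units of contralateral legs inhibit each other
with weight `alpha` and of ipsilateral legs with weight `beta`; diagonal
legs are not connected.  Every inhibitory link favours anti-phase firing, so
the only consistent phase assignment is the trot (diagonal legs in phase,
neighbours anti-phase); this is the network's hard-wired gait and is
verified as an attractor in the test suite.

A leg swings while its flexor output is positive (`y_f > 0`) and stands
otherwise.  Two afferent signals close the loop:

* **hip-angle feedback** (`k1`, antisymmetric to extensor/flexor about the
  mid-stroke angle) keeps the oscillators entrained to the mechanical
  stepping; the tests show 1:1 locking of a driven oscillator within a
  ±10% detuning band;
* **leg-loading feedback** (`-k2 * Leg_load` to the flexor only, optionally
  saturated at `feed2_cap`) delays the stance-to-swing transition of a
  loaded leg.  `k2 = 0` is the baseline model.

## The tilt-combination rule (`gait_rule`)

During trotting the two legs of a diagonal pair are loaded together.  If
the torso is tilted while a pair stands, the pair's legs carry unequal
loads; the loading feedback then delays the more-loaded leg's swing.  With
three tilt states per pair (down / level / up) and two pairs whose origins
stay anti-phase, exactly nine gaits exist.  The module constructs each
cell's swing order mechanistically: a tilted pair splits its two legs by
±0.125 cycles about the pair origin (hindleg delayed when tilted up,
foreleg delayed when tilted down); a level pair stays in phase.  This
ordinal construction reproduces all documented footfall orders (e.g.
L-walk RF-LH-LF-RH, R-canter (LF,RH)-RF-LH, RT-gallop LF-RF-LH-RH).  The
rule is ordinal only; no quantitative phase lags are claimed.  The two
"unusual canters" (split pair tilted down instead of up) are named
`UNUSUAL_CANTER_R/L` by analogy with the lead of the natural canter whose
level pair they share; their footfall orders are derived from the same
mechanism, as they are not documented anywhere.

## Gait analysis

Footfalls are digitized from the per-leg load signals with a hysteresis
threshold (on at 2% of body weight, off at half that) and a 10 ms
debounce.  Stride metrics use the LF stance onsets as the reference: the
period is the mean inter-onset interval, per-leg phases are circular means
of onset offsets, and the two signed diagonal-pair differences
`delta1 = phi(RF) - phi(LH)`, `delta2 = phi(LF) - phi(RH)` (wrapped to
(-0.5, 0.5]) drive the classifier: |delta| <= 0.07 cycles counts as
in-phase, a larger split (up to 0.38) selects the tilt sign, and the pair
origins must remain anti-phase within 0.18 cycles; anything else is
UNKNOWN.  Pace-like or bound-like patterns therefore return UNKNOWN by
construction.  The body/stride frequency ratio counts pitch oscillation
cycles by alternating ±0.25-standard-deviation threshold crossings of the
mean-removed, lightly smoothed pitch over an integer number of strides; a
pitch standard deviation under 1 mrad is reported as ratio 0 with a
low-amplitude flag.  Tilt states average the pitch over the latter half of
each pair's overlapping-stance windows with a 0.5 degree deadband.

`generate_ideal_trace` is the package's synthetic-data generator.  It
emulates idealized steady gaits: square-pulse loads at the rule table's
canonical phases (optionally Gaussian-jittered), and a pitch signal built
from raised-cosine bumps centred in the latter half of each pair's
overlapping stance with the sign of that pair's tilt state.  This
reproduces each gait's tilt signature and its body/stride frequency ratio
(2 per stride for walks, 1 for canters and gallops, ~0 for the trot).  It
does not emulate ground-reaction force profiles, impact transients,
measurement noise spectra, or speed-dependent duty factors, so classifier
tests on these fixtures demonstrate correctness of the phase logic, not
robustness to real sensor data.

## Numerics

Mechanics are integrated with fixed-step RK4 at dt = 1 ms, with contact
forces re-evaluated at every stage and the commanded joint efforts held
constant over a step (zero-order hold at the 1 kHz control rate).  Ground
contact is a penalty normal spring-damper (30 kN/m, 300 N s/m, clamped
non-negative) with viscous tangential friction capped by a Coulomb cone
(mu = 1.2); the prismatic travel is limited by stiff one-sided stops.  A
passive-bounce test with all damping removed conserves mechanical energy
to better than 0.5%, and halving dt leaves settling trajectories unchanged
to experimental precision.  The CPG is integrated with RK4 at the same
step (guard: dt <= tau_u/10).  Runs abort with a diagnostic if the torso
falls below half its standing height or any state becomes non-finite.

## Speed parameters

A scalar speed command v maps to the per-leg "speed parameters", never to
the coupling weights or feedback gains:

* hip sweep half-amplitude: 0.135 + 0.07 v rad;
* oscillator time-constant scale: 1.15 - 0.154 v (clamped to [0.45, 1.6]);
* stance-target sweep rate: (1.1 + 0.35 v) v / l, capped at 8 rad/s --
  below the cap the stance hip target is rate-limited so the stance leg
  sweeps at the speed-matched rate, above it the target is applied
  directly (the fast running regime);
* extensor/flexor drive asymmetry: 0.25 - 0.10 v (clamped to [0, 0.5]),
  which lengthens stance at low speed so that the swing duration is
  roughly speed-invariant, as in animals;
* optionally a push-off preload of the stance-length target
  (`push_gain * v`, 0 in the baseline).

These maps are this package's stand-in for the original model's
unpublished speed-parameter tables; they were tuned once so that the
baseline trots stably across commands of 0.25-2.5 m/s, and are stored in
the configuration.

## Study conditions and what they show

**Baseline (`baseline_config`, k2 = 0).**  At every tested speed command
(0.25-2.5 m/s) the model trots steadily: diagonal phase differences stay
within the in-phase tolerance, achieved speed rises monotonically with the
command, and flight phases appear at the faster commands.  The body-pitch
oscillation runs at 2 cycles per stride at low speed (long support, the
torso see-saws once per half-stride) and locks to 1 cycle per stride in
the fast flight-bearing regime, where the two half-strides spontaneously
differentiate (the measured tilt states differ between the diagonal
pairs) while the footfalls remain a trot.  These are the two quantities
the acceptance script recomputes.

**Gait generation (`gait_generation_config`, k2 = 0.06 with the feed
saturated at 2.0 and a 0.012 m/(m/s) push-off).**  With the loading
feedback on, non-trot gaits emerge from the unchanged network: at walking
commands the long-support trot develops same-sign splits of both diagonal
pairs and settles into a lateral-sequence walk, at somewhat faster
commands a diagonal-sequence walk; both walks are strictly no-flight and
occur at low achieved speeds, while the same speeds under k2 = 0 remain
trots.  This realizes the central claim — walks are generated, not
programmed, by posture-mediated loading feedback.

**Known limitation.**  The natural canters and transverse gallops are not
reproduced as steady k2 > 0 gaits at this desk scale.  In this
implementation the high-speed 1:1 pitch mode that should seed them is a
relatively low-amplitude resonance, and loading feedback strong enough to
split the pairs also stabilizes the posture and suppresses that mode (it
acts as negative feedback on the tilt before the canter-type split can
establish).  Canter- and gallop-topology splits do appear in neighbouring
parameter regions (e.g. unusual canters at k2 ~ 0.06-0.07 without the
feed cap, and both transverse-gallop orders with a tighter cap), and the
±0.14 m/s^2 ramps under the gait-generation condition pass transiently
through canter- and gallop-classified windows, but without the monotone
walk-trot-canter-gallop speed ordering of the original observations; the
seven-gait-class and ramp-transition acceptance checks are therefore
expected to fail and are left failing rather than weakened.  Likely missing physics:
a softer, more compliant high-speed stride (longer ballistic flight and
degree-scale pitch excursions) that would make the tilt signal robust to
the feedback's stabilizing action.

## Desk-scale problem sizes

Acceptance runs use 16 s of simulated time per constant-speed condition
(roughly 20-60 strides after a 3 s / 5-stride transient discard), six
speed commands for the baseline, six commands x 2 replicate seeds for the
emergence sweep, and single ±0.14 m/s^2 ramps; classifier round-trip
checks use ~100 jittered fixtures per gait.  All randomness (CPG
initial-state jitter, fixture jitter) flows from explicit integer seeds;
replicate seeds select between bistable outcomes where they exist.
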