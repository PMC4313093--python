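# quadgait

A planar neuromechanical quadruped simulator for studying how unprogrammed
gaits emerge from a trot-wired central pattern generator (CPG) network
through leg-loading feedback, together with the analytic tilt-combination
rule that organizes the emergent gaits and the footfall-analysis machinery
to detect them.

**Who it is for:** computational neuroscientists and legged-locomotion
researchers who want a small, fully scripted sagittal-plane model in which
interlimb coordination is *not* reprogrammed per gait — the network wiring
is fixed, and gait diversity must come from the body dynamics and sensory
feedback.

## The model in brief

A 7.0 kg rigid torso carries four spring-loaded inverted-pendulum (SLIP)
legs (rotary hip + prismatic knee; 8 joints).  Each leg has a Matsuoka
half-center oscillator

    tau_u du/dt = -u - b v - sum_j W y_j + s0 + feed,
    tau_v dv/dt = -v + y,          y = max(0, u),

with mutual inhibition `alpha` between contralateral legs, `beta` between
ipsilateral legs, `gamma` within a leg, and no diagonal connections — a
wiring whose only consistent phase pattern is the **trot**.  A leg swings
while its flexor output is positive.  Two afferent feedbacks close the
loop: the hip angle (gain `k1`, entrains the rhythm to the stepping) and
the leg load (`feed2 = -k2 * Leg_load` into the flexor half-center, which
prolongs stance while the leg is loaded; `k2 = 0` is the baseline).

The **tilt-combination rule** (`quadgait.gait_rule`): each diagonal pair's
torso tilt during its stance (tilted down / level / tilted up) determines
whether and in which direction the pair's two legs split their phases, so
3 x 3 = 9 gaits exist — lateral/diagonal-sequence walks, trot, right/left
canters, right/left transverse gallops, and two "unusual" canters.

## Worked example

The rule table, from the command line:

    $ quadgait rule-table
    pair1 (RF+LH)  pair2 (LF+RH)  swing order            gait
    ---------------------------------------------------------
    tilted_down    tilted_down    LF-LH-RF-RH            D-walk
    tilted_down    level          (LF,RH)-LH-RF          unusual-canter-R
    tilted_down    tilted_up      LF-RH-LH-RF            LT-gallop
    level          tilted_down    LF-(LH,RF)-RH          unusual-canter-L
    level          level          (LF,RH)-(LH,RF)        trot
    level          tilted_up      LF-RH-(LH,RF)          L-canter
    tilted_up      tilted_down    LF-RF-LH-RH            RT-gallop
    tilted_up      level          (LF,RH)-RF-LH          R-canter
    tilted_up      tilted_up      LF-RH-RF-LH            L-walk

Each row reads: if the 1st diagonal pair (RF+LH) stands under the first
tilt and the 2nd pair (LF+RH) under the second, the legs enter swing in
the listed (cyclic) order and the gait is the label on the right — e.g.
both pairs tilted up gives the lateral-sequence walk LF-RH-RF-LH.

Simulating and classifying from Python:

```python
from quadgait.presets import baseline_config, gait_generation_config
from quadgait.experiments import SpeedSchedule, run_constant_speed

cfg = gait_generation_config(duration=16.0,
                             schedule=SpeedSchedule.constant(0.7))
result = run_constant_speed(cfg)
print(result.gait.value)        # -> L-walk   (emergent; k2 = 0 gives trot)
```

The same command with `baseline_config` (no loading feedback) prints
`trot`: the walk exists only because of the leg-loading feedback.

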