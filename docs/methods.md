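# Methods

## The model organism

The Oropod is a one-dimensional musculoskeletal system: a body that can slide
along the x-axis between two walls, and two limbs, each moved by an
antagonistic extensor/flexor pair. Muscles are unidirectional
force generators — springs with zero rest length whose stiffness is scaled by
neural activation `A ∈ [0, 1]` — so force is `gain · A · stretch`, pulling
only. Limb dynamics are viscosity-dominated and first order:
`B ẋ = F − ẋ D`, solved per step as `v = F/(B + D)` and integrated with a
10-ms step (semi-implicit in the damping term). Positions are clamped to the
anatomical range ±4 units.

### Geometry and calibration

Only the ratio `muscle_gain/(B + D)` is observable in first-order dynamics,
so `B = 1` and speed lives in `muscle_gain`. Anchors sit 1 unit beyond the
±4 range (stretch spans 1–9 units); with `muscle_gain = 3.3` and `D = 2.0`
a fully activated muscle traverses the whole range in `3·ln(9)/3.3 ≈ 2.0 s`,
the published speed calibration. Walls are placed so that wall contact
occupies only the outermost 0.05 units of limb travel (walls at ±7.45 with a
tip offset of 3.5); a wider contact zone would let the contact penalty block
the 2-s traversal. Limb–limb contact occurs over the innermost 0.5 units of
each limb's travel. Both contacts use a linear penalty (`contact_stiffness =
10` force/unit). The wall reaction transmitted to the body is the surplus of
the pressing limb's extensor pull over its flexor pull, clamped positive;
the body moves only when the net wall force exceeds a stiction threshold of
3.0 — reachable by sustained near-maximal extensor drive but roughly 3×
above anything the training twitches produce, so the body never moves during
development.

## Sensors

Per muscle, with normalized length `L ∈ [0, 1]` (linear in limb position,
antagonists complementary), lengthening velocity `V = L̇`, and fusimotor
drive `A` (the β-motoneuron output):

* group II (static): `II = ((L − 0.2)·1.25 + A)/2`
* group Ia (dynamic): `Ia = (1.5 + log10(A + 0.1))·V + (A + 0.2·II)/2` —
  the velocity gain grows with fusimotor drive
* Golgi tendon organ: `Ib = L·A` (active force proxy)

Each limb's cutaneous receptor filters the net contact force `F` through the
shared Kalman filter with gain 0.054; the drive is `F·0.5·s` where the onset
scalar `s` starts at 3.0 on contact and decays per step as
`s ← 1 + (s − 1)·0.985`. The response is phasic–tonic: 1.5 F at onset,
plateau at exactly 0.5 F, reset on release. Sensor outputs are signed (Ia
can go negative during rapid shortening); the positive-part operation is
applied where signals enter synapses, not in the sensor.

## Network

36 neurons: 4 β-motoneurons (βMN), 16 excitatory (INe) and 16 inhibitory
(INi) interneurons. Each βMN receives its own muscle's Ia afferent at frozen
weight 1.0 (the heteronymous Ia weights are frozen at a configurable
residual, default 0), all 32 interneurons, and one fixed weight-1.0 synapse
from the activity pattern generator — 37 synapses. Each interneuron receives
all 14 primary afferents and the 31 other interneurons (no self-synapses) —
45 synapses. Interneurons never receive motoneuron output (no recurrent
collaterals). Learnable weights are seeded from a normal distribution
(mean 0.2, SD 0.16) redrawn below 0.001; note the truncation makes the
realized mean ≈ 0.233 and SD ≈ 0.134.

Activation uses synaptic shunting with independent Kalman filters
(gain 0.3) on the signed and unsigned summed drives, divided by the unsigned
filter plus a resting leak. The leak is 2× a slow rolling measure of the
unsigned summed drive (Kalman gain 4·10⁻⁵, time constant ≈ 250 s), floored
at 0.5; during the first 30,000 s it tracks freely, afterwards it may only
grow — neurons that become strongly driven stay appropriately leaky. `|P| ≤ 1`
holds structurally because the filtered signed sum can never exceed the
filtered unsigned sum. All neurons update synchronously from the previous
step's outputs, which makes the update order-independent and deterministic.

## Plasticity

Each learnable synapse carries a slow Kalman-filtered (gain 0.001) learning
signal `l = φ_K(pre⁺ · w · (φ_L(P_post) − P̄_post))`, clamped to [−1, 1].
For excitatory sources `φ_L` is a slight first-order high-pass (0.05 Hz,
mimicking the fast supralinear calcium transient); for inhibitory sources a
low-pass (0.2 Hz). Cutoffs convert to per-step coefficients as
`α = 1 − exp(−2π f dt)`. The weight update `Δw = l·η·c` uses the
compensation factor `c = 1 − w` (potentiation) or `w` (depression), which
confines weights to [0, 1] with no clipping, and a learning rate linear in
the neuron's slow mean activity, `η = min(P̄·0.04, 0.001)` — a silent neuron
cannot learn, an active one learns at the published maximum of 0.001.

The learning-rate expression admits two typographic readings (quartic
`P̄⁴·0.01` versus linear `P̄·4·0.01`). The quartic reading was rejected
empirically: at the mean activities this network actually reaches
(P̄ ≈ 0.07–0.13) it yields η ≈ 10⁻⁷–10⁻⁶, under which synaptic weights
cannot evolve measurably within the published developmental timescale of a
few simulated days, and the published learning-rate range 0–0.001 would
never be visited above ~3·10⁻⁶. The linear reading reproduces both.

Within a step the order is: physics → muscle kinematics → pattern-generator
drive → sensors → synchronous neuron update (leak before division) →
plasticity (`φ_L` filters advance on the new potentials; the learning drive
uses the pre-update mean activity; weights update; the mean activity
advances last). The φ_L and per-synapse filters are independent state, and
the two Kalman filters inside the activation are independent of each other.

## Activity pattern generators

**Twitch APG (training).** Each muscle runs an independent renewal process:
epochs of uniformly sampled duration (50–500 ms); with probability 0.5 the
epoch carries a twitch (uniform amplitude 0–1, uniform Kalman rise gain
0.5–0.8), otherwise rest. Each twitch is a square pulse through its own
Kalman filter, so decay tails overlap; per-muscle drive saturates at 1. The
per-muscle renewal streams use independent child generators spawned from the
master seed, so schedules are reproducible bit-exactly and insensitive to
chunking. At probability 0.5 all 16 on/off muscle combinations are equally
frequent (verified by a χ² test).

**Phasic APG (testing).** Three deterministic programs — in-phase
(homologous muscles share envelopes), symmetrical (limbs mirror each other)
and right-wave (right limb only) — built from raised-sine half-cycle pulses
(`sin²`) with a 4-s cycle: one initiation cycle plus three core cycles, 16 s
total. The exact waveform is configurable; analyses depend on the
alternating structure, not the precise shape. Tests run on a clone of the
training state with plasticity off; the initiation cycle is excluded from
analysis windows.

## Simulation engine

The full loop exists twice, deliberately: a readable per-step path composed
from the module functions, and a fused numba kernel used for long runs
(~3·10⁵ steps/s on one core). The test suite pins the two paths against
each other at 10⁻¹² over 1000 steps and the kernel against an independent
scalar straight-line oracle. Checkpoints (HDF5) store every state array
bit-exactly plus the configuration and generator states; a reloaded
simulation continues bit-identically. Training checkpoints every 500 s;
the published full duration is 400,000 s.

## Analyses

* **Archetype classification.** Twelve binary templates (3 classes × 4
  muscles) over the 18-value vector of 14 afferent input weights plus 4
  motoneuron output weights: Ib inhibitory (Ib in, homonymous βMN out), Ia
  reciprocal inhibitory (Ia in, same-limb antagonist βMN out), propriospinal
  excitatory (Ia+Ib in, homonymous βMN out). Inhibitory templates pair with
  INi, excitatory with INe. A neuron is labeled with a class iff its L2
  distance to at least one of that class's templates falls below the class's
  pooled population mean minus one SD (pooled across the four muscle
  templates and all eligible neurons; per-template thresholds would be a
  one-line change). No weight-magnitude floor: weak but accurate
  connectivity classifies. Multiple labels per neuron are allowed and
  counted.
* **Connectivity PCA.** Standard centered, unscaled PCA per neuron group
  (βMN: the 32 interneuronal input weights; interneurons: 14 afferent + 32
  interneuronal inputs with the nonexistent self-synapse filled with 1.0 so
  all 16 live in one comparable space). Reported: explained-variance ratios,
  the smallest component count reaching 95% cumulative variance (ndim95,
  computed on the end state), and per-neuron seed-to-end Euclidean distances
  inside a PCA fitted on the pooled seed+end vectors, truncated at that
  pooled space's own ndim95.
* **Cooperativity.** One PCA fitted jointly on every timestep of every
  phasic-test trace across all timepoints and movements (initiation cycles
  excluded); per movement and timepoint the metric is the summed
  step-to-step Euclidean norm of the coefficients over the first ndim95
  components. It is invariant under rotation of the retained space and zero
  iff activity is constant.
* **Grouping and afferent profiles.** Interneurons are assigned to the βMN
  receiving their largest output weight (ties, including all-zero rows,
  break to the lowest index and are flagged weak) and ordered LE, LF, RE, RF
  within INe then INi; primary-afferent profiles are normalized to sum 1,
  with zero-total neurons flagged rather than divided.

## Problem sizes and what the tests show

The package's standard evaluation uses a scaled-down ensemble — ten
independently seeded sessions of 50,000 s each with test movements at nine
evenly spaced timepoints — which one core completes in a few minutes. At
this scale the weight trajectories stabilize after their initial growth, the
four motoneurons occupy a three-dimensional input space, and all three
archetype classes appear in most seeds. Two caveats are documented rather
than hidden. First, 50,000 s is mid-development: interneuron connectivity
diversity is still higher-dimensional than it is after full training, so
explained-variance figures differ from full-scale runs. Second, the
cooperativity distance traveled is *lower* at 50,000 s than in the untrained
network: the fresh network (leak at its floor, dense random weights) has
large-amplitude population activity, and the early, expected loss of
excitatory seed weights lowers the population gain before coordinated
activity re-emerges. Longer diagnostic runs show the metric recovering and
surpassing the untrained level between 100,000 and 200,000 s, so the
trained-exceeds-untrained comparison should only be expected of full-length
training; the corresponding scaled-ensemble test documents this by failing
at the scaled horizon.

The twitch generator emulates fetal motor babbling as stationary,
independent-per-muscle renewal noise. It does not emulate developmental
trends in twitch statistics, mechanical coupling through a moving body
(stiction prevents body motion at twitch forces), or any patterned descending
drive — so passing tests speak to self-organization under stationary
babbling only.

## Numerical choices and edge cases

Synchronous updates; all filters initialize at 0 (cutaneous onset scalar at
3.0); leak floor 0.5 guards every division; P clamped to [−1, 1] as a
belt-and-braces bound; the learning signal clamped to [−1, 1] (its published
range), which also makes the weight-bound argument exact since
`|l·η| ≤ 10⁻³`. Classification with a degenerate distance population
(SD ≤ 10⁻¹²) labels nothing. ndim95 uses a 10⁻¹² slack on the 0.95 cutoff
to be robust to rounding at full rank. Non-finite mechanical state aborts
the run with a diagnostic rather than propagating NaNs. Twitch decay tails
below 10⁻⁴ are extinguished and their filter slots reclaimed; four slots per
muscle suffice because a new twitch can only start after the previous epoch
ends.

## Known limitations

One-dimensional mechanics without force–velocity muscle properties or
multiarticular limbs; single β-motoneuron per muscle (no motor pools, no
pure fusimotor neurons); no motoneuron recurrent collaterals (hence no
Renshaw-type circuitry can form); nonspiking rate units; plasticity in
inhibitory synapses assumed Hebbian like the excitatory ones. The phasic
test waveforms are plausible reconstructions of alternating movement
programs, configurable but not fitted to any reference kinematics.
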