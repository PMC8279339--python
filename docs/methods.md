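# Methods

This note documents the models, conventions, and design choices behind
`gravgait`: what each stage assumes, which defaults matter, and what the
synthetic cohort does and does not emulate.

## Study design emulated by the generator

The default `GeneratorConfig` reproduces a within-subject design: 12
participants, four simulated gravity levels {1.0, 0.76, 0.55, 0.31} G,
four overground target speeds {0.4, 0.8, 1.2, 1.6} m/s, and 4 good trials
per condition (768 trials). Gravity levels are reported inconsistently in
the source literature for this paradigm (0.55 vs 0.45 G for the third
level); the set is configurable and the generator's condition table is
interpolated over gravity, so either convention works. A trial is one pass
over a 3-plate walkway: the right foot strikes plate 1, the left foot
plate 2, and the second right contact lands on plate 3 in half the trials
and beyond the plates in the other half, which exercises both event
routes. Timing-gate speed is drawn within ±2% of target, so default trials
satisfy the ±5% good-trial rule.

Participant anthropometry is drawn once per cohort (mass ~ N(70, 8²) kg,
leg length ~ N(0.88, 0.04²) m, clipped). Participant-level multiplicative
random intercepts (SD 10% of the condition mean) act on GRF magnitudes and
per-muscle EMG amplitudes, and a 3% per-trial multiplicative jitter
provides within-participant residual variance, so the mixed model's
variance components are real properties of the data. All randomness flows
from a single seed through `numpy` `SeedSequence` spawning; identical
seeds give byte-identical trial bundles.

## Ground-reaction waveforms

Stance-phase waveforms are built from raised-cosine segments blended with
continuous first derivatives, with segment boundaries snapped to the
1000 Hz grid: vertical force rises 0 → peak1 (at 25% of support), falls to
the trough (50%), rises to peak2 (75%), and returns to 0; AP force is a
braking trough (centred 22%) plus a propulsive bump (80%); ML force is a
single bump. This family was chosen because its extrema are *analytic*:
the global vertical maximum equals max(peak1, peak2)·bodyweight exactly,
giving peak-extraction tests an exact truth channel. Default peak values
per condition come from the published per-condition peak table
(bodyweights), bilinearly interpolated over (speed, gravity); the trough
is 0.75·peak1 and peak2 = 0.97·peak1, so peak1 is the printed global peak.

True event times are defined as the analytic 18 N crossings of the
noiseless vertical waveform (a raised-cosine onset has zero slope, so the
threshold crossing necessarily lags the support onset; the truth channel
refers to the crossing, which is what any force-based detector can see).
The waveform support is widened per condition so the 18 N-to-18 N stance
duration equals the configured value (0.62 × stride time) independent of
peak height. Without this, lower-gravity trials would have systematically
shorter detected stances — an artifact of waveform scale, not of the
walker — which would leak a spurious gravity effect into every
phase-windowed quantity, corrupting the generator's null structure (e.g.
soleus stance RMS). Real reduced-gravity walking does shorten stance; the
generator trades that fidelity for exact, interpretable nulls.

Stride time defaults to {1.65, 1.35, 1.15, 1.00} s at the four speeds
(interpolated in between), independent of gravity, matching the null
gravity effect on stride length.

## The synthetic walker

Markers come from a sagittal 7-segment walker (pelvis, thighs, shanks,
feet). Foot motion is prescribed directly: each heel follows a periodic
trajectory whose height has an exact local quadratic minimum (curvature
5 m/s², ±80 ms) centred on every true contact time, a mid-swing clearance
bump, and no AP motion during stance; foot pitch plantarflexes around
toe-off. Hip and knee angles follow from closed-form two-link inverse
kinematics of the hip and ankle positions, with the pelvis advancing at
exactly the target speed and its height set so the hip–ankle distance
never exceeds 98.5% of full leg extension. Forward kinematics of those
joint angles reproduces the foot poses identically, so three construction
identities hold exactly: heel-height minima coincide with contact times,
pelvis mean AP velocity equals the target speed, and stride length equals
speed × stride time. Marker clusters (4-marker plates on thighs and
shanks) and anatomical markers are rigid in their segment frames; the hip
joint centres are placed exactly where the Coda pelvis regression will
reconstruct them (offsets 0.36/0.19/0.30 of the inter-ASIS distance,
lateral/posterior/inferior). Gaussian noise (default SD 1 mm) is added to
dynamic markers; the neutral-standing reference is noiseless.

The walker is kinematically plausible (timing, continuity, rigidity,
reachability) but makes no attempt to match human joint-angle or
joint-moment curves; at fast speeds with long strides it walks with a
crouched, compass-gait geometry. Consequently the inverse-dynamics stage
is validated by analytic oracles (statics, pendulum, equivariance), not by
comparison with normative human kinetics, and the cohort-level moment
"directions" are simply those induced by GRF scaling.

## EMG model

Each muscle's envelope is a stride-periodic sum of cos² bursts (centre,
half-width, amplitude in phase units) over a 0.05 baseline; the carrier is
Gaussian noise band-passed to 20–450 Hz and normalized to unit RMS. Bursts
are tagged stance, swing, or gravity-invariant, and the per-phase gravity
multipliers encode the direction structure under study: stance activity of
the quadriceps (rectus femoris, both vastii) and medial gastrocnemius
scales as 0.35 + 0.65·g (decreasing with support); biceps femoris stance
and tibialis anterior swing activity as 1.5 − 0.5·g (increasing); soleus
and lateral gastrocnemius are unaffected. Burst supports are kept clear of
the stance/swing boundary and the stride wrap so that each phase's RMS
carries only its intended effect.

The truth channel logs the *envelope* RMS per phase. The pipeline estimate
(30 Hz high-pass, rectification, phase RMS) is consistent with it
asymptotically to within ~2%: the high-pass removes the 20–30 Hz share of
the carrier band (by design — the stage must do real work), and a stance
window under a ~100 ms burst holds only ~10² effective samples of
band-limited noise, so single-trial RMS scatters with SD ≈ 5–7%. Tests
assert the 3% agreement on long records and a loose 25% bound per trial.

## Support force

The harness force is (1 − g)·bodyweight plus friction-like coloured noise
(white noise low-passed at 1.5 Hz, zero-meaned) rescaled so its largest
excursion equals the configured fluctuation amplitude (default 4% of
bodyweight) exactly. Every admissible configuration therefore satisfies
the ±5%-of-bodyweight constancy bound deterministically; amplitudes ≥ 5%
are rejected as invalid.

## Event detection choices

The 18 N threshold uses linear interpolation between samples and a 20 ms
debounce on both supra- and sub-threshold runs (the cutoff itself is the
only prescribed constant; debounce guards against noise chatter near the
threshold). The unloaded-plate baseline is removed as the median of the
first 100 ms of the trial. The kinematic heel-strike estimator is the
vertical minimum of the 6 Hz-filtered heel-marker height with a minimum
event spacing of half the expected stride time and parabolic sub-frame
refinement; it is deliberately simple and auditable, and the delay-offset
rule cancels its systematic bias by construction. The ±5% gate-speed bound
is inclusive. The first plate contact must match a right-heel kinematic
event to within 20% of a stride, otherwise the trial is rejected as a
left-foot-only pass.

## Filtering conventions

All filters are Butterworth designs applied forward–backward
(second-order sections), so a "4th-order, 6 Hz" specification attenuates
to |H|² = 0.5 (−6 dB) at 6 Hz, not −3 dB; no cutoff pre-warping correction
is applied, matching common gait-lab software defaults (a user wanting
−3 dB at f_c can scale the cutoff accordingly). Edge handling is
reflective padding of length 3 × order. The moving mean is centred with
symmetric truncation at the edges, preserving series length. Stride
normalization is linear interpolation onto 1001 phase points; at these
sampling rates the difference from spline interpolation is below the
marker noise floor.

## Inverse dynamics

Inertial parameters (packaged CSV, overridable): Dempster mass fractions
(foot 0.0145, shank 0.0465, thigh 0.100 of body mass) with geometric CoM
fractions (0.50/0.433/0.433 from proximal) and transverse radii of
gyration (0.475/0.302/0.323 of segment length). Segment frames use X
lateral (right), Y anterior, Z distal→proximal; thigh and shank poses come
from least-squares (Kabsch) rigid-body fits of their clusters calibrated
to anatomical points in the standing pose; the foot frame comes from
heel/metatarsal markers with the ankle defined by the malleoli through the
shank cluster. Joint angles are the about-X component of the Cardan X-Y-Z
decomposition of the distal-relative-to-proximal rotation, zeroed at
standing, with per-joint signs making plantarflexion/extension positive;
samples with the second Cardan angle beyond 80° are flagged, not dropped.
Accelerations are central differences (one-sided at the endpoints) of
6 Hz-filtered positions; the analog wrench is decimated to the 100 Hz
kinematic grid after filtering, with the CoP gap-filled by nearest loaded
sample so force smeared past stance by the filter keeps an application
point. Segment weight always acts at full 1 G: the harness supports the
torso, not the swinging limbs. Only sagittal (about-X) moments are
reported.

Validation is oracle-based: a static stance must match the closed-form
lever-arm solution to 0.5 N m; a foot swinging about a fixed ankle must
match the analytic pendulum moment to 1%; zero input must give identically
zero moments; frames and angles must be equivariant/invariant under rigid
lab rotations.

## Feature windows

The two knee extension moment peaks are separated by windows in stride
percent: early-mid stance is 0–40%, the transition peak 40% to
toe-off + 10% (module constants). The windows are a design choice — the
source material names the peaks but not their boundaries — chosen to
capture each peak across all speeds. Hip flexion, ankle plantarflexion and
the power peaks are taken over stance. The three sagittal force-vector
points are the two local maxima of the 20 Hz-filtered vertical GRF within
stance and the minimum between them; a single-peaked stance (possible
under strong support) is flagged degenerate rather than forced into three
points. Stride length is the heel-marker AP displacement between the two
heel strikes divided by leg length. Ensemble averages are two-stage:
trials → participant-condition means → unweighted across-participant mean
and SD, so unbalanced trial counts do not bias condition means.

## Statistics

"Gravity and speed as repeated factors, participants random" is modelled
as a participant random intercept with independent residuals (compound
symmetry) — the minimal faithful covariance structure. The REML criterion
is profiled: for a fixed variance ratio θ = σ_b²/σ_ε², GLS estimates and
the residual variance have closed forms via per-participant Woodbury
identities, leaving a bounded one-dimensional optimization over log θ
(with an explicit θ = 0 boundary check). The gravity main effect is a GLS
Wald F with containment denominator degrees of freedom
(N − rank(X) − (n_participants − 1)); Satterthwaite/Kenward-Roger
corrections are out of scope because calibration is established by
simulation (type-I error 0.05 ± 0.02 over 1000 null cohorts, power ≥ 0.9
at 2-SD effects with 12 participants). With θ fixed at 0 and residual df
the test reduces exactly to one-way ANOVA, and variance components agree
with `statsmodels MixedLM` to ~4 decimals (cross-checked in tests; the
in-package fit is the implementation, the library the oracle).

Benjamini–Hochberg runs over the full 26-test gravity family by default
(the inventory is presented as a single family with one adjustment);
missing variables shrink the family with a warning. Speed enters as
categorical (four discrete targets); a continuous-speed option and
gravity × speed interaction terms are available through `LmmSpec` but only
the gravity main effect enters the BH family. The EMG responses are
normalized per participant/muscle/phase by the maximum across conditions
before modelling, which removes participant amplitude scale (and hence
most of the random-intercept variance) from those variables — the model
tolerates θ → 0.

## What passing tests do and do not show

Synthetic cohorts have exactly periodic gait, stationary noise, no missing
markers or channels, no soft-tissue artifact, no crosstalk, and gravity
effects that are multiplicative and monotone. Passing the suite shows the
*pipeline* is correct (events, filters, dynamics, statistics recover known
truth at the stated tolerances), not that the biological conclusions would
replicate: on real data, event detection faces plate noise and partial
strikes, EMG normalization faces outlier maxima, and the mixed model faces
genuinely unbalanced designs (which the implementation accepts but the
default generator does not produce).

## Problem sizes

Default test and acceptance runs use desk-scale problems chosen to keep
the full suite fast while leaving the statistics well-posed: 100 trials
for the event-validation bound, the full 768-trial default cohort for the
support bound, an 8-participant × 4-gravity × 2-speed × 2-trial cohort for
the end-to-end direction-structure recovery, 1000 null simulations at
feature level for type-I error, and 10⁴ random vectors for the BH
cross-check.
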