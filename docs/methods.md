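# Methods

`fishposture` quantifies larval zebrafish free swimming from body shape
alone and closes the loop with a generative motor model.  This note
documents the models and procedures the package implements, the defaults
it ships with and why, and what its synthetic data can and cannot stand
in for.

## Postural decomposition

A swim bout is recorded as an m × 10 matrix of head-referenced tangent
angles Δθ(s_j, t_i): the direction of the body midline at ten equally
spaced arc positions s_0 = 0 (head) … s_9 = 1 (tail), relative to the
head tangent, at 500 frames/s.  Because the head column is identically
zero, the decomposition acts on the nine non-head columns:

    Δθ(s_j, t_i) = Σ_k U_k(t_i) · S_kk · V_k(s_j)

by singular value decomposition.  The V_k ("eigenshapes") are orthonormal
functions of arc length; S_kk is normalized so that the weights sum to
one and each weight is the fractional contribution of its mode; U_k(t)
carries the remaining scale, so the identity above is exact when all
modes are kept.  Sign indeterminacy is resolved by flipping each V_k so
its largest-magnitude element is positive, which makes the output
independent of the linear-algebra backend.  A "collective" basis pools
all bouts (concatenated along time); per-bout bases are available through
the same call.  No demeaning is applied: the straight posture Δθ = 0 must
map to U = 0, since rest is a fixed point of the behavior.

On the default synthetic ensemble the first three modes carry ~97% of the
summed singular values and a three-mode reconstruction leaves ~2% relative
Frobenius residual; V_1 is a single-bend (C) shape, V_2 and V_3 an
S-shaped quadrature pair — the structure expected for undulatory swimmers.

## Cycle segmentation and normalization

Bouts decompose into oscillation cycles of the leading amplitude U_1:
cycle 1 runs from the first to the third zero crossing of U_1, cycle 2
from the third to the fifth, and so on.  Robustness choices: U_1 is
smoothed with a 4 ms moving average (forced to an odd sample count so
crossings are not phase-shifted); crossings earlier than the first time
|U_1| reaches 2% of its bout maximum are discarded (no cycle can begin
before the trajectory moves); and a crossing counts only if an adjacent
lobe reaches 10% of the peak (suppressing numerical-noise crossings in
the pre- and post-bout tails).  Rest onset is the first time after the
last cycle at which every |U_k| stays below 10% of its bout maximum for
20 ms.

Each cycle is resampled by linear interpolation onto a fixed grid of
T = 50 points spanning the cycle; durations are recorded raw and relative
to the bout's cycle-1 duration.  A bout with no detectable cycles
contributes a single all-zero "rest" segment so resting behavior remains
represented downstream.  Handedness is removed by a deterministic sign
rule: if the signed area of U_1 over cycle 1 is negative, the flip set of
modes is negated (cycle 1 decides for the whole bout).  The flip set is
derived from the basis itself by rendering each eigenshape, reflecting it
about the head tangent, and re-projecting; for tangent-angle eigenshapes
the reflection negates every angle, so the procedure returns all modes —
a bout and its exact mirror image therefore map to identical normalized
segments.

## Behavioral space

The dissimilarity between two normalized cycles α, β is the
singular-value-weighted trajectory distance

    d²_αβ = Σ_i Σ_k S²_kk · [U_k^α(t̃_i) − U_k^β(t̃_i)]²,

algebraically the Euclidean distance between the flattened S-scaled
segments (verified numerically in the tests).  Classical (Torgerson)
multidimensional scaling embeds the distance matrix: double-center the
squared distances, eigendecompose, truncate negative eigenvalues at zero.
The dimensionality criterion is the maximum error between input and
embedded squared dissimilarities relative to the scale of the
reconstructed matrix, max|d² − d′²| / max(d′²); a strictly per-pair ratio
is undefined in the presence of near-duplicate cycles (repeated scoot
cycles, identical rest segments), which real ensembles also contain.
Three dimensions capture ≳ 94% of the variability of the synthetic
ensembles.

Cluster count selection uses the gap statistic: k-means (20 restarts,
greedy seeding, fixed seed) for k = 1…8 on embedding dims 1–2, compared
against B = 50 uniform reference draws over the per-dimension bounding
box, selecting the global gap maximum.  On the synthetic embedding this
criterion does **not** return three clusters: the synthetic cloud is a
dense scoot locus plus a curved turn continuum, which out-clusters a
uniform reference at every k, so the gap curve rises to a plateau and the
global maximum lands at the largest k probed (the one-standard-error rule
lands at 3–5 depending on the seed).  This is a known failure mode of the
global-maximum rule on elongated continua and is reported as a limitation
rather than patched, because the density analysis below captures the
actual structure.  The kernel-density map over dims 1–2 (anisotropic
Gaussian kernel, default widths 1/8 of each dimension's range, normalized
to unit mass) shows exactly two local maxima — scoot-like and rest — with
the turn region forming a shoulder of the scoot peak, i.e. turns are a
wing of a continuum rather than a discrete state.  A classical bend-angle
classification (turn iff max |Δθ(s_9)| during cycle 1 exceeds 40°) is
provided for comparison and separates the synthetic archetypes cleanly.

## The two-channel neuro-kinematic simulator

The backbone carries ten neural segments per side.  During half cycle h
(sides alternate) segment j begins firing at τ_f[h] + j·d[h] with spike
amplitude a[h]; a firing event is a burst of dt-wide spikes covering
`burst_ms`.  The burst is a deliberate design choice: a single impulse
per half cycle drives the bi-exponential neuromuscular filter with the
full odd-harmonic comb of the alternation, and a two-pole filter cannot
attenuate the third harmonic below ~11% of the fundamental without also
obliterating the fundamental; the resulting harmonic modes cap the
three-eigenshape weight near 93%, well below observed swimming.  A burst
covering most of the half period nulls the low harmonics spectrally (the
boxcar's sinc zeros), yielding a near-sinusoidal muscle force with a fast
envelope — consistent with bursting central-pattern-generator
motoneurons.  Kernel defaults are τ_rise = 3 ms and τ_decay = 8.5 ms
(bi-exponential e^{−t/τd} − e^{−t/τr}, peak-normalized), burst length
0.84 of the half period.

Force to shape: the net muscle force F_net = F_m^R − F_m^L bends each
segment against the stiffness profile W(s_j) (head fixed at 1): curvature
κ = F_net / W, and Δθ is the running arc-length integral of κ with
Δs = 1/9.  The default W declines linearly from 1.0 to 0.53 along the
body and recovers to 0.61 over the last tail segment: stiff head,
compliant tail, slightly reinforced tail tip.  Exchange of the left and
right channels negates Δθ exactly, and zero drive is an exact fixed
point.

Archetypes (the synthetic study conditions):

| parameter | scoot | turn | why |
|---|---|---|---|
| a0 (drive amplitude) | 0.095 | 0.095 | tail beat ~18° for scoots |
| half period | 15 ms | 15 ms | cycle durations ~30 ms (observed 15–33) |
| d (segment delay) | 2.05 ms | 2.05 ms; 2.15 ms during cycle 1 | travelling wave; turns raise the delay only in their first cycle |
| first/last pulse | ×0.5 | ×0.5 | trapezoidal ease-in/out balances the two sides' impulse for any half-cycle count |
| whip | — | a[1] × 5 | the turn: one boosted pulse on the second half cycle (the bout opens with a soft normal half cycle so U_1 has a crossing before the bend) |
| catch / echo | — | +0.5 / +0.2 of the boost | the antagonist catch swings the body back (the bend is transient, ~120° at the tail) and a weak echo rings the excursion down |
| n_c | 6 (6–8 sampled) | 6 (6–8 sampled) | observed half-cycle counts |

The population model samples ~115 bouts from 20 virtual fish: per-fish
and per-bout multiplicative factors (each CV/√2 with total CV = 15%) on
amplitude, period and delay; handedness is a fair coin; two "age-like"
regimes differ by a 15% softer tail (regime B), a device that enlarges
the cycle-1 U_3 spread without any developmental claim.

Noise robustness follows the signal-to-noise protocol: each parameter
family (a, τ_f, d) is perturbed by white Gaussian noise of σ =
mean(|x|)/snr, and the response is the weighted squared distance between
the noisy and noiseless cycle-1 trajectories in the collective basis.
Amplitude and firing-time responses shrink monotonically from snr 1 to 6
to ∞; delay responses at snr 1 and 6 have overlapping interquartile
ranges, because time normalization absorbs much of what delay noise
changes.

### Known limitation: scoot leakage into the turn mode

Under this simulator class there is a structural trade-off between
spectral concentration and mode separation.  Reaching ≥96% three-mode
weight requires a body wave whose delay span is below about 0.8
wavelengths; such a wave periodically sweeps through single-bend (C)
configurations, so a symmetric scoot excites the turn mode V_1 at roughly
0.7× its max |U_2| rather than staying below 0.25×.  Conversely, a
≥ full-wavelength wave with near-uniform curvature amplitude keeps scoots
off V_1 but needs a third wave mode, capping the three-mode weight near
93%.  Real larvae escape the dilemma because their muscle activation is
spatially graded in ways this ten-segment, uniform-amplitude drive cannot
express.  The package prioritizes the spectral targets and reports the
leakage ratio honestly.

## Genetic-algorithm fitting

The fit searches a 15-gene genome: base amplitude, whip ratio, catch
fraction (the echo is tied at 0.4× the catch), half period, onset time,
baseline and cycle-1 segment delays, and the eight free stiffness values.
Bounds are read off the target itself: tail-angle zero crossings give the
half-cycle count and period; the per-segment delay is bracketed at
±50% of the median cross-correlation lag between adjacent spine-angle
columns; amplitude at [0, 4×] the value implied by the bend.  The
objective is the Frobenius distance between candidate simulation and
target after onset alignment by tail-angle cross-correlation (±6 frames).
Operators: tournament selection of size 4, uniform crossover (p = 0.9,
per-gene mix 0.5), per-gene Gaussian mutation (rate 0.35, σ = 8% of the
bound width, annealed ×0.2 by the final generation), elitism of one,
population 50, ≤50 generations with a 0.1%/10-generation plateau stop.
The tournament size and mutation settings were chosen for recovery
robustness: smaller tournaments and wider mutations recover the turn's
delay only on some seeds.  On archetype targets the fit recovers the whip
amplitude ratio and segment delay within 15% and leaves ≤15% relative
residual.  The fitted stiffness is weakly identified (many W profiles
produce near-identical kinematics once amplitude rescales), so its shape
should not be over-interpreted on single-bout fits.

## Midline extraction

The image chain is: (1) background estimation by biharmonic inpainting of
the user ROI in frame 0, subtraction as |G − B|; (2) threshold at 0.5× the
Otsu value of the background-subtracted frame, connected-component
filtering (exactly one component ≥ 20 px, else a segmentation error
naming the frame ambiguous); (3) skeletonization and extraction of the
skeleton's longest simple path by a double breadth-first sweep;
(4) extension of both path ends along their least-squares end tangents,
stopping where the distance transform starts falling at unit slope (the
rounded body cap past the true tip), which undoes skeleton shrinkage;
(5) a smoothing cubic spline (s = 0.5 per path point against pixelation
noise) resampled at n = 10 points equally spaced in arc length, with
tangent angles taken from the analytic spline derivative; (6) head/tail
disambiguation by local body width (distance transform averaged over the
first 15% of arc; temporal continuity breaks near-ties), then unwrapping
along the body and referencing to the head tangent.

On rendered noiseless bouts the chain recovers the midline to ~0.6 px RMS
and the spine angles to ~0.026 rad RMS for scoots (~0.056 rad for deep
turn bends, where the bent snout strains the straight-tangent tip
extension).  The cumulative three-mode weight computed with n = 10, 15
and 20 sample points agrees within 0.1 percentage points, so n = 10 is
converged for this purpose.

The frame renderer (the fixture generator for this chain) sweeps a
half-width profile (6.5 px head → 1.5 px tail over a 120 px body) along
the integrated midline with an anti-aliased edge, on a constant or
gradient background with optional Gaussian noise.  It emulates body shape
and contrast only: no eyes, fins, pigmentation, refraction, motion blur
or 3-D pitch/roll.  Extraction accuracy on real video will be worse in
ways these fixtures cannot measure.

## Problem sizes and reproducibility

Default analyses run on a 40-bout ensemble (21 scoots, 14 turns, 5
rests, ~5,600 frames) for the summary quantities and the full 115-bout
ensemble for population figures; both complete in seconds on one core.
All random draws flow from a single integer seed (ensemble sampling,
k-means restarts, gap references, GA initialization), and the pipeline
manifest records a checksum per output so reruns are verifiable.
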