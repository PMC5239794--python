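# Methods

This note documents the models, conventions, numerical choices and known
limitations of `curvestats`. Everything quantitative stated here is
computed by the test suite or the worked examples; nothing is asserted
that the code does not itself produce.

## Conventions

Orientations are *axial* quantities in degrees: an element at 10° is the
element at 190°. They are stored in [0, 180) and differences are wrapped
to (−90, 90]. Angles are measured from the image x-axis (columns) toward
the y-axis (rows); because rows grow downward, a positive rotation in this
convention appears clockwise on screen. All pair-geometry and continuity
computations are internally consistent under this convention and under
reflection (mirroring an edge field negates every mapped contour's
curvature step, which the tests verify).

## Stimulus model

A stimulus is an 8°×8° field rasterised at 64 px/° (512×512 px, 8-bit).
Each element is a Gabor micro-pattern, the product of a circular Gaussian
(γ = 1) and an oriented cosine carrier, with σ = 4 px and λ = 8 px —
at 64 px/° a carrier peak frequency of 8 cycles/°. The carrier phase is
ψ = 0 (even-symmetric, bright-centred) for every element; per-element
phase is a free design point that the detection task does not constrain,
so one value is used throughout.

Density control follows the classic grid method: positions are restricted
to a 16×16 matrix of 0.5° cells, exactly one element centroid per cell
(patches may overhang their cell; only the centroid is constrained).
A complete field holds 256 elements. The contour is placed by rejection
sampling over rigid motions — uniform rotation about the path centroid,
uniform translation — accepting the first motion that puts every element
inside the field and every non-end element in its own cell, with a budget
of 10,000 attempts per seed (a fresh attempt stream is derived from the
seed on failure). For the large end-element separations of the two-shape
experiment (up to 2°) an end element is allowed to share a cell when no
free cell contains its required position; the displaced noise element is
dropped so the 256-element density is conserved, and the exemption is
recorded on the stimulus. Empty cells receive noise elements with uniform
orientation on [0, 180) — 180°-periodicity of the Gabor makes a wider
range redundant — and uniform centroid within the cell. Patches composite
additively in contrast space around mid-gray (128); out-of-range pixels
are clipped and counted.

Contour geometry: the four central elements turn by the curvature angle α
per step, positions chained so that each displacement bisects the two
adjacent orientations (which makes every consecutive pair exactly
cocircular). A C-shaped contour uses steps (+α, +α, +α); an S-shaped
contour flips the sign once at the path midpoint, between central
elements 2 and 3: (+α, −α, −α). End elements are displaced from the
terminal elements by the end separation in direction θₑ relative to the
terminal orientation — positive θₑ toward the side the contour turns, the
head end mirrored so that both ends are symmetric for a C shape — and
their own orientation equals their direction.

Condition grids: 5 curvature angles × 10 end directions (−30…60°) for the
end-direction experiment, with 0.75° element spacing for the straight
contour (whose pop-out at 0.5° would otherwise reveal it) and 0.5°
elsewhere; 5 end separations × {C, S} × {collinear, cocircular} = 20
conditions plus two 4-element no-end baselines for the separation
experiment.

## Psychometric model

Proportion correct versus end direction X is fitted per curvature angle
with Y = A·exp(−0.5 (X−M)²/SD²) by unconstrained least squares
(`scipy.optimize.curve_fit`), with the denominator as SD² (the standard
Gaussian form). Initialisation is data-driven — M at the argmax, A at the
max, SD at half the sampled range — with 5 deterministic jittered
restarts; the best sum of squares wins. SD is reported as a magnitude. A
fit is flagged *degenerate* (never raised as an error) when the amplitude
is within 0.05 of the chance level, when SD exceeds the sampled range, or
when no restart converged; fits are deliberately not bounded below by
chance. The logit transform used for continuity clamps proportions to
[1/(2n), 1−1/(2n)].

The simulated observer draws correct counts Binomial(n, max(chance, Y)).
The truncation at chance matters for interpretation: when the generating
surface dips below chance inside the sampled range (broad tuning, low
amplitude), the fitted Gaussian no longer matches the generating process
and the recovered mean acquires a bias of a few degrees. Parameter-
recovery properties are therefore stated on surfaces whose probabilities
stay above chance across the sampled end directions; recovery under
truncation is visibly worse in the high-curvature regime, which mirrors
the instability of real flat tuning data. The default simulated surface
uses amplitudes falling from ~0.91 to ~0.57 across curvature angles,
best-detection directions slightly below the curvature angle, and a broad
(~61°) tuning width (~92° and near-chance for the steepest class).

## Edge extraction

The radial (non-oriented) log-Gabor has amplitude
H(r) = exp(−a (ln(r/f_c)/B₀)²) with f_c = 0.1 cycles/px, B₀ = 1.5 and
decay constant a = 5.77, natural logarithms, zero DC. With these constants
the half-amplitude width is 2·B₀·√(ln2/a)/ln2 ≈ 1.0001·B₀ octaves, i.e.
the bandwidth parameter and the measured octave bandwidth coincide at 1.5
— the package treats this identity as the defining relation between the
two printed constants. Filtering is by frequency-domain multiplication;
zero crossings (sign change against a 4-neighbour; the pixel nearer the
crossing is marked) within 216 px of the image centre are edge candidates.

Orientation is assigned from an oriented log-Gabor quadrature bank: 18
orientations (0–170° in 10° steps — a 0–360° sweep collapses under the
180° periodicity of orientation energy), radial log-Gaussian in the
frequency component along the wave vector, angular Gaussian in the
transverse component with half-amplitude half-width f_c·tan(20°) (a 40°
orientation bandwidth at the peak frequency), and the odd filter obtained
by −i·sign(u′). Sine and cosine responses are squared and summed per
channel; the per-candidate profile is normalised to unit sum. Candidates
whose peak channel energy is below 10% of the strongest candidate in the
image are dropped (the normalisation reference is configurable; the
image-wide maximum is the default). The channel peak is refined by
parabolic interpolation of log energy over the peak and its two circular
neighbours.

Two numerical choices depart from the plainest reading of the scheme and
deserve justification:

- **Duplicate thinning.** The zero crossings and ringing sidelobes of one
  physical edge spread over roughly the filter wavelength (10 px). A
  retained candidate must be the strongest within a 9 px radius
  (deterministic tie-break by position, `peak_local_max` semantics,
  optionally gated by orientation similarity). Without this, every planted
  element is reported as a constellation of half a dozen near-duplicates
  whose spurious chains contaminate the statistics. The cost is a floor of
  ~10 px on the inter-element spacings the pipeline can observe, so the
  shortest length bins (1–8, 9–17 px) are under-sampled relative to an
  un-thinned analysis.
- **Subpixel localisation.** Retained positions get one Newton step toward
  the zero level-set of the band-pass raster (δ = −f·∇f/|∇f|², clipped to
  ±0.6 px/axis). At pure pixel resolution the relative-direction angle of
  an edge pair 20 px apart carries ~±3° of quantisation noise, which
  consumes most of the 5° continuity tolerance downstream and loses ~2% of
  exactly-cocircular planted chains; with refinement the recovery of
  planted chains is complete. `subpixel=False` restores integer positions.

## Contour mapping

Ordered pair geometry: distance d, direction φ of B in A's orientation
frame, orientation difference θ, with φ and θ axial on (−90, 90]. The pair
is continuous when |θ − 2φ| ≤ 5° (wrapped mod 180°) — the exterior-angle
characterisation of cocircularity. The continuity defect is invariant
under swapping the pair, and for exactly continuous pairs swapping negates
both φ and θ.

A mapped contour is exactly 4 members satisfying: pairwise consecutive
continuity (±5°); consecutive spacings equal within one fifth, made
precise as |dᵢ₊₁ − dᵢ| ≤ min(dᵢ, dᵢ₊₁)/5 (symmetric under chain
reversal); mean spacing within the 1–42 px scan range (±1/5); and a
constant signed orientation step — every step within ±5° of the step mean,
and no two steps strictly on opposite sides of the ±5° band (so straight
chains with jitter keep a well-defined "constant" step). The search is
greedy and unguided: seeds in deterministic order (strongest edge first
when an energy column exists, else row-major), candidate spacings taken
from the distances of continuous neighbours, growth on both sides of the
seed taking the candidate with the smallest continuity defect (ties toward
the smaller spacing deviation), chains longer than 4 truncated at the
first valid window. Accepted contours are validated against all four
criteria before being marked; marked members are removed from the
candidate pool entirely (configurable to seed-only removal). On random
and chain-seeded fields every chain the greedy search emits lies in the
solution set of an exhaustive 4-tuple enumeration, and planted
non-overlapping chains are recovered completely; the greedy/exhaustive
comparison is part of the acceptance suite (500 fields of ≤50 edges).

End elements of a mapped contour: candidates one mean spacing (±1/5) from
a terminal member, continuous with it, and in the forward half-plane
(direction within (−90, 90)° of the outward contour direction). The
recorded orientation is relative to the terminal member, sign-normalised
so positive continues the curvature; at the head the traversal direction,
hence the sign, flips. For a straight contour the curvature direction is
undefined and the sign of the record is arbitrary (the magnitude is not);
distributions for the 0° class are interpreted two-sidedly.

Binning uses the printed inter-element-distance bins 1–8, 9–17, 18–24,
25–33, 34–42 px verbatim (they are not all 8 px wide; the printed edges
win over the nominal width) on the rounded mean spacing, and curvature
classes 0–40° by rounding the absolute step to the nearest 10°.

## Statistics

Occurrence counts are per curvature class. End-orientation histograms use
10° bins over (−90, 90). Normalisation is by the total number of end
records of the curvature class — not by contour count, because a contour
can contribute two records and the distribution must stay within [0, 1]
and sum to 1 per class; per-length-bin slices of one class share the class
total, so they remain comparable across classes exactly as intended by
the per-class normalisation. Distribution Gaussians reuse the tuning
fitter with chance 0 and require ≥4 non-empty bins. The class "peak" is
the fitted mean when a clean (non-degenerate) fit exists, else the mode
bin centre. The peak-versus-curvature trend is fitted as M = S·exp(K·X):
exponential *growth*, the only reading under which the fitted constants
(S ≈ 3, K ≈ 0.07) reproduce peaks rising from ~7° to ~24° over X = 10–30°.
Linear summaries (amplitude or width versus length) use ordinary least
squares.

## Synthetic data

The corpus generator plants exactly cocircular chains (the same bisector
construction as the stimulus path) in 480×480 images: 4 members plus,
optionally, one continuation element per end whose pairing with the
terminal member is exactly continuous and whose orientation sits at the
requested offset ρ from the terminal orientation toward the curvature.
Default study conditions: spacing 20 px (inside the mid-range 18–24 px
length bin),
contrast 0.5 on a uniform mid-gray background, per-image class mix
{0°: 2, 10°: 2, 20°: 1, 30°: 1, 40°: 1} (low curvature more common),
continuation offsets equal to the curvature step, random chain sign,
3-spacing clearance between chains, everything inside the 216 px analysis
radius. 1/f-noise backgrounds (configurable SNR) and uniform random
distractor elements are available to exercise false-positive behaviour.

Elements are rendered by default as odd-symmetric Gabor micro-edges
(σ = 2 px, λ = 10 px matched to the detector's peak): a local luminance
*step*, whose band-pass zero crossing falls exactly at the element centre.
An even ridge (a drawn line segment, available as `style="segment"`) puts
the crossings on its flanks ~2.5 px off-centre and cannot support 1 px
localisation; that is a property of ridges under any zero-crossing
detector, not of this implementation.

What the synthetic corpus does *not* emulate: occlusion, luminance
gradients, texture clutter, multi-scale structure, and the continuous
(rather than discrete-element) edges of real photographs. Passing the
recovery tests therefore demonstrates the correctness of the machinery —
filters, search, bookkeeping — under known ground truth, not that
natural-image statistics would reproduce any particular published values;
corpus-dependent numbers are reported by the pipeline but are acceptance-
tested only through synthetic recovery.

## Problem sizes and determinism

Every stochastic stage takes an explicit seed and is bit-reproducible;
rerunning a pipeline with the same configuration produces byte-identical
CSVs. The test suite runs the oracle comparison on 500 fields, planted
image recovery on 200 images (100 (step, ρ, replicate) cells), observer
recovery on 200 simulated observers at 200 trials/condition, and the
end-to-end corpus property on one 50-image corpus; these sizes keep the
whole suite around a minute on one CPU while leaving each property with
clear statistical teeth.

## Known limitations

- The thinning radius imposes a ~10 px floor on observable spacings
  (shortest length bins under-sampled).
- Mapped-contour statistics on *natural* images depend on corpus choice;
  no claim is made that a particular photo collection reproduces the
  synthetic-corpus numbers.
- The simulated observer's chance truncation biases Gaussian-mean recovery
  when the generating surface dips below chance (broad/low surfaces), by
  a few degrees.
- Straight-contour end records carry an arbitrary sign.
- The exposure-linearisation hook is an interface only; no camera model is
  provided.
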