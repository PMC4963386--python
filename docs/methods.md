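# Methods

`fgseg` implements a boundary–surface cortical model of 3D figure-ground
assignment from 2D pictures, in the FACADE / 3D-LAMINART tradition, together
with the fragmented-inducer displays that probe it and a simulated
forced-choice experiment on the model's output. This note documents the model,
its assumptions, the parameters that matter, and the design choices made where
the published theory is verbal rather than equation-level. The underlying
theory has no canonical printed equations for these stages, so every kernel,
gain and threshold here is a reconstruction choice, surfaced in
`fgseg.config.PipelineConfig` and justified below.

## Stimuli

Each experimental display is a 192×160 px luminance image: a uniform
background at 50.5 cd/m², with inducer shapes at 1.5 cd/m² (Weber contrast
−0.97) and/or 99.5 cd/m² (+0.97). The nominal central rectangle is 96×80 px
(12:10 aspect, matching the 12 cm × 10 cm screen geometry at the metadata
pixel pitch of 1.25 mm/px). Inducer bars of mean thickness 8 px lie flush
against the rectangle contour — outside it for *inward*-directed contrast
edges, inside it for *outward*-directed ones — covering exactly 50% of the
perimeter; the remaining 50% carries no physical contrast and must be
completed perceptually.

Geometry choices the display literature leaves open:

* **Fragment placement.** Two bars per side, each covering 25% of the side,
  anchored at the side's two ends. End-anchoring puts physical edges at every
  rectangle corner, which a strictly collinear grouping mechanism needs: it
  cannot complete around a corner that carries no contrast. The cost is a
  wide mid-side gap (48 px horizontally, 40 px vertically), which sets the
  bipole lobe length (below).
* **Corner elements.** For inward displays the two bars meeting at a corner
  are joined into one L-shaped inducer element. Without the corner block,
  each bar's thickness edge extends the rectangle's contour lines past the
  corner, creating spurious T-junctions whose end gaps fall on the wrong side
  of the completed contour.
* **Thickness alternation.** Bars alternate 6 px and 10 px thickness (mean
  8 px) so that the inducers' outer long edges are never mutually collinear.
  With constant thickness the outer edges complete a second rectangle contour
  parallel to the nominal one, making end-gap side assignment ambiguous.
* **Mixed polarity per element.** In the mixed scheme, polarity alternates
  element-by-element around the contour (the two bars forming one corner
  element share a polarity). A strict bar-by-bar alternation would put
  opposite polarities on the two bars whose edges continue each other
  collinearly through a corner; an oriented filter straddling that point sees
  the responses cancel — precisely the within-element contrast inhomogeneity
  these displays are designed to exclude. Within each inducer element the
  contrast sign is homogeneous, and adjacent elements alternate.

Fixture displays (Kanizsa, reverse-contrast Kanizsa, Ehrenstein and its
fragmented-mixed variant, and the two- and three-abutting-rectangle occlusion
figures) are generated at the same scale. Images round-trip through 8-bit
grayscale PNG/PGM using the display calibration anchors (luminance 1.5, 50.5,
99.5 cd/m² ↔ gray 0, 148, 255; linear in between).

## Early vision (model V1)

* **Illuminant discounting.** A shunting center–surround network,
  X = (C − S)/(A + C + S), with unit-mass Gaussian center (σ = 1 px) and
  surround (σ = 3 px) and offset A = 10 cd/m². The ratio form compresses
  overall luminance scaling (doubling the input changes the peak response by
  under 10%) and gives zero on uniform fields. Half-wave rectification splits
  the signal into on and off feature-contour channels; these are the sources
  for surface filling-in.
* **Simple cells.** Odd (antisymmetric) Gabor filters, K = 8 orientations at
  22.5° spacing, wavelength 8 px, envelope σ = 3 px, applied linearly to
  luminance and rectified into two polarity channels. Antisymmetry makes the
  luminance reflection L → 2·L_bg − L swap the channels exactly.
* **Complex cells** sum the two polarity channels, making everything
  downstream contrast-sign invariant. This single pooling step is what lets
  one boundary circuit group same-polarity and mixed-polarity inducers
  identically.
* **End-stopped cells** compare short (σ = 2 px) against long (σ = 6 px)
  along-axis smoothing of each orientation channel and emit the rectified
  difference on the perpendicular channel: end cuts at line terminations,
  nothing along an unbroken line. They are exercised by the Ehrenstein-style
  fixtures and are not part of the main figure-ground path.

Driving input to grouping is normalized by the complex-cell response to a
full-contrast (1.5 | 99.5) step edge, so boundary activity is expressed
relative to the strongest physical edge a display can contain.

## Boundary grouping (model V2)

Bipole cells per position × orientation iterate to a fixed point:

* **Orientation sharpening.** Oriented filters are broadly tuned (a vertical
  edge excites the ±22.5° channels at ~70%); before grouping, a
  winner-take-most step, relu(a_k − β(max_j a_j − a_k)) with β = 2,
  sharpens the tuning. Without it, near-parallel channels acquire spurious
  collinear cooperation along any straight contour and destabilize the
  competition.
* **Cooperation.** Each cell has two collinear lobes (length 32 px, thin
  rasterized lines, flat weights summing to 1 per lobe). A lobe's support is
  the mean of the slightly blurred (σ = 0.5 px) same-orientation field along
  the lobe line: support scales with the *extent* of collinear activity (an
  isolated short edge cannot drive a bipole the way a long contour can), yet
  a distant inducer contributes at full strength per covered pixel, letting a
  cell at the middle of a 48 px gap seed completion. Cooperation is the
  thresholded hard minimum of the two lobes (threshold 0.05, gain 4) — the
  AND property: activity never extends past a lone inducer's end. The
  cooperative term is capped at 0.8 so a purely illusory (cooperation-only)
  contour can never outcompete a real, driven one where they cross; this
  resolves crossings deterministically in favor of the physically supported
  edge.
* **Competition.** Each cell is suppressed by the excess of the strongest
  *differently oriented* activity within a 3 px disc over 1.25× its own level
  (gain 12), then divisively normalized by the orientation-summed activity in
  a 5 px disc (gain 0.5, offset 0.35), rectified, and saturated at 1. The
  ratio gate is what separates T-junctions from corners: a completed head
  (drive + full cooperation) roughly doubles an abutting stem's level and
  silences it — the *end gap* — whereas two edges meeting at a corner stay
  near parity and coexist. Lobe convolutions use zero padding (no boundary
  activity exists beyond the image frame); reflective padding would
  hallucinate collinear support across the border.
* **Settling.** Synchronous updates with under-relaxation 0.7 to a residual
  of 1e-4 (typically 10–35 iterations; a degenerate border-to-border line is
  the slow case). Completion threshold θ_c = 0.3 and gap threshold
  θ_gap = 0.1 of saturation.
* **End-gap detection** finds, per orientation, pixels below θ_gap whose own
  channel resumes decisively (≥ 1.3·θ_c) within 7 px on one side while a
  differently oriented head lies within 3 px on the opposite side, and
  records a unit side vector pointing from the head into the gap-bearing
  side. The gap is read off the converged field; no explicit T-junction
  detector exists, and deleting the head abolishes the gap.

## Surface filling-in (model V2 thin stripes)

Signed feature-contour signals (on − off) act as soft-clamped sources
(clamp conductance 10³) for lattice diffusion whose edge conductances are
gated by the orientation-pooled boundary: g = 1/(1 + 50·B) below the
permeability threshold (0.3), and exactly 0 above it. Hard gating makes a
closed boundary genuinely contain its fill at steady state, while a
supra-threshold hole lets the two sides equalize — the containment /
equalization dichotomy the surface stream depends on. A tiny leak (1e-9)
regularizes source-free compartments to zero. The steady state is solved
directly (sparse Cholesky-like factorization via SuperLU); an independent
Jacobi relaxation of the same system serves as a cross-check and agrees to
1e-6 on small grids.

**Surface contours** are the rectified DoG (σ = 1, 3 px) of the filled
surface, thresholded at 20% of the response a contained unit step would give
(scaled by the surface's own amplitude), restricted to a 2 px dilation of
supra-threshold boundaries, and — crucially — gated by *separation*: a
boundary pixel emits a signal only where the compartments on its two sides
are distinct. A region that leaks through its end gaps merges with its
neighbor, so its boundary no longer separates anything and stays silent;
this operationalizes "output signals only at positions surrounded by closed
boundaries" and is why gap-bearing inducer boundaries emit no surface
feedback.

**Region analysis** thresholds the pooled boundary at the permeability
threshold, seals hairline (1–2 px) chinks between abutting boundary bands by
one morphological closing (flow through such a constriction is negligible;
genuine end gaps are several pixels wide and stay open), treats the
outermost pixel ring as a permanent closed boundary (the image frame), and
labels 4-connected compartments.

## Depth planes and figure-ground (model V2 ↔ V4)

The converged 2D boundary is projected identically onto a near (D1) and far
(D2) plane — in 2D-picture mode every boundary is initially depth-ambiguous.
An outer loop (tolerance 1e-6, at most 50 iterations, 6 bipole re-grouping
steps per plane per pass) then applies, in order: per-depth filling-in and
surface contours; boundary pruning (same-depth multiplicative strengthening,
gain 1.2; near-to-far subtractive suppression, gain 3, spread over a 5 px
disc and weighted by the near plane's orientation profile so a vertical
contour's feedback prunes far *vertical* boundaries without cutting an
unrelated horizontal contour nearby); the disparity filter (mutual
across-depth suppression proportional to relative strength; exact ties
attenuate both and eliminate neither); boundary enrichment (far plane gains
the near boundaries, for V4 filling only); surface pruning and
depth-selective capture (near-captured sources are deleted from the far
plane's input, and the V4 near plane fills only near-captured sources);
V4 filling within enriched boundaries; and top-down attention (ART matching:
multiplicative on-center from V4 surface contours, subtractive Gaussian
off-surround, σ = 6 px — purely modulatory, so zero bottom-up activity stays
zero). Suppression that reflects a decisive dominance (one plane ≥ 1.25× the
other) accumulates as persistent inhibition applied inside the re-grouping
step at the level of the bipole net, so even cooperation-sustained segments
can be silenced.

**Near-depth capture.** The initial compartment structure defines a central
region (seeded at the image center) and its surround. Each side's capture
score is q = 1/(1 + 5·f), where f is its share of the end-gap votes: every
end gap probes 6 px along its side vector and votes for the side of the
completed contour it adheres to (inside the central compartment's interior
bounding box, or outside). The higher-scoring side is captured by the near
plane; ties capture both, leaving a featureless or symmetric display
depth-ambiguous. This is the operational form of the readout rule that the
side carrying end-gap remnants is seen farther.

**Consolidation.** After the loop converges, the capture outcome is expressed
at the boundary level: the near plane retains the captured compartment's
bounding contour (computed from the morphologically closed compartment, so
spurious web crossing its interior is ignored), and the far plane regroups
with the near-owned orientations suppressed along that contour — differently
oriented contours pass freely, which is how an occluded edge completes
behind its occluder. For the three-abutting-rectangles figure this yields the
model's signature occlusion percept: the near plane holds only the occluding
rectangle's contour (end-gap remnants eliminated), and the far plane holds
one closed horizontal rectangle completed behind it.

**Readout.** margin = (q_center − q_surround)/(q_center + q_surround) ∈
[−1, 1]; positive means the central region is nearer. |margin| < τ_same =
0.05 reads out as "same plane". Border ownership assigns each contour pixel a
unit normal pointing into the nearer region. On the default displays the
margins are ±0.71/−0.62 (inward/outward), identical across the three polarity
schemes because every stage past the complex cells is contrast-sign
invariant.

## Simulated psychophysics

The depth margin maps to 3AFC probabilities through a lapse-mixed softmax
over utilities (g·margin, −g·margin, u_same). The defaults g = 1.9324,
u_same = −0.3869, lapse = 0 are a least-squares calibration
(`calibrate_choice_params`) of the rule onto the observed mean
response-frequency triples (0.83, 0.07, 0.10) for inward and (0.06, 0.75,
0.19) for outward displays, evaluated at the model's margins; they live in
the config, labeled as calibrated. A symmetric rule cannot reproduce the
asymmetric "same plane" rates of the two directions exactly; the fit
compromises at ≈ 0.14.

The simulated experiment is 10 subjects × 6 conditions × 4 presentations
(240 trials), multinomial responses, independently randomized trial order per
subject, with a counter-based Philox generator keyed per (seed, subject) for
exact cross-platform reproducibility. The experiment summary computes
per-subject conditional response frequencies, across-subject means and SEMs,
and a two-way fixed-effects ANOVA (direction × polarity, with interaction,
type-II sums of squares via statsmodels) on the "in front" and "behind"
frequencies separately. Monte Carlo calibration on this design gives a
type-I error rate of 0.05 for the direction effect under the null and
essentially complete power for an 0.8-vs-0.1 effect at α = 0.001. A
published F statistic with anomalous degrees of freedom for this design is
not a reproduction target; the raw human data are unavailable.

The design note that a session reportedly produced 300 observations from 30
trials per subject is inconsistent with 6 images × 4 presentations = 24
trials; the simulation uses the 6 × 4 design.

## What the synthetic data do and do not show

The generator reproduces the displays' printed luminances, geometry and
coverage exactly, and the decision model is calibrated to the printed group
means. It does not model inter-subject variability beyond multinomial trial
noise, exposure-duration effects (displays are treated as steady states),
eye movements, or screen calibration error. Passing tests therefore show
that the implemented circuitry produces the right *qualitative* percepts and
that the statistical pipeline is calibrated — not that the model
quantitatively predicts individual human observers.

## Numerical choices and degenerate inputs

All fields are float64. Fixed-point iterations use under-relaxation 0.7
(grouping) and tolerance 1e-4; the outer depth loop uses 1e-6. The diffusion
solve demands a residual below 1e-8 of the source scale and raises otherwise.
A featureless image short-circuits to a "same plane" report with margin 0.
Non-convergence raises a ConvergenceError carrying the stage and last
residual rather than returning a partial state. Problem sizes default to the
192×160 display with K = 8 orientations and two depth planes; a full-model
run takes roughly 10–20 s on one CPU, and the packaged test suite and
acceptance script are sized accordingly.

## Known limitations

* Strictly collinear grouping: no curved or corner-turning completion, hence
  the end-anchored fragment layout.
* Two depth planes only; no true stereo disparity, transparency, or
  bistability.
* The capture/readout step identifies exactly two candidate surfaces
  (central compartment vs surround); displays with several nested figures
  would need a more general region competition.
* "Same plane" responses arise only through the decision rule's soft
  symmetry around τ_same, not through a separate mechanistic pathway.
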