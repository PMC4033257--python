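# Methods

`gazelearn` implements a complete simulation pipeline for asking a
deceptively simple question about visual exploration: *are the gaze
sequences an observer produces on a moving, partially occluded object
sequentially structured — and does that structure make them easier to
learn?*  The pipeline renders the stimulus, produces gaze records from
several observer models, converts them into streams of foveal image
samples, and measures the learnability of those streams with a simple
recurrent network (SRN), including probes that selectively destroy the
network's short-term memory.

## The occluded-rod display

The stimulus is the classic perceptual-completion display: a vertical
rod translating horizontally behind a static horizontal occluding box.
The default display is 480 x 360 px, 117 frames at 30 fps (frame
duration 100/3 ms), one full motion cycle (far right -> far left ->
back), with frame indices treated cyclically (frame t = t mod 117).

The rod trajectory is a constant-speed triangle wave with period 117
frames.  With an odd period the analytic minimum falls between frames
58 and 59; both integer frames attain the minimum over integer frames,
and `floor(n_frames/2)` is used wherever a single "half-cycle frame" is
needed.  The triangle wave was chosen over smoother profiles because it
is the simplest motion consistent with a uniform back-and-forth sweep,
and its reflection symmetry (`pos(t) == pos(n - t)`) is exactly
testable.

The background carries a static, seeded random-dot texture (180 2x2-px
dots by default).  The texture serves two purposes: it gives the
saliency front end non-degenerate contrast structure away from the rod,
and it makes COG patches at random display locations informative about
position rather than uniformly gray.  Rendering paints the rod first
and the occluder last, so occlusion is structural, not an artifact of
drawing order.

## Synthetic reference gaze

Real infant eye-tracking data are not part of the package; the
`synthetic_gaze` module generates reference records that emulate the
published 3-month-old group kinematics: fixation durations from a
truncated normal with mean 339.38 ms and SD 96.03 ms (truncated at one
frame), and gaze-shift distances targeting mean 59.20 px, SD 18.82 px
(truncated at 1 px).  The default record length is 61 fixations (about
20 s of viewing); the true fixation-count distribution is unpublished,
so this is a free parameter.

Spatial structure comes from a small set of anchor regions and a
first-order Markov transition matrix.  For the `infant_like` style the
defaults are three static anchors clustered over the upper rod path and
occluder edge, spaced 50-60 px apart (matching the target shift
distance); each shift draws a target distance from the truncated
normal, proposes 64 jittered points (SD 18 px) around the
Markov-selected next anchor, and keeps the proposal whose realized
distance is closest to the target.  This keeps distances an *emergent*
property of anchor geometry while matching the configured moments to
within sampling error.  The `scripted_regions` style places fixations
at the (jittered) anchors themselves — with a deterministic cycle this
produces exact alternation — and `uniform_random` scatters fixations
uniformly.

What the generator does *not* emulate: habituation and look-away
dynamics, saccade kinematics within a shift, measurement noise and
track loss, and individual differences beyond the seed.  Passing tests
therefore show that the pipeline behaves correctly under
infant-*like* input statistics, not that it reproduces any particular
infant's data.

## Saliency front end

Each frame yields 24 feature maps: {motion, 4 oriented edge energies,
luminance, red-green and blue-yellow opponency} x 3 spatial scales.
Scales are Gaussian blurs with doubling sigma (2, 4, 8 px); all maps
are computed at full resolution.  Motion is the absolute
luminance-channel difference between consecutive frames (defined as
zero on the first frame, which has no predecessor).  Edge energy is
Sobel-derived oriented gradient magnitude |cos(a) Gx + sin(a) Gy| at 0,
45, 90 and 135 degrees.  Opponency maps are |R - G| and
|B - (R + G)/2| on the blurred channels.  Each map is min-max scaled to
[0, 1] (constant maps become all zeros).

The saliency map is the sum of the 24 normalized maps, downscaled to
40 x 30 by 12 x 12 block averaging (the exact integer factor of
480 x 360), then divided by the mean of its 100 largest values.  After
this normalization individual cells may slightly exceed 1; they are
clipped at 1 only inside the saliency-captured statistic so that it
remains a proportion.  The within-channel across-scale combination
order used by some saliency architectures is deliberately not applied:
the 24 maps are summed directly.

## Artificial observers

Both artificial observers are *yoked* to a reference record on four
dimensions: first fixation location, number of fixations, per-fixation
duration (rounded to whole 33-ms frames, minimum 1 — e.g. 375 ms
becomes 11 frames), and gaze-shift distance.

The saliency observer maintains a 40 x 30 inhibition-of-return map.  At
each fixation onset a 2D Gaussian (support 92 x 92 px, i.e. about twice
a COG patch; sigma = span/4 so the surface is near zero at the support
edge) is added, centred on the fixation's grid cell with peak equal to
the saliency value there; every frame the whole map decays by 10%.
Over a fixation the observer accumulates the (unnormalized) sum of the
saliency maps spanning its frames; at fixation end the fixation map is
max(0, cumulative saliency - inhibition), and the next fixation is
chosen among the 500 highest-valued cells as the cell (addressed by its
pixel centre, cell (i, j) -> (12 i + 5.5, 12 j + 5.5)) whose distance
from the current point is closest to the yoked distance, ties broken
uniformly at random.  Two readings of the original procedure were
possible and are resolved as follows: the top-500 selection operates on
the *fixation map* (otherwise the inhibition subtraction would be dead
code), and the inhibition Gaussian is added *once at onset* rather than
re-added every frame.  Cells whose fixation-map value is zero are not
candidates (they are fully inhibited); if the whole map is zero the
choice degenerates to a uniformly random cell.

The random observer draws each next fixation uniformly on the circle of
the yoked radius around the current point, rejecting and resampling
draws that land off the display; if the entire circle is infeasible the
radius is clipped to the largest feasible value with a warning.

## COG sequences

Each fixation becomes a 41 x 41 grayscale patch (luminance weights
0.299/0.587/0.114) sampled from the frame on which the fixation starts
(cumulative duration // frame duration, mod 117), centred at the
rounded fixation pixel with edge replication beyond the display border
(replication avoids injecting artificial black borders into training
input).  The patch travels with the fixation's coordinates normalized
to [0, 1].  41 monitor pixels subtend ~1.8 degrees at the original
viewing geometry (60 cm from a 76-cm 1280 x 1024 monitor), roughly the
foveal field.

## The SRN

A three-layer Elman network implements a forward model: input = current
patch (1681 units at full scale) + context copy of the previous hidden
activations (400 units) + the *upcoming* fixation's normalized (x, y);
hidden 400 units; output 1681 units; logistic activations; all biases
fixed at 0.  Weights initialize Uniform(0, 1)/fan-in.  Training is
pattern-wise backprop (learning rate 0.1, no momentum or decay) on a
half-sum-of-squares loss; the context is treated as fixed input (no
backprop through time).  The reported metric is per-pixel RMSE of each
prediction, averaged over the L - 1 patterns of a sequence.  Sample t
is presented with the coordinates of sample t + 1 and target patch
t + 1; the last sample is never an input.

The context starts every sequence at 0.5.  Under a reset interval k the
context is overwritten with 0.5 after every k presented samples, before
the next presentation; k = 1 provably reduces the SRN to a memoryless
feedforward network (asserted by direct comparison in the tests).  RMSE
is averaged per-pattern-then-over-patterns rather than pooled, matching
a per-pixel error axis.

## Training regime and analyses

A run initializes one network and clones it across references, so
within-run differences are attributable to the training sequences.
Each epoch trains the reference's observer-group sequences in a fresh
random order with weight carry-over; context never leaks across
sequences (it is re-initialized at every sequence start in both
training and testing).  Every 10 epochs learning is frozen and each
sequence is evaluated under the canonical condition and under 1-, 2-
and 5-sample resets.  Testing runs at epochs 10, 20, ... by default; an
epoch-0 probe is optional.

Analyses: (i) per (run, network, epoch), observer groups are ranked by
ascending canonical RMSE (ties share the average rank — a measure-zero
event for real runs) and averaged; (ii) percent change
= 100 (RMSE_reset - RMSE_canonical)/RMSE_canonical, averaged over runs
and networks, with zero-canonical cells excluded.  Scanpath summary
statistics follow the standard constructions: revisit rate is the peak
of the per-fixation 41 x 41 window frequency map divided by the number
of fixations; dispersion is the mean distance from the fixation
centroid; saliency captured projects each fixation onto the saliency
map of its onset frame (clipped at 1).  Group-level significance
testing is left to standard statistical routines; the package's tests
assert effect *directions*.

## Problem sizes: full vs desk presets

The `full` preset preserves the original scale: 10 runs x 12 references
x 300 epochs, 41-px patches, 400 hidden units.  The `desk` preset is
the package's working scale for routine verification: 1 run, 4
references, 100 epochs, 40-fixation sequences, 21-px patches, 200
hidden units, and a reduced-amplitude display (rod sweep 120 px) so
that three fixed anchor regions on the rod path see the rod pass
frequently.  That last choice matters: with the patch no larger than
21 px, temporal structure is only visible to the network if the rod's
phase and direction of motion modulate patch content across successive
fixations; concentrating the scripted anchors on a narrow sweep band
achieves this.  Desk-scale results reproduce the qualitative orderings
(structured sequences learn better than yoked random ones; context
resets hurt, more for frequent resets, and more for structured than
random sequences) but not the magnitudes of any full-scale statistic.

## Numerical and degenerate-input conventions

- Coordinates are 0-based, x rightward, y downward, pixel units.
- All stochastic components take explicit seeds; identical seeds give
  bit-identical outputs (frames, records, weights, result tables).
- Constant feature maps normalize to zero; an all-zero saliency sum
  skips the top-100 division; a zero-peak inhibition Gaussian is a
  no-op.
- Duration quantization uses round-half-even to nearest frame with a
  1-frame floor; onset frames use floor of cumulative duration.
- Gradient correctness is pinned by a central-difference oracle at
  1e-6 relative tolerance on toy networks.

## Known limitations

- The saliency front end implements exactly the stated channel set, not
  a full center-surround/winner-take-all architecture.
- Reference gaze is synthetic; all group-level numbers that depend on
  real infant data (e.g. published group means for saliency captured or
  interference gaps) are not reproduced quantitatively, only their
  orderings under the synthetic conditions.
- The full preset is computationally heavy (hours on one CPU); tests
  and the acceptance script exercise the desk preset.
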