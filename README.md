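# gazelearn

Are gaze sequences on a moving, partially occluded object *sequentially
structured* — and does that structure make them easier to learn?
`gazelearn` is a simulation pipeline for studying this question, aimed
at researchers in developmental and computational cognitive science who
model infant visual exploration.

The pipeline:

1. **Stimulus** — renders the classic perceptual-completion display: a
   vertical rod sweeping right → left → right behind a horizontal
   occluder (480 × 360 px, 117 frames, 30 fps, cyclic).
2. **Reference gaze** — generates synthetic gaze records with
   infant-like kinematics (fixation durations ~ N(339, 96²) ms,
   gaze-shift distances ~ N(59.2, 18.8²) px, truncated) and controllable
   temporal structure (Markov alternation among anchor regions).
3. **Saliency** — per-frame bottom-up saliency: 24 feature maps
   ({motion, 4 oriented edges, luminance, R–G and B–Y opponency} × 3
   scales), summed and normalized onto a 40 × 30 grid.
4. **Artificial observers** — an image-saliency observer (cumulative
   saliency minus a decaying inhibition-of-return map; top-500
   candidate cells; distance-matched choice) and a random-gaze
   observer, both *yoked* to a reference record on first fixation,
   fixation count, frame-quantized durations, and gaze-shift distances.
5. **COG sequences** — each fixation becomes a 41 × 41 grayscale
   center-of-gaze patch (≈ 1.8° of visual angle) from its onset frame,
   paired with normalized fixation coordinates.
6. **SRN learnability** — a simple recurrent (Elman) network
   (1681 + 400 + 2 input units → 400 hidden → 1681 output, logistic,
   zero biases, pattern-wise backprop at lr 0.1) learns to predict each
   next COG sample; every 10 epochs it is tested with full recurrence
   and with the context layer reset to 0.5 every 1, 2 or 5 samples.
7. **Analysis** — scanpath summary statistics, canonical-RMSE rank
   curves, and percent-change interference curves for the reset probes.

The central quantity is **learnability**: the per-pixel RMSE with which
an SRN predicts the next foveal sample of a gaze stream, and its rank
across observer groups trained on yoked streams.  If a group's
sequences carry temporal structure, (a) they are learned to lower RMSE,
and (b) erasing the context trace (reset every k samples) inflates RMSE
— the more, the more structure.

## Worked example

Simulate twelve infant-like references, yoke both artificial observers
to each, and tabulate group summary statistics:

```python
from gazelearn import (DisplayConfig, render_occluded_rod,
                       compute_saliency_sequence, generate_gaze, make_yoke,
                       simulate_saliency_observer, simulate_random_observer,
                       group_summary)
from gazelearn.synthetic_gaze import GazeStyleParams

display = DisplayConfig()
frames = render_occluded_rod(display)
smaps = compute_saliency_sequence(frames)

refs, sals, rnds = [], [], []
for seed in range(12):
    ref = generate_gaze(GazeStyleParams.infant_like(seed=seed), display)
    yoke = make_yoke(ref, display.frame_ms)
    refs.append(ref)
    sals.append(simulate_saliency_observer(smaps, yoke, seed=seed))
    rnds.append(simulate_random_observer(yoke, display, seed=seed))

print(group_summary({"reference": refs, "saliency": sals,
                     "random": rnds}, smaps).round(2).to_string())
```

Output (means over the 12 observers; `_sd` columns omitted here):

```
           mean_fixation_duration_ms  mean_gaze_shift_px  dispersion_px  revisit_rate  saliency_captured
reference                     341.13               60.52          38.73          0.30               0.60
saliency                      341.07               60.48          86.24          0.13               0.65
random                        341.07               60.52         109.74          0.10               0.30
```

Reading the table: the yoked dimensions (duration, shift distance) are
equated across groups by construction — durations differ from the
reference only by frame quantization.  The saliency observer captures
0.65 of maximal saliency versus 0.30 for the random observer: following
the saliency map works even under a distance constraint.  The random
observer scatters most (dispersion ≈ 110 px) and revisits least.

Training SRNs on structured versus yoked random COG streams (the
`desk` preset: 1 run, 4 networks, 100 epochs, 21-px patches):

```
gazelearn train --preset desk --seed 0 --out results.csv
```

then `gazelearn.analysis.rank_curves` / `percent_change_curves` (or the
`plot_*` helpers) show structured sequences reaching lower canonical
RMSE than random ones and suffering a positive, reset-frequency-graded
RMSE increase (tens of percent by epoch 100) when the context layer is
reset — the signature of temporal structure in the gaze stream.

Other CLI entry points: `gazelearn render`, `gazelearn saliency`,
`gazelearn simulate-gaze`, `gazelearn simulate-observer`.  See
`docs/methods.md` for the model details, parameter choices and
limitations.

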