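# fgseg — boundary–surface model of figure-ground assignment

`fgseg` is a computational-neuroscience pipeline that explains a
psychophysical finding about 3D figure-ground perception of 2D pictures:
when a central rectangle is defined by spatially disjoint inducer fragments
carrying only 50% of its contour, whether the rectangle is seen as standing
**in front** of the surround or **lying behind** it is determined by the
*direction* of the local contrast edges (inward vs outward), and not at all
by their contrast *polarity* (dark, light, or mixed inducers give the same
percept).

The package implements the boundary-stream / surface-stream account of this
effect (in the FACADE / 3D-LAMINART tradition) as a tested, parameterized
pipeline:

1. **Stimuli** — the six fragmented-inducer displays at the printed
   luminances (background 50.5 cd/m², inducers 1.5 and 99.5 cd/m², Weber
   contrasts ∓0.97, 12:10 central rectangle, exactly 50% contour coverage),
   plus classic fixtures (Kanizsa, reverse-contrast Kanizsa, Ehrenstein,
   abutting-rectangle occlusion figures).
2. **Model V1** — illuminant-discounting shunting center–surround
   (feature contours), polarity-specific simple cells, polarity-pooled
   complex cells, end-stopped cells.
3. **Model V2, boundary stream** — bipole grouping cells whose two collinear
   receptive-field lobes must *both* be active (thresholded minimum), with
   short-range competition. Completion bridges the contour gaps; at the
   emergent T-junctions the completed contour (head) suppresses the abutting
   inducer edges (stems), carving **end gaps**.
4. **Model V2, surface stream** — boundary-gated diffusion (filling-in) with
   feature-contour sources; closed boundaries contain their fill and emit
   **surface contour** feedback, leaky ones do not.
5. **V2 ↔ V4 depth loop** — two depth planes with three near-to-far
   asymmetries (boundary pruning, surface pruning, boundary enrichment), a
   disparity filter, and ART-style top-down attention. The side of the
   completed contour that carries end-gap remnants is assigned the farther
   plane; the depth **margin** ∈ [−1, 1] quantifies the assignment.
6. **Simulated psychophysics** — margins map through a calibrated softmax to
   3AFC probabilities ("in front" / "behind" / "same plane"); a 10-subject ×
   6-condition × 4-repetition experiment is simulated with multinomial
   responses and analyzed with a 2 (edge direction) × 3 (polarity) ANOVA on
   per-subject response frequencies.

See `docs/methods.md` for the model equations, parameter defaults and the
design decisions.

## Worked example

```python
from fgseg import (StimulusSpec, generate_experimental_display,
                   run_full_model)

img = generate_experimental_display(StimulusSpec(edge_direction="inward",
                                                 polarity_scheme="mixed"))
report = run_full_model(img)
print(report.central_depth, round(report.margin, 3),
      [round(p, 2) for p in report.decision_probabilities])
```

prints

```
in_front 0.714 [0.81, 0.05, 0.14]
```

meaning: the mixed-polarity inward display is judged to stand in front of
its surround with a depth margin of 0.714, and the calibrated decision rule
predicts response probabilities 0.81 / 0.05 / 0.14 for "in front" /
"behind" / "same plane" — near the observed human response frequencies
(0.83 / 0.07 / 0.10). The same call on an outward display prints
`behind -0.619 [0.07, 0.77, 0.16]`, and all three polarity schemes of a
given direction produce identical margins, because everything downstream of
the polarity-pooling complex cells is contrast-sign invariant.

The same pipeline is available from the shell:

```bash
fgseg generate --direction inward --polarity mixed --out display.png
fgseg run --input display.png --report report.json --overlay ownership.png
fgseg experiment --seed 7 --out results/exp     # trials CSV, RF table, ANOVA
```

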