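# qendosomes

Detection and kinetic quantification of fluorescent endosomes in live-cell
microscopy, for pharmacologists who use receptor endocytosis as a functional
readout of agonist activity (GPCR internalization assays with
fluorescent-protein-tagged receptors).

Upon agonist stimulation, receptors translocate from the plasma membrane
into endocytic vesicles that appear as diffraction-limited bright spots
(~0.3 µm) in epifluorescence z-stacks. Counting those spots over time turns
a movie into a pharmacological dose–response experiment — provided the
counting rejects the dominant confound, plasma-membrane fluorescence.

## The algorithm

For each timepoint's z-stack (T×Z×Y×X TIFF):

1. **Smooth** every z-plane with an isotropic Gaussian, σ = 1 px, to
   suppress camera noise.
2. **Project**: per-pixel maximum across z-planes.
3. **Candidates**: strict 8-neighborhood local maxima whose peak is ≥ 90%
   above the local background (median of the 9×9 window perimeter):
   `peak ≥ 1.9 × background`.
4. **Template correlation**: the 9×9 patch around each candidate is
   correlated (Pearson) with a unit 2D Gaussian

   g(x, y) = exp(−(x² + y²) / 2σ²),  σ = 2.30 px,

   the width of an average endosome *after* smoothing (a spot of raw width
   σ = 2.07 px reads √(2.07² + 1²) ≈ 2.30 px, by variance addition under
   Gaussian convolution). Candidates with correlation > 0.75 are accepted.
   The plasma membrane forms ridges of much larger cross-section
   (σ ≈ 5.15 px) which correlate poorly with the round narrow template and
   are rejected.

Per-frame counts, normalized per cell, are then fitted with the sigmoid

y(t) = bottom + (top − bottom) / (1 + 10^((t½ − t)·slope))

giving Emax = top (vesicles/cell), t½ (min) and slope; maximal responses
across agonist concentrations are fitted with a four-parameter logistic on
log10 dose, reported as pEC50. Bell-shaped dose series (response falling at
the highest doses) are flagged.

A synthetic-field generator (`qendosomes.synthetic`) renders ground-truthed
fields — Gaussian spots with the measured width/intensity statistics
(σ ~ N(2.07, 0.53) px, amplitude ~ N(1652, 178) a.f.u.), membrane-like
ridges along synthetic cell boundaries, camera noise — used to benchmark
detection accuracy (`qendosomes.validate`).

## Worked example

```sh
qendosomes simulate --n-endosomes 300 --seed 7 --out field.tif --truth truth.csv
qendosomes detect --input field.tif --layout ZYX --out detections.csv
```

prints `wrote detections.csv (286 detections in 1 frame(s))`: of 300
simulated endosomes, 286 are detected and all 286 match a true spot within
2 px (95.3% accuracy, no false positives).

Fitting a simulated 15-minute time course (4 cells, kinetics
bottom = 0, top = 21.29 vesicles/cell, t½ = 5.02 min, slope = 0.59):

```python
from qendosomes import (SimulationSpec, render_timelapse, detect_endosomes,
                        ImageStack, counts_per_cell, fit_sigmoid)

spec = SimulationSpec(field_shape=(512, 512), n_cells=4, seed=11)
frames = render_timelapse(spec, (0.0, 21.29, 5.02, 0.59), list(range(16)))
counts = [len(detect_endosomes(ImageStack(f.image[None]))) for f in frames]
fit = fit_sigmoid(counts_per_cell(counts, n_cells=4))
print(f"t_half={fit.t_half:.2f} min  Emax={fit.top:.2f}  slope={fit.slope:.2f}")
```

prints `t_half=4.97 min  Emax=19.56  slope=0.65`: the half-time is
recovered to 0.05 min; Emax reads ~8% low because the detector misses a
small fraction of spots (those straddling the membrane ridge or drawn from
the extreme tails of the width distribution).

The fitting layer is sklearn-compatible: `SigmoidRegressor` and
`DoseResponseRegressor` implement `fit`/`predict`/`get_params`, and
`EndosomeDetector` exposes the detection pipeline with fitted attributes
(`detections_`, `candidates_`, `projection_`).

## Layout

- `src/qendosomes/detect.py` — the four-step detection pipeline
- `src/qendosomes/synthetic.py` — ground-truthed field/movie simulation
- `src/qendosomes/validate.py` — truth matching, accuracy curves, parameter sweeps
- `src/qendosomes/kinetics.py` — sigmoid and dose–response fitting, ANOVA helper
- `src/qendosomes/io.py`, `cli.py` — TIFF/CSV/JSON/config I/O and the CLI
- `docs/methods.md` — models, parameter choices, limitations
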