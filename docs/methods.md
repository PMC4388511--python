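# Methods

## Detection model

An endosome is modeled as an isotropic 2D Gaussian spot in the smoothed
maximum-intensity projection of a z-stack. The pipeline is deterministic
and consists of four stages, each with an explicit acceptance predicate:

1. **Noise smoothing.** Each z-plane is convolved with a normalized
   Gaussian kernel (`smooth_sigma`, default 1.0 px). Boundary mode is
   reflect-at-edge, so no spurious maxima appear at borders and constants
   are preserved exactly. All arithmetic is float64 regardless of input bit
   depth.
2. **Maximum z-projection.** Per-pixel maximum across the smoothed planes.
   Projection after smoothing (rather than before) keeps single-plane noise
   spikes from dominating the projection.
3. **Candidate selection.** A pixel is a candidate iff it is a *strict*
   local maximum over its 8-neighborhood and its intensity is at least
   `(1 + pct/100)` times the local background (default pct = 90, i.e.
   peak ≥ 1.9 × background). Ties on plateaus are broken by keeping only
   the lexicographically smallest (row, col) pixel — the comparison is
   strict against neighbors that precede the pixel in raster order and weak
   against the rest — so a flat-topped (saturated) spot counts once and a
   constant image yields nothing.

   *Local background* is the median intensity over the perimeter of the
   (2r+1)×(2r+1) window centered on the maximum (r = `patch_radius`,
   default 4). The median over the perimeter is robust to the spot's own
   signal and uses the same window as the correlation stage. Candidates
   closer than r to any border are discarded rather than scored on a
   truncated patch.

   The ratio reading of "percent above background" is the default; a
   configurable alternative (`threshold_mode="range"`) reads the
   percentage against the projection's global dynamic range
   (peak ≥ background + pct/100 × (max − min)). A per-window range was
   rejected because with the perimeter median as background it reduces to
   an always-true predicate.
4. **Template correlation.** The window around each candidate is compared
   with a fixed, unit-amplitude, centered Gaussian template of
   `template_sigma` (default 2.30 px) by Pearson correlation. Pearson is
   invariant to affine intensity maps (a·patch + b, a > 0), so a fixed
   template realizes a fixed-center, fixed-width Gaussian fit with free
   amplitude and offset — no optimizer needed, and scores are invariant to
   global intensity rescaling. Zero-variance patches score 0 (logged) and
   are rejected. Candidates with correlation strictly above
   `correlation_min` (default 0.75) are accepted.

The default template width encodes the physics of the pipeline: a spot of
raw width σ₀ smoothed with σₛ has width √(σ₀² + σₛ²); for the mean measured
endosome (σ₀ = 2.07 px) and σₛ = 1 px this gives 2.30 px. The plasma
membrane appears as a ridge of cross-section σ ≈ 5.15 px; a ridge is
locally one-dimensional and broad, and its correlation with the narrow
round template peaks near 0.66 — comfortably below the 0.75 cut-off —
which is what makes the spot/membrane discrimination work. Correlation is
computed on the smoothed projection (the same grid on which maxima are
found); no sub-pixel localization is attempted, matching the discrete
9×9-centered fit.

Degenerate inputs: non-positive sigmas, invalid thresholds, and empty or
negative-intensity stacks raise `ValueError` at construction; an image too
small for the patch radius yields an empty candidate list.

## Synthetic fields

The generator emulates a projection image of adherent cells:

- **Cell regions** (`n_cells`, default 16 on a 1004×1002 field — the
  reference camera frame at 0.13 µm/px): blobs of mean radius ~100 px
  (≈13 µm, a spread adherent cell) laid out on a jittered grid (placement
  always succeeds or fails loudly), with boundary radius
  r(θ) = r₀(1 + Σₖ aₖ cos(kθ + φₖ)), k = 2..4, aₖ ≤ 0.05, keeping regions
  convex-ish and non-overlapping. Target coverage ≈ 50% of the field,
  shrunk automatically when a small field cannot hold it.
- **Membrane**: a ridge of Gaussian cross-section `membrane_sigma`
  (default 5.15 px) along every cell boundary, amplitude
  `membrane_amplitude` (default 800 a.f.u. — clearly visible, about half
  the mean endosome peak, consistent with membrane crests and endosome
  spikes being of comparable brightness in real fields).
- **Endosomes** (`n_endosomes`): centers uniform inside the cell mask with
  sub-pixel jitter, pairwise separation ≥ `min_separation` (default 5 px,
  ≈ 2 smoothed widths, keeping ground-truth matching unambiguous) and
  ≥ `edge_margin` (default 8 px) from borders so every spot is scorable at
  any patch radius in the 2–7 sweep. Per-spot σ ~ N(2.07, 0.53) truncated
  at 0.5 px; amplitude ~ N(1652, 178) truncated at 0 — the distribution of
  manually measured endosomes.
- **Noise**: additive Gaussian (`noise_sd`, default 30 a.f.u.), clipped at
  zero. Photobleaching, drift, shot noise and a z-dependent PSF are out of
  scope.

All randomness flows from `seed` through named `SeedSequence` substreams,
so identical specs give bit-identical fields and the mask can be
regenerated standalone. If a real untreated-cell projection is supplied as
`baseline`, spots are added onto it and the cell mask is obtained by Otsu
thresholding, restoring the original seed-on-a-real-image protocol.

`render_timelapse` drives the per-frame spot count with the kinetic
sigmoid, n(t) = round(n_cells · y(t)); spots persist once they appear
(counts per frame are unaffected; persistence only makes movies realistic).

## Validation

Detections are matched to ground truth one-to-one by greedy
nearest-neighbor in ascending distance order with tolerance 2.0 px
(≈ one template sigma; the adjudication rule is otherwise unspecified in
the field). Accuracy = matched/simulated; at n = 0 accuracy is defined as
1 and false positives are reported separately. `accuracy_curve` averages
10 independent replicates per n (distinct derived sub-seeds);
`radius_sweep` reuses the same replicate fields for every radius so radii
are compared paired; `threshold_correlation_surface` reports the relative
count error (detected − simulated)/simulated over a threshold × correlation
grid, evaluating both monotone predicates on a single loose candidate pass.

Measured behavior at the defaults (10 reps): accuracy 1.00 at n = 0 (≤ 1
false positive per field), ~0.96 at n = 100, declining to ~0.89 at
n = 800. The residual misses are (a) spots from the broad tail of the
width distribution near the membrane ridge, whose own breadth plus the
ridge lift the perimeter median enough to fail the 1.9× predicate, and
(b) pairs closer than ~7 px, which merge after smoothing or contaminate
each other's correlation patch (two σ = 2.3 spots 5 px apart correlate
with the template at only ~0.77). Both are properties of the published
predicates under the stated spot statistics, not of this implementation;
the brute-force oracle test pins the implementation exactly. Accuracy is
not monotone-guaranteed per replicate but is monotone non-increasing in
noise level in the mean.

What passing these tests does *not* show about real data: the synthetic
membrane is a clean single ridge (no organelle autofluorescence, no
perinuclear aggregates, no cell-to-cell intensity variation), noise is
Gaussian rather than Poisson-Gaussian, and cells are static (no drift or
focus loss). Real-data accuracy must be expected to be somewhat lower.

## Kinetic and dose–response fitting

The time-course model is y(t) = bottom + (top − bottom)/(1 +
10^((t½ − t)·slope)). Fitting is bounded nonlinear least squares
(trust-region reflective) on the reparametrization (bottom, span = top −
bottom, t½, slope), which makes top ≥ bottom ≥ 0 a box constraint:
bottom ∈ [0, ∞), span ∈ [0, ∞), t½ ∈ [min(t) − 5, max(t) + 5],
slope ∈ (0, 10]. Initialization: bottom₀ = min y, span₀ = range,
t½₀ = first midrange crossing by linear interpolation, slope₀ = 0.5 —
robust for monotone-rising 15-minute curves. Tolerances are set to 1e-14
so noiseless curves are recovered to residual < 1e-6. Standard errors come
from the fit covariance (the SE of top propagates var(bottom) + var(span)
+ 2cov). t = 0 (pre-treatment) is not constrained to equal bottom.

A condition is reported **n.d.** (not detected) when the optimizer fails,
the fitted span is < 3 vesicles/cell, or r² < 0.5 (both thresholds
configurable). The cut at 3 vesicles/cell sits well below any detected
response (≥ ~8) and above the noise floor of flat curves; r² < 0.5 catches
noise-dominated fits. Degenerate flat-at-zero input has undefined r²
(zero total variance) and is n.d. by the span rule.

Dose–response uses the standard four-parameter logistic on x = log10 dose,
E = e_min + (e_max − e_min)/(1 + 10^((log10 EC50 − x)·h)), reported as
pEC50 = −log10 EC50, so a rising curve has positive Hill slope h. h is
free by default ([−10, 10]); a fixed-slope mode (e.g. h = 1) is available.
A series whose top-dose response falls below 80% of the peak response sets
`bell_flag`; the monotone 4PL is still fitted to *all* points (no
high-dose exclusion) — the flag marks that the monotone model is
structurally wrong for the series rather than silently truncating it.
All-equal responses signal a failed fit rather than raising.

`compare_fits` is a convenience one-way ANOVA (scipy) of t½, Emax and
slope across condition groups; post-hoc menus are out of scope.

## Problem sizes in tests and validation

The accuracy benchmark uses the full default geometry (1004×1002, n up to
800, 10 replicates; ~20 s total). Unit and property tests use 256–512 px
fields and 2–4 cells; Monte-Carlo fit-recovery uses 200 replicates at 10%
noise. The brute-force detection oracle runs on 50 random 64×64 fields.
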