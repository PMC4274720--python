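# Methods

## Statistical model

Let `x_j ∈ R^n` be the intensities of grid point *j* across the *n*
spectra. After autoscaling (mean-centring and scaling each kept column to
unit standard deviation with the *n* − 1 denominator), the single-peak
correlation vector

    c_peak = (1/(n−1)) v_peakᵗ X

is, column for column, the Pearson correlation coefficient between the
selected peak's profile and `x_j`. The package computes this identity
two ways — the per-peak route used in production and the full
`C = (1/(n−1)) XᵗX` matrix kept as a small-scale oracle — and the test
suite asserts their equivalence (and agreement with an independent
textbook Pearson computation) to 1e-10.

Modelling assumptions, in decreasing order of importance:

1. **Amplitude co-variation identifies compounds.** All cross-peaks of
   one compound scale with its concentration, so intra-compound
   correlations approach 1 while peaks of independently varying compounds
   decorrelate as n grows. Biologically related compounds (shared
   pathway) correlate, but more weakly than same-compound peaks.
2. **Spectra enter already processed** (Fourier transformed, phased,
   baseline corrected) and on one common acquisition grid. No resampling
   is ever performed; grid mismatches are hard errors.
3. **Chemical-shift variation is small** relative to linewidth, so the
   single most central data point of a cross-peak tracks its amplitude.
   Large shift variation is the method's known failure mode (see
   *Limitations*).

## Pipeline and numerical choices

* **Calibration** finds the maximum within a ppm window around the
  reference (TSP at 0/0 ppm by default, window ±0.25 ppm ¹H, ±5 ppm ¹³C)
  and translates the intensity matrix by a whole number of grid points so
  that maximum lands on the grid point nearest the reference coordinate.
  Translating the data (rather than re-labelling each spectrum's axes)
  keeps every calibrated spectrum on the one shared grid, which stacking
  requires; moving whole points only (no interpolation) guarantees the
  intensity values entering the correlation are never altered. If the
  window maximum is below 5× the robust noise scale the spectrum is
  returned unshifted and flagged `uncalibrated`.
* **Flattening** is f1-major (`column = i1·n_f2 + i2`), recorded in the
  matrix's coordinate map; reconstruction re-introduces zeros at excluded
  columns and is exactly position-true (tested as a round-trip identity).
* **Noise exclusion** keeps a column iff *any* spectrum has |value| ≥
  threshold. Magnitudes rather than signed values are compared because
  processed spectra can carry negative excursions; a `signed=True` option
  restores the signed rule. The advisory threshold is
  `multiplier × MAD` (normal-consistent median absolute deviation of all
  matrix values, multiplier 5 by default) — robust because signal
  occupies a tiny fraction of the grid. The exclusion operation itself
  always takes an explicit threshold.
* **Zero-variance columns** autoscale to all-zeros and are flagged;
  their correlation coefficients are reported as 0 (never NaN), and
  selecting such a column as the peak is an error.
* **Clipping**: coefficients may exceed ±1 by floating-point error only;
  excursions beyond 1e-9 raise instead of clipping silently.
* **Cutoff** is a strict inequality (`> cutoff`); applying two cutoffs
  composes to their maximum, and the uncut plot remains retrievable.
* **Cluster extraction** labels surviving points with 8-connectivity and
  reports each cluster's maximum-coefficient point, since neighbours of a
  real cross-peak correlate almost as well as its centre.
* **Matching** assigns plot peaks to reference peaks greedily
  nearest-first under the tolerance-scaled Chebyshev distance
  (defaults 0.05 ppm ¹H, 0.5 ppm ¹³C, reflecting typical urine shift
  variability), one-to-one, ties broken by higher coefficient then lower
  δ¹H. Reference lists are tiny (≤ 9 peaks), so greedy and optimal
  assignment coincide in practice; unassigned plot peaks are reported as
  `extra`, never folded into `found`.
* **Merging** takes the pointwise maximum of surviving coefficients and
  keeps per-point provenance; single-cross-peak metabolites can be
  injected as unit-value singleton plots. Maximum (rather than sum or
  overlay) keeps merged values interpretable as "best correlation to any
  selected peak".
* **Bruker I/O**: both byte orders and tiled (XDIM) or untiled `2rr`
  layouts are read; exports are always untiled little-endian with
  `NC_proc = 0` and values scaled by 10⁶ (six decimal digits of a
  correlation coefficient survive the integer round trip). OFFSET is
  interpreted as the ppm of the first (left-edge) point,
  `ppm[i] = OFFSET − i·(SW_p/SF)/SI`, applied consistently on read and
  write. The portable HDF5 container stores float64 intensities so
  synthetic ground truth is never quantized, and is written without
  HDF5 timestamps so identical inputs give byte-identical files.

## The synthetic generator

The generator stands in for a multi-patient urine study whose spectra
cannot be redistributed. Defaults define the study conditions and are
fixed:

| parameter | default | rationale |
|---|---|---|
| samples *n* | 50 | typical cohort size for this kind of study |
| grid | 1024 × 512 (F2 × F1), sweeps 16/165 ppm, offsets 4.7/75 ppm | standard processed urine HSQC scheme |
| library | 23 multi-peak metabolites (2–9 cross-peaks, 85 peaks total) + 7 single-peak metabolites | realistic urinary metabolites; one weak long-range peak (phenylacetylglutamine, 2.27/30.4 ppm, amplitude 0.05) |
| concentrations | log-normal, sd(log) = 0.5, independent | strictly positive with a heavy tail, as in urine; dispersion configurable |
| pathway pair | citrate ↔ *trans*-aconitate, log-concentration correlation 0.7 | exercises the intra- vs inter-molecular ordering claim |
| peak shape | 2D Gaussian, sd 0.020 ppm ¹H / 0.40 ppm ¹³C | amplitude co-variation is all the method sees, so the simplest shape suffices; the ¹H width (FWHM ≈ 3 grid points) matches the digital resolution of a window-function-processed 1024-point axis — narrower peaks would be under-sampled and non-physical |
| noise | additive white Gaussian, σ = 0.005 (main peak amplitudes ≈ 0.3–1 per unit concentration) | strong-signal SNR ≈ 10² , long-range-peak SNR ≈ 10 |
| shift jitter | sd (0.005, 0.05) ppm, drawn per (sample, metabolite) | pH/ionic-strength variation moves a metabolite's peaks coherently; 3× preset (`jitter_scale=3`) demonstrates the degradation regime |
| TSP | constant amplitude 0.5 at (0, 0) ppm, jittered like any peak | exercises calibration end-to-end |

Library peak positions: the "selected" cross-peak of each metabolite is
placed at its literature urine shift; companion peaks are synthetic but
chemically plausible, and a validation test enforces minimum separations
(same metabolite: ≥ 0.12 ppm ¹H or ≥ 2.5 ppm ¹³C; across metabolites:
≥ 0.06 ppm ¹H or ≥ 1.3 ppm ¹³C) derived from the linewidth/threshold
geometry so clusters stay resolvable on the default grid.

What the generator deliberately does **not** emulate: J-coupling
multiplet structure, Lorentzian/dispersive lineshapes, phase and baseline
artifacts, water/urea suppression residues, t1 noise ridges, and
peak-position dependence on concentration itself (real pH coupling).
Passing tests therefore demonstrate the statistical machinery — not
robustness to every spectroscopic artifact of real data; in particular
heavily overlapped regions of real urine spectra will lose correlations
that the cleanly separated synthetic library retains.

All randomness flows from one integer seed; per-sample streams are
derived sub-streams, so any single spectrum can be re-rendered
independently and whole datasets are bit-reproducible.

## Problem sizes used in validation

The test suite and the acceptance script run the full default conditions
— n = 50 spectra on the complete 1024 × 512 grid — for the recovery,
pair-ordering and jitter checks (the masked matrix after noise exclusion
keeps only a few thousand of the 524 288 columns, so the correlation
step is cheap). The exact-equivalence oracles run on small random
matrices (n ∈ {3, 5, 10}, K ≤ 200) where the full K × K correlation
matrix is affordable.

## Limitations

* Whole-grid-point calibration cannot correct sub-pixel referencing
  error; residual sub-pixel offsets act as extra effective jitter.
* Large chemical-shift variation lowers intra-metabolite correlation
  (measured by the 3× jitter preset: mean intra-metabolite correlation
  drops and, far enough, peaks fall below any useful cutoff). Peak
  alignment is out of scope here.
* The noise-exclusion rule is a column-wise any-sample test; a single
  spiky artifact in one spectrum keeps its column.
* Correlation plots identify co-varying signals, not structures:
  distinguishing isomers or resolving heavily overlapped peaks still
  requires reference data or further experiments.
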