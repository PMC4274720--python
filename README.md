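# hsqcstocsy

Statistical correlation of series of 2D ¹H-¹³C HSQC NMR spectra for
unambiguous metabolite identification in complex mixtures such as urine.

## The problem and the method

A single HSQC spectrum of a biofluid contains hundreds of overlapping
cross-peaks from dozens of metabolites, and nothing in one spectrum says
which peaks belong to which compound. Across a *series* of spectra of
related samples, however, all cross-peaks of one compound rise and fall
together with its concentration. This package exploits that
(STOCSY-style) statistical signature on 2D data.

Each of the *n* spectra is flattened to a row vector encoding both
chemical-shift dimensions, giving a data matrix of size *n* × *K*.
Columns where no spectrum rises above a noise threshold are dropped, and
the remaining matrix **X** is autoscaled (each column mean-centred and
scaled to unit standard deviation, *n* − 1 denominator). Rather than the
complete correlation matrix

    C = (1/(n−1)) Xᵗ X,

one cross-peak of interest **v**_peak is selected and only its
correlations are computed:

    c_peak = (1/(n−1)) v_peakᵗ X.

Because **X** is autoscaled, `c_peak` is exactly the vector of Pearson
correlation coefficients between the selected peak's intensity profile
and every other grid point's profile. Re-introducing zeros at the
noise-excluded points and reshaping onto the grid gives a 2D
*correlation plot*; keeping only coefficients above a high cutoff
(e.g. > 0.9) yields a sub-spectrum resembling the pure compound —
including cross-peaks from isolated spin systems and weak long-range
(HMBC-like) peaks, which no through-bond experiment chain could connect.

The package reads and writes processed Bruker data (`2rr` +
`procs`/`proc2s`), provides a portable HDF5 container for whole datasets,
snaps user-selected coordinates to local maxima, collapses surviving
points into 8-connected clusters, scores plots against reference peak
lists (found/expected/extra), and merges per-metabolite plots into a
constructed spectrum. Because real patient datasets of this kind are
rarely shareable, a first-class synthetic generator produces urine-like
multi-sample datasets with known ground truth (log-normal concentrations,
chemical-shift jitter, long-range peaks, a TSP reference peak) on which
every claim is tested.

## Worked example

Generate the default synthetic study (50 spectra, 1024 × 512 grid,
23-metabolite library), build the noise-masked matrix, and correlate from
the phenylacetylglutamine-like peak at 7.41/131.5 ppm:

```python
from hsqcstocsy import synthetic, dataset, correlation, identify

model = synthetic.default_model(n_samples=50, seed=1)
grid = synthetic.default_grid()
bundle = synthetic.generate_dataset(model, grid)
spectra = [dataset.calibrate_to_reference(s) for s in bundle.spectra]
X = dataset.stack(spectra)
threshold = dataset.suggest_noise_threshold(X)
X = dataset.apply_noise_exclusion(X, threshold)
print(f"noise threshold {threshold:.4f}: kept {X.k_kept} of {X.k_total} grid points")

selection = identify.select_peak(X, (7.41, 131.5))
plot = correlation.correlate_peak(correlation.autoscale(X), selection)
plot = correlation.apply_cutoff(plot, 0.9)
print(identify.extract_plot_peaks(plot).round(3).to_string(index=False))
```

which prints

```
noise threshold 0.0252: kept 5333 of 524288 grid points
 ppm_h   ppm_c  coefficient
 7.403 131.396        1.000
 2.262  33.750        1.000
 7.341 128.496        0.999
 1.966  27.949        0.997
 4.169  55.342        0.996
 7.278 125.918        0.995
 3.669  44.707        0.993
 2.466  34.717        0.990
 2.262  30.205        0.990
```

The nine surviving clusters are exactly the nine planted cross-peaks of
the metabolite: the aromatic ring block (7.40/7.34/7.28), the isolated
aliphatic block, and — at 2.26/30.2 ppm — the weak long-range peak, all
correlating above 0.99 with the selected coordinate even though the two
spin systems share no scalar coupling.

The same pipeline is available from the shell:

```sh
hsqcstocsy simulate --n 50 --seed 1 --out data.h5
hsqcstocsy calibrate --in data.h5 --out cal.h5
hsqcstocsy mask-noise --in cal.h5 --out matrix.h5
hsqcstocsy correlate --matrix matrix.h5 --peak 7.41,131.5 --cutoff 0.9 \
    --label PAG --out plots/
hsqcstocsy run --config config.yaml   # the whole pipeline from one file
```

Correlation plots are exported both as CSV peak tables and as Bruker
processed directories (coefficients scaled by 10⁶, NC_proc = 0) that
Topspin can display.

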