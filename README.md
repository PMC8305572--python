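# nmrdecon

Fully automated deconvolution of processed 1D ¹H NMR spectra into individual
Lorentzian lines, with closed-form integration and reference-based metabolite
quantification.

In untargeted NMR metabolomics, a single urine or plasma spectrum contains
hundreds to over a thousand overlapping signals. The conventional workaround —
equidistant bucketing — integrates fixed 0.01-ppm windows and mixes every
signal that falls into the same bucket. `nmrdecon` instead decomposes the
measured spectrum into a sum of individual line shapes, so each signal gets
its own integral even when lines overlap, without needing reference spectra
or knowledge of the underlying metabolites.

## Method

Every NMR signal is modelled as a Lorentz curve

    y(x) = A·λ / (λ² + (x − x₀)²)

with area A·π, half width at half height λ, and maximum position x₀ (in
data-point units during fitting). The pipeline:

1. **Preprocessing** — blank the residual water artifact, take absolute
   values, smooth with a 5-point running mean applied twice (suppresses
   noise-induced curvature maxima).
2. **Peak selection** — compute the discrete second derivative y″; every
   index with y″(x) < 0 and y″(x+1) > y″(x) ≤ y″(x−1) is a signal maximum.
   The left/right flank points are the nearest zero crossings, local maxima
   or plateaus of y″, giving one *peak triplet* per signal. Triplets are
   kept when their curvature score exceeds mean + δ·sd of a user-declared
   signal-free region.
3. **Analytic solve** — in reciprocal space 1/y(x) is a parabola, so the
   three triplet points determine (A, λ, x₀) exactly in closed form
   (positions shifted to zero for numerical stability; λ taken in absolute
   value).
4. **Iterative height adjustment** — independent solves overshoot where
   lines overlap, so the measured intensity at each triplet point is
   apportioned among peaks in proportion to their current Lorentzian
   contributions and every system is re-solved; after 10 iterations the
   parameter set with minimal normalized mean squared error (both spectra
   normalized to total integral one) is kept.
5. **Quantification** — each fitted line has the closed-form integral
   A·(arctan((b−x₀)/λ) − arctan(−x₀/λ)) over the b data points; per-proton
   integral ratios against a reference signal of known concentration (TSP,
   or formic acid for plasma) convert areas to concentrations.

## Worked example

`examples/deconvolve_synthetic.py` builds a 16k-point spectrum of five
Lorentzian lines — two of them only 0.006 ppm apart — and deconvolutes it:

```
detected 5 triplets, fitted 5 peaks
normalized MSE: initial 1.570e-08, best 7.633e-13 (iteration 10)

               x0 (ppm)    λ (ppm)       area
        true     1.4800    0.00200     120.00
      fitted     1.4800    0.00200     119.97
        true     3.0500    0.00150      60.00
      fitted     3.0500    0.00150      60.12
        true     3.0560    0.00150      45.00
      fitted     3.0560    0.00150      44.90
```

The MSE dropping by four orders of magnitude shows the height adjustment
redistributing the overlap; the fitted areas of the two overlapping lines
are within 0.3% of truth, which is what makes the downstream concentration
estimates trustworthy. `examples/quantify_dilution_series.py` runs a full
dilution-series validation (slopes within 0.1% of 1, R² ≈ 1), and
`examples/bucketing_comparison.py` contrasts the number of resolved lines
with the 410 buckets that 0.01-ppm binning allots to the 0.50–4.60 ppm
region.

## Command line

```sh
nmrdecon deconvolute <bruker-dir|spectrum.xy> --water-region "4.6 5.0" \
    --noise-region "-1.5 -0.5" --delta 5 --out peaks.csv
nmrdecon quantify --peak-table peaks.csv --assignments assignments.csv \
    --reference tsp --reference-conc 1.0 --out concentrations.csv
nmrdecon simulate --n-peaks 50 --seed 1 --out simulated/
```

Inputs are Bruker processed-data folders (`pdata/<n>/1r` + `procs`) or
two-column `ppm intensity` text. The threshold δ is deliberately a
first-class user input: check the kept-peak count by inspection before
trusting it.

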