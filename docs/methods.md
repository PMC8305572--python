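# Methods

## Model and scope

`nmrdecon` operates on *processed* 1D ¹H spectra: Fourier-transformed,
phase-corrected and baseline-optimized, typically 128k real points over
roughly 14 to −2 ppm at 600 MHz. Acquisition processing (FT, phasing,
baseline, apodization) is explicitly upstream; the package consumes Bruker
processed folders or plain two-column text. All spectra are stored with an
explicit ppm axis, strictly decreasing with index.

Each signal is one Lorentz curve y(x) = A·λ/(λ² + (x − x₀)²) in data-point
units x. Fitting, iteration and integration all happen in point units;
conversion to ppm happens only when reporting. This keeps the integration
border (the number of data points) and the fitted parameters in one
consistent unit system, and because quantification uses only integral
*ratios*, the ppm-per-point factor cancels and never needs to be applied.

The model assumes ideal Lorentzian line shapes. Real spectra deviate
(shimming artifacts, unresolved J-coupling, baseline ripple); the method
still fits one Lorentzian per curvature maximum and absorbs the mismatch
into the residual.

## Preprocessing

Water removal blanks a user-named ppm interval (zeroing + an exclusion
flag, never deleting points, so index arithmetic and the integration border
stay valid). There is deliberately no default water region — the water
position depends on the experiment. Absolute values are taken next, then a
5-point running mean (2 neighbors per side) applied twice. Window edges are
truncated to the available points, which keeps constants invariant and
avoids phantom edge values.

Smoothing exists solely to stabilize *peak selection*: unsmoothed noise
creates spurious curvature maxima. The Lorentzian solves therefore use the
intensities of the **unsmoothed** (water-removed, absolute-value) spectrum
at the detected triplet indices. Fitting against smoothed intensities would
bias each line's area by a λ-dependent factor — the running mean broadens a
λ ≈ 4-point line noticeably while barely touching a 25-point line — which
we measured as up to ~8% area error for the narrowest realistic lines,
directly distorting concentration ratios. Detection on the smoothed, solves
on the raw: both goals are met.

## Peak selection

The discrete second derivative y″[i] = y[i−1] − 2y[i] + y[i+1] (endpoints
zero) drives detection. Centers are indices with y″(x) < 0 and
y″(x+1) > y″(x) ≤ y″(x−1); flank points are found by walking outward to the
nearest zero crossing (y″ ≥ 0), local maximum of y″ along the walk, or
plateau (two consecutive y″ values equal within 1e−12 of the local scale).
A walk that reaches the spectrum edge or a water-excluded point before any
stopping feature discards the triplet — a 3-point system with a missing
flank cannot be solved. Two adjacent peaks may legitimately share a flank
index; each system is solved independently.

### Noise filtering

Each triplet is scored by the curvature magnitude −y″ at its center and
kept iff score > mean + δ·sd of −y″ over a user-declared signal-free
region. Intensity at the center was considered as the score and rejected:
noise triplets riding on the tails of strong lines inherit the tail's
(arbitrarily high) intensity but only noise-scale curvature, so no
intensity threshold can separate them from genuine small signals. Curvature
discriminates exactly this case, and δ stays an interpretable
signal-to-noise multiple.

δ is a user decision, checked by inspection. The procedure we use and
recommend: run the filter at a few δ values and watch the kept-triplet
count. On the 400-line synthetic survey spectrum at 0.1% noise the counts
are ~2500 (δ = 3), ~535 (δ = 5), ~224 (δ = 10) — the elbow near the true
line count sits at δ = 5, which is the value the acceptance script and the
survey tests fix. A too-small δ admits noise triplets (they fit harmlessly
but slow the run); a too-large δ loses weak signals first.

There is no default noise region: no interval is universally signal-free.
A region with fewer than 30 points or containing detected centers triggers
a warning, not an error, since the threshold is then unreliable but the
user may know better.

## Parameter solving and height adjustment

In reciprocal space w(x) = 1/y(x) a Lorentzian is the parabola
w = (x² − 2x₀x + x₀² + λ²)/(Aλ). The solver shifts the triplet positions so
the left point is at zero (numerical stability — at index ~10⁵ the x² terms
would otherwise shred precision), fits the parabola through the three
(x, 1/y) pairs in closed form, and inverts: x₀ = −b/(2a), λ² = c/a − x₀²,
A = 1/(aλ), finally taking |λ|. Degenerate systems — nonpositive
intensities, coincident positions, vanishing curvature of the parabola
(relative threshold 1e−12), nonpositive amplitude — raise a typed error.

Solving each triplet independently double-counts intensity wherever lines
overlap. The height adjustment iterates: with L_k the current curve of peak
k and S = Σ L_j the current superposition, the adjusted target at triplet
point p is ŷ_k(p) = y_exp(p)·L_k(p)/S(p) — proportional apportionment of
the measured intensity, the identity for isolated peaks. All systems are
re-solved simultaneously from their adjusted targets (order-independent,
hence reproducible), the normalized MSE of the full reconstruction is
recorded, and after a fixed number of iterations (default 10) the parameter
set with minimal MSE wins. If S(p) = 0 or the ratio is not finite the
previous target is kept; a peak whose re-solve degenerates mid-iteration
keeps its previous parameters so the MSE trace stays comparable. No
early-stopping tolerance is introduced; the trace is short and minimal-MSE
selection handles the occasional non-monotone excursion the apportionment
can take on crowded spectra.

The MSE normalizes both spectra to total integral one (rectangle rule over
non-excluded points) before averaging squared differences, making the
figure scale-free and comparable across spectra.

## Integration and quantification

The integral of a fitted line over the spectrum [0, b] (b = number of data
points) is A·(arctan((b−x₀)/λ) − arctan(−x₀/λ)); far from the edges this
approaches the full-line area A·π. Truncation at the spectrum edges is not
corrected — for peaks many λ from the edges (the practical case) the error
is negligible, and the closed form is used exactly as stated.

Concentrations come from per-proton integral ratios against a reference
signal of known concentration: c_m = c_ref·(I_m/n_m)/(I_ref/n_ref), with
I summed over all peaks assigned to the signal and n the proton count.
Multiplets are handled by assigning all component peaks to one signal. An
optional per-metabolite multiplicative correction factor (default 1.0)
accommodates differential T₁ relaxation against the reference; no automatic
relaxation correction is attempted.

## Synthetic data

The generator renders sums of Lorentzians on the default 131 072-point,
14 → −2 ppm axis with additive i.i.d. Gaussian noise scaled relative to the
tallest line, deterministic per seed. Line widths default to 0.0005–0.003
ppm (≈0.3–1.8 Hz at 600 MHz), realistic for high-resolution metabolomics.
What it does *not* emulate: J-coupling multiplet structure (peaks are
user-supplied singletons), baseline and phase artifacts, the heavier-tailed
noise of magnitude-mode spectra, and peak-shape distortions. Passing tests
on this generator therefore demonstrate the algorithm's correctness on its
own model assumptions, not robustness to every pathology of real spectra.

Two standard study configurations are built in:

* **Survey spectrum** — 400 lines, areas log-uniform over two orders of
  magnitude, centers uniform in 0.5–9.5 ppm, noise at 0.1% of the tallest
  line. This stresses detection, filtering and overlap resolution at
  realistic crowding; the acceptance script reports its best normalized
  MSE.
* **Latin-square dilution series** — n metabolites as singlets at fixed
  typical chemical shifts, concentrations stepping through a cyclically
  shifted geometric 2-fold dilution (each metabolite visits each level
  exactly once; constant total), plus a constant-concentration TSP-like
  reference singlet at 0.0 ppm. Peak area = concentration × proton count ×
  a fixed response factor. Default noise is 10⁻⁶ of the tallest line:
  this design validates *integration and quantification accuracy* across a
  512-fold concentration range — its real-world counterpart quantified
  every dilution level well above the noise floor — while detection limits
  are probed separately by the survey spectrum.

## Numerical choices

* Bucket counting snaps the (upper−lower)/width quotient to the nearest
  integer when within 1e−9 relative before flooring, so decimal
  region/width pairs are not undercounted by binary floating point.
* Flank plateau tolerance: 1e−12 relative to the local |y″|.
* Degeneracy threshold in the solver: 1e−12 relative to the system scale.
* Bruker intensities are de-scaled by 2^NC_proc; the fixture writer picks
  the exponent so stored int32 values use the full range (~9 significant
  digits survive the round trip).
* Problem sizes in the test suite are chosen so the full suite runs in
  well under a minute except the acceptance checks, which use the full
  131 072-point axis and finish in a few seconds each.

## Known limitations

* One Lorentzian per curvature maximum: a shoulder that produces no
  separate curvature minimum is absorbed into its neighbor.
* Signals weaker than δ times the noise curvature are discarded; δ trades
  sensitivity against false positives and must be checked per study.
* Peaks close to the spectrum edges lose a flank and are dropped.
* Quantification accuracy inherits any systematic line-shape deviation
  (e.g. unresolved couplings) as an integral bias.
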