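"""Deconvolution resolution versus fixed-width bucketing.

Counts how many individual Lorentzian lines the pipeline resolves in a
crowded synthetic aliphatic region and compares that with the number of
0.01-ppm buckets conventional binning would allocate to the same interval.
Deconvolution reports one integral per resolved line, while a bucket mixes
every line that falls inside it.
"""

from nmrdecon.peaks import count_buckets
from nmrdecon.pipeline import deconvolute
from nmrdecon.synthetic import SyntheticSpec, generate, random_peaks

region = (0.50, 4.60)
peaks = random_peaks(
    120, seed=5, x0_range_ppm=region, min_separation_ppm=0.004
)
spectrum, _ = generate(SyntheticSpec(peaks=peaks, n_points=65536, noise_sd=0.0))
result, _, stats = deconvolute(spectrum, noise_region=None, n_iter=10)

n_buckets = count_buckets(region, 0.01)
print(f"region {region[0]}-{region[1]} ppm")
print(f"  lines simulated:            {len(peaks)}")
print(f"  lines resolved by pipeline: {len(result.peaks)}")
print(f"  0.01-ppm buckets:           {n_buckets}")
print("each resolved line gets its own closed-form integral; a bucket sums "
      "everything inside it")
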