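"""Spectrum preprocessing ahead of peak detection.

Three steps, applied in this order: blank the residual water artifact,
convert intensities to absolute values, and smooth with a repeated short
running mean.  Fourier transformation, phasing and baseline correction are
assumed to have happened upstream — the input is already a processed
spectrum.

The smoothing is the classic "2,5-mean": each point is replaced by the mean
of itself and its two neighbors on either side (a 5-point window), and the
pass is repeated.  Its only job is to suppress noise-induced curvature
maxima that would otherwise seed spurious peak triplets; two passes of a
5-point mean are gentle enough to leave metabolite lines (tens of points
wide at typical digital resolution) essentially intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Spectrum1D

__all__ = ["PreprocessParams", "remove_water", "absolute_value", "mean_smooth", "preprocess"]


@dataclass
class PreprocessParams:
    """Preprocessing configuration.

    ``water_region_ppm`` has no default on purpose: the water position
    depends on the experiment, so blanking is only done when the user names
    an interval.
    """

    water_region_ppm: tuple[float, float] | None = None
    smooth_half_width: int = 2
    smooth_passes: int = 2

    def __post_init__(self) -> None:
        if self.water_region_ppm is not None:
            lo, hi = self.water_region_ppm
            if not lo < hi:
                raise ValueError("water region must satisfy lower < upper")
        if self.smooth_half_width < 0:
            raise ValueError("smooth_half_width must be >= 0")
        if self.smooth_passes < 0:
            raise ValueError("smooth_passes must be >= 0")


def remove_water(spectrum: Spectrum1D, region: tuple[float, float]) -> Spectrum1D:
    """Zero out intensities inside a ppm interval and flag them excluded.

    The points stay in place (no deletion) so data-point index arithmetic —
    and with it the integration border — is unaffected; the flag keeps them
    out of peak detection and the normalized-MSE sums.
    """
    lo, hi = min(region), max(region)
    if lo == hi:
        raise ValueError("water region must have nonzero width")
    inside = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if not inside.any():
        raise ValueError(
            f"water region [{lo}, {hi}] ppm contains no data points of the spectrum"
        )
    intensity = spectrum.intensity.copy()
    intensity[inside] = 0.0
    return spectrum.replace(intensity=intensity, excluded=spectrum.excluded | inside)


def absolute_value(spectrum: Spectrum1D) -> Spectrum1D:
    """Replace every intensity by its absolute value (idempotent)."""
    return spectrum.replace(intensity=np.abs(spectrum.intensity))


def _one_smoothing_pass(y: np.ndarray, half_width: int) -> np.ndarray:
    """One running-mean pass with windows truncated at the edges."""
    if half_width == 0:
        return y.copy()
    window = 2 * half_width + 1
    kernel = np.ones(window)
    sums = np.convolve(y, kernel, mode="same")
    counts = np.convolve(np.ones_like(y), kernel, mode="same")
    return sums / counts


def mean_smooth(spectrum: Spectrum1D, half_width: int = 2, passes: int = 2) -> Spectrum1D:
    """Repeated running-mean smoothing.

    Each pass replaces ``y[i]`` by the mean of ``y[i−h .. i+h]``; at the
    spectrum edges the window is truncated to the available points (so a
    constant spectrum stays constant).  Passes are applied sequentially.
    """
    if half_width < 0 or passes < 0:
        raise ValueError("half_width and passes must be >= 0")
    y = spectrum.intensity
    for _ in range(passes):
        y = _one_smoothing_pass(y, half_width)
    return spectrum.replace(intensity=y)


def preprocess(spectrum: Spectrum1D, params: PreprocessParams) -> Spectrum1D:
    """Full preprocessing chain: water removal → absolute value → smoothing."""
    out = spectrum
    if params.water_region_ppm is not None:
        out = remove_water(out, params.water_region_ppm)
    out = absolute_value(out)
    out = mean_smooth(out, params.smooth_half_width, params.smooth_passes)
    return out
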