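"""Curvature-based peak-triplet detection and noise filtering.

A Lorentzian line has strictly negative second derivative between its two
inflection points (at x0 ± λ/√3) and positive curvature beyond them, so
every resolved signal — even one riding on the flank of a neighbor — shows
up as a local minimum of the discrete second derivative.  Detection
therefore works entirely on y″:

1.  *Centers*: indices x with y″(x) < 0 and y″(x+1) > y″(x) ≤ y″(x−1).
2.  *Flanks*: from each center, walk outward to the nearest zero crossing,
    local maximum, or plateau of y″; those two indices complete the triplet
    (left flank, maximum, right flank) from which one Lorentzian can be
    solved analytically.
3.  *Noise filter*: each triplet is scored by the curvature magnitude
    −y″ at its center and kept only if the score exceeds
    ``mean + delta·sd`` of −y″ across a user-declared signal-free region;
    δ is a signal-to-noise multiple the user should sanity-check by
    inspection.  Curvature (rather than raw intensity) is used because
    noise-induced triplets sitting on the tails of strong lines can have
    arbitrarily high intensity yet only noise-scale curvature, so a
    curvature score discriminates them while an intensity score cannot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import Spectrum1D

__all__ = [
    "PeakTriplet",
    "NoiseFilterParams",
    "second_derivative",
    "detect_triplets",
    "score_and_filter",
    "count_buckets",
]

logger = logging.getLogger(__name__)

#: minimum number of points for the noise statistics to be meaningful
_MIN_NOISE_POINTS = 30


@dataclass
class PeakTriplet:
    """The three characteristic points (left flank, maximum, right flank)
    of one detected signal, in data-point indices."""

    i_left: int
    i_middle: int
    i_right: int
    y_left: float
    y_middle: float
    y_right: float
    score: float = float("nan")

    def __post_init__(self) -> None:
        if not self.i_left < self.i_middle < self.i_right:
            raise ValueError("triplet indices must satisfy i_left < i_middle < i_right")

    @property
    def indices(self) -> tuple[int, int, int]:
        return (self.i_left, self.i_middle, self.i_right)

    @property
    def intensities(self) -> tuple[float, float, float]:
        return (self.y_left, self.y_middle, self.y_right)


@dataclass
class NoiseFilterParams:
    """δ-threshold configuration for signal/noise discrimination.

    ``noise_region_ppm`` must be an interval the user declares signal-free;
    there is no default because no region is universally empty.
    """

    delta: float
    noise_region_ppm: tuple[float, float]

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        lo, hi = self.noise_region_ppm
        if not lo < hi:
            raise ValueError("noise region must satisfy lower < upper")


def second_derivative(spectrum: Spectrum1D) -> np.ndarray:
    """Discrete second derivative y″[i] = y[i−1] − 2·y[i] + y[i+1].

    Endpoints are set to 0 (no curvature estimate there); the result has the
    same length as the spectrum and is in data-point units.
    """
    y = spectrum.intensity
    if len(y) < 3:
        raise ValueError("need at least 3 points for a second derivative")
    d2 = np.zeros_like(y)
    d2[1:-1] = y[:-2] - 2.0 * y[1:-1] + y[2:]
    return d2


def _flank_boundary(
    d2: np.ndarray,
    excluded: np.ndarray,
    center: int,
    step: int,
    plateau_tol: float,
) -> int | None:
    """Walk from ``center`` in direction ``step`` (−1 left, +1 right) until a
    stopping feature of the second derivative: a zero crossing (d2 ≥ 0), a
    local maximum along the walk, or a plateau.  Returns the boundary index,
    or None if the walk falls off the spectrum or into an excluded region.
    """
    n = len(d2)
    j = center + step
    while 0 < j < n - 1:
        if excluded[j]:
            return None
        if d2[j] >= 0.0:  # zero crossing reached
            return j
        ahead = j + step
        if excluded[ahead]:
            return None
        if abs(d2[ahead] - d2[j]) <= plateau_tol:  # plateau
            return j
        if d2[ahead] <= d2[j]:  # d2 stops rising: local maximum of y''
            return j
        j = ahead
    return None


def detect_triplets(spectrum: Spectrum1D, d2: np.ndarray | None = None) -> list[PeakTriplet]:
    """Find all peak triplets of a (smoothed) spectrum.

    Centers in water-excluded regions are dropped, as are centers whose
    flank walk reaches the spectrum edge or an excluded point before any
    stopping criterion (no complete 3-point system exists there).  Returned
    triplets are sorted by center index.
    """
    if d2 is None:
        d2 = second_derivative(spectrum)
    y = spectrum.intensity
    excluded = spectrum.excluded

    interior = slice(1, len(d2) - 1)
    mask = (
        (d2[interior] < 0.0)
        & (d2[2:] > d2[interior])
        & (d2[interior] <= d2[:-2])
        & ~excluded[interior]
    )
    centers = np.nonzero(mask)[0] + 1

    triplets: list[PeakTriplet] = []
    for c in centers:
        tol = 1e-12 * max(abs(d2[c]), np.finfo(float).tiny)
        left = _flank_boundary(d2, excluded, int(c), -1, tol)
        right = _flank_boundary(d2, excluded, int(c), +1, tol)
        if left is None or right is None:
            continue
        triplets.append(
            PeakTriplet(
                i_left=left,
                i_middle=int(c),
                i_right=right,
                y_left=float(y[left]),
                y_middle=float(y[c]),
                y_right=float(y[right]),
            )
        )
    return triplets


def score_and_filter(
    triplets: list[PeakTriplet],
    spectrum: Spectrum1D,
    params: NoiseFilterParams,
) -> list[PeakTriplet]:
    """Score triplets and keep those above the noise threshold.

    The score of a triplet is the curvature magnitude −y″ at its center
    (positive for every genuine maximum); the noise statistics are the mean
    and standard deviation of −y″ across the declared signal-free region.
    A triplet survives iff

        score > mean(noise) + delta · sd(noise)

    Order is preserved.  A noise region that is too small or contains
    triplet centers yields a warning (the threshold is then unreliable and
    should be checked by inspection), not an error.
    """
    lo, hi = min(params.noise_region_ppm), max(params.noise_region_ppm)
    in_region = (spectrum.ppm >= lo) & (spectrum.ppm <= hi) & ~spectrum.excluded
    n_noise = int(in_region.sum())
    if n_noise < _MIN_NOISE_POINTS:
        logger.warning(
            "noise region [%g, %g] ppm holds only %d points (< %d); "
            "threshold may be unreliable",
            lo, hi, n_noise, _MIN_NOISE_POINTS,
        )
    centers_inside = [t for t in triplets if in_region[t.i_middle]]
    if centers_inside:
        logger.warning(
            "noise region [%g, %g] ppm contains %d detected peak centers; "
            "check delta by manual inspection",
            lo, hi, len(centers_inside),
        )
    if n_noise == 0:
        raise ValueError("noise region contains no data points")

    curvature = -second_derivative(spectrum)
    noise = curvature[in_region]
    mean = float(np.mean(noise))
    sd = float(np.std(noise))
    threshold = mean + params.delta * sd

    kept = []
    for t in triplets:
        t.score = float(curvature[t.i_middle])
        if t.score > threshold:
            kept.append(t)
    logger.info(
        "noise filter: %d of %d triplets above threshold %.4g (delta=%g)",
        len(kept), len(triplets), threshold, params.delta,
    )
    return kept


def count_buckets(region: tuple[float, float], width: float) -> int:
    """Number of equidistant buckets of ``width`` ppm covering ``region``.

    This is ``floor((upper − lower)/width)``, with the quotient snapped to
    the nearest integer when within 1e−9 relative of it, so that decimal
    interval/width pairs (e.g. a 4.10-ppm region in 0.01-ppm buckets) are
    not thrown off by binary floating point.
    """
    lo, hi = region
    if not lo < hi:
        raise ValueError("region must satisfy lower < upper")
    if width <= 0:
        raise ValueError("bucket width must be positive")
    q = (hi - lo) / width
    if abs(q - round(q)) <= 1e-9 * max(1.0, abs(q)):
        q = round(q)
    return int(math.floor(q))
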