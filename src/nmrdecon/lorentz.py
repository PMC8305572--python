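"""Analytic Lorentzian fitting from peak triplets.

Every NMR signal is modelled as a Lorentz curve

    y(x) = A·λ / (λ² + (x − x0)²)

with area A·π, half width at half height λ, and maximum position x0 (all in
data-point units during fitting; converted to ppm only for reporting).

Because a Lorentzian has three parameters, the three points of a peak
triplet determine it exactly: in reciprocal space w(x) = 1/y(x) is a
parabola a·x² + b·x + c with

    a = 1/(A·λ),   b = −2·x0/(A·λ),   c = (λ² + x0²)/(A·λ),

so fitting the parabola through the three (x, 1/y) pairs and inverting
gives x0 = −b/(2a), λ² = c/a − x0², A = 1/(a·λ) in closed form.  For
numerical stability the triplet positions are shifted so the left point
sits at zero before solving, and λ is taken in absolute value.

Solving each triplet independently overshoots wherever lines overlap — the
superposition of the individual curves is then higher than the measured
spectrum.  The iterative height adjustment corrects this: at every triplet
point the measured intensity is apportioned among the peaks in proportion
to their current Lorentzian contributions, each 3-point system is re-solved
from its apportioned intensities, and the normalized mean squared error of
the summed reconstruction is tracked.  After a fixed number of iterations
the parameter set with minimal MSE wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import Spectrum1D
from .peaks import PeakTriplet

__all__ = [
    "LorentzPeak",
    "DeconvolutionResult",
    "solve_triplet",
    "lorentz_eval",
    "reconstruct",
    "normalized_mse",
    "iterate_fit",
]

logger = logging.getLogger(__name__)

#: relative threshold below which the reciprocal-space parabola is treated
#: as degenerate (no unique Lorentzian through the three points)
_DEGENERACY_RTOL = 1e-12


class DegenerateTripletError(ValueError):
    """The three triplet points do not determine a proper Lorentzian."""


@dataclass
class LorentzPeak:
    """One fitted Lorentz curve.

    ``A`` is the scaling factor (full-line area A·π) in intensity·point
    units; ``lambda_pts``/``x0_pts`` are the half width at half height and
    the maximum position in data-point units, with ppm equivalents filled
    in for reporting once a spectrum axis is known.
    """

    A: float
    lambda_pts: float
    x0_pts: float
    x0_ppm: float | None = None
    lambda_ppm: float | None = None
    peak_id: int = -1
    triplet: PeakTriplet | None = field(default=None, repr=False)
    integral: float | None = None

    @property
    def height(self) -> float:
        """Curve maximum, y(x0) = A/λ."""
        return self.A / self.lambda_pts

    @property
    def area(self) -> float:
        """Full-line area, A·π."""
        return self.A * np.pi


@dataclass
class DeconvolutionResult:
    """All fitted peaks plus the per-iteration MSE trace.

    ``mse_trace[0]`` is the MSE of the initial independent solves;
    ``best_iteration`` indexes the minimal entry, and ``peaks`` /
    ``reconstruction`` correspond to that iteration.
    """

    peaks: list[LorentzPeak]
    mse_trace: list[float]
    best_iteration: int
    reconstruction: np.ndarray

    def __post_init__(self) -> None:
        if self.mse_trace and self.best_iteration != int(np.argmin(self.mse_trace)):
            raise ValueError("best_iteration must index the minimal MSE")


def _solve_points(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Solve one 3-point system; returns (A, lambda, x0) in point units.

    Raises :class:`DegenerateTripletError` when no proper Lorentzian passes
    through the points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(set(x.tolist())) != 3:
        raise DegenerateTripletError("triplet positions must be three distinct values")
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise DegenerateTripletError("triplet intensities must be positive and finite")

    # shift so the left point is at zero (numerical stability of the solve)
    dx = x[0]
    xs = x - dx
    w = 1.0 / y

    # parabola w = a·t² + b·t + c through (0, w0), (t1, w1), (t2, w2)
    c = w[0]
    t1, t2 = xs[1], xs[2]
    det = t1 * t2 * (t1 - t2)
    rhs1 = w[1] - c
    rhs2 = w[2] - c
    scale = max(abs(t1), abs(t2)) ** 3
    if abs(det) <= _DEGENERACY_RTOL * scale:
        raise DegenerateTripletError("collinear triplet positions")
    a = (rhs1 * t2 - rhs2 * t1) / det
    b = (rhs2 * t1 * t1 - rhs1 * t2 * t2) / det

    w_scale = max(abs(c), abs(a * t2 * t2), abs(b * t2), np.finfo(float).tiny)
    if abs(a) <= _DEGENERACY_RTOL * w_scale / max(t2 * t2, 1.0):
        raise DegenerateTripletError("flat reciprocal parabola (no curvature)")

    x0s = -b / (2.0 * a)
    lam_sq = c / a - x0s * x0s
    lam = float(np.sqrt(abs(lam_sq)))  # |λ|: robustness adjustment
    if lam == 0.0 or not np.isfinite(lam):
        raise DegenerateTripletError("zero or non-finite line width")
    A = 1.0 / (a * lam)
    if not np.isfinite(A) or A <= 0.0:
        raise DegenerateTripletError("non-positive amplitude")
    return float(A), lam, float(x0s + dx)


def solve_triplet(triplet: PeakTriplet) -> LorentzPeak:
    """Solve the 3-point Lorentz system of one peak triplet exactly.

    The returned parameters satisfy y_p = A·λ/(λ² + (x_p − x0)²) at all
    three triplet points (up to round-off).
    """
    A, lam, x0 = _solve_points(
        np.array(triplet.indices, dtype=float),
        np.array(triplet.intensities, dtype=float),
    )
    return LorentzPeak(A=A, lambda_pts=lam, x0_pts=x0, triplet=triplet)


def lorentz_eval(peak: LorentzPeak, positions: np.ndarray) -> np.ndarray:
    """Evaluate the Lorentz curve at the given data-point positions."""
    x = np.asarray(positions, dtype=float)
    lam = peak.lambda_pts
    return peak.A * lam / (lam * lam + (x - peak.x0_pts) ** 2)


def reconstruct(peaks: list[LorentzPeak], spectrum: Spectrum1D) -> np.ndarray:
    """Sum of all fitted Lorentz curves on the spectrum's point grid.

    Water-excluded points are set to zero, mirroring the blanked
    experimental intensities there.
    """
    positions = np.arange(spectrum.n_points, dtype=float)
    total = np.zeros(spectrum.n_points)
    for pk in peaks:
        total += lorentz_eval(pk, positions)
    total[spectrum.excluded] = 0.0
    return total


def normalized_mse(experimental: Spectrum1D, reconstruction: np.ndarray) -> float:
    """Mean squared difference after normalizing both to total integral one.

    Integrals are rectangle-rule sums in point units over the non-excluded
    points; excluded (water) points are omitted from both the normalization
    and the mean.
    """
    mask = ~experimental.excluded
    y = experimental.intensity[mask]
    r = np.asarray(reconstruction, dtype=float)[mask]
    sy, sr = y.sum(), r.sum()
    if sy == 0 or sr == 0:
        raise ValueError("cannot normalize a zero-integral spectrum")
    diff = y / sy - r / sr
    return float(np.mean(diff * diff))


def _to_ppm(peaks: list[LorentzPeak], spectrum: Spectrum1D) -> None:
    step = spectrum.ppm_per_point
    for i, pk in enumerate(peaks):
        pk.peak_id = i
        pk.x0_ppm = float(spectrum.index_to_ppm(pk.x0_pts))
        pk.lambda_ppm = pk.lambda_pts * step


def iterate_fit(
    spectrum: Spectrum1D,
    triplets: list[PeakTriplet],
    n_iter: int = 10,
) -> DeconvolutionResult:
    """Fit all triplets and refine by iterative height adjustment.

    Iteration 0 solves every triplet independently from the measured
    intensities.  Each subsequent iteration apportions the measured
    intensity at every triplet point among the peaks in proportion to their
    current Lorentzian contributions,

        ŷ_k(p) = y_exp(p) · L_k(p) / Σ_j L_j(p),

    and re-solves every 3-point system from its apportioned intensities
    (all peaks updated simultaneously, so the result is order-independent).
    The normalized MSE of the summed reconstruction is recorded after every
    iteration and the parameter set with minimal MSE is returned.

    A triplet that is degenerate at iteration 0 is dropped with a warning;
    one that becomes degenerate mid-iteration keeps its previous parameters
    so the MSE trace stays comparable across iterations.
    """
    if not triplets:
        raise ValueError("no triplets to fit")
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")

    solved: list[tuple[PeakTriplet, LorentzPeak]] = []
    for t in triplets:
        try:
            solved.append((t, solve_triplet(t)))
        except DegenerateTripletError as exc:
            logger.warning("dropping degenerate triplet at index %d: %s", t.i_middle, exc)
    if not solved:
        raise ValueError("no fittable peaks: every triplet was degenerate")

    kept_triplets = [t for t, _ in solved]
    peaks = [pk for _, pk in solved]
    K = len(peaks)

    # triplet geometry, fixed across iterations
    points = np.array([t.indices for t in kept_triplets], dtype=float)  # (K, 3)
    y_exp = np.array([t.intensities for t in kept_triplets], dtype=float)  # (K, 3)
    targets = y_exp.copy()  # current apportioned intensities

    def params_array(ps: list[LorentzPeak]) -> np.ndarray:
        return np.array([[p.A, p.lambda_pts, p.x0_pts] for p in ps])

    def eval_all_at(pts: np.ndarray, par: np.ndarray) -> np.ndarray:
        """Sum of all current curves at each entry of ``pts`` (any shape)."""
        flat = pts.ravel()[None, :]  # (1, P)
        A = par[:, 0:1]
        lam = par[:, 1:2]
        x0 = par[:, 2:3]
        contrib = A * lam / (lam * lam + (flat - x0) ** 2)  # (K, P)
        return contrib.sum(axis=0).reshape(pts.shape)

    par = params_array(peaks)
    recon = reconstruct(peaks, spectrum)
    mse_trace = [normalized_mse(spectrum, recon)]
    best = (mse_trace[0], par.copy(), recon.copy())

    for _ in range(n_iter):
        # proportional apportionment of measured intensity at triplet points
        A = par[:, 0:1]
        lam = par[:, 1:2]
        x0 = par[:, 2:3]
        own = A * lam / (lam * lam + (points - x0) ** 2)  # L_k at own points, (K, 3)
        total = eval_all_at(points, par)  # S at the same points, (K, 3)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = own / total
        new_targets = y_exp * ratio
        ok = np.isfinite(new_targets) & (total > 0)
        targets = np.where(ok, new_targets, targets)

        # simultaneous re-solve of all 3-point systems
        new_par = par.copy()
        for k in range(K):
            try:
                new_par[k] = _solve_points(points[k], targets[k])
            except DegenerateTripletError:
                logger.warning(
                    "peak %d degenerate during height adjustment; keeping previous "
                    "parameters", k,
                )
        par = new_par

        tmp = [LorentzPeak(A=p[0], lambda_pts=p[1], x0_pts=p[2]) for p in par]
        recon = reconstruct(tmp, spectrum)
        mse = normalized_mse(spectrum, recon)
        mse_trace.append(mse)
        if mse < best[0]:
            best = (mse, par.copy(), recon.copy())

    best_iteration = int(np.argmin(mse_trace))
    best_par = best[1]
    out_peaks = [
        LorentzPeak(A=p[0], lambda_pts=p[1], x0_pts=p[2], triplet=t)
        for p, t in zip(best_par, kept_triplets)
    ]
    _to_ppm(out_peaks, spectrum)
    return DeconvolutionResult(
        peaks=out_peaks,
        mse_trace=mse_trace,
        best_iteration=best_iteration,
        reconstruction=best[2],
    )
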