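"""Synthetic 1D NMR spectra with known ground truth.

Spectra are generated as sums of Lorentz curves on a 128k-point chemical
shift axis (14 to −2 ppm by default, matching processed 600-MHz ¹H spectra)
plus additive i.i.d. Gaussian noise scaled relative to the tallest peak.
Line widths default to 0.0005–0.003 ppm (≈0.3–1.8 Hz at 600 MHz), realistic
for high-resolution metabolomics spectra.  Everything is deterministic
given the seed, and the true peak list is returned so parameter-recovery
and quantification tests have exact ground truth.

``generate_latin_square`` emulates a dilution-series validation design:
each metabolite is a singlet at a fixed position whose concentration steps
through a cyclically shifted geometric 2-fold dilution series, so every
metabolite takes every level exactly once across samples while the total
concentration stays constant; a reference singlet of constant concentration
(a TSP analogue at 0.0 ppm) is present in every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Spectrum1D

__all__ = [
    "TruePeak",
    "SyntheticSpec",
    "generate",
    "random_peaks",
    "LatinSquareSample",
    "LatinSquareDesign",
    "generate_latin_square",
    "write_bruker_fixture",
]

#: realistic line-width range in ppm (≈0.3–1.8 Hz at 600 MHz)
DEFAULT_LAMBDA_RANGE_PPM = (0.0005, 0.003)


@dataclass
class TruePeak:
    """Ground-truth parameters of one simulated Lorentz line.

    ``area`` is the full-line area A·π in intensity·point units; width and
    position are in ppm.
    """

    area: float
    lambda_ppm: float
    x0_ppm: float

    @property
    def A(self) -> float:
        return self.area / np.pi


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic spectrum."""

    peaks: list[TruePeak]
    n_points: int = 131072
    ppm_max: float = 14.0
    ppm_min: float = -2.0
    noise_sd: float = 0.0  # relative to the tallest peak of the clean spectrum
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points <= 3:
            raise ValueError("n_points must exceed 3")
        if not self.ppm_min < self.ppm_max:
            raise ValueError("ppm_min must be below ppm_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for pk in self.peaks:
            if pk.lambda_ppm <= 0:
                raise ValueError("all line widths must be positive")
            if not self.ppm_min <= pk.x0_ppm <= self.ppm_max:
                raise ValueError(f"peak at {pk.x0_ppm} ppm outside the axis range")


def generate(spec: SyntheticSpec) -> tuple[Spectrum1D, list[TruePeak]]:
    """Render a synthetic spectrum and return it with its true peak list."""
    n = spec.n_points
    ppm = np.linspace(spec.ppm_max, spec.ppm_min, n)
    step = (spec.ppm_max - spec.ppm_min) / (n - 1)
    x = np.arange(n, dtype=float)

    clean = np.zeros(n)
    for pk in spec.peaks:
        lam_pts = pk.lambda_ppm / step
        x0_pts = (spec.ppm_max - pk.x0_ppm) / step
        clean += pk.A * lam_pts / (lam_pts**2 + (x - x0_pts) ** 2)

    intensity = clean
    if spec.noise_sd > 0 and spec.peaks:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_sd * clean.max()
        intensity = clean + rng.normal(0.0, sd, size=n)

    spectrum = Spectrum1D(
        ppm=ppm,
        intensity=intensity,
        source=f"synthetic(seed={spec.seed}, n_peaks={len(spec.peaks)})",
    )
    return spectrum, list(spec.peaks)


def random_peaks(
    n_peaks: int,
    seed: int,
    area_range: tuple[float, float] = (1.0, 100.0),
    lambda_range_ppm: tuple[float, float] = DEFAULT_LAMBDA_RANGE_PPM,
    x0_range_ppm: tuple[float, float] = (0.5, 9.5),
    min_separation_ppm: float = 0.0,
) -> list[TruePeak]:
    """Draw a random peak list.

    Areas are log-uniform over ``area_range`` (spanning two orders of
    magnitude by default), widths uniform over ``lambda_range_ppm``,
    centers uniform over ``x0_range_ppm``.  With ``min_separation_ppm`` > 0
    centers are rejection-sampled to keep that pairwise distance.
    """
    rng = np.random.default_rng(seed)
    lo_a, hi_a = area_range
    areas = np.exp(rng.uniform(np.log(lo_a), np.log(hi_a), n_peaks))
    lams = rng.uniform(*lambda_range_ppm, n_peaks)

    centers: list[float] = []
    attempts = 0
    while len(centers) < n_peaks:
        c = float(rng.uniform(*x0_range_ppm))
        if min_separation_ppm == 0.0 or all(
            abs(c - c0) >= min_separation_ppm for c0 in centers
        ):
            centers.append(c)
        attempts += 1
        if attempts > 1000 * n_peaks:
            raise RuntimeError("cannot place peaks with the requested separation")

    return [
        TruePeak(area=float(a), lambda_ppm=float(l), x0_ppm=c)
        for a, l, c in zip(areas, lams, centers)
    ]


# ---------------------------------------------------------------------------
# Latin-square dilution design
# ---------------------------------------------------------------------------

#: singlet positions (ppm) and proton counts for the simulated dilution
#: panel — typical urine metabolites with well-separated resonances
_PANEL = [
    ("alanine", 1.48, 3),
    ("acetate", 1.92, 3),
    ("citrate", 2.54, 2),
    ("creatinine", 3.04, 3),
    ("ethanolamine", 3.15, 2),
    ("tmao", 3.27, 9),
    ("taurine", 3.42, 2),
    ("glycine", 3.56, 2),
    ("betaine", 3.90, 2),
    ("histidine", 7.08, 1),
]

_REFERENCE_NAME = "tsp"
_REFERENCE_PPM = 0.0
_REFERENCE_PROTONS = 9

#: integral response in intensity·points per (mmol/L · proton); one global
#: constant, as for a fixed receiver gain
_RESPONSE = 1000.0


@dataclass
class LatinSquareSample:
    spectrum: Spectrum1D
    concentrations: pd.DataFrame  # columns: metabolite, concentration
    true_peaks: list[TruePeak] = field(repr=False, default_factory=list)


@dataclass
class LatinSquareDesign:
    samples: list[LatinSquareSample]
    metabolites: pd.DataFrame  # columns: metabolite, ppm, n_protons
    reference_name: str
    reference_ppm: float
    reference_protons: int
    reference_conc: float


def generate_latin_square(
    n_samples: int,
    n_metabolites: int,
    base_conc: float = 1.0,
    seed: int = 0,
    n_points: int = 131072,
    noise_sd: float = 1e-6,
) -> LatinSquareDesign:
    """Simulate a Latin-square 2-fold dilution series with a constant reference.

    Metabolite m in sample s has concentration ``base_conc / 2**((m+s) % n)``,
    so each metabolite visits each dilution level exactly once and the total
    concentration is the same in every sample.  Peak areas are concentration
    × proton count × a fixed response factor; line widths are drawn once per
    metabolite and shared across samples.  The default noise level is far
    below every dilution level, as in a real high-SNR validation series:
    this design probes integration accuracy, not detection limits.
    """
    if n_samples != n_metabolites:
        raise ValueError("a Latin square needs n_samples == n_metabolites")
    if not 1 <= n_metabolites <= len(_PANEL):
        raise ValueError(f"n_metabolites must be in 1..{len(_PANEL)}")
    if base_conc <= 0:
        raise ValueError("base_conc must be positive")

    rng = np.random.default_rng(seed)
    panel = _PANEL[:n_metabolites]
    lam_lo, lam_hi = DEFAULT_LAMBDA_RANGE_PPM
    lams = rng.uniform(lam_lo, lam_hi, n_metabolites + 1)  # last one: reference

    samples = []
    for s in range(n_samples):
        peaks = []
        rows = []
        for m, (name, pos, protons) in enumerate(panel):
            conc = base_conc / 2.0 ** ((m + s) % n_metabolites)
            peaks.append(
                TruePeak(area=_RESPONSE * conc * protons, lambda_ppm=float(lams[m]), x0_ppm=pos)
            )
            rows.append({"metabolite": name, "concentration": conc})
        peaks.append(
            TruePeak(
                area=_RESPONSE * base_conc * _REFERENCE_PROTONS,
                lambda_ppm=float(lams[-1]),
                x0_ppm=_REFERENCE_PPM,
            )
        )
        spec = SyntheticSpec(
            peaks=peaks,
            n_points=n_points,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        spectrum, truth = generate(spec)
        samples.append(
            LatinSquareSample(
                spectrum=spectrum,
                concentrations=pd.DataFrame(rows),
                true_peaks=truth,
            )
        )

    metabolites = pd.DataFrame(
        [{"metabolite": n, "ppm": p, "n_protons": h} for n, p, h in panel]
    )
    return LatinSquareDesign(
        samples=samples,
        metabolites=metabolites,
        reference_name=_REFERENCE_NAME,
        reference_ppm=_REFERENCE_PPM,
        reference_protons=_REFERENCE_PROTONS,
        reference_conc=base_conc,
    )


# ---------------------------------------------------------------------------
# Fixture writers
# ---------------------------------------------------------------------------

def write_bruker_fixture(spectrum: Spectrum1D, path: str | Path, sf_mhz: float = 600.13) -> Path:
    """Write a spectrum as a minimal Bruker processed-data folder.

    Creates ``<path>/pdata/1/{1r,procs}`` with little-endian int32 data and
    the power-of-two scaling exponent chosen so the stored integers use the
    full int32 range.  Intended for exercising the Bruker reader with known
    content.
    """
    pdir = Path(path) / "pdata" / "1"
    pdir.mkdir(parents=True, exist_ok=True)

    y = spectrum.intensity
    max_abs = float(np.max(np.abs(y))) if len(y) else 0.0
    if max_abs == 0.0:
        nc = 0
    else:
        nc = int(np.ceil(np.log2(max_abs))) - 30
    stored = np.round(y / 2.0**nc).astype("<i4")

    n = spectrum.n_points
    step = spectrum.ppm_per_point
    sweep_ppm = step * n
    offset = float(spectrum.ppm[0])
    if spectrum.spectrometer_freq_hz:
        sf_mhz = spectrum.spectrometer_freq_hz / 1e6

    stored.tofile(pdir / "1r")
    with open(pdir / "procs", "w") as fh:
        fh.write("##TITLE= Parameter file, synthetic fixture\n")
        fh.write("##$BYTORDP= 0\n")
        fh.write("##$DTYPP= 0\n")
        fh.write(f"##$NC_proc= {nc}\n")
        fh.write(f"##$OFFSET= {offset!r}\n")
        fh.write(f"##$SF= {sf_mhz!r}\n")
        fh.write(f"##$SI= {n}\n")
        fh.write(f"##$SW_p= {sweep_ppm * sf_mhz!r}\n")
        fh.write("##END=\n")
    return Path(path)
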