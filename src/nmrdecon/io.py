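"""Reading and writing 1D NMR spectra and peak tables.

Two input routes are supported and both produce the same in-memory object:

* Bruker processed-data folders — the ``1r`` intensity binary plus the
  ``procs`` parameter file of a processed 1D dataset.  Only processed real
  data are read; raw FIDs and 2D data are out of scope.
* Generic two-column text — ``ppm  intensity`` rows in any order.

The chemical-shift axis is always stored explicitly, strictly decreasing
with index (index 0 = highest ppm, the conventional left edge of a plotted
spectrum), so downstream code never needs to know where a spectrum came
from.  All peak fitting happens in data-point units; the axis is used only
to convert fitted positions and widths back to ppm for reporting.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .lorentz import DeconvolutionResult

__all__ = [
    "Spectrum1D",
    "read_bruker",
    "read_xy",
    "write_xy",
    "write_peak_table",
    "read_peak_table",
]


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


@dataclass
class Spectrum1D:
    """A processed (Fourier-transformed, phased, baseline-corrected) 1D spectrum.

    Parameters
    ----------
    ppm
        Chemical shifts in ppm, strictly decreasing with index.
    intensity
        Real intensities, same length as ``ppm``.
    spectrometer_freq_hz
        Proton resonance frequency in Hz (metadata only).
    source
        Provenance string (file path or generator description).
    excluded
        Boolean mask of points blanked by water-artifact removal; these are
        ignored by peak detection and by the normalized-MSE computation.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    spectrometer_freq_hz: float | None = None
    source: str = ""
    excluded: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D vectors")
        if len(self.ppm) != len(self.intensity):
            raise ValueError("ppm and intensity differ in length")
        if len(self.ppm) <= 3:
            raise ValueError("a spectrum needs more than 3 data points")
        if not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly decreasing with index")
        if self.excluded is None:
            self.excluded = np.zeros(len(self.ppm), dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if len(self.excluded) != len(self.ppm):
                raise ValueError("excluded mask length mismatch")

    @property
    def n_points(self) -> int:
        return len(self.ppm)

    @property
    def ppm_per_point(self) -> float:
        """Mean axis step (positive), used for point↔ppm conversions."""
        return float((self.ppm[0] - self.ppm[-1]) / (self.n_points - 1))

    def index_to_ppm(self, index: np.ndarray | float) -> np.ndarray | float:
        """Convert (fractional) data-point indices to ppm."""
        return self.ppm[0] - np.asarray(index, dtype=float) * self.ppm_per_point

    def ppm_to_index(self, ppm: np.ndarray | float) -> np.ndarray | float:
        """Convert ppm values to (fractional) data-point indices."""
        return (self.ppm[0] - np.asarray(ppm, dtype=float)) / self.ppm_per_point

    def replace(self, **changes) -> "Spectrum1D":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# Bruker processed data
# ---------------------------------------------------------------------------

def _parse_procs(path: Path) -> dict:
    """Parse a JCAMP-style ``procs`` parameter file into a flat dict."""
    params: dict[str, str] = {}
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##$") and "=" in line:
                key, _, value = line[3:].partition("=")
                params[key.strip()] = value.strip()
    return params


def _procs_float(params: dict, key: str, path: Path) -> float:
    try:
        return float(params[key])
    except KeyError:
        raise FormatError(f"{path}: parameter {key} missing from procs") from None
    except ValueError:
        raise FormatError(f"{path}: parameter {key} is not numeric") from None


def read_bruker(path: str | os.PathLike, proc_no: int = 1) -> Spectrum1D:
    """Read a Bruker processed 1D dataset (``1r`` + ``procs``).

    ``path`` may point either at the dataset root (containing
    ``pdata/<proc_no>/``) or directly at a processed-data folder holding
    ``1r`` and ``procs``.

    The ppm axis is reconstructed from the stored offset (left-edge ppm),
    sweep width and size as ``ppm[i] = offset − i·sweep_ppm/size``, and
    intensities are de-scaled by the stored power-of-two exponent
    (``NC_proc``).
    """
    root = Path(path)
    pdir = root / "pdata" / str(proc_no)
    if not (pdir / "procs").exists():
        pdir = root
    procs_path = pdir / "procs"
    data_path = pdir / "1r"
    if not procs_path.exists() or not data_path.exists():
        raise FormatError(f"{path}: not a Bruker processed dataset (missing 1r/procs)")

    params = _parse_procs(procs_path)
    size = int(_procs_float(params, "SI", procs_path))
    offset = _procs_float(params, "OFFSET", procs_path)
    sw_hz = _procs_float(params, "SW_p", procs_path)
    sf_mhz = _procs_float(params, "SF", procs_path)
    nc_proc = int(_procs_float(params, "NC_proc", procs_path))
    byte_order = int(params.get("BYTORDP", "0"))
    dtypp = int(params.get("DTYPP", "0"))

    if dtypp == 2:
        dtype = np.dtype("<f8" if byte_order == 0 else ">f8")
    else:
        dtype = np.dtype("<i4" if byte_order == 0 else ">i4")
    raw = np.fromfile(data_path, dtype=dtype)
    if len(raw) != size:
        raise FormatError(
            f"{data_path}: declared size {size} but file holds {len(raw)} points"
        )

    sweep_ppm = sw_hz / sf_mhz  # Hz / MHz -> ppm
    ppm = offset - np.arange(size) * (sweep_ppm / size)
    intensity = raw.astype(float) * 2.0 ** nc_proc
    return Spectrum1D(
        ppm=ppm,
        intensity=intensity,
        spectrometer_freq_hz=sf_mhz * 1e6,
        source=str(data_path),
    )


# ---------------------------------------------------------------------------
# Two-column text
# ---------------------------------------------------------------------------

def read_xy(path: str | os.PathLike) -> Spectrum1D:
    """Read a two-column ``ppm intensity`` text file (rows in any order)."""
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric or malformed rows ({exc})") from exc
    if data.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns, found {data.shape[1]}")
    if data.shape[0] < 4:
        raise FormatError(f"{path}: a spectrum needs at least 4 rows")
    ppm, intensity = data[:, 0], data[:, 1]
    if len(np.unique(ppm)) != len(ppm):
        raise FormatError(f"{path}: duplicate ppm values")
    order = np.argsort(ppm)[::-1]  # decreasing ppm
    return Spectrum1D(ppm=ppm[order], intensity=intensity[order], source=str(path))


def write_xy(spectrum: Spectrum1D, path: str | os.PathLike) -> None:
    """Write a spectrum as two-column text at full double precision."""
    np.savetxt(path, np.column_stack([spectrum.ppm, spectrum.intensity]), fmt="%.17g")


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = [
    "peak_id",
    "x0_ppm",
    "lambda_ppm",
    "A",
    "x0_pts",
    "lambda_pts",
    "integral_closed_form",
    "i_left",
    "i_middle",
    "i_right",
]


def write_peak_table(
    result: "DeconvolutionResult",
    path: str | os.PathLike,
    run_params: dict | None = None,
) -> None:
    """Write fitted peaks as CSV plus a sidecar JSON with run parameters.

    The CSV holds one row per peak; the JSON (same stem, ``.json`` suffix)
    records everything needed to reproduce the run (noise threshold delta,
    iteration count, water/noise regions, seed, spectrum size).
    """
    path = Path(path)
    rows = []
    for pk in result.peaks:
        rows.append(
            {
                "peak_id": pk.peak_id,
                "x0_ppm": pk.x0_ppm,
                "lambda_ppm": pk.lambda_ppm,
                "A": pk.A,
                "x0_pts": pk.x0_pts,
                "lambda_pts": pk.lambda_pts,
                "integral_closed_form": pk.integral,
                "i_left": pk.triplet.i_left if pk.triplet else -1,
                "i_middle": pk.triplet.i_middle if pk.triplet else -1,
                "i_right": pk.triplet.i_right if pk.triplet else -1,
            }
        )
    frame = pd.DataFrame(rows, columns=_PEAK_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.17g")

    meta = dict(run_params or {})
    meta.setdefault("n_peaks", len(result.peaks))
    meta.setdefault("mse_trace", [float(v) for v in result.mse_trace])
    meta.setdefault("best_iteration", int(result.best_iteration))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_peak_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a peak-table CSV written by :func:`write_peak_table`."""
    frame = pd.read_csv(path)
    missing = set(_PEAK_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing peak-table columns {sorted(missing)}")
    return frame
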