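"""Reading, validating, blank-correcting and resampling UV-Vis absorbance spectra.

Spectra are plain two-column tables (wavelength in nm, absorbance in AU) or
"wide" tables (one wavelength column, one absorbance column per replicate),
as exported by common spectrophotometer software. All downstream index
calculations assume the canonical grid: 200-800 nm inclusive at 1 nm steps.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumFormatError",
    "GridMismatchError",
    "ExtrapolationError",
    "CANONICAL_START",
    "CANONICAL_STOP",
    "CANONICAL_STEP",
    "canonical_grid",
    "read_spectrum",
    "write_spectrum",
    "blank_correct",
    "resample_to_grid",
]

# Canonical wavelength grid used by every index computation: 200-800 nm at 1 nm.
CANONICAL_START = 200.0
CANONICAL_STOP = 800.0
CANONICAL_STEP = 1.0

# Wavelengths a UV-Vis instrument can plausibly report.
_WL_MIN, _WL_MAX = 190.0, 1100.0

# Blank correction leaving residuals below this is suspicious (bad blank).
_NEGATIVE_WARN_AU = -0.005


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file cannot be parsed or violates invariants."""


class GridMismatchError(ValueError):
    """Raised when two spectra that must share a wavelength grid do not."""


class ExtrapolationError(ValueError):
    """Raised when a resampling request falls outside the measured range."""


def canonical_grid() -> np.ndarray:
    """Return the canonical 200-800 nm, 1 nm wavelength grid."""
    n = int(round((CANONICAL_STOP - CANONICAL_START) / CANONICAL_STEP)) + 1
    return CANONICAL_START + CANONICAL_STEP * np.arange(n)


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace on an explicit wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelengths in nm, all within 190-1100 nm.
    absorbance
        Absorbance in AU, same length as ``wavelengths``, all finite.
    sample_id, replicate_id
        Identity of the measured test portion.
    pathlength_cm
        Cuvette pathlength; the method is defined for 1 cm cells, other
        values are stored but trigger a warning.
    toc_ppm_c
        Optional total organic carbon of the measured dilution, in ppm C.
    is_normalized
        True once the trace has been divided by its maximum absorbance.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    replicate_id: str = ""
    pathlength_cm: float = 1.0
    toc_ppm_c: float | None = None
    is_normalized: bool = False

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise SpectrumFormatError(
                "wavelengths and absorbance must be 1-D arrays of equal length"
            )
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise SpectrumFormatError("wavelengths must be strictly increasing")
        if wl.size and (wl[0] < _WL_MIN or wl[-1] > _WL_MAX):
            raise SpectrumFormatError(
                f"wavelengths must lie within [{_WL_MIN:g}, {_WL_MAX:g}] nm"
            )
        if not np.all(np.isfinite(ab)):
            raise SpectrumFormatError("absorbance values must be finite")
        if self.pathlength_cm <= 0:
            raise SpectrumFormatError("pathlength_cm must be positive")
        if self.pathlength_cm != 1.0:
            warnings.warn(
                f"pathlength {self.pathlength_cm} cm != 1 cm; the decision "
                "thresholds were established for 1 cm cuvettes",
                stacklevel=2,
            )
        if self.toc_ppm_c is not None and self.toc_ppm_c <= 0:
            raise SpectrumFormatError("toc_ppm_c must be positive when given")
        if self.is_normalized and wl.size:
            if abs(ab.max() - 1.0) > 1e-9:
                raise SpectrumFormatError(
                    "is_normalized set but max(absorbance) != 1"
                )

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def value_at(self, wavelength: float) -> float:
        """Exact grid lookup; raises if the wavelength is not a grid point."""
        idx = np.searchsorted(self.wavelengths, wavelength)
        if idx >= len(self) or self.wavelengths[idx] != wavelength:
            raise KeyError(
                f"{wavelength} nm is not on this spectrum's wavelength grid"
            )
        return float(self.absorbance[idx])

    def on_canonical_grid(self) -> bool:
        grid = canonical_grid()
        return len(self) == grid.size and bool(np.array_equal(self.wavelengths, grid))


# --- file parsing -----------------------------------------------------------

_DECIMAL_COMMA = re.compile(r"^-?\d+,\d+$")


def _detect_delimiter(lines: Sequence[str]) -> str:
    # tab and semicolon take precedence on ties: in those dialects a comma
    # inside a field is a decimal comma, which must surface as an error,
    # not silently reshape the table
    counts = {d: 0 for d in ("\t", ";", ",")}
    for line in lines:
        for d in counts:
            counts[d] += line.count(d)
    return max(counts, key=counts.get)


def _parse_fields(fields: list[str], lineno: int) -> list[float] | None:
    """Parse one row. Returns None for a header row (first field non-numeric)."""
    for f in fields:
        if _DECIMAL_COMMA.match(f.strip()):
            raise SpectrumFormatError(
                f"line {lineno}: decimal comma detected ({f.strip()!r}); "
                "export the file with '.' as the decimal separator"
            )
    try:
        first = float(fields[0])
    except ValueError:
        return None  # header / units row
    values = [first]
    for f in fields[1:]:
        f = f.strip()
        if f == "":
            raise SpectrumFormatError(f"line {lineno}: empty absorbance field")
        try:
            values.append(float(f))
        except ValueError:
            raise SpectrumFormatError(
                f"line {lineno}: non-numeric value {f!r}"
            ) from None
    return values


def read_spectrum(
    path: str | Path,
    dialect: str = "two_column",
    sample_id: str | None = None,
) -> list[Spectrum]:
    """Read one or more spectra from a delimited text file.

    ``dialect='two_column'`` expects (wavelength, absorbance) rows and yields
    one spectrum; ``dialect='wide'`` expects a wavelength column followed by
    one column per replicate and yields one spectrum per column. The
    delimiter is auto-detected among comma, semicolon and tab; header rows
    are skipped. Wavelengths arriving out of order are re-sorted with a
    warning; duplicated wavelengths raise (they signal a corrupted export).
    """
    if dialect not in ("two_column", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    text = path.read_text()
    raw_lines = text.splitlines()
    nonempty = [ln for ln in raw_lines if ln.strip()]
    if not nonempty:
        raise SpectrumFormatError(f"{path}: file is empty")
    delim = _detect_delimiter(nonempty[:20])

    rows: list[list[float]] = []
    for lineno, line in enumerate(raw_lines, start=1):
        if not line.strip():
            continue
        fields = line.split(delim)
        if dialect == "two_column" and len(fields) < 2 and len(fields[0].split()) == 2:
            fields = fields[0].split()  # whitespace-delimited fallback
        parsed = _parse_fields(fields, lineno)
        if parsed is None:
            continue
        if len(parsed) < 2:
            raise SpectrumFormatError(
                f"line {lineno}: expected at least 2 columns, got {len(parsed)}"
            )
        if rows and len(parsed) != len(rows[0]):
            raise SpectrumFormatError(
                f"line {lineno}: inconsistent column count "
                f"({len(parsed)} vs {len(rows[0])})"
            )
        rows.append(parsed)

    if len(rows) < 2:
        raise SpectrumFormatError(
            f"{path}: fewer than 2 usable data rows; cannot build a spectrum"
        )

    data = np.asarray(rows, dtype=float)
    wl = data[:, 0]
    uniq, counts = np.unique(wl, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        raise SpectrumFormatError(
            f"{path}: duplicate wavelength {dup:g} nm (corrupted export?)"
        )
    order = np.argsort(wl)
    if not np.array_equal(order, np.arange(wl.size)):
        warnings.warn(f"{path}: wavelengths out of order; re-sorting", stacklevel=2)
        data = data[order]

    sid = sample_id if sample_id is not None else path.stem
    if dialect == "two_column":
        if data.shape[1] > 2:
            raise SpectrumFormatError(
                f"{path}: {data.shape[1]} columns found; use dialect='wide' "
                "for multi-replicate files"
            )
        return [Spectrum(data[:, 0], data[:, 1], sample_id=sid, replicate_id="r1")]
    return [
        Spectrum(data[:, 0], data[:, 1 + j], sample_id=sid, replicate_id=f"r{j + 1}")
        for j in range(data.shape[1] - 1)
    ]


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write the canonical two-column CSV with full float precision."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("wavelength_nm,absorbance\n")
        for wl, ab in zip(s.wavelengths, s.absorbance):
            fh.write(f"{float(wl)!r},{float(ab)!r}\n")


# --- arithmetic -------------------------------------------------------------


def blank_correct(sample: Spectrum, blank: Spectrum) -> Spectrum:
    """Subtract a buffer/DI blank measured on the identical wavelength grid.

    Negative residuals are kept (clipping would bias the slope fits) but a
    warning is issued when they drop below -0.005 AU, which usually means
    the blank does not match the sample matrix.
    """
    if not np.array_equal(sample.wavelengths, blank.wavelengths):
        raise GridMismatchError(
            "sample and blank are on different wavelength grids; "
            "resample_to_grid both onto a common grid first"
        )
    corrected = sample.absorbance - blank.absorbance
    if corrected.min() < _NEGATIVE_WARN_AU:
        warnings.warn(
            f"blank correction produced absorbance down to {corrected.min():.4f} AU; "
            "check the blank",
            stacklevel=2,
        )
    return replace(sample, absorbance=corrected, is_normalized=False)


def resample_to_grid(
    s: Spectrum,
    grid_start: float = CANONICAL_START,
    grid_stop: float = CANONICAL_STOP,
    step: float = CANONICAL_STEP,
) -> Spectrum:
    """Linearly interpolate onto the inclusive grid [start, stop] at ``step``.

    Extrapolation is refused: the requested grid must lie inside the
    measured wavelength range. Query points that coincide with measured
    points reproduce the measured values exactly.
    """
    if grid_start < s.wavelengths[0] or grid_stop > s.wavelengths[-1]:
        raise ExtrapolationError(
            f"requested grid {grid_start:g}-{grid_stop:g} nm exceeds measured "
            f"range {s.wavelengths[0]:g}-{s.wavelengths[-1]:g} nm; refusing to "
            "extrapolate"
        )
    n = int(round((grid_stop - grid_start) / step)) + 1
    grid = grid_start + step * np.arange(n)
    values = np.interp(grid, s.wavelengths, s.absorbance)
    return replace(s, wavelengths=grid, absorbance=values)
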