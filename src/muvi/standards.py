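"""Reference index values for the IHSS fulvic-acid standards.

The screening method scores every sample against two hydrophobic fulvic
acid reference materials from the International Humic Substances Society:
Suwannee River fulvic acid (SRFA) and Pahokee peat fulvic acid (PPFA). The
published index values for both standards ship with the package; users with
their own standard material can derive a reference from replicate spectra
instead.

Note that the bundled values are the published rounded figures; the
low-precision slope entries (e.g. S275 = 0.01 with one significant digit)
limit how precisely percent errors on the slope indices can be reproduced.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .indices import INDEX_NAMES, IndexSet, compute_indices, normalize
from .spectra_io import Spectrum

__all__ = [
    "StandardReference",
    "UnknownStandardError",
    "bundled_standard",
    "available_standards",
    "standard_from_spectra",
    "published_summary",
]


class UnknownStandardError(KeyError):
    """Raised when a requested bundled standard does not exist."""


@dataclass(frozen=True)
class StandardReference:
    """A named fulvic-acid reference with its ten index values."""

    name: str
    indices: IndexSet
    source: str = "bundled_table"  # or "computed_from_spectrum"

    def __post_init__(self) -> None:
        vals = self.indices.as_array()
        if not np.all(vals > 0):
            raise ValueError(
                f"standard {self.name!r} has a non-positive index value; "
                "all indices must be positive to serve as percent-error "
                "denominators"
            )


def _load_table() -> dict[str, IndexSet]:
    out: dict[str, IndexSet] = {}
    ref = resources.files("muvi.data").joinpath("standards_table.csv")
    with ref.open() as fh:
        for row in csv.DictReader(fh):
            name = row.pop("name")
            out[name] = IndexSet.from_dict({k: float(v) for k, v in row.items()})
    return out


def available_standards() -> list[str]:
    return sorted(_load_table())


def bundled_standard(name: str) -> StandardReference:
    """Return the published index values for a bundled standard (SRFA, PPFA)."""
    table = _load_table()
    key = name.upper()
    if key not in table:
        raise UnknownStandardError(
            f"unknown standard {name!r}; available: {', '.join(sorted(table))}"
        )
    return StandardReference(name=key, indices=table[key], source="bundled_table")


def standard_from_spectra(
    spectra: Sequence[Spectrum], name: str
) -> StandardReference:
    """Build a reference from replicate spectra of a user-supplied standard.

    Indices are computed per replicate on the normalized trace and averaged
    field-wise, mirroring how a triplicate 5 ppm C standard preparation is
    reduced to one index set.
    """
    if len(spectra) == 0:
        raise ValueError("at least one replicate spectrum is required")
    per_rep: list[IndexSet] = []
    for s in spectra:
        try:
            ns = s if s.is_normalized else normalize(s)
            per_rep.append(compute_indices(ns))
        except Exception as exc:
            raise RuntimeError(
                f"index computation failed for replicate "
                f"{s.replicate_id or '?'} of standard {name!r}: {exc}"
            ) from exc
    mean = {
        k: float(np.mean([getattr(r, k) for r in per_rep])) for k in INDEX_NAMES
    }
    return StandardReference(
        name=name, indices=IndexSet.from_dict(mean), source="computed_from_spectrum"
    )


def published_summary(phase: int):
    """Published per-sample screening summaries (validation-study results).

    Returns a DataFrame with columns ``sample``, ``a254`` (raw AU),
    ``pe_srfa`` / ``pe_ppfa`` (PE_avg %, ``pe_ppfa`` may be NaN where a
    sample was scored against SRFA only) and the published ``decision``
    string. These are the development (phase 1) and inter-laboratory
    validation (phase 2) result tables; they serve as regression anchors
    for the decision rule.
    """
    import pandas as pd

    if phase not in (1, 2):
        raise ValueError("phase must be 1 or 2")
    ref = resources.files("muvi.data").joinpath(f"phase{phase}_classification.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)
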