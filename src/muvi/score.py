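"""Percent-error scoring, replicate aggregation, and the fulvic decision rule.

A sample's ten index values are compared against each reference standard by
percent error, PE = |v_a - v_s| / v_s * 100, and the equal-weighted mean of
the ten PEs gives one PE_avg per standard. The minimum PE_avg across
standards feeds a dual-cutoff rule:

* screening gate: raw (non-normalized) absorbance at 254 nm must exceed
  0.08 AU — dilute sugars and organic acids fail here even when their
  normalized curve happens to resemble a fulvic one;
* shape gate: the minimum PE_avg must be below 70 %.

A sample is called fulvic only when both gates pass. PE_avg between 60 and
90 % is a gray zone where orthogonal confirmation (FTICR-MS, C-NMR) is
recommended; by default the verdict stays binary and the gray zone is only
flagged.

Also provided is SSSAD, the prior-art screening statistic (squared sum of
scaled absorbance differences over 290-330 nm), for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .indices import INDEX_NAMES, IndexSet
from .spectra_io import Spectrum
from .standards import StandardReference

__all__ = [
    "Thresholds",
    "PEReport",
    "Decision",
    "percent_error",
    "pe_profile",
    "aggregate_replicates",
    "classify",
    "sssad",
    "DEFAULT_THRESHOLDS",
]


@dataclass(frozen=True)
class Thresholds:
    """Decision constants of the screening method.

    ``a254_gate`` is in raw AU (1 cm cell); the remaining values are
    percentages. ``concordance_limit`` is the maximum allowed spread, in
    percentage points, between replicate PE values for any one index.
    """

    a254_gate: float = 0.08
    pe_cutoff: float = 70.0
    gray_low: float = 60.0
    gray_high: float = 90.0
    concordance_limit: float = 20.0

    def __post_init__(self) -> None:
        if not (self.a254_gate > 0 and self.pe_cutoff > 0):
            raise ValueError("thresholds must be positive")
        if not (self.gray_low <= self.pe_cutoff <= self.gray_high):
            raise ValueError("gray-zone bounds must bracket the PE cutoff")


DEFAULT_THRESHOLDS = Thresholds()


def percent_error(va: float, vs: float) -> float:
    """PE = |v_a - v_s| / |v_s| * 100 between a sample and a standard index."""
    if vs == 0:
        raise ZeroDivisionError(
            "percent error undefined: standard index value is zero"
        )
    return abs(va - vs) / abs(vs) * 100.0


@dataclass(frozen=True)
class PEReport:
    """Percent-error profile of one sample against one or more standards.

    ``per_index_pe`` maps standard name -> index name -> PE (%); ``pe_avg``
    holds the equal-weighted mean of the ten PEs per standard and is
    verified on construction; ``pe_avg_min`` is the minimum across
    standards — the quantity the decision rule consumes.
    """

    sample_id: str
    per_index_pe: dict[str, dict[str, float]]
    pe_avg: dict[str, float]
    pe_avg_min: float
    raw_a254: float
    replicate_count: int = 1
    concordance_ok: bool = True

    def __post_init__(self) -> None:
        for std, per_idx in self.per_index_pe.items():
            if set(per_idx) != set(INDEX_NAMES):
                raise ValueError(
                    f"per-index PE map for {std!r} must cover all "
                    f"{len(INDEX_NAMES)} indices"
                )
            if any(v < 0 for v in per_idx.values()):
                raise ValueError("percent errors must be non-negative")
            mean = float(np.mean(list(per_idx.values())))
            if abs(mean - self.pe_avg[std]) > 1e-9:
                raise ValueError(
                    f"pe_avg[{std!r}]={self.pe_avg[std]} inconsistent with "
                    f"mean of per-index PEs {mean}"
                )
        if abs(self.pe_avg_min - min(self.pe_avg.values())) > 1e-9:
            raise ValueError("pe_avg_min inconsistent with pe_avg map")

    @classmethod
    def from_per_index(
        cls,
        sample_id: str,
        per_index_pe: dict[str, dict[str, float]],
        raw_a254: float,
        replicate_count: int = 1,
        concordance_ok: bool = True,
    ) -> "PEReport":
        pe_avg = {
            std: float(np.mean([per_idx[k] for k in INDEX_NAMES]))
            for std, per_idx in per_index_pe.items()
        }
        return cls(
            sample_id=sample_id,
            per_index_pe=per_index_pe,
            pe_avg=pe_avg,
            pe_avg_min=min(pe_avg.values()),
            raw_a254=raw_a254,
            replicate_count=replicate_count,
            concordance_ok=concordance_ok,
        )


def pe_profile(
    sample: IndexSet,
    standards: list[StandardReference],
    raw_a254: float,
    sample_id: str = "",
) -> PEReport:
    """Score one sample index set against each standard.

    Per-standard PE_avg is the equal-weighted mean over the ten indices;
    ``pe_avg_min`` keeps the lower of the two standards, which is the value
    the decision rule uses (a sample near the cutoff passes if it matches
    either standard).
    """
    if not standards:
        raise ValueError("at least one standard is required")
    per_index = {
        std.name: {
            k: percent_error(getattr(sample, k), getattr(std.indices, k))
            for k in INDEX_NAMES
        }
        for std in standards
    }
    return PEReport.from_per_index(sample_id, per_index, raw_a254)


def aggregate_replicates(reports: list[PEReport]) -> PEReport:
    """Collapse replicate PE reports into one per-sample report.

    Per-index PEs are averaged across replicates, then PE_avg is recomputed
    from the averaged values (both steps are linear, so the order does not
    change PE_avg). Concordance fails when any index, against any standard,
    spreads more than the 20-percentage-point limit across replicates —
    flagged, not fatal, since the remedy (re-acquisition) is a lab action.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    ids = {r.sample_id for r in reports}
    if len(ids) > 1:
        raise ValueError(f"mixed sample_ids in replicate set: {sorted(ids)}")
    std_sets = [set(r.per_index_pe) for r in reports]
    if any(s != std_sets[0] for s in std_sets):
        raise ValueError("replicates scored against different standard sets")

    limit = DEFAULT_THRESHOLDS.concordance_limit
    concordant = all(r.concordance_ok for r in reports)
    per_index: dict[str, dict[str, float]] = {}
    for std in std_sets[0]:
        per_index[std] = {}
        for k in INDEX_NAMES:
            vals = [r.per_index_pe[std][k] for r in reports]
            per_index[std][k] = float(np.mean(vals))
            if max(vals) - min(vals) > limit:
                concordant = False
    return PEReport.from_per_index(
        sample_id=reports[0].sample_id,
        per_index_pe=per_index,
        raw_a254=float(np.mean([r.raw_a254 for r in reports])),
        replicate_count=sum(r.replicate_count for r in reports),
        concordance_ok=concordant,
    )


@dataclass(frozen=True)
class Decision:
    """Outcome of the dual-cutoff rule for one sample."""

    verdict: str  # "fulvic" | "non_fulvic" | "indeterminate"
    gate_a254_passed: bool
    gate_pe_passed: bool
    gray_zone: bool
    rationale: str

    def __post_init__(self) -> None:
        if self.verdict not in ("fulvic", "non_fulvic", "indeterminate"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict == "fulvic" and not (
            self.gate_a254_passed and self.gate_pe_passed
        ):
            raise ValueError("fulvic verdict requires both gates to pass")


def classify(
    raw_a254: float,
    pe_avg_min: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    gray_zone_mode: bool = False,
) -> Decision:
    """Apply the dual-cutoff rule to one sample.

    Both cutoffs are strict: the raw 254 nm absorbance must exceed
    ``a254_gate`` (0.08 AU) and the minimum PE_avg must be strictly below
    ``pe_cutoff`` (70 %); boundary values fail. With ``gray_zone_mode`` the
    verdict becomes ``indeterminate`` when PE_avg falls in the 60-90 % gray
    zone and the absorbance gate passed; by default the rule stays binary.
    """
    if not (np.isfinite(raw_a254) and np.isfinite(pe_avg_min)):
        raise ValueError("classify requires finite inputs")
    if pe_avg_min < 0:
        raise ValueError("pe_avg_min must be non-negative")
    gate_a254 = raw_a254 > thresholds.a254_gate
    gate_pe = pe_avg_min < thresholds.pe_cutoff
    gray = thresholds.gray_low <= pe_avg_min <= thresholds.gray_high

    parts = [
        f"raw a254 {raw_a254:.3f} {'>' if gate_a254 else '<='} "
        f"{thresholds.a254_gate:g} ({'pass' if gate_a254 else 'fail'})",
        f"min PE_avg {pe_avg_min:.1f}% {'<' if gate_pe else '>='} "
        f"{thresholds.pe_cutoff:g}% ({'pass' if gate_pe else 'fail'})",
    ]
    if gate_a254 and gate_pe:
        verdict = "fulvic"
    else:
        verdict = "non_fulvic"
    if gray:
        parts.append(
            f"PE_avg within gray zone {thresholds.gray_low:g}-"
            f"{thresholds.gray_high:g}%: orthogonal confirmation recommended"
        )
        if gray_zone_mode and gate_a254:
            verdict = "indeterminate"
    return Decision(
        verdict=verdict,
        gate_a254_passed=gate_a254,
        gate_pe_passed=gate_pe,
        gray_zone=gray,
        rationale="; ".join(parts),
    )


_SSSAD_WAVELENGTHS = np.arange(290, 331, 5)


def sssad(sample: Spectrum, standard: Spectrum, mode: str = "squared") -> float:
    """Squared sum of scaled absorbance differences over 290-330 nm.

    Each spectrum's values at 290, 295, ..., 330 nm are zeroed by the
    series minimum and scaled by the zeroed value at 290 nm; the statistic
    is the sum of squared differences between the two scaled series
    (``mode='absolute'`` sums absolute differences instead). Scaling makes
    the statistic invariant to a raw multiplicative factor.
    """
    if mode not in ("squared", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")

    def scaled(s: Spectrum) -> np.ndarray:
        vals = np.array([s.value_at(w) for w in _SSSAD_WAVELENGTHS])
        zeroed = vals - vals.min()
        ref = zeroed[0]  # zeroed value at 290 nm
        if ref == 0:
            raise ZeroDivisionError(
                "SSSAD scaling undefined: zeroed absorbance at 290 nm is zero"
            )
        return zeroed / ref

    diff = scaled(sample) - scaled(standard)
    if mode == "squared":
        return float(np.sum(diff**2))
    return float(np.sum(np.abs(diff)))
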