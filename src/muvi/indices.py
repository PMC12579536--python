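"""Spectrum normalization and the ten UV-Vis indices used for fulvic screening.

The index set characterizes the shape of a chromophoric dissolved organic
matter (CDOM) absorbance curve: six point absorbances (254, 280, 325, 355,
412, 440 nm) read off the normalized spectrum, two spectral slopes from the
exponential-decay model

    a(lambda) = a_ref * exp(-S * (lambda - lambda0)) + K

fitted over 275-295 nm and 350-400 nm, their ratio SR = S275/S350, and the
absorbance ratio a250/a365 (the classic E2:E3 proxy for molecular size).
All indices are computed from the spectrum normalized to unit maximum, which
makes them invariant to concentration and pathlength.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .spectra_io import Spectrum

__all__ = [
    "INDEX_NAMES",
    "IndexSet",
    "SlopeFit",
    "FitFailedError",
    "NormalizationError",
    "S275_WINDOW",
    "S350_WINDOW",
    "normalize",
    "absorbance_at",
    "fit_spectral_slope",
    "compute_indices",
]

# Slope-fit windows (nm). 275-295 serves both the short-wavelength slope and
# the SR numerator so that SR(275/350) is self-consistent.
S275_WINDOW = (275.0, 295.0)
S350_WINDOW = (350.0, 400.0)

# Point-absorbance wavelengths (nm) of the index set.
ABSORBANCE_WAVELENGTHS = (254, 280, 325, 355, 412, 440)

INDEX_NAMES = (
    "s275", "s350", "a254", "a280", "a325", "a355", "a412", "a440", "sr", "e2e3",
)

# A fitted decay rate at (or below) this is treated as "no exponential decay".
_NON_EXPONENTIAL_S = 1e-6

_S_BOUNDS = (1e-9, 1.0)
_K_BOUNDS = (-0.1, 1.0)
_AREF_BOUNDS = (1e-12, 10.0)
_FIT_TOL = 1e-10
# Deterministic restart offsets applied to the background initial guess.
_K0_PERTURBATIONS = (0.0, 0.01, -0.01, 0.005)


class FitFailedError(RuntimeError):
    """Raised when the exponential slope fit fails to converge."""


class NormalizationError(ValueError):
    """Raised when a spectrum cannot be normalized (max absorbance <= 0)."""


@dataclass(frozen=True)
class IndexSet:
    """The ten index values computed from one normalized spectrum."""

    s275: float
    s350: float
    a254: float
    a280: float
    a325: float
    a355: float
    a412: float
    a440: float
    sr: float
    e2e3: float

    def __post_init__(self) -> None:
        for name in INDEX_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"index {name} is not finite: {v}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in INDEX_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in INDEX_NAMES])

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "IndexSet":
        return cls(**{name: float(d[name]) for name in INDEX_NAMES})


@dataclass(frozen=True)
class SlopeFit:
    """Result of fitting a_ref*exp(-s*(lambda-lambda0)) + k over one window.

    ``s`` is the per-nm decay rate; ``converged`` reflects the optimizer
    status. A fit whose decay rate collapses to (numerical) zero is flagged
    non-exponential rather than raised: downstream percent errors against a
    genuine fulvic standard will simply be large.
    """

    s: float
    a_ref: float
    k: float
    lambda0: float
    window: tuple[float, float]
    rss: float
    converged: bool

    @property
    def is_exponential(self) -> bool:
        return self.s > _NON_EXPONENTIAL_S

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be non-negative")


def normalize(s: Spectrum) -> Spectrum:
    """Divide every absorbance by the maximum over the spectrum.

    Idempotent; the result has unit maximum and carries ``is_normalized``.
    A non-positive maximum (blank or inverted trace) raises
    :class:`NormalizationError`.
    """
    peak = float(s.absorbance.max())
    if peak <= 0:
        raise NormalizationError(
            f"maximum absorbance is {peak:g} <= 0; cannot normalize "
            "(blank or inverted spectrum?)"
        )
    return replace(s, absorbance=s.absorbance / peak, is_normalized=True)


def absorbance_at(s: Spectrum, wavelength: float) -> float:
    """Exact grid lookup of the absorbance at an integer-nm wavelength."""
    try:
        return s.value_at(wavelength)
    except KeyError:
        raise KeyError(
            f"{wavelength} nm is off the spectrum grid; resample to the "
            "canonical 1 nm grid first"
        ) from None


def _exp_model(params: np.ndarray, lam: np.ndarray, lambda0: float) -> np.ndarray:
    a_ref, s, k = params
    return a_ref * np.exp(-s * (lam - lambda0)) + k


def fit_spectral_slope(
    s: Spectrum,
    window: tuple[float, float] = S275_WINDOW,
    lambda0: float | None = None,
) -> SlopeFit:
    """Fit the three-parameter exponential-decay model over a window.

    The fit is deterministic: the decay rate is initialized from an ordinary
    least-squares line through log(a - min + eps) versus wavelength, the
    background from the window minimum, and up to three restarts perturb
    only the background guess. ``lambda0`` defaults to the window start,
    which only rescales the amplitude, never the decay rate.
    """
    lo, hi = window
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    lam = s.wavelengths[mask]
    y = s.absorbance[mask]
    if lam.size < 6:
        raise ValueError(
            f"window {lo:g}-{hi:g} nm holds only {lam.size} points; >= 6 required"
        )
    if lambda0 is None:
        lambda0 = float(lo)

    span = float(y.max() - y.min())
    eps = 1e-3 * span + 1e-12
    logy = np.log(y - y.min() + eps)
    slope = np.polyfit(lam, logy, 1)[0]
    s0 = float(np.clip(-slope, _S_BOUNDS[0], _S_BOUNDS[1]))
    k0_base = float(np.clip(y.min(), *_K_BOUNDS))
    a0 = float(np.clip(y[0] - k0_base, *_AREF_BOUNDS))

    lower = np.array([_AREF_BOUNDS[0], _S_BOUNDS[0], _K_BOUNDS[0]])
    upper = np.array([_AREF_BOUNDS[1], _S_BOUNDS[1], _K_BOUNDS[1]])

    best = None
    for dk in _K0_PERTURBATIONS:
        k0 = float(np.clip(k0_base + dk, *_K_BOUNDS))
        x0 = np.clip(np.array([a0, s0, k0]), lower, upper)
        res = least_squares(
            lambda p: _exp_model(p, lam, lambda0) - y,
            x0,
            bounds=(lower, upper),
            xtol=_FIT_TOL,
            ftol=_FIT_TOL,
            gtol=_FIT_TOL,
            max_nfev=5000,  # flat/noise-floor windows need a long leash
        )
        rss = float(np.sum(res.fun**2))
        if best is None or (res.success and not best[1]) or (
            res.success == best[1] and rss < best[2]
        ):
            best = (res, bool(res.success), rss)
        if res.success:
            break

    res, success, rss = best
    if not success:
        raise FitFailedError(
            f"exponential fit over {lo:g}-{hi:g} nm did not converge "
            f"(status {res.status}: {res.message})"
        )
    a_ref, s_fit, k = (float(v) for v in res.x)
    return SlopeFit(
        s=s_fit, a_ref=a_ref, k=k, lambda0=lambda0,
        window=(float(lo), float(hi)), rss=rss, converged=success,
    )


def compute_indices(
    s: Spectrum,
    return_fits: bool = False,
    s275_window: tuple[float, float] = S275_WINDOW,
    s350_window: tuple[float, float] = S350_WINDOW,
) -> IndexSet | tuple[IndexSet, dict[str, SlopeFit]]:
    """Compute the full ten-index set from a normalized canonical-grid spectrum.

    Raises if the spectrum is not normalized (the indices are defined on the
    unit-maximum curve) or if a365 vanishes (undefined a250/a365 ratio).
    """
    if not s.is_normalized:
        raise ValueError(
            "compute_indices requires a normalized spectrum; call normalize() first"
        )
    fit275 = fit_spectral_slope(s, s275_window)
    fit350 = fit_spectral_slope(s, s350_window)
    a365 = absorbance_at(s, 365)
    if a365 == 0:
        raise ZeroDivisionError("a250/a365 undefined: absorbance at 365 nm is zero")
    idx = IndexSet(
        s275=fit275.s,
        s350=fit350.s,
        a254=absorbance_at(s, 254),
        a280=absorbance_at(s, 280),
        a325=absorbance_at(s, 325),
        a355=absorbance_at(s, 355),
        a412=absorbance_at(s, 412),
        a440=absorbance_at(s, 440),
        sr=fit275.s / fit350.s,
        e2e3=absorbance_at(s, 250) / a365,
    )
    if return_fits:
        return idx, {"s275": fit275, "s350": fit350}
    return idx
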