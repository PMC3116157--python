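"""Emission spectra, lambda_max extraction and transition-curve assembly.

A denaturation experiment monitored by intrinsic Trp fluorescence yields one
emission spectrum per denaturant concentration; the wavelength of maximum
emission (lambda_max) red-shifts as buried tryptophans become solvent
exposed.  This module extracts lambda_max from raw spectra and assembles the
(concentration, lambda_max) transition curve that the fitting module consumes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignalKind",
    "EmissionSpectrum",
    "DenaturationCurve",
    "SpectrumError",
    "extract_lambda_max",
    "build_transition_curve",
    "DEFAULT_WINDOW_NM",
]

#: Default recorded spectral window (nm) for Trp emission.
DEFAULT_WINDOW_NM = (300.0, 450.0)


class SpectrumError(ValueError):
    """Raised for degenerate or out-of-contract spectra."""


class SignalKind(str, enum.Enum):
    """What a transition-curve signal physically is."""

    LAMBDA_MAX_NM = "lambda_max_nm"
    INTENSITY_AU = "intensity_au"
    GENERIC = "generic"


@dataclass(frozen=True)
class EmissionSpectrum:
    """One fluorescence emission spectrum at a fixed denaturant concentration.

    Wavelengths must be strictly increasing and inside ``window``;
    intensities non-negative; at least 5 points.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    denaturant_conc: float
    sample_id: str = ""
    window: tuple[float, float] = DEFAULT_WINDOW_NM

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or it.ndim != 1 or len(wl) != len(it):
            raise SpectrumError("wavelengths and intensities must be "
                                "equal-length 1-D arrays")
        if len(wl) < 5:
            raise SpectrumError(f"need >= 5 points, got {len(wl)}")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        lo, hi = self.window
        if wl[0] < lo or wl[-1] > hi:
            raise SpectrumError(
                f"wavelengths [{wl[0]}, {wl[-1]}] outside window {self.window}")
        if np.any(it < 0):
            raise SpectrumError("intensities must be non-negative")
        if self.denaturant_conc < 0:
            raise SpectrumError("denaturant concentration must be >= 0")


@dataclass(frozen=True)
class DenaturationCurve:
    """A (denaturant concentration, signal) series for one sample.

    Stored sorted by ascending concentration; concentrations must be unique
    and non-negative.  The minimum point count for *fitting* (>= 8) is
    enforced by the fitting routines, not at construction, so short curves
    can still be built, inspected and serialised.
    """

    concs: np.ndarray
    signals: np.ndarray
    signal_kind: SignalKind = SignalKind.GENERIC
    sample_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concs, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if c.ndim != 1 or s.ndim != 1 or len(c) != len(s):
            raise ValueError("concs and signals must be equal-length 1-D arrays")
        if len(c) == 0:
            raise ValueError("curve must contain at least one point")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if len(np.unique(c)) != len(c):
            raise ValueError("concentrations must be unique")
        order = np.argsort(c)
        object.__setattr__(self, "concs", c[order])
        object.__setattr__(self, "signals", s[order])
        object.__setattr__(self, "signal_kind", SignalKind(self.signal_kind))

    def __len__(self) -> int:
        return len(self.concs)


def extract_lambda_max(s: EmissionSpectrum, method: str = "parabolic",
                       centroid_fraction: float = 0.8) -> float:
    """Wavelength of maximum emission, in nm.

    Methods
    -------
    ``argmax``
        Grid wavelength of the maximum intensity (ties broken toward the
        lower wavelength).
    ``parabolic`` (default)
        Quadratic through the discrete maximum and its two neighbours;
        returns the vertex.  Sub-grid precision without assuming a band
        shape.
    ``centroid``
        Intensity-weighted mean wavelength over points at or above
        ``centroid_fraction`` of the peak intensity.

    Raises
    ------
    SpectrumError
        If the discrete maximum sits on the window edge (the band was
        clipped; the vertex is undefined) or the spectrum has no unique
        maximum structure (e.g. constant intensities).
    """
    wl, it = s.wavelengths, s.intensities
    if np.ptp(it) == 0:
        raise SpectrumError("constant spectrum: no unique maximum")
    i = int(np.argmax(it))  # np.argmax returns the first (lowest-wl) maximum
    if i == 0 or i == len(wl) - 1:
        raise SpectrumError(
            f"intensity maximum at window edge ({wl[i]} nm); the emission "
            "band appears clipped")
    if method == "argmax":
        return float(wl[i])
    if method == "parabolic":
        x = wl[i - 1:i + 2]
        y = it[i - 1:i + 2]
        denom = (y[0] - 2 * y[1] + y[2])
        if denom == 0:  # flat-topped triple: fall back to the grid maximum
            return float(wl[i])
        # vertex of the quadratic through 3 points on a (possibly uneven) grid
        a, b, c = np.polyfit(x, y, 2)
        if a == 0:
            return float(wl[i])
        return float(-b / (2 * a))
    if method == "centroid":
        if not 0 < centroid_fraction <= 1:
            raise ValueError("centroid_fraction must be in (0, 1]")
        mask = it >= centroid_fraction * it[i]
        return float(np.sum(wl[mask] * it[mask]) / np.sum(it[mask]))
    raise ValueError(f"unknown method {method!r}; "
                     "expected argmax | parabolic | centroid")


def build_transition_curve(spectra: list[EmissionSpectrum],
                           method: str = "parabolic") -> DenaturationCurve:
    """Assemble a lambda_max transition curve from per-concentration spectra.

    All spectra must share one sample_id and have unique concentrations.
    The returned curve is sorted by ascending concentration with
    ``signal_kind = lambda_max_nm``.
    """
    if not spectra:
        raise ValueError("no spectra supplied")
    ids = {sp.sample_id for sp in spectra}
    if len(ids) > 1:
        raise ValueError(f"mixed sample ids: {sorted(ids)}")
    concs = np.array([sp.denaturant_conc for sp in spectra])
    if len(np.unique(concs)) != len(concs):
        raise ValueError("duplicate denaturant concentrations across spectra")
    lmax = np.array([extract_lambda_max(sp, method=method) for sp in spectra])
    return DenaturationCurve(concs=concs, signals=lmax,
                             signal_kind=SignalKind.LAMBDA_MAX_NM,
                             sample_id=ids.pop())
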