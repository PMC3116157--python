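"""Synthetic denaturation data with the statistical structure the fits assume.

Generates transition curves (population-weighted signal plus iid Gaussian
noise) and raw Trp emission spectra (population-weighted Gaussian bands) for
any parameter set, and ships the HCAII Pro237 mutant panel — pseudo
wild-type plus five point mutants — with its published three-state
thermodynamic parameters as the generating truth, for end-to-end pipeline
validation by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import ThreeStateParams, TransitionThermo, predicted_signal
from .models import _fractions_three  # vectorised populations
from .spectra import (DEFAULT_WINDOW_NM, DenaturationCurve, EmissionSpectrum,
                      SignalKind)

__all__ = [
    "PanelSpec",
    "generate_curve",
    "generate_spectra",
    "hcaii_panel",
    "DEFAULT_BASELINES_NM",
    "DEFAULT_NOISE_SD_NM",
    "DEFAULT_CONC_GRID",
]

#: Generator-default lambda_max plateaus (nm) for N / I / U.  These are
#: typical Trp-fluorescence values for a folded protein, a molten globule
#: and an unfolded chain — synthetic defaults, not measured values — and are
#: freely overridable per variant.
DEFAULT_BASELINES_NM = (336.0, 341.0, 355.0)

#: Default measurement noise on lambda_max, nm (1 sigma).
DEFAULT_NOISE_SD_NM = 0.3

#: Default denaturant grid: 31 points, 0-3 M GdnHCl, covering both
#: transition midpoints of the panel (~0.9 and ~2.0 M).
DEFAULT_CONC_GRID = tuple(np.linspace(0.0, 3.0, 31))

# Published three-state parameters of the HCAII Pro237 panel:
# (dG_NI, m_NI, dG_IU, m_IU), kcal/mol and kcal mol^-1 M^-1.
_PANEL_THERMO: dict[str, tuple[float, float, float, float]] = {
    "HCAII_pwt":   (5.7, 6.3, 7.8, 3.9),
    "HCAII_P237A": (6.5, 6.5, 6.0, 2.8),
    "HCAII_P237T": (4.7, 5.2, 6.4, 3.0),
    "HCAII_P237N": (5.0, 5.5, 7.3, 3.6),
    "HCAII_P237I": (5.1, 6.2, 7.5, 3.7),
    "HCAII_P237F": (5.3, 6.3, 5.3, 2.5),
}


@dataclass(frozen=True)
class PanelSpec:
    """A set of variants to simulate, with grid, noise and seeding.

    Replicate ``r`` of variant ``i`` draws its noise from seed
    ``seed + i * n_replicates + r`` so every curve is independently and
    reproducibly seeded.
    """

    variants: dict[str, ThreeStateParams]
    conc_grid: tuple[float, ...] = DEFAULT_CONC_GRID
    noise_sd: float = DEFAULT_NOISE_SD_NM
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        grid = np.asarray(self.conc_grid, dtype=float)
        if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("conc_grid must be sorted, unique, non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "conc_grid", tuple(grid))


def generate_curve(p: ThreeStateParams, conc_grid=DEFAULT_CONC_GRID,
                   noise_sd: float = DEFAULT_NOISE_SD_NM, seed: int = 0,
                   sample_id: str = "") -> DenaturationCurve:
    """Simulate one lambda_max transition curve.

    signal = predicted_signal(p, conc) + eps,  eps ~ iid N(0, noise_sd^2),
    drawn from ``numpy.random.default_rng(seed)``.  ``noise_sd = 0`` gives
    the exact model curve.
    """
    conc = np.asarray(conc_grid, dtype=float)
    y = np.asarray(predicted_signal(p, conc), dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=len(conc))
    return DenaturationCurve(concs=conc, signals=y,
                             signal_kind=SignalKind.LAMBDA_MAX_NM,
                             sample_id=sample_id)


def generate_spectra(p: ThreeStateParams, conc_grid=DEFAULT_CONC_GRID,
                     band_width_nm: float = 20.0, grid_step_nm: float = 1.0,
                     noise_sd: float = 0.0, seed: int = 0,
                     sample_id: str = "",
                     window=DEFAULT_WINDOW_NM) -> list[EmissionSpectrum]:
    """Simulate raw emission spectra, one per denaturant concentration.

    Each spectrum is the population-weighted sum of unit-amplitude Gaussian
    bands centred at the state baselines (band sigma ``band_width_nm``),
    sampled every ``grid_step_nm`` across ``window``, plus iid Gaussian
    intensity noise.  For well-separated populations the mixed spectrum
    peaks near the model's lambda_max; when two bands are comparably
    populated the mixture peak deviates slightly from the weighted-mean
    lambda_max (sub-0.5 nm at the default band width) — the known gap
    between the mixture physics and the linear-observable fit model.
    """
    lo, hi = window
    for b in p.baselines:
        if not lo <= b <= hi:
            raise ValueError(f"band centre {b} nm outside window {window}")
    wl = np.arange(lo, hi + grid_step_nm / 2, grid_step_nm)
    conc = np.asarray(conc_grid, dtype=float)
    fracs = np.column_stack(_fractions_three(p, conc))  # (n_conc, 3)
    centers = np.asarray(p.baselines)
    rng = np.random.default_rng(seed)
    spectra = []
    for ci, fv in zip(conc, fracs):
        bands = np.exp(-0.5 * ((wl[:, None] - centers[None, :])
                               / band_width_nm) ** 2)
        intensity = bands @ fv
        if noise_sd > 0:
            intensity = np.clip(
                intensity + rng.normal(0.0, noise_sd, size=len(wl)), 0, None)
        spectra.append(EmissionSpectrum(
            wavelengths=wl, intensities=intensity, denaturant_conc=float(ci),
            sample_id=sample_id, window=window))
    return spectra


def hcaii_panel(conc_grid=DEFAULT_CONC_GRID,
                noise_sd: float = DEFAULT_NOISE_SD_NM, seed: int = 0,
                n_replicates: int = 1,
                baselines: tuple[float, float, float] = DEFAULT_BASELINES_NM
                ) -> PanelSpec:
    """The HCAII Pro237 mutant panel with published generating parameters.

    Returns the six fit-able variants (pwt reference and the P237A/T/N/I/F
    mutants) with their reported dG and m point estimates as generating
    thermodynamic truth.  P237H is excluded: its component free energies
    were never resolved (only a literature ddG_NU of 7.3 kcal/mol exists),
    so it cannot be simulated.  The lambda_max plateaus are generator
    defaults, not measured values.
    """
    bn, bi, bu = baselines
    variants = {
        name: ThreeStateParams(
            ni=TransitionThermo(dg_ni, m_ni),
            iu=TransitionThermo(dg_iu, m_iu),
            baseline_n=bn, baseline_i=bi, baseline_u=bu)
        for name, (dg_ni, m_ni, dg_iu, m_iu) in _PANEL_THERMO.items()
    }
    return PanelSpec(variants=variants, conc_grid=tuple(conc_grid),
                     noise_sd=noise_sd, seed=seed, n_replicates=n_replicates)
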