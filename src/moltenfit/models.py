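"""Equilibrium unfolding thermodynamics under the linear extrapolation method.

Implements the closed-form population and observable models for two-state
(N<->U) and three-state (N<->I<->U) chemical denaturation, where I is a
molten-globule intermediate.  Free energies follow the linear extrapolation
method (LEM),

    dG([D]) = dG0 - m * [D],

with dG0 the unfolding free energy in water (kcal/mol), m the denaturant
dependence (kcal mol^-1 M^-1) and [D] the denaturant concentration (M).
State populations are Boltzmann-weighted::

    K1 = exp(-dG_NI([D]) / RT)      N <-> I
    K2 = exp(-dG_IU([D]) / RT)      I <-> U
    Z  = 1 + K1 + K1*K2
    f_N = 1/Z,  f_I = K1/Z,  f_U = K1*K2/Z

and the measured signal (here typically the tryptophan-fluorescence emission
maximum, lambda_max in nm) is the population-weighted mean of per-state
baselines, each optionally linear in denaturant.  Treating lambda_max as a
linear mixture of state baselines is an approximation — physically the
observed peak is the maximum of a mixture of emission bands — but it is the
standard fitting practice for this readout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "TransitionThermo",
    "ThreeStateParams",
    "TwoStateParams",
    "StateFractions",
    "delta_g_at_denaturant",
    "equilibrium_constant",
    "state_fractions_three_state",
    "state_fractions_two_state",
    "predicted_signal",
    "midpoint",
]

#: Gas constant in kcal mol^-1 K^-1 (energies throughout are kcal/mol).
GAS_CONSTANT_KCAL = 1.987204e-3

#: Default temperature: 25 degC, the incubation temperature of the
#: equilibrium unfolding experiments this model describes.
DEFAULT_TEMPERATURE_K = 298.15

#: Exponent magnitude beyond which exp() is clamped to avoid overflow.
EXP_CLAMP = 700.0


@dataclass(frozen=True)
class TransitionThermo:
    """Thermodynamics of one unfolding transition under the LEM.

    Parameters
    ----------
    dg0 : float
        Unfolding free energy at zero denaturant, kcal/mol.
    m : float
        Denaturant dependence of the free energy, kcal mol^-1 M^-1.
        Must be positive for a physically meaningful unfolding transition.
    """

    dg0: float
    m: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.dg0):
            raise ValueError(f"dg0 must be finite, got {self.dg0}")
        if not math.isfinite(self.m) or self.m <= 0:
            raise ValueError(f"m must be finite and > 0, got {self.m}")


@dataclass(frozen=True)
class ThreeStateParams:
    """Full parameter set of the three-state N<->I<->U observable model.

    ``baseline_*`` are the signal values of the pure states (e.g. lambda_max
    in nm); ``baseline_slope_*`` give each baseline an optional linear
    denaturant dependence (signal units per M, default 0).
    """

    ni: TransitionThermo
    iu: TransitionThermo
    baseline_n: float
    baseline_i: float
    baseline_u: float
    baseline_slope_n: float = 0.0
    baseline_slope_i: float = 0.0
    baseline_slope_u: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        _check_common(self.temperature,
                      (self.baseline_n, self.baseline_i, self.baseline_u))

    @property
    def baselines(self) -> tuple[float, float, float]:
        return (self.baseline_n, self.baseline_i, self.baseline_u)

    @property
    def baseline_slopes(self) -> tuple[float, float, float]:
        return (self.baseline_slope_n, self.baseline_slope_i,
                self.baseline_slope_u)


@dataclass(frozen=True)
class TwoStateParams:
    """Two-state N<->U observable model (degenerate three-state limit)."""

    nu: TransitionThermo
    baseline_n: float
    baseline_u: float
    baseline_slope_n: float = 0.0
    baseline_slope_u: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        _check_common(self.temperature, (self.baseline_n, self.baseline_u))

    @property
    def baselines(self) -> tuple[float, float]:
        return (self.baseline_n, self.baseline_u)

    @property
    def baseline_slopes(self) -> tuple[float, float]:
        return (self.baseline_slope_n, self.baseline_slope_u)


def _check_common(temperature: float, baselines: tuple) -> None:
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    for b in baselines:
        if not math.isfinite(b):
            raise ValueError(f"baselines must be finite, got {b}")


@dataclass(frozen=True)
class StateFractions:
    """Equilibrium population fractions of N, I and U (sum to 1)."""

    f_n: float
    f_i: float
    f_u: float

    def __post_init__(self) -> None:
        total = self.f_n + self.f_i + self.f_u
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        for f in (self.f_n, self.f_i, self.f_u):
            if f < -1e-15 or f > 1 + 1e-15:
                raise ValueError(f"fraction out of [0, 1]: {f}")


def delta_g_at_denaturant(t: TransitionThermo, conc) -> np.ndarray | float:
    """Unfolding free energy at denaturant concentration ``conc`` (M).

    LEM: ``dG([D]) = dg0 - m * [D]``.  Accepts scalars or arrays.
    """
    conc = _validated_conc(conc)
    return t.dg0 - t.m * conc


def equilibrium_constant(dg, temperature: float = DEFAULT_TEMPERATURE_K):
    """Equilibrium constant ``K = exp(-dG / RT)``.

    The exponent is clamped at |x| = 700 to stay inside double range; a
    clamped evaluation warns, since the resulting K (~1e304 or ~1e-304)
    is saturated rather than exact.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    x = -np.asarray(dg, dtype=float) / (GAS_CONSTANT_KCAL * temperature)
    if np.any(np.abs(x) > EXP_CLAMP):
        warnings.warn(
            "equilibrium_constant: |dG/RT| exceeds the overflow clamp "
            f"({EXP_CLAMP}); result saturated", RuntimeWarning, stacklevel=2)
        x = np.clip(x, -EXP_CLAMP, EXP_CLAMP)
    out = np.exp(x)
    return float(out) if out.ndim == 0 else out


def state_fractions_three_state(p: ThreeStateParams, conc) -> StateFractions:
    """Populations of N, I, U at ``conc`` M denaturant (scalar input)."""
    f_n, f_i, f_u = _fractions_three(p, float(conc))
    return StateFractions(float(f_n), float(f_i), float(f_u))


def state_fractions_two_state(p: TwoStateParams, conc) -> StateFractions:
    """Populations of N and U (f_i fixed at 0) at ``conc`` M denaturant."""
    f_n, f_u = _fractions_two(p, float(conc))
    return StateFractions(float(f_n), 0.0, float(f_u))


def _fractions_three(p: ThreeStateParams, conc):
    """Vectorised three-state fractions; returns (f_n, f_i, f_u) arrays."""
    conc = _validated_conc(conc)
    k1 = equilibrium_constant(delta_g_at_denaturant(p.ni, conc), p.temperature)
    k2 = equilibrium_constant(delta_g_at_denaturant(p.iu, conc), p.temperature)
    z = 1.0 + k1 + k1 * k2
    return 1.0 / z, k1 / z, (k1 * k2) / z


def _fractions_two(p: TwoStateParams, conc):
    conc = _validated_conc(conc)
    k = equilibrium_constant(delta_g_at_denaturant(p.nu, conc), p.temperature)
    return 1.0 / (1.0 + k), k / (1.0 + k)


def predicted_signal(p: ThreeStateParams | TwoStateParams, conc):
    """Population-weighted observable ``Y([D]) = sum_s f_s (b_s + s_s [D])``.

    Accepts scalar or array concentrations; returns the same shape.
    """
    conc = _validated_conc(conc)
    if isinstance(p, ThreeStateParams):
        fracs = _fractions_three(p, conc)
    elif isinstance(p, TwoStateParams):
        fracs = _fractions_two(p, conc)
    else:
        raise TypeError(f"unsupported parameter type {type(p).__name__}")
    out = sum(f * (b + s * conc)
              for f, b, s in zip(fracs, p.baselines, p.baseline_slopes))
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


def midpoint(t: TransitionThermo) -> float:
    """Transition midpoint ``Cm = dg0 / m`` (M), where dG([Cm]) = 0."""
    # m > 0 is enforced by TransitionThermo; re-checked for raw duck-typed use
    if t.m <= 0:
        raise ValueError(f"midpoint requires m > 0, got {t.m}")
    return t.dg0 / t.m


def _validated_conc(conc):
    arr = np.asarray(conc, dtype=float)
    if np.any(arr < 0):
        raise ValueError("denaturant concentration must be >= 0")
    return arr if arr.ndim else float(arr)
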