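"""Nonlinear least-squares fitting of denaturation transition curves.

Estimates two-state or three-state LEM parameters (free energies, m-values
and per-state baselines) from a :class:`~moltenfit.spectra.DenaturationCurve`
by trust-region-reflective least squares with box bounds, reports
covariance- or bootstrap-based standard errors, and selects between the two
models by small-sample-corrected AIC (AICc).

Curves are fit individually (no global/shared-m fitting across variants),
so each variant gets its own m-values, matching how per-variant stability
tables are reported.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .models import (
    DEFAULT_TEMPERATURE_K,
    ThreeStateParams,
    TransitionThermo,
    TwoStateParams,
    predicted_signal,
)
from .spectra import DenaturationCurve

__all__ = [
    "ModelKind",
    "FitOptions",
    "FitResult",
    "ModelSelection",
    "NoTransitionError",
    "initial_guess",
    "fit_curve",
    "select_model",
]

# Default m-value starting guesses, kcal mol^-1 M^-1: the order of magnitude
# typical for GdnHCl unfolding of a ~30 kDa globular protein.
DEFAULT_M_NI = 6.0
DEFAULT_M_IU = 4.0
DEFAULT_M_NU = 5.0


class NoTransitionError(ValueError):
    """The curve shows no usable transition (signal span below noise floor)."""


class ModelKind(str, enum.Enum):
    TWO_STATE = "two_state"
    THREE_STATE = "three_state"


@dataclass(frozen=True)
class FitOptions:
    """Options controlling :func:`fit_curve`.

    ``n_bootstrap = 0`` (default) reports Jacobian/covariance-based standard
    errors; a positive count switches to case-resampling bootstrap errors,
    seeded and reproducible.
    """

    model: ModelKind = ModelKind.THREE_STATE
    fit_baseline_slopes: bool = False
    max_iterations: int = 2000
    tolerance: float = 1e-10
    n_bootstrap: int = 0
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")
        object.__setattr__(self, "model", ModelKind(self.model))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single curve fit.

    ``stderr`` maps free-parameter names to standard errors (same units as
    the estimates); ``covariance`` is the matching square matrix in
    ``param_names`` order.  ``identifiable`` is False when the Jacobian at
    the solution is numerically rank-deficient (some parameter — typically
    an invisible intermediate's — is unconstrained by the data).
    """

    params: ThreeStateParams | TwoStateParams
    param_names: tuple[str, ...]
    stderr: dict[str, float]
    covariance: np.ndarray
    rss: float
    n_points: int
    aic: float
    converged: bool
    residuals: np.ndarray
    identifiable: bool = True
    message: str = ""

    @property
    def model(self) -> ModelKind:
        return (ModelKind.THREE_STATE
                if isinstance(self.params, ThreeStateParams)
                else ModelKind.TWO_STATE)

    @property
    def n_free(self) -> int:
        return len(self.param_names)


@dataclass(frozen=True)
class ModelSelection:
    """Result of two-state vs three-state comparison by AICc."""

    selected: ModelKind
    two_state: FitResult | None
    three_state: FitResult | None
    delta_aic: float | None
    ambiguous: bool
    message: str = ""


# ---------------------------------------------------------------------------
# parameter vector <-> parameter objects

def _param_names(model: ModelKind, slopes: bool) -> tuple[str, ...]:
    if model is ModelKind.THREE_STATE:
        names = ["dg_ni", "m_ni", "dg_iu", "m_iu",
                 "baseline_n", "baseline_i", "baseline_u"]
        if slopes:
            names += ["baseline_slope_n", "baseline_slope_i",
                      "baseline_slope_u"]
    else:
        names = ["dg_nu", "m_nu", "baseline_n", "baseline_u"]
        if slopes:
            names += ["baseline_slope_n", "baseline_slope_u"]
    return tuple(names)


def _pack(params: ThreeStateParams | TwoStateParams, slopes: bool) -> np.ndarray:
    if isinstance(params, ThreeStateParams):
        x = [params.ni.dg0, params.ni.m, params.iu.dg0, params.iu.m,
             params.baseline_n, params.baseline_i, params.baseline_u]
        if slopes:
            x += list(params.baseline_slopes)
    else:
        x = [params.nu.dg0, params.nu.m, params.baseline_n, params.baseline_u]
        if slopes:
            x += list(params.baseline_slopes)
    return np.asarray(x, dtype=float)


def _unpack(x: np.ndarray, model: ModelKind, slopes: bool,
            temperature: float) -> ThreeStateParams | TwoStateParams:
    if model is ModelKind.THREE_STATE:
        sn, si, su = (x[7], x[8], x[9]) if slopes else (0.0, 0.0, 0.0)
        return ThreeStateParams(
            ni=TransitionThermo(float(x[0]), float(x[1])),
            iu=TransitionThermo(float(x[2]), float(x[3])),
            baseline_n=float(x[4]), baseline_i=float(x[5]),
            baseline_u=float(x[6]),
            baseline_slope_n=float(sn), baseline_slope_i=float(si),
            baseline_slope_u=float(su), temperature=temperature)
    sn, su = (x[4], x[5]) if slopes else (0.0, 0.0)
    return TwoStateParams(
        nu=TransitionThermo(float(x[0]), float(x[1])),
        baseline_n=float(x[2]), baseline_u=float(x[3]),
        baseline_slope_n=float(sn), baseline_slope_u=float(su),
        temperature=temperature)


def _bounds(model: ModelKind, slopes: bool,
            signals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Box bounds: m > 0, dG unbounded, baselines inside signal range +- span."""
    span = max(float(np.ptp(signals)), 1e-6)
    blo = float(signals.min()) - span
    bhi = float(signals.max()) + span
    if model is ModelKind.THREE_STATE:
        lo = [-np.inf, 1e-4, -np.inf, 1e-4, blo, blo, blo]
        hi = [np.inf, 100.0, np.inf, 100.0, bhi, bhi, bhi]
        if slopes:
            lo += [-np.inf] * 3
            hi += [np.inf] * 3
    else:
        lo = [-np.inf, 1e-4, blo, blo]
        hi = [np.inf, 100.0, bhi, bhi]
        if slopes:
            lo += [-np.inf] * 2
            hi += [np.inf] * 2
    return np.asarray(lo), np.asarray(hi)


# ---------------------------------------------------------------------------
# initial guess

def _noise_floor(signals: np.ndarray) -> float:
    """Robust noise scale from second differences (transition-insensitive)."""
    if len(signals) < 4:
        return 0.0
    d2 = np.diff(signals, n=2)
    # sd of iid noise from second differences: Var(d2) = 6 sigma^2
    return float(np.median(np.abs(d2)) / 0.6745 / math.sqrt(6.0))


def _crossing(concs: np.ndarray, y_norm: np.ndarray, level: float) -> float:
    """First concentration where the normalised signal crosses ``level``."""
    above = y_norm >= level
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return float(concs[-1])
    i = idx[0]
    if i == 0:
        return float(concs[0])
    # linear interpolation between the bracketing points
    y0, y1 = y_norm[i - 1], y_norm[i]
    if y1 == y0:
        return float(concs[i])
    t = (level - y0) / (y1 - y0)
    return float(concs[i - 1] + t * (concs[i] - concs[i - 1]))


def initial_guess(curve: DenaturationCurve,
                  model: ModelKind = ModelKind.THREE_STATE,
                  temperature: float = DEFAULT_TEMPERATURE_K
                  ) -> ThreeStateParams | TwoStateParams:
    """Heuristic starting parameters for :func:`fit_curve`.

    Baselines come from the means of the first/last 15% of points; transition
    midpoints from the 25%/75% crossings of the N-to-U signal span (50% for
    the two-state model); m-values start at field-typical defaults (6 and 4
    kcal mol^-1 M^-1 for N<->I and I<->U) and dG0 = m * Cm.

    Raises
    ------
    NoTransitionError
        If the total signal span is below the curve's noise floor (flat
        curve: nothing to fit).
    """
    model = ModelKind(model)
    c, y = curve.concs, curve.signals
    n = len(c)
    k = max(2, int(math.ceil(0.15 * n))) if n >= 4 else 1
    b_n = float(np.mean(y[:k]))
    b_u = float(np.mean(y[-k:]))
    span = b_u - b_n
    floor = max(4.0 * _noise_floor(y), 1e-12)
    if abs(span) < floor or span == 0:
        raise NoTransitionError(
            f"signal span {span:.3g} below noise floor {floor:.3g}; "
            "curve shows no transition")
    y_norm = (y - b_n) / span

    if model is ModelKind.TWO_STATE:
        cm = _crossing(c, y_norm, 0.5)
        cm = max(cm, 1e-3)
        return TwoStateParams(
            nu=TransitionThermo(DEFAULT_M_NU * cm, DEFAULT_M_NU),
            baseline_n=b_n, baseline_u=b_u, temperature=temperature)

    cm1 = _crossing(c, y_norm, 0.25)
    cm2 = _crossing(c, y_norm, 0.75)
    cm1 = max(cm1, 1e-3)
    if cm2 <= cm1:
        cm2 = cm1 + max(0.25 * (c[-1] - c[0]), 1e-3)
    b_i = float(np.interp(0.5 * (cm1 + cm2), c, y))
    return ThreeStateParams(
        ni=TransitionThermo(DEFAULT_M_NI * cm1, DEFAULT_M_NI),
        iu=TransitionThermo(DEFAULT_M_IU * cm2, DEFAULT_M_IU),
        baseline_n=b_n, baseline_i=b_i, baseline_u=b_u,
        temperature=temperature)


# ---------------------------------------------------------------------------
# fitting

def _solve(c, y, x0, bounds, model, slopes, temperature, options):
    def resid(x):
        p = _unpack(x, model, slopes, temperature)
        return predicted_signal(p, c) - y

    return least_squares(
        resid, x0, bounds=bounds, method="trf",
        ftol=options.tolerance, xtol=options.tolerance,
        gtol=options.tolerance,
        max_nfev=options.max_iterations * (len(x0) + 1))


def _aicc(rss: float, n: int, n_free: int) -> float:
    """AIC with small-sample correction; k counts the residual variance."""
    k = n_free + 1
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    denom = n - k - 1
    if denom <= 0:
        return math.inf
    return aic + 2 * k * (k + 1) / denom


_RANK_RTOL = 1e-10


def _covariance(jac: np.ndarray, rss: float, n: int
                ) -> tuple[np.ndarray, bool]:
    """Covariance ``s^2 (J^T J)^-1`` via SVD, flagging rank deficiency."""
    p = jac.shape[1]
    dof = max(n - p, 1)
    s2 = rss / dof
    u, sv, vt = np.linalg.svd(jac, full_matrices=False)
    identifiable = bool(sv[0] > 0 and sv[-1] / sv[0] > _RANK_RTOL)
    sv_inv2 = np.where(sv > _RANK_RTOL * sv[0], 1.0 / sv**2, 0.0)
    cov = (vt.T * sv_inv2) @ vt * s2
    return cov, identifiable


def fit_curve(curve: DenaturationCurve, options: FitOptions | None = None,
              start: ThreeStateParams | TwoStateParams | None = None
              ) -> FitResult:
    """Fit a transition curve by bounded trust-region least squares.

    Minimises ``sum (y_obs - predicted_signal)^2`` over the model's free
    parameters from :func:`initial_guess` (or a caller-supplied ``start``).
    If the first start fails to converge, five seeded, jittered restarts are
    tried and the best is kept.  Non-convergence is reported through
    ``converged=False`` with the last iterate — never silently raised over.

    Standard errors default to the Jacobian-based covariance scaled by
    ``rss/(n-p)``; with ``n_bootstrap > 0`` they come from case-resampled
    refits instead.
    """
    options = options or FitOptions()
    model = options.model
    slopes = options.fit_baseline_slopes
    names = _param_names(model, slopes)
    c, y = curve.concs, curve.signals
    n = len(c)
    if n < len(names) + 3:
        raise ValueError(
            f"curve has {n} points; need more than free parameters + 2 "
            f"(= {len(names) + 2}) to fit the {model.value} model")

    if start is None:
        start = initial_guess(curve, model, options.temperature)
    x0 = _pack(start, slopes)
    lo, hi = _bounds(model, slopes, y)
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

    res = _solve(c, y, x0, (lo, hi), model, slopes, options.temperature,
                 options)
    if not res.success:
        # multi-start fallback: jittered restarts, deterministic given seed
        rng = np.random.default_rng(options.seed)
        best = res
        for _ in range(5):
            jitter = 1.0 + 0.2 * rng.standard_normal(len(x0))
            xj = np.clip(x0 * jitter, lo + 1e-12, hi - 1e-12)
            trial = _solve(c, y, xj, (lo, hi), model, slopes,
                           options.temperature, options)
            if trial.cost < best.cost and trial.success:
                best = trial
        res = best

    rss = float(2 * res.cost)
    cov, identifiable = _covariance(res.jac, rss, n)
    if not identifiable:
        warnings.warn(
            "fit_curve: Jacobian is numerically rank-deficient — some "
            "parameters are not identifiable from this curve (e.g. an "
            "invisible intermediate)", RuntimeWarning, stacklevel=2)
    stderr_vec = np.sqrt(np.clip(np.diag(cov), 0, None))

    if options.n_bootstrap > 0:
        stderr_vec, cov = _bootstrap_errors(
            curve, res.x, (lo, hi), model, slopes, options)

    params = _unpack(res.x, model, slopes, options.temperature)
    return FitResult(
        params=params, param_names=names,
        stderr=dict(zip(names, stderr_vec.tolist())),
        covariance=cov, rss=rss, n_points=n,
        aic=_aicc(rss, n, len(names)),
        converged=bool(res.success),
        residuals=np.asarray(-res.fun),  # y_obs - y_model
        identifiable=identifiable,
        message=str(res.message))


def _bootstrap_errors(curve, x_hat, bounds, model, slopes, options):
    """Case-resampling bootstrap standard errors, seeded and reproducible."""
    rng = np.random.default_rng(options.seed)
    c, y = curve.concs, curve.signals
    n = len(c)
    estimates = []
    for _ in range(options.n_bootstrap):
        idx = np.sort(rng.integers(0, n, size=n))
        # resampling can duplicate concentrations; the model is still defined
        try:
            r = _solve(c[idx], y[idx], x_hat, bounds, model, slopes,
                       options.temperature, options)
        except Exception:  # pragma: no cover - defensive
            continue
        if r.success:
            estimates.append(r.x)
    if len(estimates) < 2:
        warnings.warn("bootstrap produced < 2 successful refits; "
                      "returning NaN errors", RuntimeWarning, stacklevel=3)
        p = len(x_hat)
        return np.full(p, np.nan), np.full((p, p), np.nan)
    est = np.asarray(estimates)
    return est.std(axis=0, ddof=1), np.cov(est.T)


def select_model(curve: DenaturationCurve,
                 options: FitOptions | None = None) -> ModelSelection:
    """Fit both models and pick the one with lower AICc.

    ``delta_aic = aic(two_state) - aic(three_state)``; positive favours the
    three-state model.  A difference below 2 is reported as ambiguous, with
    the two-state model preferred on parsimony.  If only one model's fit
    converges, it is returned with a warning message.
    """
    options = options or FitOptions()
    results: dict[ModelKind, FitResult | None] = {}
    for model in (ModelKind.TWO_STATE, ModelKind.THREE_STATE):
        try:
            results[model] = fit_curve(
                curve, replace(options, model=model))
        except (NoTransitionError, ValueError) as exc:
            results[model] = None
            warnings.warn(f"{model.value} fit failed: {exc}",
                          RuntimeWarning, stacklevel=2)

    two = results[ModelKind.TWO_STATE]
    three = results[ModelKind.THREE_STATE]
    two_ok = two is not None and two.converged
    three_ok = three is not None and three.converged

    if two_ok and three_ok:
        delta = two.aic - three.aic
        if abs(delta) < 2.0:
            return ModelSelection(ModelKind.TWO_STATE, two, three, delta,
                                  ambiguous=True,
                                  message="dAICc < 2: models are "
                                          "statistically indistinguishable; "
                                          "two-state preferred on parsimony")
        pick = ModelKind.THREE_STATE if delta > 0 else ModelKind.TWO_STATE
        return ModelSelection(pick, two, three, delta, ambiguous=False)
    if two_ok or three_ok:
        pick = ModelKind.TWO_STATE if two_ok else ModelKind.THREE_STATE
        msg = f"only the {pick.value} fit converged"
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        return ModelSelection(pick, two, three, None, ambiguous=False,
                              message=msg)
    raise RuntimeError("neither model converged on this curve")
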