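"""Mutant stability tables (dG_NU, ddG_NU) and prediction comparison.

Turns per-variant three-state fit results into a stability table: total
unfolding free energy dG_NU = dG_NI + dG_IU, mutation-induced change
ddG_NU = dG_NU(reference) - dG_NU(mutant) (positive = destabilising),
classification of significantly destabilising mutations, and comparison of
experimental ddG against an external predictor's output (e.g. a FoldX
ddG table).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fitting import FitResult, ModelKind

__all__ = [
    "StabilityRecord",
    "ComparisonResult",
    "total_dg",
    "ddg_nu",
    "build_stability_table",
    "classify_destabilizing",
    "compare_predictions",
    "DESTABILIZING_THRESHOLD",
]

#: Default significance threshold for "destabilising", kcal/mol.
DESTABILIZING_THRESHOLD = 2.0


@dataclass(frozen=True)
class StabilityRecord:
    """Per-variant thermodynamic summary.

    Fitted records carry both transitions and their m-values; literature
    records may carry only a ddG value (component fields None).  All
    energies kcal/mol; m-values kcal mol^-1 M^-1.
    """

    variant: str
    dg_ni: float | None = None
    dg_iu: float | None = None
    dg_nu: float | None = None
    ddg_nu: float | None = None
    m_ni: float | None = None
    m_iu: float | None = None
    se_dg_ni: float | None = None
    se_dg_iu: float | None = None
    se_dg_nu: float | None = None
    se_m_ni: float | None = None
    se_m_iu: float | None = None
    source: str = "fitted"

    def __post_init__(self) -> None:
        if self.source not in ("fitted", "literature"):
            raise ValueError(f"source must be fitted|literature, "
                             f"got {self.source!r}")
        if (self.source == "fitted" and None not in
                (self.dg_ni, self.dg_iu, self.dg_nu)):
            if abs(self.dg_nu - (self.dg_ni + self.dg_iu)) > 1e-9:
                raise ValueError(
                    f"{self.variant}: dg_nu must equal dg_ni + dg_iu "
                    f"({self.dg_nu} vs {self.dg_ni + self.dg_iu})")


@dataclass(frozen=True)
class ComparisonResult:
    """Experimental-vs-predicted ddG comparison over matched variants."""

    pairs: tuple[tuple[str, float, float], ...]  # (variant, exp, pred)
    pearson_r: float
    rmse: float
    max_abs_deviation: float
    max_deviation_variant: str
    n: int
    unmatched: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n != len(self.pairs):
            raise ValueError("n must equal len(pairs)")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if not (math.isnan(self.pearson_r) or abs(self.pearson_r) <= 1 + 1e-12):
            raise ValueError("|pearson_r| must be <= 1")


def total_dg(fit: FitResult) -> tuple[float, float]:
    """Total unfolding free energy dG_NU0 = dG_NI0 + dG_IU0 and its error.

    The propagated standard error is sqrt(var_NI + var_IU + 2 cov), using
    the fit's covariance between the two dG estimates.

    Requires a converged three-state fit.
    """
    if fit.model is not ModelKind.THREE_STATE:
        raise ValueError("total_dg requires a three-state fit")
    if not fit.converged:
        raise ValueError("total_dg requires a converged fit")
    i = fit.param_names.index("dg_ni")
    j = fit.param_names.index("dg_iu")
    dg = fit.params.ni.dg0 + fit.params.iu.dg0
    var = fit.covariance[i, i] + fit.covariance[j, j] + 2 * fit.covariance[i, j]
    return float(dg), float(math.sqrt(max(var, 0.0)))


def ddg_nu(reference: StabilityRecord, mutant: StabilityRecord) -> float:
    """Stability change ddG_NU = dG_NU(reference) - dG_NU(mutant).

    Positive values mean the mutation destabilises the protein relative to
    the reference.
    """
    if reference.dg_nu is None or mutant.dg_nu is None:
        raise ValueError("both records need dg_nu")
    return reference.dg_nu - mutant.dg_nu


def build_stability_table(fits: dict[str, FitResult], reference: str,
                          literature: dict[str, float] | None = None
                          ) -> list[StabilityRecord]:
    """Assemble the per-variant stability table relative to ``reference``.

    ``fits`` maps variant label to a converged three-state FitResult;
    ``literature`` maps extra variant labels to published ddG_NU values
    (kcal/mol) with no component free energies (source="literature").
    The reference appears first with ddg_nu = 0; fitted mutants follow in
    input order, then literature records.
    """
    if reference not in fits:
        raise ValueError(f"reference variant {reference!r} not among fits")
    literature = literature or {}
    dup = set(fits) & set(literature)
    if dup:
        raise ValueError(f"duplicate variant labels: {sorted(dup)}")

    def record(variant: str, fit: FitResult) -> StabilityRecord:
        dg, se_dg = total_dg(fit)
        return StabilityRecord(
            variant=variant,
            dg_ni=fit.params.ni.dg0, dg_iu=fit.params.iu.dg0, dg_nu=dg,
            m_ni=fit.params.ni.m, m_iu=fit.params.iu.m,
            se_dg_ni=fit.stderr.get("dg_ni"),
            se_dg_iu=fit.stderr.get("dg_iu"), se_dg_nu=se_dg,
            se_m_ni=fit.stderr.get("m_ni"), se_m_iu=fit.stderr.get("m_iu"),
            source="fitted")

    ref_rec = record(reference, fits[reference])
    table = [StabilityRecord(**{**ref_rec.__dict__, "ddg_nu": 0.0})]
    for variant, fit in fits.items():
        if variant == reference:
            continue
        rec = record(variant, fit)
        table.append(StabilityRecord(
            **{**rec.__dict__, "ddg_nu": ddg_nu(ref_rec, rec)}))
    for variant, ddg in literature.items():
        table.append(StabilityRecord(variant=variant, ddg_nu=float(ddg),
                                     source="literature"))
    return table


def classify_destabilizing(records: list[StabilityRecord],
                           threshold: float = DESTABILIZING_THRESHOLD
                           ) -> list[str]:
    """Variants whose ddG_NU exceeds ``threshold`` (kcal/mol).

    Returns labels sorted by descending ddG_NU, so the most deleterious
    mutation comes first.  Records without a ddG value are skipped.
    """
    hits = [(r.ddg_nu, r.variant) for r in records
            if r.ddg_nu is not None and r.ddg_nu > threshold]
    hits.sort(key=lambda t: (-t[0], t[1]))
    return [v for _, v in hits]


def compare_predictions(experimental: list[StabilityRecord],
                        predicted: dict[str, float]) -> ComparisonResult:
    """Compare experimental ddG_NU values against predictor output.

    Pairs are matched by variant label; at least two common variants are
    required.  Reports Pearson r, RMSE and the variant with the largest
    absolute experiment-prediction deviation.  Variants present on only one
    side are listed in ``unmatched`` and reported via a warning.
    """
    exp_map = {r.variant: r.ddg_nu for r in experimental
               if r.ddg_nu is not None}
    common = [v for v in exp_map if v in predicted]
    unmatched = sorted((set(exp_map) | set(predicted)) - set(common))
    if len(common) < 2:
        raise ValueError(
            f"need >= 2 variants in common, got {len(common)}")
    if unmatched:
        warnings.warn(f"variants without a counterpart: {unmatched}",
                      UserWarning, stacklevel=2)
    pairs = tuple((v, float(exp_map[v]), float(predicted[v])) for v in common)
    e = np.array([p[1] for p in pairs])
    p_ = np.array([p[2] for p in pairs])
    dev = np.abs(e - p_)
    imax = int(np.argmax(dev))
    if np.ptp(e) == 0 or np.ptp(p_) == 0:
        r = math.nan  # correlation undefined for a constant series
    else:
        r = float(stats.pearsonr(e, p_).statistic)
    return ComparisonResult(
        pairs=pairs, pearson_r=r,
        rmse=float(np.sqrt(np.mean((e - p_) ** 2))),
        max_abs_deviation=float(dev[imax]),
        max_deviation_variant=pairs[imax][0],
        n=len(pairs), unmatched=tuple(unmatched))
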