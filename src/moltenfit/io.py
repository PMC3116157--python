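"""Readers and writers for curves, spectra, fits, stability tables and
predictor ddG tables.

All formats are plain text: CSV for curves and spectra (self-describing
column names with units, metadata in ``# key=value`` comment lines), TSV for
the human-readable stability table and predictor input, JSON for
machine-readable fit results and comparisons.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import numpy as np

from .fitting import FitResult, ModelKind
from .models import ThreeStateParams, TransitionThermo, TwoStateParams
from .spectra import DenaturationCurve, EmissionSpectrum, SignalKind
from .stability import ComparisonResult, StabilityRecord

__all__ = [
    "read_curve_csv", "write_curve_csv",
    "read_spectrum_csv", "write_spectrum_csv",
    "read_prediction_table",
    "write_stability_table", "read_stability_table",
    "write_fit_json", "read_fit_json",
    "write_comparison_json",
]


class DataFormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def _parse_comments(lines: list[tuple[int, str]]) -> dict[str, str]:
    meta = {}
    for _, line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def _read_table(path, expected_cols: tuple[str, ...], delimiter: str = ","):
    """Read a two-column numeric table with # metadata; returns (rows, meta).

    Rows are (line_number, value0, value1); malformed rows raise with the
    1-based line number.
    """
    path = Path(path)
    comments: list[tuple[int, str]] = []
    header: list[str] | None = None
    rows: list[tuple[int, float, float]] = []
    with path.open(newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append((lineno, line))
                continue
            cells = next(csv.reader([line], delimiter=delimiter))
            if header is None:
                header = [c.strip() for c in cells]
                missing = [c for c in expected_cols if c not in header]
                if missing:
                    raise DataFormatError(
                        f"{path}: line {lineno}: missing column(s) "
                        f"{missing}; found {header}")
                continue
            try:
                idx = [header.index(c) for c in expected_cols]
                rows.append((lineno, *(float(cells[i]) for i in idx)))
            except (ValueError, IndexError) as exc:
                raise DataFormatError(
                    f"{path}: line {lineno}: malformed row {line!r} "
                    f"({exc})") from None
    if header is None:
        raise DataFormatError(f"{path}: empty file (no header)")
    return rows, _parse_comments(comments)


# ---------------------------------------------------------------------------
# transition curves

def read_curve_csv(path) -> DenaturationCurve:
    """Read a transition curve from CSV with columns ``conc_M,signal``.

    Optional ``# sample=...`` and ``# signal_kind=...`` comment lines carry
    metadata.  Duplicate concentrations and non-numeric cells are reported
    with their line numbers.
    """
    rows, meta = _read_table(path, ("conc_M", "signal"))
    if not rows:
        raise DataFormatError(f"{path}: no data rows")
    seen: dict[float, int] = {}
    for lineno, conc, _ in rows:
        if conc in seen:
            raise DataFormatError(
                f"{path}: line {lineno}: duplicate concentration {conc} "
                f"(first seen on line {seen[conc]})")
        seen[conc] = lineno
    return DenaturationCurve(
        concs=np.array([r[1] for r in rows]),
        signals=np.array([r[2] for r in rows]),
        signal_kind=SignalKind(meta.get("signal_kind", "generic")),
        sample_id=meta.get("sample", ""))


def write_curve_csv(curve: DenaturationCurve, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        if curve.sample_id:
            fh.write(f"# sample={curve.sample_id}\n")
        fh.write(f"# signal_kind={curve.signal_kind.value}\n")
        fh.write("conc_M,signal\n")
        for c, s in zip(curve.concs, curve.signals):
            fh.write(f"{float(c)!r},{float(s)!r}\n")


# ---------------------------------------------------------------------------
# emission spectra

def read_spectrum_csv(path) -> EmissionSpectrum:
    """Read one emission spectrum: columns ``wavelength_nm,intensity`` with
    ``# conc_M=...`` and ``# sample=...`` metadata lines."""
    rows, meta = _read_table(path, ("wavelength_nm", "intensity"))
    if "conc_M" not in meta:
        raise DataFormatError(f"{path}: missing '# conc_M=' metadata line")
    return EmissionSpectrum(
        wavelengths=np.array([r[1] for r in rows]),
        intensities=np.array([r[2] for r in rows]),
        denaturant_conc=float(meta["conc_M"]),
        sample_id=meta.get("sample", ""))


def write_spectrum_csv(spectrum: EmissionSpectrum, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        if spectrum.sample_id:
            fh.write(f"# sample={spectrum.sample_id}\n")
        fh.write(f"# conc_M={float(spectrum.denaturant_conc)!r}\n")
        fh.write("wavelength_nm,intensity\n")
        for w, i in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{float(w)!r},{float(i)!r}\n")


# ---------------------------------------------------------------------------
# predictor ddG tables

def read_prediction_table(path) -> dict[str, float]:
    """Read a predictor ddG table: TSV ``variant<TAB>ddG_kcal_mol`` or a
    JSON object mapping variant to ddG (kcal/mol)."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise DataFormatError(f"{path}: empty file")
    if path.suffix == ".json" or text.startswith("{"):
        data = json.loads(text)
        if not isinstance(data, dict) or not data:
            raise DataFormatError(f"{path}: expected a non-empty JSON object")
        out = {}
        for k, v in data.items():
            try:
                out[str(k)] = float(v)
            except (TypeError, ValueError):
                raise DataFormatError(
                    f"{path}: non-numeric ddG for {k!r}: {v!r}") from None
        return out
    out = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        if lineno == 1 and cells[0].strip().lower() == "variant":
            continue
        if len(cells) < 2:
            raise DataFormatError(f"{path}: line {lineno}: expected "
                                  f"variant<TAB>ddG, got {line!r}")
        variant = cells[0].strip()
        if variant in out:
            raise DataFormatError(
                f"{path}: line {lineno}: duplicate variant {variant!r}")
        try:
            out[variant] = float(cells[1])
        except ValueError:
            raise DataFormatError(
                f"{path}: line {lineno}: non-numeric ddG "
                f"{cells[1]!r}") from None
    if not out:
        raise DataFormatError(f"{path}: no data rows")
    return out


# ---------------------------------------------------------------------------
# stability tables

_STAB_COLS = ("variant", "dG_NI", "se_dG_NI", "dG_IU", "se_dG_IU",
              "dG_NU", "se_dG_NU", "ddG_NU", "m_NI", "se_m_NI",
              "m_IU", "se_m_IU", "source")
_STAB_FIELDS = ("variant", "dg_ni", "se_dg_ni", "dg_iu", "se_dg_iu",
                "dg_nu", "se_dg_nu", "ddg_nu", "m_ni", "se_m_ni",
                "m_iu", "se_m_iu", "source")


def write_stability_table(records: list[StabilityRecord], path,
                          as_json: bool = False) -> None:
    """Write the stability table as TSV (default) or JSON.

    The TSV mirrors the usual report layout — one row per variant, empty
    cells for unavailable values (literature records).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if as_json:
        payload = [{f: getattr(r, f) for f in _STAB_FIELDS} for r in records]
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    with path.open("w", newline="") as fh:
        fh.write("\t".join(_STAB_COLS) + "\n")
        for r in records:
            cells = []
            for f in _STAB_FIELDS:
                v = getattr(r, f)
                cells.append("" if v is None else
                             (v if isinstance(v, str) else repr(float(v))))
            fh.write("\t".join(cells) + "\n")


def read_stability_table(path) -> list[StabilityRecord]:
    """Read back a stability table written by :func:`write_stability_table`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return [StabilityRecord(**rec) for rec in payload]
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            kwargs = {}
            for col, fname in zip(_STAB_COLS, _STAB_FIELDS):
                v = row.get(col, "")
                if fname in ("variant", "source"):
                    kwargs[fname] = v
                else:
                    kwargs[fname] = float(v) if v not in ("", None) else None
            records.append(StabilityRecord(**kwargs))
    if not records:
        raise DataFormatError(f"{path}: no records")
    return records


# ---------------------------------------------------------------------------
# fit results

def write_fit_json(fit: FitResult, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    p = fit.params
    if isinstance(p, ThreeStateParams):
        pdata = {"model": "three_state",
                 "dg_ni": p.ni.dg0, "m_ni": p.ni.m,
                 "dg_iu": p.iu.dg0, "m_iu": p.iu.m,
                 "baseline_n": p.baseline_n, "baseline_i": p.baseline_i,
                 "baseline_u": p.baseline_u,
                 "baseline_slopes": list(p.baseline_slopes),
                 "temperature_K": p.temperature}
    else:
        pdata = {"model": "two_state",
                 "dg_nu": p.nu.dg0, "m_nu": p.nu.m,
                 "baseline_n": p.baseline_n, "baseline_u": p.baseline_u,
                 "baseline_slopes": list(p.baseline_slopes),
                 "temperature_K": p.temperature}
    payload = {
        "params": pdata,
        "param_names": list(fit.param_names),
        "stderr": fit.stderr,
        "covariance": np.asarray(fit.covariance).tolist(),
        "rss": fit.rss, "n_points": fit.n_points, "aic": fit.aic,
        "converged": fit.converged, "identifiable": fit.identifiable,
        "residuals": np.asarray(fit.residuals).tolist(),
        "message": fit.message,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")


def read_fit_json(path) -> FitResult:
    payload = json.loads(Path(path).read_text())
    pd_ = payload["params"]
    slopes = pd_.get("baseline_slopes", [])
    if pd_["model"] == "three_state":
        sn, si, su = (slopes + [0.0] * 3)[:3]
        params = ThreeStateParams(
            ni=TransitionThermo(pd_["dg_ni"], pd_["m_ni"]),
            iu=TransitionThermo(pd_["dg_iu"], pd_["m_iu"]),
            baseline_n=pd_["baseline_n"], baseline_i=pd_["baseline_i"],
            baseline_u=pd_["baseline_u"],
            baseline_slope_n=sn, baseline_slope_i=si, baseline_slope_u=su,
            temperature=pd_.get("temperature_K", 298.15))
    else:
        sn, su = (slopes + [0.0] * 2)[:2]
        params = TwoStateParams(
            nu=TransitionThermo(pd_["dg_nu"], pd_["m_nu"]),
            baseline_n=pd_["baseline_n"], baseline_u=pd_["baseline_u"],
            baseline_slope_n=sn, baseline_slope_u=su,
            temperature=pd_.get("temperature_K", 298.15))
    return FitResult(
        params=params, param_names=tuple(payload["param_names"]),
        stderr=dict(payload["stderr"]),
        covariance=np.asarray(payload["covariance"]),
        rss=payload["rss"], n_points=payload["n_points"],
        aic=payload["aic"], converged=payload["converged"],
        residuals=np.asarray(payload["residuals"]),
        identifiable=payload.get("identifiable", True),
        message=payload.get("message", ""))


def write_comparison_json(result: ComparisonResult, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    r = result.pearson_r
    payload = {
        "pairs": [{"variant": v, "ddg_experimental": e, "ddg_predicted": p}
                  for v, e, p in result.pairs],
        "pearson_r": None if math.isnan(r) else r,
        "rmse": result.rmse,
        "max_abs_deviation": result.max_abs_deviation,
        "max_deviation_variant": result.max_deviation_variant,
        "n": result.n,
        "unmatched": list(result.unmatched),
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
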