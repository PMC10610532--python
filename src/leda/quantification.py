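"""Peak integration, external-standard calibration and back-calculation.

Quantification uses the reference-ion (unfragmented precursor) signal: peak
areas on the Ri trace are converted to concentrations through an external
calibration curve, by default the single chlorogenic acid (5-CQA) curve
shared across all isomers — a reasonable compromise since isomers ionize
with near-identical efficiency in the electrospray source. Limits of
detection and quantification follow the standard-error-of-intercept
approach: LOD = 3.3*SE(intercept)/slope, LOQ = 10*SE(intercept)/slope.
Working-solution concentrations are scaled back to the extract through a
configurable dilution factor (default 20, i.e. 50 uL brought to 1 mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .leda_core import ReconstructedChromatogram

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "DEFAULT_DILUTION_FACTOR",
    "LOD_FACTOR",
    "LOQ_FACTOR",
    "integrate_peak",
    "fit_calibration",
    "read_calibration_csv",
    "quantify",
    "quantify_deconvolved",
    "aggregate_replicates",
    "results_to_frame",
]

DEFAULT_DILUTION_FACTOR = 20.0
LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass(frozen=True)
class CalibrationCurve:
    """External-standard regression of Ri peak area on concentration."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    y_se: float
    lod: float
    loq: float
    levels: tuple[tuple[float, tuple[float, ...]], ...]
    valid: bool = True

    def concentration(self, area: float) -> float:
        return (area - self.intercept) / self.slope

    def area(self, concentration: float) -> float:
        return self.intercept + self.slope * concentration


@dataclass(frozen=True)
class QuantResult:
    """One analyte's concentration in working solution and extract."""

    isomer: str
    ws_concentration: float
    es_concentration: float
    ri_area: float
    ws_sd: float = 0.0
    es_sd: float = 0.0
    n_replicates: int = 1
    flags: tuple[str, ...] = ()


def integrate_peak(
    times: Sequence[float],
    abundances: Sequence[float],
    window: tuple[float, float],
) -> float:
    """Trapezoidal area of a trace inside a retention-time window (zero baseline)."""
    t = np.asarray(times, float)
    y = np.asarray(abundances, float)
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 2:
        raise ValueError(
            f"window {window} contains {int(mask.sum())} points; need at least 2"
        )
    return float(np.trapezoid(y[mask], t[mask]))


def fit_calibration(
    levels: Sequence[tuple[float, Sequence[float]]],
    analyte: str = "5-CQA",
) -> CalibrationCurve:
    """Ordinary least-squares calibration line over all replicate points.

    ``levels`` is a list of (nominal concentration, replicate areas). LOD
    and LOQ come from the standard error of the y-intercept divided by the
    slope (factors 3.3 and 10).
    """
    distinct = {float(c) for c, _ in levels}
    if len(distinct) < 3:
        raise ValueError(f"need >= 3 distinct concentration levels, got {len(distinct)}")
    x = np.array([c for c, areas in levels for _ in areas], float)
    y = np.array([a for _, areas in levels for a in areas], float)
    fit = scipy.stats.linregress(x, y)
    y_se = float(fit.intercept_stderr)
    valid = fit.slope > 0
    lod = LOD_FACTOR * y_se / fit.slope if valid else math.nan
    loq = LOQ_FACTOR * y_se / fit.slope if valid else math.nan
    return CalibrationCurve(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        y_se=y_se,
        lod=lod,
        loq=loq,
        levels=tuple((float(c), tuple(map(float, areas))) for c, areas in levels),
        valid=bool(valid),
    )


def read_calibration_csv(path: str | Path, analyte: str = "5-CQA") -> CalibrationCurve:
    """Read a calibration CSV (columns: level_mg_l, replicate, area) and fit."""
    df = pd.read_csv(path)
    levels = [
        (float(level), tuple(grp["area"].astype(float)))
        for level, grp in df.groupby("level_mg_l")
    ]
    return fit_calibration(levels, analyte)


def quantify(
    ri_area: float,
    curve: CalibrationCurve,
    dilution_factor: float = DEFAULT_DILUTION_FACTOR,
    isomer: str = "",
) -> QuantResult:
    """Convert one Ri peak area to working-solution and extract concentrations.

    Values below the curve's LOQ/LOD are flagged; a concentration that
    comes out negative is reported as zero with a below-LOD flag rather
    than as a negative number.
    """
    if not curve.valid:
        raise ValueError("calibration curve flagged invalid (non-positive slope)")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be > 0")
    ws = curve.concentration(ri_area)
    flags: list[str] = []
    if ws < 0:
        ws = 0.0
        flags.append("below LOD")
    elif ws < curve.lod:
        flags.append("below LOD")
    elif ws < curve.loq:
        flags.append("below LOQ")
    return QuantResult(
        isomer=isomer,
        ws_concentration=ws,
        es_concentration=ws * dilution_factor,
        ri_area=float(ri_area),
        flags=tuple(flags),
    )


def quantify_deconvolved(
    reconstruction: ReconstructedChromatogram,
    windows: Mapping[str, tuple[float, float]],
    curve: CalibrationCurve,
    dilution_factor: float = DEFAULT_DILUTION_FACTOR,
) -> list[QuantResult]:
    """Quantify each isomer from its reconstructed reference-ion trace.

    Each isomer's trace is integrated over its configured window and
    converted through the shared calibration curve. Isomers without a
    window entry are skipped.
    """
    results = []
    for isomer, trace in reconstruction.per_isomer_traces.items():
        if isomer not in windows:
            continue
        area = integrate_peak(reconstruction.times, trace, windows[isomer])
        results.append(quantify(area, curve, dilution_factor, isomer=isomer))
    return results


def aggregate_replicates(replicates: Sequence[QuantResult]) -> QuantResult:
    """Mean and sample SD across replicate analyses of the same isomer."""
    if not replicates:
        raise ValueError("no replicates to aggregate")
    isomers = {r.isomer for r in replicates}
    if len(isomers) != 1:
        raise ValueError(f"replicates span several isomers: {sorted(isomers)}")
    ws = np.array([r.ws_concentration for r in replicates])
    es = np.array([r.es_concentration for r in replicates])
    n = len(replicates)
    flags = tuple(sorted({f for r in replicates for f in r.flags}))
    return QuantResult(
        isomer=replicates[0].isomer,
        ws_concentration=float(ws.mean()),
        es_concentration=float(es.mean()),
        ri_area=float(np.mean([r.ri_area for r in replicates])),
        ws_sd=float(ws.std(ddof=1)) if n > 1 else 0.0,
        es_sd=float(es.std(ddof=1)) if n > 1 else 0.0,
        n_replicates=n,
        flags=flags,
    )


def results_to_frame(results: Sequence[QuantResult]) -> pd.DataFrame:
    """Tabulate results (isomer, ws, ws_sd, es, es_sd, flags)."""
    return pd.DataFrame(
        {
            "isomer": [r.isomer for r in results],
            "ws_mg_l": [r.ws_concentration for r in results],
            "ws_sd": [r.ws_sd for r in results],
            "es_mg_l": [r.es_concentration for r in results],
            "es_sd": [r.es_sd for r in results],
            "ri_area": [r.ri_area for r in results],
            "flags": ["; ".join(r.flags) for r in results],
        }
    )
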