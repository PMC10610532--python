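"""Energy-resolved MS/MS (ERMS) breakdown-curve analysis.

An ERMS experiment fragments the same precursor ion at stepwise-increasing
excitation amplitudes (ExA) and records, at each step, the surviving
precursor and every product ion. Three curves summarize the energetics of
collision-induced dissociation (CID):

* survival yield, ``SY = 100 * precursor / (precursor + sum(products))``;
* product-ion formation, ``PiF = 100 * sum(products) / (precursor + sum(products))``,
  the complement of SY;
* product-ion yield, ``PiY = 100 * sum(products) / precursor_max``, which
  references the pre-activation precursor level and therefore exposes ion
  losses (precursor ejection, products below the trap's low-mass cut-off)
  that SY/PiF cannot see.

``precursor_max`` is the mean precursor abundance over the low-ExA plateau,
before any fragmentation channel opens. The summary statistics are the ExA
at 50% survival (SY_ExA50, where the SY and PiF curves cross), the ExA of
maximal product yield (ExA_max — the amplitude to use in an acquisition
method) and that maximal yield (PiY_max).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ErmsSeries",
    "BreakdownCurves",
    "CidSummary",
    "UndefinedGridPointError",
    "PlateauError",
    "compute_sy_pif",
    "estimate_precursor_max",
    "compute_piy",
    "build_breakdown_curves",
    "estimate_cid_summary",
    "read_erms_csv",
    "write_erms_csv",
    "write_curves_csv",
]

#: Grid points with survival yield at or above this value (%) form the
#: pre-activation plateau used to estimate the precursor level.
PLATEAU_SY_THRESHOLD = 95.0


class UndefinedGridPointError(ValueError):
    """Total ion abundance is zero at a grid point; SY/PiF are undefined."""


class PlateauError(ValueError):
    """No grid point qualifies as pre-activation plateau."""


@dataclass(frozen=True)
class ErmsSeries:
    """Ion abundances of one compound across an ExA ramp.

    ``product_abundances`` maps product m/z to a per-ExA abundance trace of
    the same length as ``exa_grid``.
    """

    compound_id: str
    exa_grid: tuple[float, ...]
    precursor_abundance: tuple[float, ...]
    product_abundances: Mapping[float, tuple[float, ...]]

    def __post_init__(self) -> None:
        grid = np.asarray(self.exa_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("empty ExA grid")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("exa_grid must be strictly increasing")
        n = grid.size
        if len(self.precursor_abundance) != n:
            raise ValueError("precursor trace length differs from grid")
        if min(self.precursor_abundance, default=0.0) < 0:
            raise ValueError("negative precursor abundance")
        for mz, trace in self.product_abundances.items():
            if len(trace) != n:
                raise ValueError(f"product {mz} trace length differs from grid")
            if min(trace, default=0.0) < 0:
                raise ValueError(f"negative abundance in product {mz} trace")

    def product_sum(self) -> np.ndarray:
        if not self.product_abundances:
            return np.zeros(len(self.exa_grid))
        return np.sum([np.asarray(t, float) for t in self.product_abundances.values()], axis=0)


@dataclass(frozen=True)
class BreakdownCurves:
    """SY/PiF/PiY curves on the ExA grid.

    ``defined`` marks grid points with nonzero total ion current; SY and
    PiF are NaN elsewhere. ``per_ion_yield`` is each product trace divided
    by the pre-activation precursor level (fraction, not percent).
    """

    exa_grid: tuple[float, ...]
    sy: tuple[float, ...]
    pif: tuple[float, ...]
    piy: tuple[float, ...]
    per_ion_yield: Mapping[float, tuple[float, ...]]
    precursor_max: float
    defined: tuple[bool, ...]


@dataclass(frozen=True)
class CidSummary:
    """Summary statistics of a CID energetic study.

    ``sy_exa50`` is None when the survival curve never falls below 50%.
    """

    sy_exa50: float | None
    exa_max: float
    piy_max: float
    precursor_max: float


def compute_sy_pif(precursor: float, products: Sequence[float]) -> tuple[float, float]:
    """Survival yield and product-ion formation (%) at one grid point.

    Both are fractions of the total detected ion current, so they sum to
    100 by construction. A zero total is flagged rather than imputed.
    """
    if precursor < 0 or any(p < 0 for p in products):
        raise ValueError("abundances must be >= 0")
    total = precursor + float(np.sum(products)) if products else float(precursor)
    if total <= 0:
        raise UndefinedGridPointError("total ion abundance is zero")
    sy = 100.0 * precursor / total
    return sy, 100.0 - sy


def estimate_precursor_max(
    series: ErmsSeries, plateau_threshold: float = PLATEAU_SY_THRESHOLD
) -> float:
    """Mean precursor abundance over the pre-activation plateau.

    The plateau is the set of grid points whose survival yield is at least
    ``plateau_threshold`` percent.
    """
    precursor = np.asarray(series.precursor_abundance, float)
    products = series.product_sum()
    total = precursor + products
    with np.errstate(invalid="ignore", divide="ignore"):
        sy = np.where(total > 0, 100.0 * precursor / np.where(total > 0, total, 1.0), np.nan)
    mask = sy >= plateau_threshold
    if not mask.any():
        raise PlateauError(
            f"no grid point has SY >= {plateau_threshold}%; lower the plateau threshold"
        )
    return float(precursor[mask].mean())


def compute_piy(products: Sequence[float], precursor_max: float) -> float:
    """Product-ion yield (%) relative to the pre-activation precursor level."""
    if precursor_max <= 0:
        raise ValueError("precursor_max must be > 0")
    return 100.0 * float(np.sum(products)) / precursor_max


def build_breakdown_curves(
    series: ErmsSeries, plateau_threshold: float = PLATEAU_SY_THRESHOLD
) -> BreakdownCurves:
    """Evaluate SY, PiF, PiY and per-ion yields at every grid point."""
    precursor = np.asarray(series.precursor_abundance, float)
    products = series.product_sum()
    total = precursor + products
    defined = total > 0
    sy = np.full_like(precursor, np.nan)
    sy[defined] = 100.0 * precursor[defined] / total[defined]
    pif = np.where(defined, 100.0 - sy, np.nan)
    pmax = estimate_precursor_max(series, plateau_threshold)
    piy = 100.0 * products / pmax
    per_ion = {
        mz: tuple(np.asarray(trace, float) / pmax)
        for mz, trace in series.product_abundances.items()
    }
    return BreakdownCurves(
        exa_grid=tuple(series.exa_grid),
        sy=tuple(sy),
        pif=tuple(pif),
        piy=tuple(piy),
        per_ion_yield=per_ion,
        precursor_max=pmax,
        defined=tuple(bool(d) for d in defined),
    )


def estimate_cid_summary(curves: BreakdownCurves) -> CidSummary:
    """Extract SY_ExA50, ExA_max and PiY_max from breakdown curves.

    SY_ExA50 is the first downward 50% crossing of the survival curve,
    linearly interpolated between the bracketing grid points; it is None if
    the curve never falls below 50%. ExA_max is reported on the sampled
    grid (ties broken toward the lower amplitude).
    """
    grid = np.asarray(curves.exa_grid, float)
    defined = np.asarray(curves.defined, bool)
    sy = np.asarray(curves.sy, float)[defined]
    gsy = grid[defined]
    sy_exa50 = None
    for i in range(1, sy.size):
        if sy[i - 1] >= 50.0 > sy[i]:
            frac = (sy[i - 1] - 50.0) / (sy[i - 1] - sy[i])
            sy_exa50 = float(gsy[i - 1] + frac * (gsy[i] - gsy[i - 1]))
            break
    if sy_exa50 is None and sy.size and sy[0] < 50.0:
        sy_exa50 = float(gsy[0])
    piy = np.asarray(curves.piy, float)
    imax = int(np.argmax(piy))  # argmax returns the first (lowest-ExA) tie
    return CidSummary(
        sy_exa50=sy_exa50,
        exa_max=float(grid[imax]),
        piy_max=float(piy[imax]),
        precursor_max=curves.precursor_max,
    )


# ---------------------------------------------------------------------------
# CSV interfaces (tidy: compound, exa, ion_mz, abundance)


def write_erms_csv(series: ErmsSeries, path: str | Path, precursor_mz: float) -> None:
    rows = []
    for exa, ab in zip(series.exa_grid, series.precursor_abundance):
        rows.append((series.compound_id, exa, precursor_mz, ab))
    for mz, trace in series.product_abundances.items():
        for exa, ab in zip(series.exa_grid, trace):
            rows.append((series.compound_id, exa, mz, ab))
    pd.DataFrame(rows, columns=["compound", "exa", "ion_mz", "abundance"]).to_csv(
        path, index=False
    )


def read_erms_csv(
    path: str | Path, precursor_mz: float, mz_tolerance: float = 0.5
) -> list[ErmsSeries]:
    """Read tidy ERMS tables; rows within ``mz_tolerance`` of the precursor
    m/z form the precursor trace, all other ions are products."""
    df = pd.read_csv(path)
    out = []
    for compound, grp in df.groupby("compound", sort=False):
        grid = np.array(sorted(grp["exa"].unique()), float)
        is_precursor = (grp["ion_mz"] - precursor_mz).abs() <= mz_tolerance
        prec = (
            grp[is_precursor]
            .groupby("exa")["abundance"]
            .sum()
            .reindex(grid, fill_value=0.0)
        )
        products = {}
        for mz, sub in grp[~is_precursor].groupby("ion_mz"):
            products[float(mz)] = tuple(
                sub.groupby("exa")["abundance"].sum().reindex(grid, fill_value=0.0)
            )
        out.append(
            ErmsSeries(
                compound_id=str(compound),
                exa_grid=tuple(grid),
                precursor_abundance=tuple(prec),
                product_abundances=products,
            )
        )
    return out


def write_curves_csv(curves: BreakdownCurves, path: str | Path) -> None:
    data = {
        "exa": curves.exa_grid,
        "sy": curves.sy,
        "pif": curves.pif,
        "piy": curves.piy,
    }
    for mz, trace in curves.per_ion_yield.items():
        data[f"yield_{mz:g}"] = trace
    pd.DataFrame(data).to_csv(path, index=False)
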