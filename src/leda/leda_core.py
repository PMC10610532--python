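"""Linear deconvolution of co-eluting isomers from MS/MS ratio fingerprints.

Positional isomers such as the caffeoylquinic acids share a precursor ion
and a common panel of product ions, but form each product with a different,
reproducible yield. Dividing every product-ion (Pi) abundance by the
reference-ion (Ri) abundance — the unfragmented precursor acquired in the
alternating low-energy event — gives a per-isomer fingerprint of
characteristic Pi/Ri ratios that is independent of the amount on column.

A measured ratio vector from a mixture is then modelled as a non-negative
combination of the pure-isomer fingerprints,

    (Pi/Ri)_measured = sum_x (Pi/Ri)_x * f_x ,

one equation per retained product ion. With more product ions than isomers
the system is overdetermined and is solved by non-negative least squares;
``f_x`` is the fraction of the reference-ion signal attributable to isomer
``x``. Applied to every acquired data point in turn, the solution splits
the reference-ion chromatogram into one reconstructed trace per isomer;
applied to integrated peak areas it yields the peak-purity proportions.

Only product ions with a characteristic ratio of at least 2% for some
isomer enter the system: smaller ratios are indistinguishable from their
own run-to-run variability and would only inject noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .scan_model import DEFAULT_MZ_TOLERANCE, PairedDataPoint, extract_ion

__all__ = [
    "RatioTable",
    "LedaMatrix",
    "DeconvolutionResult",
    "ReconstructedChromatogram",
    "UnderdeterminedSystemError",
    "RATIO_THRESHOLD",
    "CONDITION_NUMBER_FLAG",
    "MIN_RI_GATE_FRACTION",
    "load_bundled_ratio_table",
    "compute_characteristic_ratios",
    "assemble_leda_matrix",
    "solve_leda",
    "deconvolve_scanwise",
    "deconvolve_peak",
]

#: Characteristic ratios below this value for every isomer are dropped
#: from the linear system (the ">= 2%" retention rule).
RATIO_THRESHOLD = 0.02

#: Design matrices with a condition number above this get a collinearity flag.
CONDITION_NUMBER_FLAG = 1e6

#: Scanwise deconvolution skips points whose Ri is below this fraction of
#: the run's maximum Ri (baseline gate); their signal goes to the residual.
MIN_RI_GATE_FRACTION = 0.01


class UnderdeterminedSystemError(ValueError):
    """Fewer retained product ions than isomers after the ratio filter."""


@dataclass(frozen=True)
class RatioTable:
    """Characteristic Pi/Ri ratios of a group of isomers.

    ``ratios`` and ``ratio_sds`` are (product ion x isomer) matrices; rows
    follow ``product_mzs`` and columns follow ``isomer_ids``.
    """

    group_id: str
    reference_mz: float
    isomer_ids: tuple[str, ...]
    product_mzs: tuple[float, ...]
    ratios: np.ndarray
    ratio_sds: np.ndarray

    def __post_init__(self) -> None:
        ratios = np.asarray(self.ratios, float)
        sds = np.asarray(self.ratio_sds, float)
        object.__setattr__(self, "ratios", ratios)
        object.__setattr__(self, "ratio_sds", sds)
        if len(self.isomer_ids) < 2:
            raise ValueError("a ratio table needs at least two isomers")
        expected = (len(self.product_mzs), len(self.isomer_ids))
        if ratios.shape != expected or sds.shape != expected:
            raise ValueError(f"ratio matrices must have shape {expected}")
        if (ratios < 0).any() or (sds < 0).any():
            raise ValueError("ratios and SDs must be >= 0")

    def column(self, isomer_id: str) -> np.ndarray:
        """The full (unfiltered) characteristic ratio vector of one isomer."""
        return self.ratios[:, self.isomer_ids.index(isomer_id)].copy()

    @classmethod
    def from_csv(cls, path: str | Path, group_id: str | None = None) -> "RatioTable":
        """Read one isomer group from a long-format ratio CSV.

        Columns: group, reference_mz, product_mz, isomer, ratio, sd. If the
        file holds several groups, ``group_id`` selects one.
        """
        df = pd.read_csv(path)
        groups = df["group"].unique()
        if group_id is None:
            if len(groups) != 1:
                raise ValueError(
                    f"file holds groups {list(groups)}; pass group_id to pick one"
                )
            group_id = groups[0]
        sub = df[df["group"] == group_id]
        if sub.empty:
            raise ValueError(f"no rows for group {group_id!r}")
        ref = sub["reference_mz"].unique()
        if len(ref) != 1:
            raise ValueError(f"group {group_id!r} has conflicting reference m/z {ref}")
        isomers = tuple(dict.fromkeys(sub["isomer"]))
        mzs = tuple(dict.fromkeys(sub["product_mz"].astype(float)))
        wide_r = sub.pivot(index="product_mz", columns="isomer", values="ratio")
        wide_s = sub.pivot(index="product_mz", columns="isomer", values="sd")
        ratios = wide_r.loc[list(mzs), list(isomers)].to_numpy(float)
        sds = wide_s.loc[list(mzs), list(isomers)].to_numpy(float)
        return cls(str(group_id), float(ref[0]), isomers, mzs, ratios, sds)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            (self.group_id, self.reference_mz, mz, iso, self.ratios[i, j], self.ratio_sds[i, j])
            for i, mz in enumerate(self.product_mzs)
            for j, iso in enumerate(self.isomer_ids)
        ]
        pd.DataFrame(
            rows, columns=["group", "reference_mz", "product_mz", "isomer", "ratio", "sd"]
        ).to_csv(path, index=False)


def load_bundled_ratio_table(group_id: str) -> RatioTable:
    """Load the shipped caffeoylquinic-acid ratio table ('CQAs' or 'diCQAs')."""
    ref = resources.files("leda.data").joinpath("caffeoylquinic_ratios.csv")
    with resources.as_file(ref) as path:
        return RatioTable.from_csv(path, group_id)


@dataclass(frozen=True)
class LedaMatrix:
    """The filtered (product ion x isomer) design matrix of the system."""

    design: np.ndarray
    row_mzs: tuple[float, ...]
    isomer_ids: tuple[str, ...]
    reference_mz: float
    row_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        design = np.asarray(self.design, float)
        object.__setattr__(self, "design", design)
        m, n = design.shape
        if m < n:
            raise UnderdeterminedSystemError(
                f"{m} retained product ions for {n} isomers"
            )


@dataclass(frozen=True)
class DeconvolutionResult:
    """Per-isomer fractions of the reference-ion signal for one solve.

    ``unassigned`` is the part of the signal the known fingerprints do not
    explain (clipped at zero); overshoot above one is renormalized away and
    flagged instead.
    """

    isomer_ids: tuple[str, ...]
    fractions: np.ndarray
    residual_norm: float
    unassigned: float
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.isomer_ids, map(float, self.fractions)))


@dataclass(frozen=True)
class ReconstructedChromatogram:
    """Reference-ion chromatogram split into per-isomer traces.

    At every time point the per-isomer traces plus the residual trace sum
    to the reference-ion trace.
    """

    times: np.ndarray
    ri_trace: np.ndarray
    per_isomer_traces: Mapping[str, np.ndarray]
    residual_trace: np.ndarray
    point_flags: tuple[tuple[str, ...], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "ri": self.ri_trace}
        data.update(self.per_isomer_traces)
        data["residual"] = self.residual_trace
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Characteristic ratios


def compute_characteristic_ratios(
    points: Sequence[PairedDataPoint],
    product_mzs: Sequence[float],
    reference_mz: float,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of each product/reference ratio over a pure-isomer peak.

    Each paired point with nonzero reference-ion abundance contributes one
    ratio observation per product ion (the product abundance extracted from
    its high-energy spectrum divided by the interpolated reference-ion
    abundance). ``reference_mz`` is carried for signature symmetry with the
    acquisition config; the reference abundance itself comes from pairing.
    """
    usable = [p for p in points if p.ri_abundance > 0]
    if not usable:
        raise ValueError("no paired point has reference-ion abundance > 0")
    obs = np.array(
        [
            [extract_ion(p.pis_spectrum, mz, tolerance) / p.ri_abundance for mz in product_mzs]
            for p in usable
        ]
    )
    means = obs.mean(axis=0)
    sds = obs.std(axis=0, ddof=1) if obs.shape[0] > 1 else np.zeros(len(product_mzs))
    return means, sds


# ---------------------------------------------------------------------------
# System assembly and solving


def assemble_leda_matrix(
    table: RatioTable, threshold: float = RATIO_THRESHOLD
) -> LedaMatrix:
    """Build the overdetermined system, dropping uninformative product ions.

    A product ion is retained when its characteristic ratio reaches
    ``threshold`` for at least one isomer; row order is preserved. Raises
    if fewer rows than isomers survive.
    """
    keep = np.max(table.ratios, axis=1) >= threshold
    m, n = int(keep.sum()), len(table.isomer_ids)
    if m < n:
        raise UnderdeterminedSystemError(
            f"only {m} product ions pass the {threshold:.0%} filter for {n} isomers"
        )
    return LedaMatrix(
        design=table.ratios[keep],
        row_mzs=tuple(mz for mz, k in zip(table.product_mzs, keep) if k),
        isomer_ids=table.isomer_ids,
        reference_mz=table.reference_mz,
        row_sds=table.ratio_sds[keep],
    )


def solve_leda(
    matrix: LedaMatrix,
    measured: Sequence[float],
    weighted: bool = False,
) -> DeconvolutionResult:
    """Solve one measured ratio vector for non-negative isomer fractions.

    Ordinary non-negative least squares by default; with ``weighted`` each
    row is scaled by 1/SD of its characteristic ratio (rows with zero SD
    keep unit weight). No sum-to-one constraint is imposed, so signal from
    unknown co-eluting species appears as an unassigned remainder rather
    than being forced onto the known isomers.
    """
    b = np.asarray(measured, float)
    m, n = matrix.design.shape
    if b.shape != (m,):
        raise ValueError(f"measured vector has shape {b.shape}, expected ({m},)")
    if (b < 0).any():
        raise ValueError("measured ratios must be >= 0")
    flags: list[str] = []
    if not b.any():
        return DeconvolutionResult(
            isomer_ids=matrix.isomer_ids,
            fractions=np.zeros(n),
            residual_norm=0.0,
            unassigned=1.0,
            flags=("no product signal",),
        )
    design = matrix.design
    if weighted and matrix.row_sds is not None:
        sds = np.where(matrix.row_sds.max(axis=1) > 0, matrix.row_sds.max(axis=1), 1.0)
        design = design / sds[:, None]
        b = b / sds
    if np.linalg.cond(matrix.design) > CONDITION_NUMBER_FLAG:
        flags.append("collinear design")
    fractions, rnorm = scipy.optimize.nnls(design, b)
    total = float(fractions.sum())
    if total > 1.0:
        fractions = fractions / total
        flags.append("overshoot renormalized")
        unassigned = 0.0
    else:
        unassigned = 1.0 - total
    return DeconvolutionResult(
        isomer_ids=matrix.isomer_ids,
        fractions=fractions,
        residual_norm=float(rnorm),
        unassigned=unassigned,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Scanwise and peak-mode deconvolution


def _measured_vector(
    point: PairedDataPoint, matrix: LedaMatrix, tolerance: float
) -> np.ndarray:
    products = np.array(
        [extract_ion(point.pis_spectrum, mz, tolerance) for mz in matrix.row_mzs]
    )
    return products / point.ri_abundance


def deconvolve_scanwise(
    points: Sequence[PairedDataPoint],
    matrix: LedaMatrix,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
    min_ri_fraction: float = MIN_RI_GATE_FRACTION,
    weighted: bool = False,
) -> ReconstructedChromatogram:
    """Deconvolve every acquired data point and reconstruct the chromatogram.

    For each paired point the measured Pi/Ri vector is solved for isomer
    fractions and the reference-ion abundance is apportioned accordingly;
    whatever is unassigned goes to the residual trace. Points whose Ri is
    below ``min_ri_fraction`` of the run's maximum (baseline) are not
    solved: their Ri goes entirely to the residual, keeping the pointwise
    conservation Ri = sum(isomer traces) + residual exact.
    """
    if not points:
        raise ValueError("no paired data points to deconvolve")
    pts = sorted(points, key=lambda p: p.retention_time)
    times = np.array([p.retention_time for p in pts])
    ri = np.array([p.ri_abundance for p in pts])
    gate = ri.max() * min_ri_fraction if ri.size else 0.0
    traces = {iso: np.zeros(len(pts)) for iso in matrix.isomer_ids}
    residual = np.zeros(len(pts))
    point_flags: list[tuple[str, ...]] = []
    for i, p in enumerate(pts):
        if p.ri_abundance <= 0:
            point_flags.append(("zero reference signal",))
            continue
        if p.ri_abundance < gate:
            residual[i] = p.ri_abundance
            point_flags.append(("below baseline gate",))
            continue
        result = solve_leda(matrix, _measured_vector(p, matrix, tolerance), weighted)
        for iso, frac in zip(matrix.isomer_ids, result.fractions):
            traces[iso][i] = p.ri_abundance * float(frac)
        residual[i] = p.ri_abundance * result.unassigned
        point_flags.append(result.flags)
    return ReconstructedChromatogram(
        times=times,
        ri_trace=ri,
        per_isomer_traces=traces,
        residual_trace=residual,
        point_flags=tuple(point_flags),
    )


def deconvolve_peak(
    points: Sequence[PairedDataPoint],
    matrix: LedaMatrix,
    window: tuple[float, float] | None = None,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
    weighted: bool = False,
) -> DeconvolutionResult:
    """Peak-purity deconvolution from integrated areas over one peak.

    Product-ion and reference-ion traces are integrated (trapezoidal) over
    the window; the vector of area ratios is then solved exactly like a
    single scan. The fractions are the proportions of the reference-ion
    peak area attributable to each isomer.
    """
    pts = sorted(points, key=lambda p: p.retention_time)
    if window is not None:
        pts = [p for p in pts if window[0] <= p.retention_time <= window[1]]
    if len(pts) < 2:
        raise ValueError("peak window holds fewer than two paired points")
    t = np.array([p.retention_time for p in pts])
    ri_area = float(np.trapezoid([p.ri_abundance for p in pts], t))
    if ri_area <= 0:
        raise ValueError("reference-ion area over the window is zero")
    pi_areas = np.array(
        [
            np.trapezoid([extract_ion(p.pis_spectrum, mz, tolerance) for p in pts], t)
            for mz in matrix.row_mzs
        ]
    )
    return solve_leda(matrix, pi_areas / ri_area, weighted)
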