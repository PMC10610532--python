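"""Seedable generators for alternating-event LC-MS/MS runs and ERMS series.

The run generator emulates an ion-trap acquisition with chromatographic
time segments, alternating low-energy (reference-ion) and high-energy
(product-ion) events at a fixed cadence, Gaussian elution peaks, and
per-isomer product yields taken from a characteristic-ratio table: at any
instant each isomer contributes its Gaussian peak value to the precursor
signal, and each product ion receives that contribution multiplied by the
isomer's characteristic Pi/Ri ratio. Noise is multiplicative lognormal
with a configurable coefficient of variation, matching the roughly
constant relative scatter of measured ratio tables across signal levels.

The ERMS generator draws a logistic precursor survival curve over an ExA
ramp; the fragmented fraction, minus a configurable ion-loss fraction
(precursor ejection and sub-cut-off products), is split across product
ions in fixed proportions.

Both generators are pure functions of (scenario, seed): the same inputs
reproduce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.special import erfc

from .erms_breakdown import ErmsSeries
from .leda_core import RatioTable, load_bundled_ratio_table
from .scan_model import EventKind, MsmsScan, TimeSegmentConfig, read_segment_config

__all__ = [
    "GaussianPeak",
    "RunScenario",
    "ErmsScenario",
    "simulate_run",
    "simulate_erms",
    "acmella_like_scenario",
    "pure_isomer_scenario",
    "read_scenario_yaml",
    "DEFAULT_SCAN_PERIOD",
]

#: Minutes between consecutive acquisition events (0.6 s); one Ri/Pis pair
#: every 1.2 s gives >= 15 paired points across a 0.2-min-wide peak.
DEFAULT_SCAN_PERIOD = 0.01


@dataclass(frozen=True)
class GaussianPeak:
    """One isomer's elution peak: Gaussian, optionally exponentially modified.

    ``height`` is the reference-ion apex abundance (counts), ``width`` the
    Gaussian sigma in minutes. A positive ``tau`` (minutes) switches to an
    exponentially modified Gaussian of the same area, for tailing-peak
    stress tests.
    """

    retention_time: float
    width: float
    height: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.height < 0:
            raise ValueError("peak height must be >= 0")

    def value(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, float)
        if self.tau <= 0:
            return self.height * np.exp(-0.5 * ((t - self.retention_time) / self.width) ** 2)
        # EMG with the same area as the Gaussian (height * width * sqrt(2*pi))
        s, tau, mu = self.width, self.tau, self.retention_time
        z = (s / tau - (t - mu) / s) / math.sqrt(2)
        return (
            self.height
            * s
            / tau
            * math.sqrt(math.pi / 2)
            * np.exp(0.5 * (s / tau) ** 2 - (t - mu) / tau)
            * erfc(z)
        )

    @property
    def area(self) -> float:
        """Closed-form area of the peak (identical for Gaussian and EMG)."""
        return self.height * self.width * math.sqrt(2 * math.pi)


@dataclass(frozen=True)
class RunScenario:
    """Everything needed to simulate one acquisition run.

    ``ratio_tables`` maps segment id to the characteristic-ratio table of
    the isomer group acquired in that segment; ``isomer_peaks`` maps each
    isomer (a column of one of those tables) to its elution peak.
    """

    segments: tuple[TimeSegmentConfig, ...]
    ratio_tables: Mapping[int, RatioTable]
    isomer_peaks: Mapping[str, GaussianPeak]
    scan_period: float = DEFAULT_SCAN_PERIOD
    noise_cv: float = 0.0
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_period <= 0:
            raise ValueError("scan_period must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        known = {iso for t in self.ratio_tables.values() for iso in t.isomer_ids}
        unknown = set(self.isomer_peaks) - known
        if unknown:
            raise ValueError(f"peaks for isomers absent from all ratio tables: {sorted(unknown)}")


@dataclass(frozen=True)
class ErmsScenario:
    """Parameters of a synthetic energy-resolved MS/MS series.

    The precursor survives with probability ``1/(1+exp(steepness*(ExA -
    midpoint)))``; of the fragmented signal, ``ion_loss_fraction`` vanishes
    (ejection / sub-cut-off products) and the rest is split across
    ``product_split`` (m/z -> proportion, summing to 1).
    """

    compound_id: str = "synthetic"
    sy_midpoint: float = 21.0
    sy_steepness: float = 1.0
    ion_loss_fraction: float = 0.0
    product_split: Mapping[float, float] = field(
        default_factory=lambda: {191.0: 0.6, 179.0: 0.25, 173.0: 0.1, 135.0: 0.05}
    )
    precursor_level: float = 1_000_000.0
    exa_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 51))
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ion_loss_fraction < 1:
            raise ValueError("ion_loss_fraction must lie in [0, 1)")
        total = sum(self.product_split.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"product_split sums to {total}, expected 1")
        if np.any(np.diff(self.exa_grid) <= 0):
            raise ValueError("exa_grid must be strictly increasing")

    def survival(self, exa: np.ndarray | float) -> np.ndarray | float:
        exa = np.asarray(exa, float)
        return 1.0 / (1.0 + np.exp(self.sy_steepness * (exa - self.sy_midpoint)))


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def simulate_run(scenario: RunScenario) -> list[MsmsScan]:
    """Simulate one alternating-event acquisition run.

    Within each segment, events alternate reference-ion / product-ion at
    the scan cadence. The reference-ion scan records the summed isomer
    contributions plus baseline at the precursor m/z; the product-ion scan
    records, for each product m/z of the segment's ratio table, the sum
    over isomers of (contribution x characteristic ratio). Every recorded
    abundance is perturbed independently by unit-mean lognormal noise.
    """
    rng = np.random.default_rng(scenario.seed)
    scans: list[MsmsScan] = []
    for cfg in scenario.segments:
        table = scenario.ratio_tables.get(cfg.segment_id)
        if table is None:
            raise ValueError(f"no ratio table for segment {cfg.segment_id}")
        peaks = {
            iso: scenario.isomer_peaks[iso]
            for iso in table.isomer_ids
            if iso in scenario.isomer_peaks
        }
        t = cfg.rt_window[0]
        kind = EventKind.RI
        while t < cfg.rt_window[1]:
            contributions = {iso: float(pk.value(t)) for iso, pk in peaks.items()}
            if kind is EventKind.RI:
                ri = sum(contributions.values()) + scenario.baseline
                ri *= float(_noise_factors(rng, scenario.noise_cv, 1)[0])
                peak_list = ((cfg.precursor_mz, ri),) if ri > 0 else ()
                scan_range, exa = cfg.ri_event
            else:
                noise = _noise_factors(rng, scenario.noise_cv, len(table.product_mzs))
                peak_list = []
                for i, mz in enumerate(table.product_mzs):
                    ab = sum(
                        contributions[iso] * table.ratios[i, table.isomer_ids.index(iso)]
                        for iso in contributions
                    ) * float(noise[i])
                    if ab > 0:
                        peak_list.append((mz, ab))
                peak_list = tuple(peak_list)
                scan_range, exa = cfg.pis_event
            scans.append(
                MsmsScan(
                    retention_time=round(t, 9),
                    segment_id=cfg.segment_id,
                    event_kind=kind,
                    precursor_mz=cfg.precursor_mz,
                    excitation_amplitude=exa,
                    excitation_time=cfg.excitation_time,
                    scan_range=scan_range,
                    peaks=peak_list,
                )
            )
            t += scenario.scan_period
            kind = EventKind.PIS if kind is EventKind.RI else EventKind.RI
    scans.sort(key=lambda s: s.retention_time)
    return scans


def simulate_erms(scenario: ErmsScenario) -> ErmsSeries:
    """Simulate a logistic-survival ERMS series."""
    rng = np.random.default_rng(scenario.seed)
    grid = np.asarray(scenario.exa_grid, float)
    survival = scenario.survival(grid)
    precursor = scenario.precursor_level * survival
    precursor = precursor * _noise_factors(rng, scenario.noise_cv, grid.size)
    fragmented = (
        scenario.precursor_level * (1.0 - survival) * (1.0 - scenario.ion_loss_fraction)
    )
    products = {}
    for mz, share in scenario.product_split.items():
        trace = fragmented * share * _noise_factors(rng, scenario.noise_cv, grid.size)
        products[float(mz)] = tuple(trace)
    return ErmsSeries(
        compound_id=scenario.compound_id,
        exa_grid=tuple(grid),
        precursor_abundance=tuple(precursor),
        product_abundances=products,
    )


# ---------------------------------------------------------------------------
# Reference scenario and YAML interface


def _bundled_segments() -> tuple[TimeSegmentConfig, ...]:
    from importlib import resources

    ref = resources.files("leda.data").joinpath("fast_gradient_segments.yaml")
    with resources.as_file(ref) as path:
        return tuple(read_segment_config(path))


def acmella_like_scenario(
    seed: int = 0, noise_cv: float = 0.05, baseline: float = 500.0
) -> RunScenario:
    """A six-isomer run mimicking an Acmella oleracea root extract on the
    fast gradient: two time segments, three mono- and three di-acyl
    isomers, with the 4-CQA peak co-eluting under the tail of a much more
    concentrated 5-CQA peak. Peak heights are proportional to typical
    working-solution concentrations (counts per mg/L chosen to put the
    largest peak near 10^6 counts)."""
    segments = _bundled_segments()
    tables = {1: load_bundled_ratio_table("CQAs"), 2: load_bundled_ratio_table("diCQAs")}
    counts_per_mg_l = 2.0e5
    conc = {
        "3-CQA": 0.8,
        "5-CQA": 5.5,
        "4-CQA": 0.4,
        "3,4-diCQA": 7.0,
        "3,5-diCQA": 18.0,
        "4,5-diCQA": 4.5,
    }
    rts = {
        "3-CQA": 1.20,
        "5-CQA": 2.00,
        "4-CQA": 2.08,
        "3,4-diCQA": 4.30,
        "3,5-diCQA": 4.55,
        "4,5-diCQA": 5.40,
    }
    peaks = {
        iso: GaussianPeak(rts[iso], 0.05, conc[iso] * counts_per_mg_l) for iso in conc
    }
    return RunScenario(
        segments=segments,
        ratio_tables=tables,
        isomer_peaks=peaks,
        noise_cv=noise_cv,
        baseline=baseline,
        seed=seed,
    )


def pure_isomer_scenario(
    isomer_id: str,
    height: float = 1.0e6,
    width: float = 0.5,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[RunScenario, tuple[float, float]]:
    """A single pure-isomer run for characteristic-ratio measurement.

    Emulates the slow conventional-gradient analysis of one purified
    isomer: a broad Gaussian peak (sigma 0.5 min) centered in its group's
    time segment, so the reference-ion signal varies slowly on the scan
    cadence. Returns the scenario and the apex +/- 1 sigma integration
    window.
    """
    segments = _bundled_segments()
    tables = {1: load_bundled_ratio_table("CQAs"), 2: load_bundled_ratio_table("diCQAs")}
    for seg in segments:
        table = tables[seg.segment_id]
        if isomer_id in table.isomer_ids:
            rt = 0.5 * (seg.rt_window[0] + seg.rt_window[1])
            scenario = RunScenario(
                segments=(seg,),
                ratio_tables={seg.segment_id: table},
                isomer_peaks={isomer_id: GaussianPeak(rt, width, height)},
                noise_cv=noise_cv,
                baseline=0.0,
                seed=seed,
            )
            return scenario, (rt - width, rt + width)
    raise ValueError(f"isomer {isomer_id!r} is in no bundled ratio table")


def read_scenario_yaml(path: str | Path, seed: int | None = None) -> RunScenario:
    """Build a RunScenario from a YAML description.

    Layout::

        segments: [...]            # as in the acquisition config
        ratio_tables:
          1: bundled:CQAs          # or a CSV path, with optional ':group'
          2: bundled:diCQAs
        peaks:
          5-CQA: {rt: 2.0, width: 0.05, height: 1.1e6, tau: 0.0}
        scan_period: 0.01
        noise_cv: 0.05
        baseline: 500
        seed: 0
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    segments = tuple(read_segment_config(path))
    tables: dict[int, RatioTable] = {}
    for seg_id, spec_str in doc["ratio_tables"].items():
        spec_str = str(spec_str)
        if spec_str.startswith("bundled:"):
            tables[int(seg_id)] = load_bundled_ratio_table(spec_str.split(":", 1)[1])
        elif ":" in spec_str and not Path(spec_str).exists():
            csv_path, group = spec_str.rsplit(":", 1)
            tables[int(seg_id)] = RatioTable.from_csv(csv_path, group)
        else:
            tables[int(seg_id)] = RatioTable.from_csv(spec_str)
    peaks = {
        str(iso): GaussianPeak(
            float(p["rt"]), float(p["width"]), float(p["height"]), float(p.get("tau", 0.0))
        )
        for iso, p in doc["peaks"].items()
    }
    return RunScenario(
        segments=segments,
        ratio_tables=tables,
        isomer_peaks=peaks,
        scan_period=float(doc.get("scan_period", DEFAULT_SCAN_PERIOD)),
        noise_cv=float(doc.get("noise_cv", 0.0)),
        baseline=float(doc.get("baseline", 0.0)),
        seed=int(doc.get("seed", 0)) if seed is None else int(seed),
    )
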