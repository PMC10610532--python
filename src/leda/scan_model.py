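"""Domain model for alternating-event ion-trap MS/MS acquisitions.

An ion trap monitoring a group of isomers runs, within each chromatographic
time segment, two interleaved MS/MS events on the shared precursor ion:

* a low-energy event whose excitation amplitude (ExA) is too small to
  activate fragmentation, so the surviving precursor is recorded and serves
  as the reference ion (Ri);
* a high-energy event at the ExA of maximal product-ion yield, recording the
  full product-ion (Pis) spectrum.

This module holds the scan-level types, readers/writers for mzML and a
line-oriented internal CSV format, the pairing of Ri and Pis events onto a
common time axis, and basic spectral filtering.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EventKind",
    "MsmsScan",
    "TimeSegmentConfig",
    "PairedDataPoint",
    "ScanClassificationError",
    "PairingError",
    "DEFAULT_MZ_TOLERANCE",
    "read_run",
    "write_run",
    "read_segment_config",
    "extract_ion",
    "pair_events",
    "filter_relative_abundance",
]

#: Default m/z matching half-window in Th; unit-resolution ion trap.
DEFAULT_MZ_TOLERANCE = 0.5

#: ExA values are compared after rounding to this decimal place (a.u.).
_EXA_DECIMALS = 1


class EventKind(enum.Enum):
    """Which of the two alternating MS/MS events a scan belongs to."""

    RI = "ri"
    PIS = "pis"


class ScanClassificationError(ValueError):
    """A scan's ExA matches neither event of its time segment."""


class PairingError(ValueError):
    """A segment contains product-ion scans but no reference-ion scans."""


@dataclass(frozen=True)
class MsmsScan:
    """One MS/MS acquisition event.

    Parameters
    ----------
    retention_time : float
        Retention time in minutes.
    segment_id : int
        Chromatographic time segment the scan belongs to.
    event_kind : EventKind
        Low-energy reference-ion event or high-energy product-ion event.
    precursor_mz : float
        Isolated precursor m/z in Th.
    excitation_amplitude : float
        CID excitation amplitude in instrument arbitrary units.
    excitation_time : float
        CID excitation time in milliseconds.
    scan_range : tuple of (float, float), optional
        Low/high m/z bounds of the recorded spectrum.
    peaks : tuple of (mz, abundance)
        Centroided peak list; abundances in counts, >= 0.
    """

    retention_time: float
    segment_id: int
    event_kind: EventKind
    precursor_mz: float
    excitation_amplitude: float
    excitation_time: float = 50.0
    scan_range: tuple[float, float] | None = None
    peaks: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.retention_time < 0:
            raise ValueError("retention_time must be >= 0")
        for mz, ab in self.peaks:
            if ab < 0:
                raise ValueError(f"negative abundance {ab} at m/z {mz}")
            if self.scan_range is not None and not (
                self.scan_range[0] <= mz <= self.scan_range[1]
            ):
                raise ValueError(
                    f"peak m/z {mz} outside scan range {self.scan_range}"
                )


@dataclass(frozen=True)
class TimeSegmentConfig:
    """Acquisition parameters of one chromatographic time segment.

    ``ri_event`` and ``pis_event`` are ``(scan_range, exa)`` pairs; the
    reference-ion event must use the lower excitation amplitude.
    """

    segment_id: int
    rt_window: tuple[float, float]
    precursor_mz: float
    ri_event: tuple[tuple[float, float], float]
    pis_event: tuple[tuple[float, float], float]
    isolation_width: float = 3.0
    q_value: float = 0.25
    excitation_time: float = 50.0

    def __post_init__(self) -> None:
        if self.ri_event[1] >= self.pis_event[1]:
            raise ValueError("reference-ion ExA must be below product-ion ExA")
        if self.rt_window[0] >= self.rt_window[1]:
            raise ValueError("rt_window start must precede end")

    def classify(self, excitation_amplitude: float) -> EventKind:
        """Map an ExA to the event it belongs to (0.1 a.u. rounding)."""
        exa = round(excitation_amplitude, _EXA_DECIMALS)
        if exa == round(self.ri_event[1], _EXA_DECIMALS):
            return EventKind.RI
        if exa == round(self.pis_event[1], _EXA_DECIMALS):
            return EventKind.PIS
        raise ScanClassificationError(
            f"ExA {excitation_amplitude} matches neither event of segment "
            f"{self.segment_id} (Ri {self.ri_event[1]}, Pis {self.pis_event[1]})"
        )

    def scan_range_for(self, kind: EventKind) -> tuple[float, float]:
        return self.ri_event[0] if kind is EventKind.RI else self.pis_event[0]


@dataclass(frozen=True)
class PairedDataPoint:
    """A product-ion spectrum with the reference-ion abundance at its time.

    The reference-ion abundance is interpolated from the bracketing
    low-energy scans to the product-ion scan's retention time.
    """

    retention_time: float
    ri_abundance: float
    pis_spectrum: tuple[tuple[float, float], ...]
    segment_id: int

    def __post_init__(self) -> None:
        if self.ri_abundance < 0:
            raise ValueError("ri_abundance must be >= 0")


# ---------------------------------------------------------------------------
# Segment configuration I/O


def _segment_from_dict(d: dict) -> TimeSegmentConfig:
    return TimeSegmentConfig(
        segment_id=int(d["segment_id"]),
        rt_window=(float(d["rt_window"][0]), float(d["rt_window"][1])),
        precursor_mz=float(d["precursor_mz"]),
        ri_event=(
            (float(d["ri_event"]["scan_range"][0]), float(d["ri_event"]["scan_range"][1])),
            float(d["ri_event"]["exa"]),
        ),
        pis_event=(
            (float(d["pis_event"]["scan_range"][0]), float(d["pis_event"]["scan_range"][1])),
            float(d["pis_event"]["exa"]),
        ),
        isolation_width=float(d.get("isolation_width", 3.0)),
        q_value=float(d.get("q_value", 0.25)),
        excitation_time=float(d.get("excitation_time", 50.0)),
    )


def read_segment_config(path: str | Path) -> list[TimeSegmentConfig]:
    """Read a YAML acquisition config into a list of segments.

    Distinct segments must not overlap in retention time.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    segments = [_segment_from_dict(d) for d in doc["segments"]]
    windows = sorted(s.rt_window for s in segments)
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 < a1:
            raise ValueError(f"segment rt windows overlap: {(a0, a1)} and {(b0, b1)}")
    return segments


def _segment_for(
    segments: Sequence[TimeSegmentConfig], segment_id: int
) -> TimeSegmentConfig | None:
    for s in segments:
        if s.segment_id == segment_id:
            return s
    return None


# ---------------------------------------------------------------------------
# Run I/O

_INTERNAL_COLUMNS = [
    "rt_min",
    "segment",
    "event",
    "precursor_mz",
    "exa",
    "ext_ms",
    "mz",
    "abundance",
]


def write_run(scans: Iterable[MsmsScan], path: str | Path) -> None:
    """Write scans to the internal CSV format (one row per peak).

    A scan with no peaks is written as a single row with blank ``mz`` and
    ``abundance`` fields so the scan itself round-trips.
    """
    rows: list[tuple] = []
    for scan in scans:
        meta = (
            scan.retention_time,
            scan.segment_id,
            scan.event_kind.value,
            scan.precursor_mz,
            scan.excitation_amplitude,
            scan.excitation_time,
        )
        if scan.peaks:
            rows.extend(meta + (mz, ab) for mz, ab in scan.peaks)
        else:
            rows.append(meta + (np.nan, np.nan))
    pd.DataFrame(rows, columns=_INTERNAL_COLUMNS).to_csv(path, index=False)


def _read_internal(
    path: str | Path, segments: Sequence[TimeSegmentConfig] | None
) -> list[MsmsScan]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_INTERNAL_COLUMNS) - set(df.columns)
    if missing:
        raise IOError(f"internal scan file {path} lacks columns {sorted(missing)}")
    scans: list[MsmsScan] = []
    group_keys = ["rt_min", "segment", "event", "precursor_mz", "exa", "ext_ms"]
    for (rt, seg, event, pmz, exa, ext), grp in df.groupby(group_keys, sort=False):
        seg = int(seg)
        peaks = tuple(
            (float(m), float(a))
            for m, a in zip(grp["mz"], grp["abundance"])
            if np.isfinite(m)
        )
        kind = EventKind(event)
        scan_range = None
        if segments is not None:
            cfg = _segment_for(segments, seg)
            if cfg is not None:
                kind = cfg.classify(float(exa))  # may raise ScanClassificationError
                scan_range = cfg.scan_range_for(kind)
        scans.append(
            MsmsScan(
                retention_time=float(rt),
                segment_id=seg,
                event_kind=kind,
                precursor_mz=float(pmz),
                excitation_amplitude=float(exa),
                excitation_time=float(ext),
                scan_range=scan_range,
                peaks=peaks,
            )
        )
    scans.sort(key=lambda s: s.retention_time)
    return scans


def _decode_binary_array(elem) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit float, plain or zlib)."""
    import base64
    import zlib

    accessions = {
        cv.get("accession") for cv in elem.findall(_MZML_NS + "cvParam")
    }
    payload = elem.findtext(_MZML_NS + "binary") or ""
    raw = base64.b64decode(payload)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

#: cvParam accessions read from mzML: scan start time, ms level, isolation
#: target, selected ion m/z, collision energy, m/z / intensity arrays.
_ACC_RT = "MS:1000016"
_ACC_MS_LEVEL = "MS:1000511"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_COLLISION_ENERGY = "MS:1000045"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"


def _cv_value(parent, accession: str) -> str | None:
    for cv in parent.iter(_MZML_NS + "cvParam"):
        if cv.get("accession") == accession:
            return cv.get("value")
    return None


def _read_mzml(
    path: str | Path, segments: Sequence[TimeSegmentConfig]
) -> list[MsmsScan]:
    """Read MS2 spectra from an mzML file.

    A deliberately small reader (lxml over the PSI schema) covering what
    the pairing workflow needs: retention time, precursor m/z from the
    isolation-window target (selected-ion m/z as fallback), collision
    energy from the activation block, and the two float peak arrays. The
    collision energy is matched against the segment config to classify
    each spectrum as a reference-ion or product-ion event.
    """
    from lxml import etree

    scans: list[MsmsScan] = []
    for _, spec in etree.iterparse(str(path), tag=_MZML_NS + "spectrum"):
        try:
            level = _cv_value(spec, _ACC_MS_LEVEL)
            if level is not None and int(level) < 2:
                continue
            scan_block = spec.find(f"{_MZML_NS}scanList/{_MZML_NS}scan")
            rt = None
            for cv in scan_block.iter(_MZML_NS + "cvParam"):
                if cv.get("accession") == _ACC_RT:
                    rt = float(cv.get("value"))
                    if "second" in (cv.get("unitName") or "minute"):
                        rt /= 60.0
            if rt is None:
                raise IOError(f"spectrum {spec.get('id')} carries no scan start time")
            precursor = spec.find(
                f"{_MZML_NS}precursorList/{_MZML_NS}precursor"
            )
            if precursor is None:
                raise IOError(f"spectrum {spec.get('id')} has no precursor block")
            pmz = _cv_value(
                precursor.find(_MZML_NS + "isolationWindow"), _ACC_ISO_TARGET
            ) if precursor.find(_MZML_NS + "isolationWindow") is not None else None
            if pmz is None:
                pmz = _cv_value(precursor, _ACC_SELECTED_MZ)
            exa = _cv_value(
                precursor.find(_MZML_NS + "activation"), _ACC_COLLISION_ENERGY
            ) if precursor.find(_MZML_NS + "activation") is not None else None
            if pmz is None or exa is None:
                raise IOError(
                    f"spectrum {spec.get('id')} lacks precursor/collision-energy metadata"
                )
            pmz, exa = float(pmz), float(exa)
            mz_arr = inten_arr = None
            for arr in spec.iter(_MZML_NS + "binaryDataArray"):
                accs = {cv.get("accession") for cv in arr.findall(_MZML_NS + "cvParam")}
                if _ACC_MZ_ARRAY in accs:
                    mz_arr = _decode_binary_array(arr)
                elif _ACC_INTENSITY_ARRAY in accs:
                    inten_arr = _decode_binary_array(arr)
            cfg = None
            for s in segments:
                if s.rt_window[0] <= rt <= s.rt_window[1] and abs(
                    s.precursor_mz - pmz
                ) <= s.isolation_width:
                    cfg = s
                    break
            if cfg is None:
                raise ScanClassificationError(
                    f"spectrum {spec.get('id')} (rt {rt:.3f} min, precursor "
                    f"{pmz:.1f}) matches no configured segment"
                )
            kind = cfg.classify(exa)
            peaks = ()
            if mz_arr is not None and inten_arr is not None:
                peaks = tuple(
                    (float(m), float(a)) for m, a in zip(mz_arr, inten_arr)
                )
            scans.append(
                MsmsScan(
                    retention_time=rt,
                    segment_id=cfg.segment_id,
                    event_kind=kind,
                    precursor_mz=pmz,
                    excitation_amplitude=exa,
                    excitation_time=cfg.excitation_time,
                    scan_range=cfg.scan_range_for(kind),
                    peaks=peaks,
                )
            )
        finally:
            spec.clear()
    scans.sort(key=lambda s: s.retention_time)
    return scans


def read_run(
    path: str | Path,
    format: str = "internal",
    segments: Sequence[TimeSegmentConfig] | None = None,
) -> list[MsmsScan]:
    """Read an acquisition run, returned in retention-time order.

    Parameters
    ----------
    path : path
        Input file.
    format : {"internal", "mzml"}
        ``internal`` is the package's one-row-per-peak CSV; ``mzml`` is
        read-only and requires ``segments`` for event classification.
    segments : list of TimeSegmentConfig, optional
        When given, each scan's event kind is inferred from its ExA against
        its segment's two events (error if it matches neither) and the scan
        range is filled in from the config.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such run file: {path}")
    if format == "internal":
        return _read_internal(path, segments)
    if format == "mzml":
        if segments is None:
            raise ValueError("mzML reading requires a segment config")
        return _read_mzml(path, segments)
    raise ValueError(f"unknown run format {format!r}")


# ---------------------------------------------------------------------------
# Spectral primitives


def extract_ion(
    scan_or_peaks: MsmsScan | Sequence[tuple[float, float]],
    target_mz: float,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> float:
    """Summed abundance of peaks within ``tolerance`` Th of ``target_mz``.

    Absence of matching peaks is a valid zero, not an error.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    peaks = scan_or_peaks.peaks if isinstance(scan_or_peaks, MsmsScan) else scan_or_peaks
    return float(
        sum(ab for mz, ab in peaks if abs(mz - target_mz) <= tolerance)
    )


def filter_relative_abundance(
    peaks: Sequence[tuple[float, float]], threshold_pct: float = 1.0
) -> list[tuple[float, float]]:
    """Keep peaks whose abundance is >= threshold_pct% of the base peak."""
    if not 0 <= threshold_pct <= 100:
        raise ValueError("threshold_pct must lie in [0, 100]")
    peaks = list(peaks)
    if not peaks:
        return []
    cutoff = threshold_pct / 100.0 * max(ab for _, ab in peaks)
    return [(mz, ab) for mz, ab in peaks if ab >= cutoff]


# ---------------------------------------------------------------------------
# Event pairing


def pair_events(
    scans: Sequence[MsmsScan],
    config: TimeSegmentConfig,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> list[PairedDataPoint]:
    """Pair each product-ion scan of a segment with a reference-ion value.

    The reference-ion abundance (the precursor signal in the low-energy
    scan, summed within ``tolerance`` of the precursor m/z) is linearly
    interpolated between the bracketing low-energy scans at each
    product-ion scan's retention time; at segment edges the nearest
    low-energy scan's value is used.
    """
    seg_scans = [s for s in scans if s.segment_id == config.segment_id]
    ri_scans = [s for s in seg_scans if s.event_kind is EventKind.RI]
    pis_scans = [s for s in seg_scans if s.event_kind is EventKind.PIS]
    if not pis_scans:
        return []
    if not ri_scans:
        raise PairingError(
            f"segment {config.segment_id} has {len(pis_scans)} product-ion "
            "scans but no reference-ion scans"
        )
    ri_times = np.array([s.retention_time for s in ri_scans])
    ri_values = np.array(
        [extract_ion(s, config.precursor_mz, tolerance) for s in ri_scans]
    )
    order = np.argsort(ri_times, kind="stable")
    ri_times, ri_values = ri_times[order], ri_values[order]
    points = []
    for scan in pis_scans:
        ri = float(np.interp(scan.retention_time, ri_times, ri_values))
        points.append(
            PairedDataPoint(
                retention_time=scan.retention_time,
                ri_abundance=ri,
                pis_spectrum=scan.peaks,
                segment_id=config.segment_id,
            )
        )
    points.sort(key=lambda p: p.retention_time)
    return points
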