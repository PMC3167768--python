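"""Ventilator waveform ingestion and pressure-volume loop extraction.

Reads sampled airway-pressure/flow recordings from a staircase PEEP
recruitment manoeuvre, segments them into breaths, reconstructs lung volume
by flow integration, detects PEEP plateaus, estimates auto-PEEP and
inspiratory resistance from hold manoeuvres, and assembles one
representative pressure-volume loop per PEEP level for model fitting.

Units follow bedside convention throughout: pressure in cmH2O, flow in L/s
(positive = inspiratory), volume in ml, time in seconds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "IoConfig",
    "PressureFlowRecord",
    "BreathSegment",
    "PVLoop",
    "HoldMeasurements",
    "load_waveform",
    "segment_breaths",
    "extract_pv_loops",
    "estimate_auto_peep",
    "estimate_resistance",
    "correct_resistive_pressure",
    "flag_pressure_drop_anomaly",
    "qc_report",
    "write_waveform_csv",
    "write_loops_csv",
    "read_loops_csv",
]


@dataclass(frozen=True)
class IoConfig:
    """Column mapping and detection thresholds for waveform files.

    The file dialect is delimited text with a header row; default column
    names are ``time_s, paw_cmH2O, flow_lps``.
    """

    time_column: str = "time_s"
    pressure_column: str = "paw_cmH2O"
    flow_column: str = "flow_lps"
    delimiter: str = ","
    # breath detection
    flow_hysteresis: float = 0.02      # L/s, zero-crossing hysteresis
    min_tidal_ml: float = 50.0         # discard breaths smaller than this
    # plateau handling
    peep_step: float = 5.0             # cmH2O, protocol staircase increment
    peep_snap_tolerance: float = 1.5   # cmH2O, snap-to-grid tolerance
    plateau_window_s: float = 0.05     # averaging window for end-exp pressure
    breaths_to_average: int = 3        # last k breaths of a plateau
    loop_grid_points: int = 25         # common-pressure-grid resolution
    # pressure-drop anomaly flag
    anomaly_drop_cmh2o: float = 1.0
    anomaly_duration_s: float = 0.05
    anomaly_min_flow_lps: float = 0.1


DEFAULT_CONFIG = IoConfig()


@dataclass(frozen=True)
class PressureFlowRecord:
    """A sampled ventilator waveform with derived volume.

    ``volume`` (ml) is the trapezoidal integral of flow from the start of
    the record, i.e. lung volume above the start-of-manoeuvre end-expiratory
    level; ``volume[0] == 0``.
    """

    time: np.ndarray     # s, uniformly sampled
    paw: np.ndarray      # cmH2O
    flow: np.ndarray     # L/s, positive = inspiratory
    volume: np.ndarray   # ml, integrated from flow

    @classmethod
    def from_channels(cls, time: np.ndarray, paw: np.ndarray,
                      flow: np.ndarray) -> "PressureFlowRecord":
        time = np.asarray(time, dtype=float)
        paw = np.asarray(paw, dtype=float)
        flow = np.asarray(flow, dtype=float)
        if time.size == 0:
            raise ValueError("empty waveform: no samples")
        if not (time.size == paw.size == flow.size):
            raise ValueError("channel lengths differ")
        dt = np.diff(time)
        if time.size > 1:
            if np.any(dt <= 0):
                raise ValueError("time channel is not strictly increasing")
            mean_dt = dt.mean()
            if np.any(np.abs(dt - mean_dt) > 0.01 * mean_dt):
                raise ValueError(
                    "sampling interval varies by more than 1%; "
                    "resample before loading")
        volume = np.concatenate(
            ([0.0], cumulative_trapezoid(flow, time))) * 1000.0  # L -> ml
        return cls(time=time, paw=paw, flow=flow, volume=volume)

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class BreathSegment:
    """Index bounds of one breath plus its plateau assignment."""

    i_insp_start: int
    i_insp_end: int          # first expiratory sample
    i_exp_end: int           # exclusive; start of the next breath
    peep_level: float        # cmH2O, end-expiratory plateau snapped to grid
    tidal_volume_ml: float
    end_exp_pressure: float  # cmH2O, raw plateau reading

    def __post_init__(self) -> None:
        if not (self.i_insp_start < self.i_insp_end < self.i_exp_end):
            raise ValueError("breath indices must be strictly ordered")
        if self.tidal_volume_ml <= 0:
            raise ValueError("tidal volume must be positive")


@dataclass(frozen=True)
class PVLoop:
    """One PEEP level's averaged inflation and deflation limbs.

    Volumes are absolute in the manoeuvre frame (ml above the reference
    baseline handed to :func:`extract_pv_loops`); pressures in cmH2O.
    Per-point flows are retained so resistive-pressure correction can be
    applied after extraction.
    """

    peep: float
    inflation_p: np.ndarray
    inflation_v: np.ndarray
    deflation_p: np.ndarray
    deflation_v: np.ndarray
    inflation_q: np.ndarray | None = None
    deflation_q: np.ndarray | None = None
    n_breaths_averaged: int = 1

    def __post_init__(self) -> None:
        if np.any(np.diff(self.inflation_p) < 0):
            raise ValueError("inflation pressures must be non-decreasing")
        if np.any(np.diff(self.deflation_p) > 0):
            raise ValueError("deflation pressures must be non-increasing")
        if np.any(self.inflation_v < 0) or np.any(self.deflation_v < 0):
            raise ValueError("volumes must be non-negative")

    @property
    def inflation(self) -> list[tuple[float, float]]:
        return list(zip(self.inflation_p.tolist(), self.inflation_v.tolist()))

    @property
    def deflation(self) -> list[tuple[float, float]]:
        return list(zip(self.deflation_p.tolist(), self.deflation_v.tolist()))


@dataclass(frozen=True)
class HoldMeasurements:
    """Results of the end-inspiratory and end-expiratory hold manoeuvres."""

    auto_peep: float                 # cmH2O above set PEEP
    inspiratory_resistance: float    # cmH2O.s/L
    peak_pressure: float             # cmH2O
    plateau_pressure: float          # cmH2O

    def __post_init__(self) -> None:
        if self.auto_peep < 0:
            raise ValueError("auto-PEEP must be non-negative")
        if self.inspiratory_resistance < 0:
            raise ValueError("resistance must be non-negative")
        if self.plateau_pressure > self.peak_pressure + 1e-9:
            raise ValueError("plateau pressure exceeds peak pressure")


# ---------------------------------------------------------------------------
# loading

def load_waveform(path: str | Path,
                  config: IoConfig = DEFAULT_CONFIG) -> PressureFlowRecord:
    """Read a delimited-text waveform file and integrate volume.

    Raises ``ValueError`` on missing columns, an empty file or a
    non-monotonic time channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"waveform file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=config.delimiter)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"waveform file is empty: {path}") from exc
    needed = [config.time_column, config.pressure_column, config.flow_column]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(
            f"waveform file {path} lacks required columns {missing}; "
            f"found {list(frame.columns)}")
    if len(frame) == 0:
        raise ValueError(f"waveform file has a header but no samples: {path}")
    return PressureFlowRecord.from_channels(
        frame[config.time_column].to_numpy(),
        frame[config.pressure_column].to_numpy(),
        frame[config.flow_column].to_numpy(),
    )


def write_waveform_csv(record: PressureFlowRecord, path: str | Path,
                       config: IoConfig = DEFAULT_CONFIG) -> None:
    frame = pd.DataFrame({
        config.time_column: record.time,
        config.pressure_column: record.paw,
        config.flow_column: record.flow,
    })
    frame.to_csv(path, sep=config.delimiter, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# breath segmentation

def _phase_array(flow: np.ndarray, hysteresis: float) -> np.ndarray:
    """+1 during inspiration, -1 during expiration, forward-filled through
    the hysteresis dead band (holds inherit the preceding phase)."""
    raw = np.zeros(flow.size, dtype=np.int8)
    raw[flow > hysteresis] = 1
    raw[flow < -hysteresis] = -1
    idx = np.arange(raw.size)
    has = raw != 0
    if not has.any():
        return raw
    last = np.maximum.accumulate(np.where(has, idx, -1))
    phase = np.where(last >= 0, raw[np.clip(last, 0, None)], 0)
    return phase.astype(np.int8)


def segment_breaths(record: PressureFlowRecord,
                    min_tidal_ml: float | None = None,
                    config: IoConfig = DEFAULT_CONFIG) -> list[BreathSegment]:
    """Split a record into breaths at inspiratory flow zero-crossings.

    A breath runs from one inspiration onset to the next; breaths whose
    tidal volume falls below ``min_tidal_ml`` are discarded.  Each segment
    carries the end-expiratory plateau pressure and its snap-to-grid PEEP
    label.  Returns an empty list (with a warning) when no breaths are
    detectable.
    """
    if min_tidal_ml is None:
        min_tidal_ml = config.min_tidal_ml
    phase = _phase_array(record.flow, config.flow_hysteresis)
    insp = phase == 1
    onsets = np.flatnonzero(insp & ~np.concatenate(([False], insp[:-1])))
    # drop an onset at index 0 only if there is no expiration before it ends
    segments: list[BreathSegment] = []
    dt = 1.0 / record.sample_rate
    win = max(1, int(round(config.plateau_window_s / dt)))
    for k, start in enumerate(onsets):
        end = onsets[k + 1] if k + 1 < onsets.size else record.time.size
        # inspiration ends where phase first turns expiratory
        exp_onset_rel = np.flatnonzero(phase[start:end] == -1)
        if exp_onset_rel.size == 0:
            continue  # inspiration never followed by expiration (record tail)
        i_insp_end = start + int(exp_onset_rel[0])
        tidal = record.volume[i_insp_end] - record.volume[start]
        if tidal < min_tidal_ml:
            continue
        p_ee = float(np.mean(record.paw[max(start, end - win):end]))
        grid = round(p_ee / config.peep_step) * config.peep_step
        if abs(p_ee - grid) <= config.peep_snap_tolerance:
            level = float(grid)
        else:
            level = float(round(p_ee))
        segments.append(BreathSegment(
            i_insp_start=int(start), i_insp_end=int(i_insp_end),
            i_exp_end=int(end), peep_level=level,
            tidal_volume_ml=float(tidal), end_exp_pressure=p_ee))
    if not segments:
        warnings.warn("no breaths detected in record", stacklevel=2)
    return segments


# ---------------------------------------------------------------------------
# loop extraction

def _monotone_samples(p: np.ndarray, rising: bool) -> np.ndarray:
    """Boolean mask keeping samples that advance pressure monotonically.

    For inflation this retains only the region where pressure (and, because
    inspiratory flow is positive, volume) is increasing — which is also the
    fitting region prescribed for breaths flagged by the pressure-drop
    anomaly QC check.
    """
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if rising:
        run = np.maximum.accumulate(p)
        keep = p >= run - 1e-12
        # drop repeats of the same running max
        keep &= np.concatenate(([True], np.diff(run) > 0))
        keep[0] = True
    else:
        run = np.minimum.accumulate(p)
        keep = p <= run + 1e-12
        keep &= np.concatenate(([True], np.diff(run) < 0))
        keep[0] = True
    return keep


def _limb_points(record: PressureFlowRecord, seg: BreathSegment,
                 limb: str, config: IoConfig):
    if limb == "inflation":
        sl = slice(seg.i_insp_start, seg.i_insp_end)
        mask = record.flow[sl] > config.flow_hysteresis
    else:
        sl = slice(seg.i_insp_end, seg.i_exp_end)
        mask = record.flow[sl] < -config.flow_hysteresis
    p = record.paw[sl][mask]
    v = record.volume[sl][mask]
    q = record.flow[sl][mask]
    keep = _monotone_samples(p, rising=(limb == "inflation"))
    return p[keep], v[keep], q[keep]


def extract_pv_loops(record: PressureFlowRecord,
                     segments: Sequence[BreathSegment],
                     peep_step: float | None = None,
                     config: IoConfig = DEFAULT_CONFIG,
                     baseline_ml: float = 0.0) -> list[PVLoop]:
    """Group breaths into PEEP plateaus and average one loop per level.

    The last ``config.breaths_to_average`` breaths of each plateau are
    interpolated onto a common pressure grid and averaged point-wise.
    Volumes are cumulative from the manoeuvre start plus ``baseline_ml``
    (the end-expiratory lung volume at the first plateau, if known).
    Plateaus re-visited during a decremental phase keep their first
    (incremental) occurrence.  A plateau without a complete breath is
    skipped with a warning.
    """
    if peep_step is not None and peep_step != config.peep_step:
        config = replace(config, peep_step=peep_step)
    if not segments:
        raise ValueError("no breath segments supplied")
    # consecutive same-label runs form plateaus
    plateaus: list[tuple[float, list[BreathSegment]]] = []
    for seg in segments:
        if plateaus and plateaus[-1][0] == seg.peep_level:
            plateaus[-1][1].append(seg)
        else:
            plateaus.append((seg.peep_level, [seg]))
    seen: dict[float, bool] = {}
    loops: list[PVLoop] = []
    for level, segs in plateaus:
        if level in seen:
            continue
        seen[level] = True
        take = segs[-config.breaths_to_average:]
        limbs = {}
        ok = True
        for limb in ("inflation", "deflation"):
            pts = [_limb_points(record, s, limb, config) for s in take]
            pts = [t for t in pts if t[0].size >= 2]
            if not pts:
                warnings.warn(
                    f"plateau at PEEP {level} has no complete breath; skipped",
                    stacklevel=2)
                ok = False
                break
            lo = max(t[0].min() for t in pts)
            hi = min(t[0].max() for t in pts)
            if not hi > lo:
                warnings.warn(
                    f"plateau at PEEP {level} has degenerate {limb} limb; "
                    "skipped", stacklevel=2)
                ok = False
                break
            grid = np.linspace(lo, hi, config.loop_grid_points)
            vs, qs = [], []
            for p, v, q in pts:
                if limb == "deflation":
                    p, v, q = p[::-1], v[::-1], q[::-1]
                vs.append(np.interp(grid, p, v))
                qs.append(np.interp(grid, p, q))
            v_mean = np.mean(vs, axis=0) + baseline_ml
            q_mean = np.mean(qs, axis=0)
            if limb == "deflation":
                grid, v_mean, q_mean = grid[::-1], v_mean[::-1], q_mean[::-1]
            limbs[limb] = (grid, v_mean, q_mean)
        if not ok:
            continue
        loops.append(PVLoop(
            peep=level,
            inflation_p=limbs["inflation"][0],
            inflation_v=np.maximum(limbs["inflation"][1], 0.0),
            deflation_p=limbs["deflation"][0],
            deflation_v=np.maximum(limbs["deflation"][1], 0.0),
            inflation_q=limbs["inflation"][2],
            deflation_q=limbs["deflation"][2],
            n_breaths_averaged=len(take)))
    return loops


# ---------------------------------------------------------------------------
# hold manoeuvres

def _window_indices(record: PressureFlowRecord,
                    window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    idx = np.flatnonzero((record.time >= t0) & (record.time <= t1))
    if idx.size == 0:
        raise ValueError(f"hold window ({t0}, {t1}) s contains no samples")
    return idx


def estimate_auto_peep(record: PressureFlowRecord,
                       hold_window: tuple[float, float],
                       set_peep: float = 0.0,
                       flow_tolerance: float = 0.05) -> float:
    """Auto-PEEP from an end-expiratory hold: mean airway pressure over the
    hold window minus the set PEEP (at ZEEP the plateau itself), clipped at
    zero.  Fails if flow is not near zero throughout the window."""
    idx = _window_indices(record, hold_window)
    if np.max(np.abs(record.flow[idx])) > flow_tolerance:
        raise ValueError(
            "invalid hold: flow is not near zero in the given window")
    plateau = float(np.mean(record.paw[idx]))
    return max(plateau - set_peep, 0.0)


def estimate_resistance(record: PressureFlowRecord,
                        insp_hold_window: tuple[float, float],
                        lookback_s: float = 2.0,
                        min_flow: float = 0.05) -> float:
    """Inspiratory resistance from an end-inspiratory hold.

    R = (peak pressure - plateau pressure) / flow at peak pressure, with the
    peak searched over the delivered inspiration immediately preceding the
    hold and the plateau taken as the mean pressure over the final third of
    the hold window.
    """
    idx = _window_indices(record, insp_hold_window)
    tail = idx[-max(1, idx.size // 3):]
    plateau = float(np.mean(record.paw[tail]))
    t0 = insp_hold_window[0]
    search = np.flatnonzero(
        (record.time >= t0 - lookback_s) & (record.time <= insp_hold_window[1])
        & (record.flow > min_flow))
    if search.size == 0:
        raise ValueError(
            "invalid hold: no positive-flow samples precede the window")
    i_peak = search[np.argmax(record.paw[search])]
    peak = float(record.paw[i_peak])
    q_peak = float(record.flow[i_peak])
    if plateau > peak + 1e-9:
        raise ValueError(
            "mislabelled window: plateau pressure exceeds peak pressure")
    if q_peak <= min_flow:
        raise ValueError("zero flow at peak pressure; cannot estimate R")
    return (peak - plateau) / q_peak


# ---------------------------------------------------------------------------
# resistive-pressure correction

def correct_resistive_pressure(loop: PVLoop, resistance: float,
                               inflation_flow: np.ndarray | None = None,
                               deflation_flow: np.ndarray | None = None
                               ) -> PVLoop:
    """Subtract the resistive pressure R*flow from every loop point.

    Flow is signed, so inflation pressures fall and deflation pressures rise
    toward each other and the loop narrows.  R = 0 is the identity.
    """
    if resistance < 0:
        raise ValueError("resistance must be non-negative")
    q_inf = loop.inflation_q if inflation_flow is None else np.asarray(
        inflation_flow, dtype=float)
    q_def = loop.deflation_q if deflation_flow is None else np.asarray(
        deflation_flow, dtype=float)
    if q_inf is None or q_def is None:
        raise ValueError("per-point flows are required for the correction")
    p_inf = loop.inflation_p - resistance * q_inf
    p_def = loop.deflation_p - resistance * q_def
    # re-impose limb monotonicity, dropping points the correction reordered
    ki = _monotone_samples(p_inf, rising=True)
    kd = _monotone_samples(p_def, rising=False)
    return PVLoop(
        peep=loop.peep,
        inflation_p=p_inf[ki], inflation_v=loop.inflation_v[ki],
        deflation_p=p_def[kd], deflation_v=loop.deflation_v[kd],
        inflation_q=q_inf[ki], deflation_q=q_def[kd],
        n_breaths_averaged=loop.n_breaths_averaged)


# ---------------------------------------------------------------------------
# QC

def flag_pressure_drop_anomaly(record: PressureFlowRecord,
                               segments: Sequence[BreathSegment],
                               config: IoConfig = DEFAULT_CONFIG
                               ) -> list[int]:
    """Indices of breaths whose airway pressure falls while the ventilator
    is still delivering positive flow.

    A breath is flagged when, during sustained flow above
    ``anomaly_min_flow_lps``, pressure drops more than ``anomaly_drop_cmh2o``
    below its running maximum for longer than ``anomaly_duration_s``.  Such
    loops should be fitted only on the region where pressure and volume both
    increase (which the extraction's monotone filter enforces).
    """
    dt = 1.0 / record.sample_rate
    need = max(1, int(round(config.anomaly_duration_s / dt)))
    flagged = []
    for b, seg in enumerate(segments):
        sl = slice(seg.i_insp_start, seg.i_insp_end)
        p = record.paw[sl]
        q = record.flow[sl]
        active = q > config.anomaly_min_flow_lps
        deficit = np.maximum.accumulate(p) - p
        bad = active & (deficit > config.anomaly_drop_cmh2o)
        # longest run of consecutive bad samples
        run = 0
        longest = 0
        for flag in bad:
            run = run + 1 if flag else 0
            longest = max(longest, run)
        if longest >= need:
            flagged.append(b)
    return flagged


def qc_report(holds: HoldMeasurements | None,
              anomalies: Sequence[int],
              excluded_peeps: Sequence[float] = (),
              path: str | Path | None = None) -> dict:
    """Structured QC summary (auto-PEEP, resistance, anomaly flags,
    excluded PEEP levels), optionally written as JSON."""
    report = {
        "auto_peep_cmh2o": None if holds is None else holds.auto_peep,
        "inspiratory_resistance_cmh2o_s_per_l":
            None if holds is None else holds.inspiratory_resistance,
        "peak_pressure_cmh2o": None if holds is None else holds.peak_pressure,
        "plateau_pressure_cmh2o":
            None if holds is None else holds.plateau_pressure,
        "pressure_drop_anomaly_breaths": sorted(int(i) for i in anomalies),
        "excluded_peep_levels": sorted(float(p) for p in excluded_peeps),
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# loop serialisation

def write_loops_csv(loops: Sequence[PVLoop], path: str | Path) -> None:
    """Serialise loops as ``peep,limb,pressure_cmH2O,volume_ml[,flow_lps]``."""
    rows = []
    for loop in loops:
        for limb in ("inflation", "deflation"):
            p = getattr(loop, f"{limb}_p")
            v = getattr(loop, f"{limb}_v")
            q = getattr(loop, f"{limb}_q")
            if q is None:
                q = np.full_like(p, np.nan)
            for pi, vi, qi in zip(p, v, q):
                rows.append((loop.peep, limb, pi, vi, qi))
    frame = pd.DataFrame(
        rows, columns=["peep", "limb", "pressure_cmH2O", "volume_ml",
                       "flow_lps"])
    frame.to_csv(path, index=False, float_format="%.6f")


def read_loops_csv(path: str | Path) -> list[PVLoop]:
    frame = pd.read_csv(path)
    needed = {"peep", "limb", "pressure_cmH2O", "volume_ml"}
    if not needed.issubset(frame.columns):
        raise ValueError(
            f"loop file {path} lacks columns {sorted(needed)}")
    has_flow = "flow_lps" in frame.columns
    loops = []
    for peep, grp in frame.groupby("peep", sort=True):
        limbs = {}
        for limb in ("inflation", "deflation"):
            sub = grp[grp["limb"] == limb]
            if len(sub) == 0:
                raise ValueError(f"PEEP {peep} is missing its {limb} limb")
            p = sub["pressure_cmH2O"].to_numpy(float)
            v = sub["volume_ml"].to_numpy(float)
            q = sub["flow_lps"].to_numpy(float) if has_flow else None
            order = np.argsort(p) if limb == "inflation" else np.argsort(-p)
            limbs[limb] = (p[order], v[order],
                           None if q is None or np.isnan(q).all()
                           else q[order])
        loops.append(PVLoop(
            peep=float(peep),
            inflation_p=limbs["inflation"][0],
            inflation_v=limbs["inflation"][1],
            inflation_q=limbs["inflation"][2],
            deflation_p=limbs["deflation"][0],
            deflation_v=limbs["deflation"][1],
            deflation_q=limbs["deflation"][2]))
    return loops
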