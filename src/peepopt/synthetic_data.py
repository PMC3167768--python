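"""Synthetic staircase-PEEP manoeuvre generator.

Emulates the recruitment-manoeuvre protocol — volume-controlled breaths
with a decelerating inspiratory flow ramp, ~5 breaths per PEEP plateau,
PEEP incremented in 5-cmH2O steps with peak airway pressure capped at
45 cmH2O, end-inspiratory/end-expiratory holds at ZEEP, series airway
resistance, auto-PEEP and additive Gaussian sensor noise — on top of a
ground-truth threshold-pressure recruitment model, so that every pipeline
stage can be tested against known parameters.

Within a breath, recruitment is treated as quasi-static along the current
limb's CDF: airway pressure is the pressure at which the model's recruited
volume equals the instantaneous lung volume, plus the resistive term
R * flow.  Auto-PEEP follows the flow-limitation waterfall: the effective
end-expiratory alveolar pressure is max(set PEEP, intrinsic PEEP measured
at ZEEP), and the TOP/TCP mean-shift schedules respond to that effective
PEEP (set PEEP below the intrinsic level changes nothing downstream of the
choke point).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from scipy.special import ndtr, ndtri

from . import waveform_io
from .waveform_io import PVLoop, PressureFlowRecord

__all__ = [
    "GroundTruth",
    "ProtocolScript",
    "SyntheticManoeuvre",
    "generate_manoeuvre",
    "inject_anomaly",
]


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of one synthetic patient trial.

    Mean-shift schedules are linear in effective PEEP by default
    (``mean_at_zeep + slope * peep``); a tabulated schedule
    ``[(peep, mean), ...]`` may be supplied instead and is interpolated
    piecewise-linearly with end-slope extrapolation (this also emulates a
    TOP up-turn at high PEEP for over-inflation scenarios).
    """

    seed: int
    tlc_ml: float = 1440.0
    inflation_sd: float = 15.0
    deflation_sd: float = 7.0
    top_mean_at_zeep: float = 32.8
    top_slope: float = -0.26          # cmH2O per cmH2O PEEP
    tcp_mean_at_zeep: float = 10.8
    tcp_slope: float = 0.46
    top_schedule: tuple[tuple[float, float], ...] | None = None
    tcp_schedule: tuple[tuple[float, float], ...] | None = None
    resistance: float = 8.0           # cmH2O.s/L
    auto_peep: float = 3.0            # cmH2O, intrinsic PEEP at ZEEP
    noise_sd_pressure: float = 0.3    # cmH2O
    noise_sd_flow: float = 0.01      # L/s

    def __post_init__(self) -> None:
        if self.tlc_ml <= 0:
            raise ValueError("TLC must be positive")
        if self.inflation_sd <= 0 or self.deflation_sd <= 0:
            raise ValueError("SDs must be positive")
        if self.resistance < 0 or self.auto_peep < 0:
            raise ValueError("resistance and auto-PEEP must be non-negative")

    def _schedule(self, peep, schedule, at_zeep, slope):
        peep = np.asarray(peep, dtype=float)
        if schedule is None:
            out = at_zeep + slope * peep
        else:
            pts = np.asarray(schedule, dtype=float)
            x, y = pts[:, 0], pts[:, 1]
            out = np.interp(peep, x, y)
            lo = peep < x[0]
            hi = peep > x[-1]
            if x.size >= 2:
                s0 = (y[1] - y[0]) / (x[1] - x[0])
                s1 = (y[-1] - y[-2]) / (x[-1] - x[-2])
                out = np.where(lo, y[0] + s0 * (peep - x[0]), out)
                out = np.where(hi, y[-1] + s1 * (peep - x[-1]), out)
        return out if out.ndim else float(out)

    def top_mean(self, effective_peep):
        return self._schedule(effective_peep, self.top_schedule,
                              self.top_mean_at_zeep, self.top_slope)

    def tcp_mean(self, effective_peep):
        return self._schedule(effective_peep, self.tcp_schedule,
                              self.tcp_mean_at_zeep, self.tcp_slope)

    def effective_peep(self, set_peep: float) -> float:
        return max(float(set_peep), self.auto_peep)


@dataclass(frozen=True)
class ProtocolScript:
    """The manoeuvre protocol: staircase steps, breath shape, safety cap."""

    peep_steps: tuple[float, ...] = (0, 5, 10, 15, 20, 25, 30, 35, 40, 45)
    breaths_per_step: int = 5
    tidal_volume_ml: float = 500.0
    peak_pressure_cap: float = 45.0   # cmH2O
    sample_rate_hz: float = 100.0
    t_insp_s: float = 1.0
    t_exp_s: float = 3.0
    exp_time_constant_s: float = 0.8
    flow_end_fraction: float = 0.25   # decelerating ramp: peak -> 25% of peak
    include_holds: bool = True
    hold_duration_s: float = 2.0

    def __post_init__(self) -> None:
        if self.tidal_volume_ml <= 0 or self.breaths_per_step < 1:
            raise ValueError("invalid protocol script")
        if not (0 < self.flow_end_fraction <= 1):
            raise ValueError("flow_end_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticManoeuvre:
    """A generated manoeuvre: the noisy record, the noise-free model loops,
    the exact volume trace, hold windows, and bookkeeping for tests."""

    record: PressureFlowRecord
    loops: tuple[PVLoop, ...]           # noise-free, absolute volumes
    truth: GroundTruth
    script: ProtocolScript
    peep_levels: tuple[float, ...]      # effective (deduplicated) levels
    set_peep_levels: tuple[float, ...]  # as commanded, incl. capped final
    hold_windows: dict                  # {'end_insp': (t0,t1), 'end_exp': ...}
    frc_ml: float                       # lung volume at record start
    true_volume: np.ndarray             # ml, analytic volume - frc
    breath_tidal_ml: tuple[float, ...]  # delivered volume per breath
    n_breaths: int


def _insp_profile(script: ProtocolScript, n: int):
    """Decelerating flow ramp delivering exactly the scripted tidal volume.

    Returns (flow L/s, volume-above-start ml) sampled at n points spanning
    the inspiration (endpoint excluded)."""
    t = np.arange(n) / script.sample_rate_hz
    ti = script.t_insp_s
    f1 = script.flow_end_fraction
    q_peak = (script.tidal_volume_ml / 1000.0) / (ti * (1 + f1) / 2.0)
    q = q_peak * (1 - (1 - f1) * t / ti)
    vol = q_peak * (t - (1 - f1) * t ** 2 / (2 * ti)) * 1000.0
    return q, vol


def _alveolar_pressure(v_ml, mean, sd, tlc):
    ratio = np.clip(np.asarray(v_ml, dtype=float) / tlc, 1e-9, 1 - 1e-9)
    return mean + sd * ndtri(ratio)


def _v_ee(truth: GroundTruth, set_peep: float) -> float:
    e = truth.effective_peep(set_peep)
    return truth.tlc_ml * float(
        ndtr((e - truth.tcp_mean(e)) / truth.deflation_sd))


def _breath_peak_pressure(truth: GroundTruth, script: ProtocolScript,
                          set_peep: float) -> float:
    """Predicted peak airway pressure of a converged breath at this PEEP."""
    e = truth.effective_peep(set_peep)
    v0 = _v_ee(truth, set_peep)
    if v0 + script.tidal_volume_ml >= 0.999 * truth.tlc_ml:
        return float("inf")
    n = int(round(script.t_insp_s * script.sample_rate_hz))
    q, dv = _insp_profile(script, n)
    p = _alveolar_pressure(v0 + dv, truth.top_mean(e), truth.inflation_sd,
                           truth.tlc_ml) + truth.resistance * q
    return float(np.max(p))


def _capped_steps(truth: GroundTruth,
                  script: ProtocolScript) -> list[float]:
    """Ascending steps truncated at the peak-pressure cap; the final level
    may be off-grid (the largest integer PEEP whose predicted peak stays
    within the cap)."""
    steps: list[float] = []
    prev = None
    for p in script.peep_steps:
        if prev is not None and p < prev:
            steps.append(p)    # decremental phase: no cap logic needed
            prev = p
            continue
        peak = _breath_peak_pressure(truth, script, p)
        if peak <= script.peak_pressure_cap:
            steps.append(p)
            prev = p
            continue
        lo = prev if prev is not None else 0.0
        hi = p
        if prev is None:
            raise ValueError(
                "infeasible script: the first PEEP step already exceeds "
                "the peak-pressure cap (tidal volume too large for TLC?)")
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if _breath_peak_pressure(truth, script, mid) <= \
                    script.peak_pressure_cap:
                lo = mid
            else:
                hi = mid
        final = float(np.floor(lo))
        if final > prev:
            steps.append(final)
        break
    return steps


def _model_loop(truth: GroundTruth, set_peep: float,
                script: ProtocolScript, n_pts: int = 40) -> PVLoop:
    """The noise-free quasi-static loop at one level, absolute volumes."""
    e = truth.effective_peep(set_peep)
    v0 = _v_ee(truth, set_peep)
    v1 = v0 + script.tidal_volume_ml
    v_grid = np.linspace(v0, v1, n_pts)
    p_inf = _alveolar_pressure(v_grid, truth.top_mean(e),
                               truth.inflation_sd, truth.tlc_ml)
    p_def = _alveolar_pressure(v_grid[::-1], truth.tcp_mean(e),
                               truth.deflation_sd, truth.tlc_ml)
    return PVLoop(peep=e, inflation_p=p_inf, inflation_v=v_grid,
                  deflation_p=p_def, deflation_v=v_grid[::-1],
                  inflation_q=np.zeros(n_pts), deflation_q=np.zeros(n_pts),
                  n_breaths_averaged=1)


def generate_manoeuvre(truth: GroundTruth,
                       script: ProtocolScript | None = None
                       ) -> SyntheticManoeuvre:
    """Simulate the full staircase manoeuvre.

    Returns the noisy sampled waveform together with the exact model loops
    and bookkeeping (hold windows, FRC, per-breath delivered volumes).
    Same seed, same output, bit for bit.
    """
    if script is None:
        script = ProtocolScript()
    if script.tidal_volume_ml >= truth.tlc_ml:
        raise ValueError("infeasible script: tidal volume exceeds TLC")
    steps = _capped_steps(truth, script)
    dt = 1.0 / script.sample_rate_hz
    n_insp = int(round(script.t_insp_s * script.sample_rate_hz))
    n_exp = int(round(script.t_exp_s * script.sample_rate_hz))
    n_hold = int(round(script.hold_duration_s * script.sample_rate_hz))

    paw: list[np.ndarray] = []
    flow: list[np.ndarray] = []
    volume: list[np.ndarray] = []
    tidal: list[float] = []
    hold_windows: dict = {}
    n_breaths = 0

    # Lung volume is tracked as the trapezoidal integral of the emitted
    # flow samples — the same quadrature the loader applies — so that the
    # sampled record and the model are exactly consistent and no
    # phase-boundary discretisation error accumulates across the staircase.
    frc = _v_ee(truth, steps[0])
    v_now = frc
    q_prev: float | None = None
    t_now = 0.0

    def integrate(q: np.ndarray) -> np.ndarray:
        nonlocal v_now, q_prev
        if q_prev is None:          # very first sample of the record
            inc = np.concatenate(([0.0],
                                  (q[1:] + q[:-1]) * 0.5 * dt * 1000.0))
        else:
            qq = np.concatenate(([q_prev], q))
            inc = (qq[1:] + qq[:-1]) * 0.5 * dt * 1000.0
        v = v_now + np.cumsum(inc)
        v_now = float(v[-1])
        q_prev = float(q[-1])
        return v

    def emit(p, q, v):
        nonlocal t_now
        paw.append(np.asarray(p, dtype=float))
        flow.append(np.asarray(q, dtype=float))
        volume.append(np.asarray(v, dtype=float))
        t_now += len(p) * dt

    def inspiration(e):
        nonlocal n_breaths
        q, _ = _insp_profile(script, n_insp)
        v_start = v_now
        v = integrate(q)
        if v[-1] >= 0.999 * truth.tlc_ml:
            raise ValueError(
                "infeasible script: inspiration would exceed TLC at "
                f"effective PEEP {e}")
        p = _alveolar_pressure(v, truth.top_mean(e), truth.inflation_sd,
                               truth.tlc_ml) + truth.resistance * q
        emit(p, q, v)
        n_breaths += 1
        tidal.append(v[-1] - v_start)

    def expiration(e, set_peep):
        v_target = _v_ee(truth, set_peep)
        dv = v_now - v_target
        t = (np.arange(n_exp) + 1) * dt
        q = -(dv / script.exp_time_constant_s) * np.exp(
            -t / script.exp_time_constant_s) / 1000.0  # ml/s -> L/s
        v = integrate(q)
        p = _alveolar_pressure(v, truth.tcp_mean(e), truth.deflation_sd,
                               truth.tlc_ml) + truth.resistance * q
        emit(p, q, v)

    def hold(mean, sd, name):
        window = (t_now, t_now + n_hold * dt - dt)
        q = np.zeros(n_hold)
        v = integrate(q)
        emit(_alveolar_pressure(v, mean, sd, truth.tlc_ml), q, v)
        hold_windows[name] = window

    for k, set_peep in enumerate(steps):
        e = truth.effective_peep(set_peep)
        for _ in range(script.breaths_per_step):
            inspiration(e)
            expiration(e, set_peep)
        if k == 0 and script.include_holds:
            # extra ZEEP breath carrying the two hold manoeuvres
            inspiration(e)
            hold(truth.top_mean(e), truth.inflation_sd, "end_insp")
            expiration(e, set_peep)
            hold(truth.tcp_mean(e), truth.deflation_sd, "end_exp")

    paw_all = np.concatenate(paw)
    flow_all = np.concatenate(flow)
    vol_all = np.concatenate(volume)
    time = np.arange(paw_all.size) * dt

    rng = np.random.default_rng(truth.seed)
    if truth.noise_sd_pressure > 0:
        paw_all = paw_all + rng.normal(0, truth.noise_sd_pressure,
                                       paw_all.size)
    if truth.noise_sd_flow > 0:
        flow_all = flow_all + rng.normal(0, truth.noise_sd_flow,
                                         flow_all.size)

    record = PressureFlowRecord.from_channels(time, paw_all, flow_all)
    effective = []
    for p in steps:
        e = truth.effective_peep(p)
        if e not in effective:
            effective.append(e)
    loops = tuple(_model_loop(truth, p, script)
                  for p in sorted(set(truth.effective_peep(s)
                                      for s in steps)))
    return SyntheticManoeuvre(
        record=record, loops=loops, truth=truth, script=script,
        peep_levels=tuple(effective), set_peep_levels=tuple(steps),
        hold_windows=hold_windows, frc_ml=frc,
        true_volume=vol_all - frc, breath_tidal_ml=tuple(tidal),
        n_breaths=n_breaths)


# ---------------------------------------------------------------------------

def inject_anomaly(record: PressureFlowRecord, index: int,
                   drop_cmh2o: float, by: str = "breath",
                   width_fraction: float = 0.2) -> PressureFlowRecord:
    """Inject a mid-inspiratory pressure dip while flow stays positive.

    ``by='breath'`` treats ``index`` as a breath ordinal and centres the dip
    mid-inspiration; ``by='sample'`` treats it as a sample index, which must
    fall inside an inspiration (a dip during expiration is rejected).  A
    zero-depth drop returns the record unchanged.
    """
    if drop_cmh2o < 0:
        raise ValueError("drop must be non-negative")
    segments = waveform_io.segment_breaths(record)
    if by == "breath":
        if not 0 <= index < len(segments):
            raise IndexError(
                f"breath index {index} out of range (0..{len(segments)-1})")
        seg = segments[index]
        centre = (seg.i_insp_start + seg.i_insp_end) // 2
        half = max(1, int((seg.i_insp_end - seg.i_insp_start)
                          * width_fraction / 2))
        lo, hi = centre - half, centre + half
    elif by == "sample":
        if not 0 <= index < len(record):
            raise IndexError("sample index out of range")
        seg = next((s for s in segments
                    if s.i_insp_start <= index < s.i_insp_end), None)
        if seg is None or record.flow[index] <= 0:
            raise ValueError(
                "anomaly must be injected during an inspiration "
                "(positive-flow phase)")
        half = max(1, int((seg.i_insp_end - seg.i_insp_start)
                          * width_fraction / 2))
        lo, hi = index - half, index + half
    else:
        raise ValueError("by must be 'breath' or 'sample'")
    if drop_cmh2o == 0:
        return record
    paw = record.paw.copy()
    n = hi - lo
    window = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))
    paw[lo:hi] -= drop_cmh2o * window
    return PressureFlowRecord(time=record.time, paw=paw, flow=record.flow,
                              volume=record.volume)


def write_ground_truth_json(man: SyntheticManoeuvre,
                            path: str | Path) -> None:
    """Sidecar with everything a downstream stage may treat as known:
    hold windows, set PEEP levels, FRC, and the generating parameters."""
    truth = man.truth
    data = {
        "seed": truth.seed,
        "tlc_ml": truth.tlc_ml,
        "inflation_sd": truth.inflation_sd,
        "deflation_sd": truth.deflation_sd,
        "resistance": truth.resistance,
        "auto_peep": truth.auto_peep,
        "top_schedule": [[p, float(truth.top_mean(truth.effective_peep(p)))]
                         for p in man.set_peep_levels],
        "tcp_schedule": [[p, float(truth.tcp_mean(truth.effective_peep(p)))]
                         for p in man.set_peep_levels],
        "set_peep_levels": list(man.set_peep_levels),
        "effective_peep_levels": list(man.peep_levels),
        "frc_ml": man.frc_ml,
        "hold_windows": {k: list(v) for k, v in man.hold_windows.items()},
        "tidal_volume_ml": man.script.tidal_volume_ml,
        "n_breaths": man.n_breaths,
    }
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))
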