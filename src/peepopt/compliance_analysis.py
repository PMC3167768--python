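"""Linear-region compliance and its relationship to the model SD.

Dynamic-loop compliance varies with PEEP: low at both extremes (units still
closed, or over-distension) and roughly constant over a middle "linear"
band of the staircase.  Because total lung capacity differs widely between
patients, compliances are also normalised to a reference TLC of 1 L before
comparing patients; the normalised linear compliance then follows the
inflation SD closely (an exponential decay — a wider threshold-pressure
spread means a flatter recruitment curve, hence a stiffer-looking lung).

Note the SD is an *indicator* of compliance, not numerically equal to it:
the steepest slope the forward model can produce is TLC/(sd*sqrt(2*pi)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .waveform_io import PVLoop

__all__ = [
    "ComplianceSummary",
    "SdComplianceFit",
    "loop_compliance",
    "linear_region",
    "normalise_compliance",
    "sd_compliance_fit",
    "summarise_compliance",
]


@dataclass(frozen=True)
class ComplianceSummary:
    """Per-trial compliance layout: linear band, top-PEEP value, and the
    TLC-normalised linear compliance."""

    linear_peep_range: tuple[float, float]      # cmH2O
    linear_compliance_range: tuple[float, float]  # ml/cmH2O, min-max in band
    highest_peep: float
    compliance_at_max_peep: float               # ml/cmH2O
    tlc_ml: float
    linear_compliance: float                    # representative (band mean)
    normalised_compliance: float                # at the reference TLC
    reference_tlc_ml: float = 1000.0


@dataclass(frozen=True)
class SdComplianceFit:
    """c = a * exp(b * sd) fitted by least squares on log-compliance."""

    a: float
    b: float
    r_squared: float
    n_used: int


def loop_compliance(loop: PVLoop,
                    region: tuple[float, float] = (0.25, 0.75)) -> float:
    """Least-squares slope (ml/cmH2O) of inflation volume vs pressure over
    the mid-tidal region (central volume quantiles of the limb)."""
    p = np.asarray(loop.inflation_p, dtype=float)
    v = np.asarray(loop.inflation_v, dtype=float)
    if p.size < 2:
        raise ValueError("at least two inflation points are required")
    if np.ptp(p) < 1e-9:
        raise ValueError("degenerate limb: all pressures equal")
    lo = v.min() + region[0] * np.ptp(v)
    hi = v.min() + region[1] * np.ptp(v)
    mask = (v >= lo) & (v <= hi)
    if mask.sum() < 2 or np.ptp(p[mask]) < 1e-9:
        mask = np.ones_like(p, dtype=bool)
    return float(np.polyfit(p[mask], v[mask], 1)[0])


def linear_region(loops: Sequence[PVLoop], max_ratio: float = 1.5,
                  region: tuple[float, float] = (0.25, 0.75)
                  ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Widest contiguous PEEP band whose loop compliances vary by less than
    ``max_ratio`` (max/min).  Returns ((peep_lo, peep_hi), (c_min, c_max)).
    Falls back to the whole range with a warning when no two adjacent
    levels qualify."""
    if len(loops) < 3:
        raise ValueError("at least three loops are required")
    loops = sorted(loops, key=lambda l: l.peep)
    peeps = [l.peep for l in loops]
    comps = [loop_compliance(l, region) for l in loops]
    best: tuple[int, int] | None = None
    for i in range(len(loops)):
        for j in range(i + 1, len(loops)):
            window = comps[i:j + 1]
            cmin, cmax = min(window), max(window)
            if cmin <= 0 or cmax / cmin >= max_ratio:
                break
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
    if best is None:
        warnings.warn(
            "no contiguous PEEP band has stable compliance; "
            "returning the whole range", stacklevel=2)
        best = (0, len(loops) - 1)
    i, j = best
    window = comps[i:j + 1]
    return ((peeps[i], peeps[j]), (min(window), max(window)))


def normalise_compliance(compliance: float, tlc_ml: float,
                         reference_tlc_ml: float = 1000.0) -> float:
    """Scale a compliance to a reference TLC (default 1 L):
    c_norm = c * ref_tlc / tlc.  Linear and exactly invertible."""
    if tlc_ml <= 0:
        raise ValueError("TLC must be positive")
    return compliance * reference_tlc_ml / tlc_ml


def sd_compliance_fit(points: Sequence[tuple[float, float]]
                      ) -> SdComplianceFit:
    """Fit c = a * exp(b * sd) by linear least squares on ln(c).

    Non-positive compliances are excluded with a warning.  The reported R^2
    is that of the log-linear regression.  Log-linear rather than nonlinear
    least squares keeps the fit deterministic and closed-form.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("at least three (sd, compliance) points required")
    good = pts[:, 1] > 0
    if not good.all():
        warnings.warn(
            f"excluding {int((~good).sum())} non-positive compliance "
            "point(s) from the exponential fit", stacklevel=2)
    pts = pts[good]
    if pts.shape[0] < 3:
        raise ValueError("fewer than three positive-compliance points")
    sd, logc = pts[:, 0], np.log(pts[:, 1])
    b, loga = np.polyfit(sd, logc, 1)
    pred = loga + b * sd
    ss_res = float(np.sum((logc - pred) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SdComplianceFit(a=float(np.exp(loga)), b=float(b),
                           r_squared=r2, n_used=int(pts.shape[0]))


def summarise_compliance(loops: Sequence[PVLoop], tlc_ml: float,
                         max_ratio: float = 1.5,
                         reference_tlc_ml: float = 1000.0
                         ) -> ComplianceSummary:
    """Assemble the per-trial compliance summary: linear band, compliance
    at the highest trialled PEEP, and the TLC-normalised representative
    (band-mean) linear compliance."""
    loops = sorted(loops, key=lambda l: l.peep)
    (p_lo, p_hi), (c_min, c_max) = linear_region(loops, max_ratio)
    in_band = [loop_compliance(l) for l in loops if p_lo <= l.peep <= p_hi]
    c_lin = float(np.mean(in_band))
    top = loops[-1]
    return ComplianceSummary(
        linear_peep_range=(p_lo, p_hi),
        linear_compliance_range=(c_min, c_max),
        highest_peep=top.peep,
        compliance_at_max_peep=loop_compliance(top),
        tlc_ml=tlc_ml,
        linear_compliance=c_lin,
        normalised_compliance=normalise_compliance(c_lin, tlc_ml,
                                                   reference_tlc_ml),
        reference_tlc_ml=reference_tlc_ml)
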