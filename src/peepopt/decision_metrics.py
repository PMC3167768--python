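"""PEEP-selection metrics and disease-evolution tracking.

Three metrics turn one fitted manoeuvre into a patient-specific optimal
PEEP:

* **TOP shift** — falling mean TOP with PEEP means added PEEP still recruits
  new units; a rise signals over-inflation.  Recommend the highest trialled
  PEEP reached while the TOP mean is still strictly decreasing.
* **TCP benchmark** — when PEEP is below the mean TCP, more than half of the
  recruited units de-recruit at end-expiration.  Recommend the lowest
  trialled PEEP at which the fitted TCP mean no longer exceeds PEEP.
* **Net recruitment** — the deflation-limb recruited fraction minus the
  inflation-limb recruited fraction, each evaluated at PEEP with that
  level's fitted distribution; recommend its argmax, valid only while the
  TOP mean keeps decreasing.

Four further quantities track the disease state across repeated trials:
the PEEP-averaged mean TOP (stiffness/recruitability), the inflation SD
(compliance heterogeneity), and the TOP and TCP mean-shift gradients
(responsiveness to PEEP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .recruitment_model import TrialFit

__all__ = [
    "PeepRecommendation",
    "DiseaseTrajectory",
    "top_based_peep",
    "tcp_based_peep",
    "net_recruitment_curve",
    "net_recruitment_from_params",
    "net_recruitment_peep",
    "classify_recruitability",
    "top_gradient",
    "tcp_gradient",
    "recommend",
    "build_trajectory",
]

# fitted-mean changes smaller than this are treated as flat (fit noise)
TREND_TOLERANCE = 0.1   # cmH2O
SLOPE_TOLERANCE = 0.05  # cmH2O per cmH2O PEEP


@dataclass(frozen=True)
class PeepRecommendation:
    """The three metric-based optimal PEEPs for one trial."""

    top_peep: float
    tcp_peep: float
    tcp_reached: bool            # False when TCP never falls to PEEP
    net_recruitment_peep: float
    net_valid: bool              # False when TOP rises at/below the argmax
    recruitability_class: str
    auto_peep: float = 0.0

    def to_dict(self) -> dict:
        return {
            "top_peep_cmh2o": self.top_peep,
            "tcp_peep_cmh2o": self.tcp_peep,
            "tcp_benchmark_reached": self.tcp_reached,
            "net_recruitment_peep_cmh2o": self.net_recruitment_peep,
            "net_recruitment_valid": self.net_valid,
            "recruitability_class": self.recruitability_class,
            "auto_peep_cmh2o": self.auto_peep,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True))


@dataclass(frozen=True)
class DiseaseTrajectory:
    """Per-trial summary metrics across repeated manoeuvres."""

    labels: tuple[str, ...]
    avg_top: tuple[float, ...]          # cmH2O, PEEP-averaged mean TOP
    inflation_sd: tuple[float, ...]     # cmH2O
    top_gradients: tuple[float, ...]    # cmH2O per cmH2O PEEP
    tcp_gradients: tuple[float, ...]
    trends: dict                        # qualitative labels

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "avg_top_cmh2o": list(self.avg_top),
            "inflation_sd_cmh2o": list(self.inflation_sd),
            "top_gradient": list(self.top_gradients),
            "tcp_gradient": list(self.tcp_gradients),
            "trends": self.trends,
        }


def _check_means(means) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(sorted(means), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("at least two (peep, mean) pairs are required")
    return arr[:, 0], arr[:, 1]


def top_based_peep(top_means: Sequence[tuple[float, float]],
                   tolerance: float = TREND_TOLERANCE) -> float:
    """Highest trialled PEEP reached while mean TOP is still strictly
    decreasing; stops at the level before the first rise (over-inflation
    signal).  Flat means recommend the lowest level (no recruitment benefit,
    so minimise pressure)."""
    peeps, means = _check_means(top_means)
    for i in range(1, peeps.size):
        if means[i] >= means[i - 1] - tolerance:
            return float(peeps[i - 1])
    return float(peeps[-1])


def tcp_based_peep(tcp_means: Sequence[tuple[float, float]],
                   interpolate: bool = False) -> tuple[float, bool]:
    """Lowest trialled PEEP whose fitted TCP mean does not exceed that PEEP
    (no more than 50% of units de-recruit at end-expiration).  If no level
    qualifies, returns the maximum trialled PEEP with ``reached=False``.

    ``interpolate=True`` returns the linearly interpolated crossing of the
    TCP-mean line with the identity instead of snapping to a trialled
    level.
    """
    peeps, means = _check_means(tcp_means)
    for i, (p, m) in enumerate(zip(peeps, means)):
        if m <= p:
            if interpolate and i > 0:
                p0, m0 = peeps[i - 1], means[i - 1]
                # crossing of mean(p) with the identity between the levels
                denom = (p - p0) - (m - m0)
                frac = (m0 - p0) / denom if abs(denom) > 1e-12 else 0.0
                return float(p0 + frac * (p - p0)), True
            return float(p), True
    return float(peeps[-1]), False


def net_recruitment_from_params(peeps, top_means, tcp_means,
                                inflation_sd, deflation_sd
                                ) -> list[tuple[float, float]]:
    """net(p) = Phi((p - mu_TCP(p))/sd_def) - Phi((p - mu_TOP(p))/sd_inf),
    evaluated at each trialled PEEP with that level's fitted means."""
    out = []
    for p, mt, mc in zip(peeps, top_means, tcp_means):
        net = float(ndtr((p - mc) / deflation_sd)
                    - ndtr((p - mt) / inflation_sd))
        out.append((float(p), net))
    return out


def net_recruitment_curve(trial: TrialFit) -> list[tuple[float, float]]:
    """Net recruitment at each trialled PEEP of a fitted manoeuvre.

    Levels missing either limb are omitted."""
    tops = {lf.peep: lf.distribution for lf in trial.limb("inflation")}
    tcps = {lf.peep: lf.distribution for lf in trial.limb("deflation")}
    peeps = sorted(set(tops) & set(tcps))
    return net_recruitment_from_params(
        peeps, [tops[p].mean for p in peeps], [tcps[p].mean for p in peeps],
        trial.inflation_sd, trial.deflation_sd)


def net_recruitment_peep(curve: Sequence[tuple[float, float]],
                         top_means: Sequence[tuple[float, float]],
                         tolerance: float = TREND_TOLERANCE,
                         interpolate: bool = False) -> tuple[float, bool]:
    """Argmax of net recruitment over trialled PEEPs (ties to the lowest),
    plus a validity flag that is False when the TOP mean rises anywhere at
    or below the selected level.  ``interpolate=True`` refines an interior
    argmax by the parabola through it and its neighbours."""
    if not curve:
        raise ValueError("empty net-recruitment curve")
    arr = np.asarray(sorted(curve), dtype=float)
    k = int(np.argmax(arr[:, 1]))
    best = float(arr[k, 0])
    if interpolate and 0 < k < arr.shape[0] - 1:
        x, y = arr[k - 1:k + 2, 0], arr[k - 1:k + 2, 1]
        a, b, _ = np.polyfit(x, y, 2)
        if a < 0:
            best = float(np.clip(-b / (2 * a), x[0], x[2]))
    peeps, means = _check_means(top_means)
    valid = True
    for i in range(1, peeps.size):
        if peeps[i] <= best and means[i] >= means[i - 1] - tolerance:
            valid = False
            break
    return best, valid


def _slope_label(slope: float, tolerance: float) -> str:
    if abs(slope) < tolerance:
        return "flat"
    return "down" if slope < 0 else "up"


def classify_recruitability(top_means, tcp_means,
                            tolerance: float = SLOPE_TOLERANCE) -> str:
    """Quadrant label from the signs of the fitted TOP and TCP slopes
    (e.g. ``TOP-down/TCP-up`` = recruitable and PEEP retains units);
    ``unresponsive`` when both slopes sit inside the flat band."""
    st = top_gradient(top_means)
    sc = tcp_gradient(tcp_means)
    lt, lc = _slope_label(st, tolerance), _slope_label(sc, tolerance)
    if lt == "flat" and lc == "flat":
        return "unresponsive"
    return f"TOP-{lt}/TCP-{lc}"


def top_gradient(top_means: Sequence[tuple[float, float]]) -> float:
    """Ordinary least-squares slope of the TOP mean shift vs PEEP
    (dimensionless: cmH2O per cmH2O PEEP)."""
    peeps, means = _check_means(top_means)
    return float(np.polyfit(peeps, means, 1)[0])


def tcp_gradient(tcp_means: Sequence[tuple[float, float]]) -> float:
    """OLS slope of the TCP mean shift vs PEEP."""
    return top_gradient(tcp_means)


def recommend(trial: TrialFit,
              tolerance: float = TREND_TOLERANCE) -> PeepRecommendation:
    """All three PEEP selections plus the recruitability class for one
    fitted manoeuvre.  Every recommendation is one of the trialled levels."""
    tops = trial.top_means
    tcps = trial.tcp_means
    tcp_p, reached = tcp_based_peep(tcps)
    curve = net_recruitment_curve(trial)
    net_p, net_valid = net_recruitment_peep(curve, tops, tolerance)
    return PeepRecommendation(
        top_peep=top_based_peep(tops, tolerance),
        tcp_peep=tcp_p, tcp_reached=reached,
        net_recruitment_peep=net_p, net_valid=net_valid,
        recruitability_class=classify_recruitability(tops, tcps),
        auto_peep=trial.auto_peep)


# ---------------------------------------------------------------------------
# disease tracking

def _step_labels(values: Sequence[float], rel_tol: float) -> list[str]:
    labels = []
    for a, b in zip(values, values[1:]):
        base = abs(a) if abs(a) > 1e-12 else 1.0
        if abs(b - a) < rel_tol * base:
            labels.append("stable")
        else:
            labels.append("increased" if b > a else "decreased")
    return labels


def _join(labels: Sequence[str]) -> str:
    if len(set(labels)) == 1:
        return labels[0]
    return " then ".join(labels)


def build_trajectory(series: Sequence[tuple[str, TrialFit]],
                     rel_tol: float = 0.05) -> DiseaseTrajectory:
    """Summarise an ordered series of trials for one patient.

    Per trial: unweighted mean of the fitted TOP means over its PEEP
    levels, the inflation SD, and the two mean-shift gradients.  Trend
    labels compare consecutive trials with a no-change band of
    ``rel_tol`` (5% of the preceding value by default) and are interpreted
    against the canonical scenarios: falling average TOP = recruitment
    improving, rising SD = compliance worsening / more injured units,
    growing gradient magnitude = more responsive to PEEP.
    """
    if len(series) < 2:
        raise ValueError(
            "disease tracking needs at least two time-ordered trials")
    labels = tuple(str(lab) for lab, _ in series)
    fits = [fit for _, fit in series]
    avg_top = tuple(float(np.mean([m for _, m in f.top_means]))
                    for f in fits)
    sds = tuple(float(f.inflation_sd) for f in fits)
    tg = tuple(top_gradient(f.top_means) for f in fits)
    cg = tuple(tcp_gradient(f.tcp_means) for f in fits)

    top_steps = _step_labels(avg_top, rel_tol)
    sd_steps = _step_labels(sds, rel_tol)
    resp_steps = _step_labels([abs(g) for g in tg], rel_tol)

    def overall(first, last, tol_base):
        if abs(last - first) < rel_tol * max(abs(first), 1e-12):
            return "stable"
        return "increased" if last > first else "decreased"

    trends = {
        "avg_top": _join(top_steps),
        "inflation_sd": _join(sd_steps),
        "top_gradient_magnitude": _join(resp_steps),
        "recruitment": {"decreased": "improved", "increased": "worsened",
                        "stable": "stable"}[overall(avg_top[0], avg_top[-1],
                                                    avg_top[0])],
        "compliance": {"increased": "worsened", "decreased": "improved",
                       "stable": "stable"}[overall(sds[0], sds[-1], sds[0])],
        "responsiveness": {"increased": "more responsive",
                           "decreased": "less responsive",
                           "stable": "stable"}[
            overall(abs(tg[0]), abs(tg[-1]), abs(tg[0]))],
    }
    return DiseaseTrajectory(labels=labels, avg_top=avg_top,
                             inflation_sd=sds, top_gradients=tg,
                             tcp_gradients=cg, trends=trends)
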