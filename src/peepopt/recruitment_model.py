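"""Threshold-pressure recruitment model and its fitting procedure.

The lung is modelled as a large population of identical units that are
either recruited or collapsed.  Each unit opens during inflation once
airway pressure exceeds its threshold opening pressure (TOP) and collapses
during deflation once pressure falls below its threshold closing pressure
(TCP).  TOP and TCP are normally distributed across units, so the recruited
fraction at pressure p is the normal CDF Phi((p - mean)/sd) and lung volume
is TLC * Phi(.) in the continuum limit.

As PEEP changes, the TOP/TCP means shift while the per-trial standard
deviations stay fixed; fitting one manoeuvre therefore estimates a TOP and
TCP mean per PEEP level, one inflation SD, one deflation SD, the total lung
capacity TLC, and a volume-baseline offset (the unobserved end-expiratory
lung volume at the start of the manoeuvre, since measured volumes are
integrated flow relative to that point).  The objective is the mean
absolute volume error, reported per limb in ml and as a percentage of the
limb's mean absolute volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import ndtr, ndtri

from .waveform_io import PVLoop

__all__ = [
    "ThresholdDistribution",
    "LungModelConfig",
    "FitConfig",
    "LimbFit",
    "TrialFit",
    "recruited_fraction",
    "forward_volume",
    "fit_limb_mean",
    "fit_trial",
    "fit_error_summary",
]


@dataclass(frozen=True)
class ThresholdDistribution:
    """A normal TOP or TCP distribution over lung units."""

    mean: float              # cmH2O
    sd: float                # cmH2O
    limb: Literal["inflation", "deflation"] = "inflation"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class LungModelConfig:
    """Unit population defining TLC = n_units * unit_volume.

    ``compartment_offsets`` optionally adds fixed superimposed-pressure
    offsets (cmH2O) for a multi-compartment lung; the default single
    compartment lets the normal distribution absorb gravitational spread.
    """

    n_units: int = 144_000
    unit_volume_ml: float = 0.01
    compartment_offsets: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.n_units <= 0 or self.unit_volume_ml <= 0:
            raise ValueError("n_units and unit_volume must be positive")
        if len(self.compartment_offsets) == 0:
            raise ValueError("at least one compartment is required")

    @property
    def tlc_ml(self) -> float:
        return self.n_units * self.unit_volume_ml

    @classmethod
    def from_tlc(cls, tlc_ml: float, unit_volume_ml: float = 0.01,
                 compartment_offsets: tuple[float, ...] = (0.0,)
                 ) -> "LungModelConfig":
        return cls(n_units=int(round(tlc_ml / unit_volume_ml)),
                   unit_volume_ml=unit_volume_ml,
                   compartment_offsets=compartment_offsets)


@dataclass(frozen=True)
class FitConfig:
    """Search space and objective for trial fitting.

    SDs are searched over an integer grid, the mean continuously (coarse
    grid + bounded scalar refinement), TLC over [tlc_min, tlc_max] at 10 ml
    grid resolution before a continuous polish, and the volume-baseline
    offset jointly with TLC.  Grid tie-breaks take the smallest parameter;
    fitting is deterministic and seedless.
    """

    sd_min: int = 1
    sd_max: int = 40
    tlc_min: float = 500.0
    tlc_max: float = 4000.0
    mean_min: float = -20.0
    mean_max: float = 80.0
    objective: Literal["mae", "lsq"] = "mae"
    offset: Literal["fit", "zero"] | float = "fit"
    unit_volume_ml: float = 0.01


DEFAULT_FIT = FitConfig()

# measurement slack when excluding loops below auto-PEEP: a level equal to
# the (noisily estimated) auto-PEEP is kept, as in the reference cohort
AUTO_PEEP_TOLERANCE = 0.5  # cmH2O


@dataclass(frozen=True)
class LimbFit:
    """Fitted threshold distribution for one limb at one PEEP level."""

    peep: float
    distribution: ThresholdDistribution
    abs_error_ml: float
    pct_error: float

    def __post_init__(self) -> None:
        if self.abs_error_ml < 0 or self.pct_error < 0:
            raise ValueError("errors must be non-negative")


@dataclass(frozen=True)
class TrialFit:
    """Full fit of one recruitment manoeuvre."""

    trial_id: str
    inflation_sd: float
    deflation_sd: float
    tlc_ml: float
    auto_peep: float
    limb_fits: tuple[LimbFit, ...]
    baseline_ml: float = 0.0

    def __post_init__(self) -> None:
        for lf in self.limb_fits:
            if lf.peep < self.auto_peep - AUTO_PEEP_TOLERANCE:
                raise ValueError(
                    "fitted PEEP levels must not lie below auto-PEEP")

    def limb(self, which: str) -> list[LimbFit]:
        out = [lf for lf in self.limb_fits if lf.distribution.limb == which]
        return sorted(out, key=lambda lf: lf.peep)

    @property
    def peeps(self) -> list[float]:
        return [lf.peep for lf in self.limb("inflation")]

    @property
    def top_means(self) -> list[tuple[float, float]]:
        return [(lf.peep, lf.distribution.mean) for lf in self.limb("inflation")]

    @property
    def tcp_means(self) -> list[tuple[float, float]]:
        return [(lf.peep, lf.distribution.mean) for lf in self.limb("deflation")]

    @property
    def n_units(self) -> int:
        return int(round(self.tlc_ml / 0.01))

    def to_table(self) -> pd.DataFrame:
        """Per-PEEP fit layout: inflation/deflation mean, error ml, error %."""
        rows = {}
        for lf in self.limb_fits:
            limb = lf.distribution.limb
            row = rows.setdefault(lf.peep, {})
            row[f"{limb}_mean"] = lf.distribution.mean
            row[f"{limb}_error_ml"] = lf.abs_error_ml
            row[f"{limb}_error_pct"] = lf.pct_error
        frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        frame.index.name = "peep"
        return frame

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "inflation_sd": self.inflation_sd,
            "deflation_sd": self.deflation_sd,
            "tlc_ml": self.tlc_ml,
            "auto_peep": self.auto_peep,
            "baseline_ml": self.baseline_ml,
            "limb_fits": [
                {"peep": lf.peep, "limb": lf.distribution.limb,
                 "mean": lf.distribution.mean, "sd": lf.distribution.sd,
                 "abs_error_ml": lf.abs_error_ml,
                 "pct_error": lf.pct_error}
                for lf in self.limb_fits],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TrialFit":
        fits = tuple(
            LimbFit(peep=d["peep"],
                    distribution=ThresholdDistribution(
                        mean=d["mean"], sd=d["sd"], limb=d["limb"]),
                    abs_error_ml=d["abs_error_ml"],
                    pct_error=d["pct_error"])
            for d in data["limb_fits"])
        return cls(trial_id=data["trial_id"],
                   inflation_sd=data["inflation_sd"],
                   deflation_sd=data["deflation_sd"],
                   tlc_ml=data["tlc_ml"], auto_peep=data["auto_peep"],
                   baseline_ml=data.get("baseline_ml", 0.0),
                   limb_fits=fits)

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True))

    @classmethod
    def load_json(cls, path: str | Path) -> "TrialFit":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# forward model

def recruited_fraction(p, dist: ThresholdDistribution,
                       config: LungModelConfig | None = None):
    """Fraction of units recruited at pressure ``p``: Phi((p - mean)/sd),
    averaged over compartment pressure offsets when more than one is set."""
    p = np.asarray(p, dtype=float)
    if config is None or len(config.compartment_offsets) == 1:
        off = (config.compartment_offsets[0] if config is not None else 0.0)
        out = ndtr((p - off - dist.mean) / dist.sd)
    else:
        offs = np.asarray(config.compartment_offsets, dtype=float)
        out = ndtr((p[..., None] - offs - dist.mean) / dist.sd).mean(axis=-1)
    return out if out.ndim else float(out)


def forward_volume(p, dist: ThresholdDistribution,
                   config: LungModelConfig, discrete: bool = False):
    """Model lung volume (ml) at pressure ``p``.

    The continuum form is TLC * Phi((p - mean)/sd).  ``discrete=True``
    enumerates the N-unit population at mid-probability quantiles instead;
    with the default 144 000 units the two differ by at most one unit
    volume.
    """
    if not discrete:
        return config.tlc_ml * recruited_fraction(p, dist, config)
    p = np.asarray(p, dtype=float)
    n = config.n_units
    quantiles = (np.arange(n) + 0.5) / n
    thresholds = dist.mean + dist.sd * ndtri(quantiles)
    if len(config.compartment_offsets) > 1:
        offs = np.asarray(config.compartment_offsets)
        per = (thresholds[None, :] + offs[:, None]).ravel()
        counts = np.searchsorted(np.sort(per), p, side="right") / len(offs)
    else:
        counts = np.searchsorted(thresholds, p, side="right")
    out = counts * config.unit_volume_ml
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# limb fitting

def _limb_arrays(limb) -> tuple[np.ndarray, np.ndarray]:
    p, v = np.asarray(limb[0], dtype=float), np.asarray(limb[1], dtype=float)
    if p.size != v.size:
        raise ValueError("pressure and volume arrays differ in length")
    if p.size < 3:
        raise ValueError("a limb needs at least 3 points to fit")
    if np.ptp(p) < 1e-9:
        raise ValueError("degenerate limb: all pressures equal")
    return p, v


def _loss(residual: np.ndarray, objective: str) -> float:
    if objective == "lsq":
        return float(np.mean(residual ** 2))
    return float(np.mean(np.abs(residual)))


def _mean_objective(mu, p, v, sd, tlc, objective):
    return _loss(tlc * ndtr((p - mu) / sd) - v, objective)


def _refine_mean(p, v, sd, tlc, mu0, half_width, objective) -> tuple[float, float]:
    """Bounded scalar refinement around a grid minimum; keeps the grid value
    on a tie (smallest parameter wins)."""
    res = minimize_scalar(
        _mean_objective, bounds=(mu0 - half_width, mu0 + half_width),
        args=(p, v, sd, tlc, objective), method="bounded",
        options={"xatol": 1e-5})
    e0 = _mean_objective(mu0, p, v, sd, tlc, objective)
    if res.fun < e0 - 1e-12:
        return float(res.x), float(res.fun)
    return float(mu0), e0


def fit_limb_mean(limb, sd: float, tlc: float,
                  peep: float = float("nan"),
                  config: FitConfig = DEFAULT_FIT,
                  kind: str | None = None) -> LimbFit:
    """Fit the threshold-distribution mean of one limb with SD and TLC fixed.

    Minimises the mean absolute volume error between TLC * Phi((p - mean)/sd)
    and the measured volumes, by scanning the means that interpolate each
    data point and refining between the bracketing candidates (agrees with
    a 0.01-cmH2O brute-force grid search to within the grid resolution).
    Returns the fit with its error in ml and as a percentage of the limb's
    mean absolute volume.
    """
    p, v = _limb_arrays(limb)
    if sd <= 0 or tlc <= 0:
        raise ValueError("sd and tlc must be positive")
    mu, _ = _fit_mean(p, v, sd, tlc, config.objective)
    mae = float(np.mean(np.abs(tlc * ndtr((p - mu) / sd) - v)))
    denom = float(np.mean(np.abs(v)))
    pct = 100.0 * mae / denom if denom > 1e-9 else float("nan")
    if kind is None:  # infer from pressure ordering when not stated
        kind = "inflation" if not np.any(np.diff(p) < 0) else "deflation"
    return LimbFit(
        peep=peep,
        distribution=ThresholdDistribution(mean=mu, sd=float(sd), limb=kind),
        abs_error_ml=mae, pct_error=pct)


# ---------------------------------------------------------------------------
# trial fitting

def _limb_data(loops: Sequence[PVLoop]):
    """(limb_kind, peep, pressures, volumes) for every limb of every loop."""
    out = []
    for loop in loops:
        out.append(("inflation", loop.peep, loop.inflation_p,
                    loop.inflation_v))
        out.append(("deflation", loop.peep, loop.deflation_p,
                    loop.deflation_v))
    return out


def _mean_candidates(p, w, sd, tlc):
    """Interpolation candidates for the best-fit mean.

    Because the residual of every point is monotone in the mean, the MAE
    optimum makes the curve pass through (or balance between) data points;
    the means that interpolate each point, mu_i = p_i - sd * Phi^-1(w_i /
    TLC), therefore bracket and (generically) contain the optimum.  This
    keeps the inner search exact at any SD scale, where a fixed mean grid
    would systematically favour large SDs.
    """
    z = ndtri(np.clip(w / tlc, 1e-7, 1 - 1e-7))
    return p - sd * z


def _candidate_errors(p, w, sd_grid, tlc, objective, stride=1):
    """Error of the candidate-optimal mean for every SD in ``sd_grid``.

    Returns (errors[n_sd], means[n_sd]).  Vectorised: the model argument at
    candidate c, point j, SD s is (p_j - p_c)/sd_s + z_c.
    """
    z = ndtri(np.clip(w / tlc, 1e-7, 1 - 1e-7))
    pc = p[::stride]
    zc = z[::stride]
    arg = ((p[None, None, :] - pc[None, :, None])
           / sd_grid[:, None, None] + zc[None, :, None])
    resid = tlc * ndtr(arg) - w[None, None, :]
    per = (np.mean(resid ** 2, axis=2) if objective == "lsq"
           else np.mean(np.abs(resid), axis=2))      # (n_sd, n_cand)
    idx = np.argmin(per, axis=1)
    errs = per[np.arange(sd_grid.size), idx]
    means = pc[idx] - sd_grid * zc[idx]
    return errs, means


def _fit_mean(p, w, sd, tlc, objective, refine=True):
    """Best-fit mean for one limb at fixed (sd, tlc): candidate scan plus
    bounded scalar refinement between the neighbouring candidates."""
    cands = np.sort(_mean_candidates(p, w, sd, tlc))
    resid = tlc * ndtr((p[None, :] - cands[:, None]) / sd) - w[None, :]
    errs = (np.mean(resid ** 2, axis=1) if objective == "lsq"
            else np.mean(np.abs(resid), axis=1))
    i = int(np.argmin(errs))
    mu0, e0 = float(cands[i]), float(errs[i])
    if not refine:
        return mu0, e0
    lo = cands[i - 1] if i > 0 else mu0 - sd
    hi = cands[i + 1] if i + 1 < cands.size else mu0 + sd
    half = max(hi - mu0, mu0 - lo, 1e-6)
    return _refine_mean(p, w, sd, tlc, mu0, half, objective)


def _grid_stage(limbs, sd_grid, tlc_grid, v0_grid, objective,
                cand_stride=1):
    """Exhaustive search over (tlc, v0); SDs and means optimised inside.

    Returns (err, tlc, v0, sd_inf, sd_def).  Inflation and deflation errors
    are separable given (tlc, v0): each limb's error is minimised over the
    candidate means, summed per SD, and the best SD picked per limb kind.
    """
    w_max = max(float(v.max()) for _, _, _, v in limbs)
    best = None
    for tlc in tlc_grid:
        for v0 in v0_grid:
            if v0 + w_max >= 0.999 * tlc:
                continue
            err_inf = np.zeros(sd_grid.size)
            err_def = np.zeros(sd_grid.size)
            for kind, _, p, v in limbs:
                e, _ = _candidate_errors(p, v + v0, sd_grid, tlc,
                                         objective, stride=cand_stride)
                if kind == "inflation":
                    err_inf += e
                else:
                    err_def += e
            total = err_inf.min() + err_def.min()
            if best is None or total < best[0] - 1e-12:
                best = (total, float(tlc), float(v0),
                        int(sd_grid[int(np.argmin(err_inf))]),
                        int(sd_grid[int(np.argmin(err_def))]))
    if best is None:
        raise ValueError(
            "no feasible (TLC, offset) combination: measured volumes "
            "exceed the TLC search range")
    return best


def _means_at(limbs, sd_inf, sd_def, tlc, v0, config):
    """Per-limb best means at fixed (sd_inf, sd_def, tlc, v0);
    returns (total_error, means)."""
    if v0 < 0 or any(float(v.max()) + v0 >= 0.999 * tlc
                     for _, _, _, v in limbs):
        return float("inf"), []
    total = 0.0
    means = []
    for kind, _, p, v in limbs:
        sd = sd_inf if kind == "inflation" else sd_def
        mu, err = _fit_mean(p, v + v0, sd, tlc, config.objective)
        total += err
        means.append(mu)
    return total, means


def _best_sds(limbs, tlc, v0, config):
    """Integer-grid SD re-selection at fixed (tlc, v0)."""
    sd_grid = np.arange(config.sd_min, config.sd_max + 1, dtype=float)
    out = {}
    for kind in ("inflation", "deflation"):
        err = np.zeros(sd_grid.size)
        for k, _, p, v in limbs:
            if k != kind:
                continue
            e, _ = _candidate_errors(p, v + v0, sd_grid, tlc,
                                     config.objective)
            err += e
        out[kind] = int(sd_grid[int(np.argmin(err))])
    return out["inflation"], out["deflation"]


def fit_trial(loops: Sequence[PVLoop], auto_peep: float,
              config: FitConfig = DEFAULT_FIT,
              trial_id: str = "trial") -> TrialFit:
    """Fit a whole manoeuvre: per-PEEP TOP/TCP means, one inflation SD, one
    deflation SD, TLC and the volume-baseline offset.

    Loops with PEEP below the measured auto-PEEP are excluded before
    fitting.  The search is nested: an outer coarse-to-fine grid over
    (TLC, baseline offset) with integer SDs and gridded means inside, then
    a continuous Nelder-Mead polish of (TLC, offset) with an SD re-selection
    pass.  Raises when fewer than two usable PEEP levels remain.
    """
    usable = sorted(
        (l for l in loops if l.peep >= auto_peep - AUTO_PEEP_TOLERANCE),
        key=lambda l: l.peep)
    if len(usable) < 2:
        raise ValueError(
            "insufficient PEEP levels: at least two loops at or above "
            f"auto-PEEP ({auto_peep} cmH2O) are required")
    limbs = []
    for kind, peep, p, v in _limb_data(usable):
        pa, va = _limb_arrays((p, v))
        limbs.append((kind, peep, pa, va))

    sd_grid = np.arange(config.sd_min, config.sd_max + 1, dtype=float)
    tlc_coarse = np.arange(config.tlc_min, config.tlc_max + 1e-9, 100.0)
    if isinstance(config.offset, str) and config.offset == "fit":
        v0_coarse = np.arange(0.0, 0.6 * config.tlc_max, 50.0)
    else:
        v0_fixed = 0.0 if config.offset == "zero" else float(config.offset)
        v0_coarse = np.array([v0_fixed])

    _, tlc_a, v0_a, _, _ = _grid_stage(
        limbs, sd_grid, tlc_coarse, v0_coarse, config.objective,
        cand_stride=2)

    # local refinement at 10 ml TLC resolution
    tlc_b = np.arange(max(config.tlc_min, tlc_a - 150.0),
                      min(config.tlc_max, tlc_a + 150.0) + 1e-9, 10.0)
    if v0_coarse.size > 1:
        v0_b = np.arange(max(0.0, v0_a - 75.0), v0_a + 75.0 + 1e-9, 10.0)
    else:
        v0_b = v0_coarse
    _, tlc_c, v0_c, sd_inf, sd_def = _grid_stage(
        limbs, sd_grid, tlc_b, v0_b, config.objective)

    # continuous polish of (tlc, v0) at fixed SDs, then SD re-selection
    for _ in range(2):
        if v0_coarse.size > 1:
            def objective(x):
                tlc, v0 = x
                if tlc <= 0 or v0 < 0 or v0 >= 0.95 * tlc:
                    return np.inf
                return _means_at(limbs, sd_inf, sd_def, tlc, v0, config)[0]

            res = minimize(objective, x0=[tlc_c, v0_c], method="Nelder-Mead",
                           options={"xatol": 0.5, "fatol": 1e-6,
                                    "maxiter": 300})
            tlc_c, v0_c = float(res.x[0]), float(res.x[1])
        new_inf, new_def = _best_sds(limbs, tlc_c, v0_c, config)
        if (new_inf, new_def) == (sd_inf, sd_def):
            break
        sd_inf, sd_def = new_inf, new_def

    # final per-limb fits at the polished parameters
    limb_fits = []
    for kind, peep, p, v in limbs:
        sd = sd_inf if kind == "inflation" else sd_def
        lf = fit_limb_mean((p, v + v0_c), sd, tlc_c, peep=peep, config=config)
        limb_fits.append(LimbFit(
            peep=peep,
            distribution=ThresholdDistribution(
                mean=lf.distribution.mean, sd=float(sd), limb=kind),
            abs_error_ml=lf.abs_error_ml, pct_error=lf.pct_error))
    return TrialFit(trial_id=trial_id, inflation_sd=float(sd_inf),
                    deflation_sd=float(sd_def), tlc_ml=tlc_c,
                    auto_peep=float(auto_peep), baseline_ml=v0_c,
                    limb_fits=tuple(limb_fits))


# ---------------------------------------------------------------------------
# error summary

def fit_error_summary(fits: Sequence[TrialFit]) -> pd.DataFrame:
    """Median, IQR and 90% range of absolute and percentage fit errors,
    pooled over all limb fits of all trials, inflation and deflation
    separately."""
    if not fits:
        raise ValueError("at least one trial fit is required")
    rows = []
    for limb in ("inflation", "deflation"):
        ml = np.array([lf.abs_error_ml for f in fits for lf in f.limb(limb)])
        pct = np.array([lf.pct_error for f in fits for lf in f.limb(limb)])
        row = {"limb": limb}
        for name, vals in (("error_ml", ml), ("error_pct", pct)):
            row[f"{name}_median"] = float(np.median(vals))
            row[f"{name}_iqr_low"] = float(np.percentile(vals, 25))
            row[f"{name}_iqr_high"] = float(np.percentile(vals, 75))
            row[f"{name}_p05"] = float(np.percentile(vals, 5))
            row[f"{name}_p95"] = float(np.percentile(vals, 95))
        rows.append(row)
    return pd.DataFrame(rows).set_index("limb")
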