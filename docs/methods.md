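# Methods

## Recruitment model

Lung units are binary (recruited / collapsed) with normally distributed
threshold opening and closing pressures. The recruited fraction at airway
pressure p on a limb is Φ((p − μ)/σ) and lung volume is TLC·Φ. The
continuum CDF is the default; a discrete N-unit mode (units placed at
mid-probability quantiles, N = 144 000 by default so TLC = 1440 ml at
0.01 ml/unit) exists for cross-checking and differs from the continuum by
at most one unit volume. A multi-compartment variant adds fixed
superimposed-pressure offsets per compartment; the default is a single
compartment, letting the normal spread absorb the gravitational gradient,
because no per-compartment pressures are available to calibrate more.

As PEEP changes, the TOP/TCP means shift while the per-trial SDs are held
constant — one inflation SD and one deflation SD per manoeuvre. Hysteresis
(V_def ≥ V_inf at equal pressure) is not imposed; it emerges whenever
μ_TCP < μ_TOP.

## Fitting

**Objective.** Mean absolute volume error (ml) between TLC·Φ and the
measured limb volumes, reported per limb both in ml and as a percentage of
the limb's mean absolute volume. That denominator is a modelling choice —
the reference tables never define one — selected because it reproduces the
published ml-to-percent ratio pattern (percentages fall with PEEP while ml
errors stay flat, since limb volumes grow with PEEP). A least-squares
objective is available via `FitConfig(objective="lsq")`.

**Volume baseline.** Measured volume is integrated flow, referenced to the
start-of-manoeuvre ZEEP end-expiratory level; the model's volume is
absolute. The fit therefore includes a baseline offset v₀ (the unobserved
functional residual capacity at the reference point), estimated jointly
with TLC. The scaled/shifted normal-CDF family is identifiable from
multiple limbs sharing (TLC, v₀, σ): matching curvature across levels pins
all three, which the noise-free recovery tests confirm.

**Search.** Nested and fully deterministic (no seeds):

* outer coarse grid over TLC ∈ [0.5, 4] L (100-ml step) × v₀ (50-ml step),
  refined locally to the 10-ml grid, then polished continuously by
  Nelder–Mead;
* SDs on an integer grid 1–40 cmH₂O (the reference trials report integer
  SDs), re-selected after the continuous polish with one alternation pass;
* the per-limb mean is optimised exactly inside every stage using an L1
  property of the family: each point's residual is monotone in μ, so the
  optimum interpolates a data point (or sits between two); scanning the
  candidate means μᵢ = pᵢ − σ·Φ⁻¹(wᵢ/TLC) and refining between the
  bracketing candidates is therefore exact at any σ scale. A fixed μ grid
  is *not* used because its misalignment error grows as σ shrinks, which
  systematically biases a joint grid search toward large-σ solutions.
  The optimiser agrees with a 0.01-cmH₂O brute-force grid to within the
  grid step (tested).

Ties in grid searches resolve to the smallest parameter value. Loops whose
PEEP lies below the measured auto-PEEP are excluded before fitting, with
0.5 cmH₂O of slack so a level equal to a noisily estimated auto-PEEP is
kept (the reference cohort retained the level equal to auto-PEEP).

## Decision metrics

TOP rule: walk the PEEP-sorted means; stop at the level before the first
rise, where "rise" means failing to decrease by more than 0.1 cmH₂O (fit
noise band; the source states the principle without a threshold). Flat
series recommend the lowest level. TCP rule: lowest trialled p with
μ_TCP(p) ≤ p; if never reached, the maximum level is returned with a flag.
Net recruitment is evaluated at each trialled PEEP with that level's own
fitted distributions, and its argmax (ties to the lowest PEEP) is the
recommendation, flagged invalid if TOP rises at or below it. All
recommendations snap to trialled levels (the published selections are all
trialled levels, including off-grid pressure-capped tops such as 27 and
29); no interpolation is offered by default.

Recruitability classes come from the signs of the OLS slopes of mean vs
PEEP (flat band |slope| < 0.05), e.g. `TOP-down/TCP-up`. Disease
trajectories report, per trial, the unweighted PEEP-average of the TOP
means, the inflation SD and both gradients; consecutive-trial changes
within 5 % of the preceding value are labelled stable.

## Waveform processing

Waveforms are delimited text (`time_s, paw_cmH2O, flow_lps`; mapping
configurable). Volume is the cumulative trapezoid of flow. Breaths are
segmented at flow zero-crossings with 0.02 L/s hysteresis; breaths under
50 ml are discarded. The end-expiratory plateau pressure (last 50 ms of
each breath) labels the PEEP level: snapped to the nearest 5-cmH₂O
protocol step when within 1.5 cmH₂O, otherwise kept at the nearest integer
so pressure-capped off-grid top levels survive. One representative loop
per level averages the last 3 breaths of the plateau point-wise on a
common pressure grid; limbs are first filtered to their
pressure-monotone region, which is also exactly the
pressure-and-volume-increasing region prescribed for breaths flagged by
the pressure-drop QC check (pressure falling > 1 cmH₂O below its running
maximum for > 50 ms while flow > 0.1 L/s).

Auto-PEEP is the mean airway pressure over an end-expiratory
zero-flow hold minus set PEEP, clipped at zero. Inspiratory resistance is
(peak − plateau)/flow-at-peak around an end-inspiratory hold. Resistive
correction subtracts R·flow (signed) from every loop point, narrowing the
loop; it is the identity at R = 0 and linear in R. The end-to-end pipeline
corrects loops with the hold-estimated R before fitting; without it the
resistive term biases fitted TOP means upward by roughly R times the mean
inspiratory flow.

## Synthetic data

The generator emulates the staircase protocol: PEEP 0 → max in 5-cmH₂O
steps, ~5 volume-controlled breaths per plateau, decelerating inspiratory
flow (linear ramp to 25 % of peak — the protocol names the shape only),
fixed tidal volume (default 500 ml), peak pressure capped at 45 cmH₂O, and
end-inspiratory/end-expiratory holds at ZEEP. Within a breath, recruitment
is quasi-static along the current limb's CDF: airway pressure is the
model's inverse at the instantaneous volume plus R·flow. Expiration decays
exponentially (τ = 0.8 s over 3 s) toward the deflation-limb volume at the
effective end-expiratory pressure.

Auto-PEEP follows the flow-limitation waterfall: effective end-expiratory
alveolar pressure is max(set PEEP, intrinsic PEEP at ZEEP), and the
mean-shift schedules respond to this effective PEEP. Set points below the
intrinsic level are therefore physiologically identical — which is how the
example patient's twin reproduces its fitted levels {10, 15, 20, 25, 27}
from a 0-to-max script with intrinsic PEEP 10. The staircase truncates at
the largest integer PEEP whose predicted peak pressure stays within the
cap, yielding off-grid tops such as 27.

Internally the generator tracks lung volume as the trapezoidal integral of
its own emitted flow samples — the same quadrature the loader applies — so
the sampled record and the model are exactly consistent and no
discretisation error accumulates across the staircase; this is what makes
noise-free round-trip recovery exact up to numerics.

Defaults represent a severe-ARDS cohort: TLC 1440 ml, inflation SD 15,
deflation SD 7, linear mean schedules μ_TOP = 32.8 − 0.26·p and
μ_TCP = 10.8 + 0.46·p (least-squares representations of the example
patient's tabulated means; a tabulated schedule with end-slope
extrapolation is available and is what the twin uses), resistance
8 cmH₂O·s/L (typical tube-plus-airways; no published value), intrinsic
PEEP 3 cmH₂O (cohort median), sensor noise 0.3 cmH₂O and 0.01 L/s. The
twin overrides tidal volume to 250 ml ("500 ml or 6 ml/kg, whichever is
lower") because a 1440-ml quasi-static lung cannot admit 500 ml near the
top of the staircase. Seeds are mandatory; same seed, same record, bit for
bit.

What the generator does **not** emulate: spontaneous effort (the protocol
used muscle relaxants), cardiogenic oscillations, sensor drift,
viscoelastic/time-dependent recruitment, and the two-pathway airway
mechanism behind the pressure-drop anomaly (only its observable signature
can be injected). Passing recovery tests therefore demonstrate internal
consistency of the pipeline under the model's own assumptions, not
fidelity to any particular clinical waveform.

## Compliance analysis

Loop compliance is the least-squares slope of inflation volume vs pressure
over the central 25–75 % of the limb's volume span. The linear region is
the widest contiguous PEEP band whose compliances vary by less than 1.5×
(the published ranges motivate a tolerant band; no criterion is printed).
Normalisation scales compliance to a 1-L reference TLC
(c·1000/TLC), is exactly invertible, and reproduces all 13 published
cohort rows within 0.1 ml/cmH₂O (three rows carry apparent rounding of
their printed TLC; the exact-recompute fixtures use rows that reproduce to
printed precision). The SD–compliance relationship is fitted as
c = a·e^(b·sd) by closed-form least squares on log-compliance for
determinism; the analytic ceiling TLC/(σ√(2π)) on model compliance is
asserted in tests. SD is an indicator of compliance, not an estimate of
it.

## Problem sizes

The test suite and acceptance script run desk-scale: the synthetic twin is
one ~150-s manoeuvre at 100 Hz (~15 000 samples, 36 breaths) fitted in a
few seconds; Monte-Carlo robustness uses 100 seeds per noise level on
20-point limbs; oracle equivalence scans 20 random loops against a
6 000-point grid and one 144 000-unit enumeration.

## Known limitations

* The fitted (TLC, v₀, σ) ridge is shallow when limbs only sample
  near-linear stretches of the CDF; identification relies on levels that
  approach saturation. Very narrow staircases may return boundary values.
* Auto-PEEP is modelled (and estimated) as a single ZEEP quantity; PEEP
  dependence of intrinsic PEEP beyond the waterfall is not represented.
* The quasi-static within-breath assumption ignores time constants, so
  dynamic loops from patients with pronounced stress relaxation will fit
  with larger errors than the synthetic studies suggest.
* Population-level error statistics from the original cohort depend on
  non-public waveforms and are not reproduced here; only their ordering
  properties are tested on synthetic data.
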