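"""Bundled reference dataset: a published ARDS PEEP-titration cohort.

Fitted threshold-pressure parameters and compliance summaries for a
ten-patient pilot cohort of mechanically ventilated ALI/ARDS patients who
underwent incremental-PEEP recruitment manoeuvres (two patients repeatedly,
13 trials in all).  These printed per-trial values serve as worked-example
inputs for the decision metrics and the compliance normalisation, and as
the parameter schedule of the example-patient synthetic twin; the
underlying waveforms are not public.
"""

from __future__ import annotations

from .recruitment_model import (LimbFit, ThresholdDistribution, TrialFit)
from .synthetic_data import GroundTruth, ProtocolScript

__all__ = [
    "EXAMPLE_PATIENT",
    "COHORT_PEEP_SELECTIONS",
    "COHORT_SD_COMPLIANCE",
    "example_trial_fit",
    "example_ground_truth",
    "example_protocol",
]

# Example patient (patient 1 of the cohort): per-PEEP fitted TOP/TCP means
# with the per-limb mean-absolute fit errors, one SD per limb per trial.
EXAMPLE_PATIENT = {
    "trial_id": "example-patient",
    "n_units": 144_000,
    "unit_volume_ml": 0.01,          # TLC 1440 ml
    "inflation_sd": 15.0,
    "deflation_sd": 7.0,
    "auto_peep": 10.0,
    # peep: (mean cmH2O, error ml, error %)
    "inflation": {
        10: (30.97, 22.17, 7.86),
        15: (28.07, 22.50, 4.44),
        20: (27.12, 22.27, 3.11),
        25: (26.41, 21.71, 2.05),
        27: (26.18, 15.11, 1.34),
    },
    "deflation": {
        10: (15.57, 15.48, 4.61),
        15: (17.68, 5.61, 1.02),
        20: (19.88, 5.72, 0.63),
        25: (22.43, 7.47, 0.68),
        27: (23.39, 2.73, 0.24),
    },
    # published metric-based selections for this patient
    "selections": {"top": 27.0, "tcp": 20.0, "net": 20.0},
}

# Cohort summary: auto-PEEP, clinically selected PEEP, inflation SD and the
# three model-based PEEP selections, one row per trial.
COHORT_PEEP_SELECTIONS = {
    "patient-1": {"auto_peep": 10, "clinical": 10, "sd": 15,
                  "top": 27, "tcp": 20, "net": 20},
    "patient-2": {"auto_peep": 2, "clinical": 12, "sd": 11,
                  "top": 15, "tcp": 15, "net": 15},
    "patient-3": {"auto_peep": 0, "clinical": 10, "sd": 12,
                  "top": 10, "tcp": 15, "net": 20},
    "patient-4": {"auto_peep": 9, "clinical": 10, "sd": 25,
                  "top": 20, "tcp": 20, "net": 30},
    "patient-5-trial-1": {"auto_peep": 13, "clinical": 12, "sd": 16,
                          "top": 20, "tcp": 25, "net": 25},
    "patient-5-trial-2": {"auto_peep": 8, "clinical": 12, "sd": 15,
                          "top": 20, "tcp": 25, "net": 20},
    "patient-6-trial-1": {"auto_peep": 10, "clinical": 11, "sd": 11,
                          "top": 15, "tcp": 20, "net": 20},
    "patient-6-trial-2": {"auto_peep": 3, "clinical": 13, "sd": 14,
                          "top": 15, "tcp": 15, "net": 20},
    "patient-6-trial-3": {"auto_peep": 2, "clinical": 10, "sd": 14,
                          "top": 10, "tcp": 20, "net": 15},
    "patient-7": {"auto_peep": 2, "clinical": 7.5, "sd": 10,
                  "top": 5, "tcp": 10, "net": 10},
    "patient-8": {"auto_peep": 0, "clinical": 12, "sd": 15,
                  "top": 15, "tcp": 20, "net": 30},
    "patient-9": {"auto_peep": 12, "clinical": 10, "sd": 15,
                  "top": 25, "tcp": 20, "net": 29},
    "patient-10": {"auto_peep": 3, "clinical": 10, "sd": 16,
                   "top": 15, "tcp": 20, "net": 15},
}

# Cohort inflation SD vs linear compliance (static-curve linear portion),
# fitted TLC, and the published compliance normalised to a 1-L TLC.
COHORT_SD_COMPLIANCE = {
    "patient-1": {"sd": 15, "linear_compliance": 37.79, "tlc_ml": 1440,
                  "normalised_compliance": 26.25},
    "patient-2": {"sd": 11, "linear_compliance": 60.52, "tlc_ml": 1710,
                  "normalised_compliance": 35.40},
    "patient-3": {"sd": 12, "linear_compliance": 71.66, "tlc_ml": 2200,
                  "normalised_compliance": 32.48},
    "patient-4": {"sd": 25, "linear_compliance": 34.94, "tlc_ml": 2200,
                  "normalised_compliance": 15.88},
    "patient-5-trial-1": {"sd": 16, "linear_compliance": 48.80,
                          "tlc_ml": 1980, "normalised_compliance": 24.61},
    "patient-5-trial-2": {"sd": 15, "linear_compliance": 42.26,
                          "tlc_ml": 1610, "normalised_compliance": 26.25},
    "patient-6-trial-1": {"sd": 11, "linear_compliance": 33.92,
                          "tlc_ml": 960, "normalised_compliance": 35.36},
    "patient-6-trial-2": {"sd": 14, "linear_compliance": 47.97,
                          "tlc_ml": 1710, "normalised_compliance": 28.02},
    "patient-6-trial-3": {"sd": 14, "linear_compliance": 43.21,
                          "tlc_ml": 1540, "normalised_compliance": 28.04},
    "patient-7": {"sd": 10, "linear_compliance": 25.11, "tlc_ml": 650,
                  "normalised_compliance": 38.57},
    "patient-8": {"sd": 15, "linear_compliance": 46.20, "tlc_ml": 1760,
                  "normalised_compliance": 26.23},
    "patient-9": {"sd": 15, "linear_compliance": 49.58, "tlc_ml": 1890,
                  "normalised_compliance": 26.23},
    "patient-10": {"sd": 16, "linear_compliance": 36.17, "tlc_ml": 1470,
                   "normalised_compliance": 24.60},
}


def example_trial_fit() -> TrialFit:
    """The example patient's fitted manoeuvre as a :class:`TrialFit`."""
    d = EXAMPLE_PATIENT
    fits = []
    for limb, sd in (("inflation", d["inflation_sd"]),
                     ("deflation", d["deflation_sd"])):
        for peep, (mean, err_ml, err_pct) in sorted(d[limb].items()):
            fits.append(LimbFit(
                peep=float(peep),
                distribution=ThresholdDistribution(mean=mean, sd=sd,
                                                   limb=limb),
                abs_error_ml=err_ml, pct_error=err_pct))
    return TrialFit(
        trial_id=d["trial_id"],
        inflation_sd=d["inflation_sd"], deflation_sd=d["deflation_sd"],
        tlc_ml=d["n_units"] * d["unit_volume_ml"],
        auto_peep=d["auto_peep"], limb_fits=tuple(fits))


def example_ground_truth(seed: int = 0, noise: bool = False) -> GroundTruth:
    """Synthetic twin of the example patient.

    Tabulated mean schedules (the published per-PEEP fitted means), TLC
    1440 ml, SDs 15/7, intrinsic PEEP 10 cmH2O.  Noise-free by default so
    that round-trip recovery is exact up to numerics.
    """
    d = EXAMPLE_PATIENT
    return GroundTruth(
        seed=seed,
        tlc_ml=d["n_units"] * d["unit_volume_ml"],
        inflation_sd=d["inflation_sd"], deflation_sd=d["deflation_sd"],
        top_schedule=tuple((float(p), m)
                           for p, (m, _, _) in sorted(d["inflation"].items())),
        tcp_schedule=tuple((float(p), m)
                           for p, (m, _, _) in sorted(d["deflation"].items())),
        resistance=8.0,
        auto_peep=d["auto_peep"],
        noise_sd_pressure=0.3 if noise else 0.0,
        noise_sd_flow=0.01 if noise else 0.0)


def example_protocol() -> ProtocolScript:
    """Staircase protocol for the example-patient twin.

    Tidal volume 250 ml ("500 ml or 6 ml/kg, whichever is lower" — this is
    a small, severely restricted lung with a 1440-ml model TLC, which
    cannot admit 500 ml near the top of the staircase); 5-cmH2O steps with
    the 45-cmH2O peak-pressure cap, which truncates the staircase at the
    off-grid top level this patient actually reached.
    """
    return ProtocolScript(tidal_volume_ml=250.0)
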