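"""Shared fixtures: synthetic manoeuvres and their fitted results.

The example-patient twin (a noise-free synthetic manoeuvre generated from
the bundled reference parameters) is expensive to fit, so it is built once
per session and shared by the waveform, model and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from peepopt import (reference, recruitment_model, synthetic_data,
                     waveform_io)


@pytest.fixture(scope="session")
def twin_manoeuvre():
    """Noise-free synthetic twin of the example patient."""
    truth = reference.example_ground_truth(seed=0)
    return synthetic_data.generate_manoeuvre(truth,
                                             reference.example_protocol())


@pytest.fixture(scope="session")
def twin_pipeline(twin_manoeuvre):
    """The twin pushed through the full measurement pipeline: segmentation,
    hold estimates, loop extraction, resistive correction and the trial
    fit.  Returns a dict of every intermediate artifact."""
    man = twin_manoeuvre
    segments = waveform_io.segment_breaths(man.record)
    resistance = waveform_io.estimate_resistance(
        man.record, man.hold_windows["end_insp"])
    auto_peep = waveform_io.estimate_auto_peep(
        man.record, man.hold_windows["end_exp"],
        set_peep=man.set_peep_levels[0])
    raw_loops = waveform_io.extract_pv_loops(man.record, segments)
    loops = [waveform_io.correct_resistive_pressure(l, resistance)
             for l in raw_loops]
    trial = recruitment_model.fit_trial(loops, auto_peep, trial_id="twin")
    return {"manoeuvre": man, "segments": segments,
            "resistance": resistance, "auto_peep": auto_peep,
            "raw_loops": raw_loops, "loops": loops, "trial": trial}


@pytest.fixture(scope="session")
def plain_manoeuvre():
    """A clean six-level staircase with no auto-PEEP, no resistance and no
    noise: 5 breaths per step at PEEP 0..25, no holds."""
    truth = synthetic_data.GroundTruth(
        seed=11, auto_peep=0.0, resistance=0.0,
        noise_sd_pressure=0.0, noise_sd_flow=0.0)
    script = synthetic_data.ProtocolScript(
        peep_steps=(0, 5, 10, 15, 20, 25), tidal_volume_ml=300.0,
        include_holds=False)
    return synthetic_data.generate_manoeuvre(truth, script)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
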