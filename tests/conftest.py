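import dataclasses

import pytest

from thermoleaf.geometry import measure_angles
from thermoleaf.synthetic import ScenarioConfig, generate_sequence
from thermoleaf.thermometry import build_time_series, extract_readings


@pytest.fixture(scope="session")
def noiseless_scenario():
    return dataclasses.replace(ScenarioConfig(), noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_run(noiseless_scenario):
    """Default 5-day scenario at zero noise, run through extraction and
    angle measurement; the shared oracle for pipeline-level checks."""
    sequence, truth = generate_sequence(noiseless_scenario)
    readings = extract_readings(sequence)
    angles = measure_angles(sequence, readings[["time_min", "air_temp"]])
    series = build_time_series(
        readings, angles,
        treatments={r.name: r.treatment for r in sequence.plant_rois()},
        sequence=sequence)
    return {
        "config": noiseless_scenario,
        "sequence": sequence,
        "truth": truth,
        "readings": readings,
        "angles": angles,
        "series": series,
    }
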