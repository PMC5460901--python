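import numpy as np
import pandas as pd
import pytest

import rtpscreen as rts


@pytest.fixture(scope="session")
def zero_noise_screen():
    """Default desk-scale screen with all noise switched off, plus truth."""
    measurements, layout, truth = rts.generate_screen(
        seed=11, noise=rts.NoiseModel(firefly_cv=0.0, renilla_cv=0.0)
    )
    return measurements, layout, truth


@pytest.fixture(scope="session")
def zero_noise_result(zero_noise_screen):
    measurements, layout, _ = zero_noise_screen
    return rts.analyze_screen(
        measurements, layout, rts.PipelineConfig(seed=11), run_dependence=False
    )


@pytest.fixture()
def tiny_tables():
    """Hand-sized measurement + layout tables (one plate, 6 wells)."""
    measurements = pd.DataFrame(
        {
            "plate_id": ["P1"] * 6,
            "well_id": ["A01", "A02", "A03", "A04", "A05", "A06"],
            "firefly": [200.0, 500.0, 800.0, 200.0, 500.0, 800.0],
            "renilla": [1000.0] * 6,
        }
    )
    layout = pd.DataFrame(
        {
            "plate_id": ["P1"] * 6,
            "well_id": ["A01", "A02", "A03", "A04", "A05", "A06"],
            "or_name": ["OR1"] * 6,
            "rtp_condition": ["RTP1S"] * 6,
            "odorant": ["vehicle", "odorA", "odorA", "vehicle", "odorA", "odorA"],
            "concentration_uM": [0.0, 10.0, 100.0, 0.0, 10.0, 100.0],
        }
    )
    return measurements, layout


def make_summary_row(mean, sem, n):
    return pd.Series({"mean": mean, "sem": sem, "n_replicates": n})


@pytest.fixture()
def summary_row_factory():
    return make_summary_row
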