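import numpy as np
import pandas as pd
import pytest

import myothermo as mt


@pytest.fixture(scope="session")
def cfg():
    return mt.RunConfig(seed=1)


@pytest.fixture()
def two_sample_cohort(tmp_path):
    """Well-formed two-sample cohort written to CSV files."""
    samples = pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "group": ["caesarean", "hysterectomy"],
        "temperature_K": [302.15, 302.15],
        "cross_section_mm2": [1.1, 0.9],
        "Lo_mm": [5.0, 4.5],
        "TT_mN_per_mm2": [28.3, 20.5],
        "MC_nmol_per_g": [2.2, 2.7],
        "contracted_spontaneously": [True, True],
    })
    rows = []
    for sid, TT, vmax, G in [("s1", 28.3, 0.034, 2.14), ("s2", 20.5, 0.013, 0.85)]:
        load, vel = mt.hyperbola_points(vmax, G, TT, [0, 0.2, 0.4, 0.6, 0.8])
        for l, v in zip(load, vel):
            rows.append({"sample_id": sid, "load_mN_per_mm2": l,
                         "velocity_Lo_per_s": v})
    points = pd.DataFrame(rows)
    sp, pp = tmp_path / "samples.csv", tmp_path / "points.csv"
    samples.to_csv(sp, index=False)
    points.to_csv(pp, index=False)
    return sp, pp, samples, points
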