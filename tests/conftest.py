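import numpy as np
import pandas as pd
import pytest

from meth3dlink.io_formats import BetaMatrix, SampleMeta
from meth3dlink.synthetic_data import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic study shared by read-only tests."""
    return generate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate_dataset(SimConfig(seed=0, beta_noise_sd=0.0, expr_noise_sd=0.0))


def make_beta_matrix(rows: dict[str, dict[int, list[float]]]) -> BetaMatrix:
    """Build a small transdiff-only BetaMatrix from {probe: {timepoint: reps}}.

    All probes must share the same timepoint/replicate layout.
    """
    layout = next(iter(rows.values()))
    samples = []
    columns: dict[str, list[float]] = {}
    for t, reps in layout.items():
        for r in range(1, len(reps) + 1):
            sid = f"t{t:03d}_r{r}"
            samples.append(SampleMeta(sid, t, r, "transdiff"))
            columns[sid] = [rows[p][t][r - 1] for p in rows]
    values = pd.DataFrame(columns, index=pd.Index(list(rows), name="probe_id"))
    return BetaMatrix(values, samples)
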