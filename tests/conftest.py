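import numpy as np
import pandas as pd
import pytest

from radioshift.matrix import ExpressionMatrix


def make_matrix(values, groups, timepoints, scale="raw", probe_prefix="p"):
    """Build an ExpressionMatrix from a 2-D array and per-array labels."""
    values = np.asarray(values, dtype=float)
    n_probes, n_arrays = values.shape
    probes = [f"{probe_prefix}{i}" for i in range(n_probes)]
    arrays = [f"a{j}" for j in range(n_arrays)]
    ann = pd.DataFrame({"group": groups, "timepoint": timepoints,
                        "replicate": list(range(1, n_arrays + 1))}, index=arrays)
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=arrays), ann, scale)


@pytest.fixture
def two_group_ratio_matrix():
    """4 arrays (2 control, 2 treated) at one timepoint, control_ratio scale."""
    rng = np.random.default_rng(7)
    vals = rng.lognormal(0, 0.1, size=(20, 4))
    return make_matrix(vals, ["ctrl", "ctrl", "trt", "trt"], ["18w"] * 4,
                       scale="control_ratio")
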