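import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


def make_plateset(
    log2_values: np.ndarray,
    condition: str = "uninduced",
    plate: str = "P01",
    control_columns=(1, 2, 23, 24),
    control_log2: float = 10.0,
):
    """Build a single 16x24 PlateSet from a (16, 24) array of log2 sample values.

    Columns in ``control_columns`` become control wells at ``control_log2``;
    NaN entries become empty wells.
    """
    from wntpipe.screen import PlateSet

    records = []
    for row in range(1, 17):
        for col in range(1, 25):
            if col in control_columns:
                records.append(
                    (plate, row, col, "CTRL", "control", condition,
                     2.0**control_log2)
                )
                continue
            v = log2_values[row - 1, col - 1]
            if np.isnan(v):
                records.append((plate, row, col, "", "empty", condition, np.nan))
            else:
                records.append(
                    (plate, row, col, f"G_r{row}c{col}", "sample", condition,
                     2.0**v)
                )
    return PlateSet(
        wells=pd.DataFrame(
            records,
            columns=["plate", "row", "col", "gene", "well_type", "condition",
                     "signal"],
        )
    )


@pytest.fixture
def small_network():
    """Three regulators with disjoint signed target pools."""
    from wntpipe.itr import RegulatorNetwork

    rows = []
    for r, reg in enumerate(["CTNNB1", "WNT3A", "REGX"]):
        for t in range(8):
            rows.append((reg, f"{reg}_T{t}", 1.0 if t % 2 == 0 else -1.0, 1.0))
    return RegulatorNetwork(
        edges=pd.DataFrame(rows, columns=["regulator", "target", "sign", "weight"])
    )


@pytest.fixture
def toy_signature():
    from wntpipe.signature import Signature

    genes = pd.DataFrame(
        {
            "gene": [f"SIG{i:03d}" for i in range(20)],
            "direction": [1 if i % 2 == 0 else -1 for i in range(20)],
            "support": 2,
        }
    )
    return Signature(regulator="CTNNB1", genes=genes)
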