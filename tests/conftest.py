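import pandas as pd
import pytest

from moringa_qc import load_fixture


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1_regressions")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_validation")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3_quant")


@pytest.fixture()
def replicate_csv(tmp_path):
    """Well-formed 7-replicate tidy calibration file for one solvent curve."""
    rows = []
    for level in (1, 2, 3, 5, 7, 9, 10):
        for rep in range(1, 8):
            rows.append({"compound": 1, "medium": "solvent", "level": level,
                         "replicate": rep, "day": 1, "response": 5.6426 * level + 0.1675})
    path = tmp_path / "replicates.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
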