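import numpy as np
import pandas as pd
import pytest

from earnorm import CqTable, ReplicateDesign, SimulationConfig


@pytest.fixture
def six_rep_csv(tmp_path):
    """One sample, one gene, the standard 2 RT x 3 PCR design (6 rows)."""
    path = tmp_path / "cq.csv"
    rows = ["sample,gene,rt_rep,pcr_rep,cq"]
    for rt in (1, 2):
        for pcr in (1, 2, 3):
            rows.append(f"s1,g1,{rt},{pcr},{20 + 0.1 * pcr}")
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def small_table():
    """Two samples x two genes, constant Cq per pair, 2x3 design."""
    rows = []
    cq = {("s1", "g1"): 20.0, ("s1", "g2"): 22.0,
          ("s2", "g1"): 21.0, ("s2", "g2"): 22.0}
    for (s, g), c in cq.items():
        for rt in (1, 2):
            for pcr in (1, 2, 3):
                rows.append({"sample": s, "gene": g, "rt_rep": rt,
                             "pcr_rep": pcr, "cq": c})
    return CqTable(pd.DataFrame(rows), ReplicateDesign(2, 3))


@pytest.fixture
def default_config():
    return SimulationConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
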