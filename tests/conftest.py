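import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from nfiomics.io_formats import ControlLibrary, RunRecord, RunTable


@pytest.fixture
def small_run_table() -> RunTable:
    """Two baits x two replicates plus two control runs, three preys."""
    runs = [
        RunRecord("A_r1", "BAITA", "BIOID", 3.0, "HEK293", 1),
        RunRecord("A_r2", "BAITA", "BIOID", 3.0, "HEK293", 2),
        RunRecord("B_r1", "BAITB", "BIOID", 3.0, "HEK293", 1),
        RunRecord("B_r2", "BAITB", "BIOID", 3.0, "HEK293", 2),
        RunRecord("C_r1", "GFP", "BIOID", 3.0, "HEK293", 1, is_control=True),
        RunRecord("C_r2", "GFP", "BIOID", 3.0, "HEK293", 2, is_control=True),
    ]
    counts = {
        ("A_r1", "P1"): 20, ("A_r2", "P1"): 25,
        ("A_r1", "P2"): 2, ("A_r2", "P2"): 1,
        ("B_r1", "P1"): 18, ("B_r2", "P1"): 22,
        ("B_r1", "P3"): 7, ("B_r2", "P3"): 9,
        ("C_r1", "P2"): 3, ("C_r2", "P2"): 1,
    }
    return RunTable(runs=runs, counts=counts)


@pytest.fixture
def small_control_library() -> ControlLibrary:
    return ControlLibrary(
        n_control_runs=6,
        detection_frequency={"P2": 0.5, "CONTAM": 0.5},
        mean_count={"P2": 0.667, "CONTAM": 3.0},
    )
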