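import numpy as np
import pandas as pd
import pytest

from uvep.matrix import RUN_COLUMNS, RunTable, SpcMatrix


def make_run_table(run_values: dict[str, dict[str, float]],
                   meta: dict[str, tuple[str, int]]) -> RunTable:
    """Build a RunTable from {run_id: {accession: spc}} and run metadata."""
    rows = []
    for run_id, prot in run_values.items():
        sid, rep = meta[run_id]
        for acc, spc in prot.items():
            rows.append((run_id, sid, rep, acc, None, float(spc)))
    return RunTable(records=pd.DataFrame(rows, columns=RUN_COLUMNS))


def make_subject_matrix(data: dict[str, list[float]], proteins: list[str]) -> SpcMatrix:
    """Subject-level aSpC matrix from {subject: column values}."""
    return SpcMatrix(
        values=pd.DataFrame(data, index=proteins, dtype=float),
        level="subject",
    )


@pytest.fixture
def two_subject_runs() -> RunTable:
    """Two subjects x two replicates over three proteins."""
    return make_run_table(
        {
            "r1a": {"P1": 4, "P2": 10},
            "r1b": {"P1": 6, "P2": 12, "P3": 2},
            "r2a": {"P2": 8, "P3": 5},
            "r2b": {"P2": 6, "P3": 7},
        },
        {"r1a": ("s1", 1), "r1b": ("s1", 2), "r2a": ("s2", 1), "r2b": ("s2", 2)},
    )


@pytest.fixture
def three_group_matrix() -> tuple[SpcMatrix, dict[str, str]]:
    """Nine subjects in three groups; first protein separates the groups."""
    rng = np.random.default_rng(11)
    subjects = [f"s{i}" for i in range(1, 10)]
    groups = {s: "ABC"[(i - 1) // 3] for i, s in enumerate(subjects, 1)}
    base = {
        "s1": 1, "s2": 2, "s3": 3,
        "s4": 4, "s5": 5, "s6": 6,
        "s7": 7, "s8": 8, "s9": 9,
    }
    data = {s: [base[s], *(rng.poisson(5, 4) + 1.0)] for s in subjects}
    return make_subject_matrix(data, ["Pdisc", "Pa", "Pb", "Pc", "Pd"]), groups
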