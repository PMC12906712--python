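import numpy as np
import pandas as pd
import pytest

from diadetect.diann_io import DIANN_DIALECT
from diadetect.simulate import SyntheticConfig, generate_report, write_bundle


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic bundle shared across tests (seed fixed)."""
    return generate_report(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def bundle_paths(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    return write_bundle(bundle, out)


@pytest.fixture
def meta45():
    rows = [("D1", "a1", "Dep", "F"), ("D2", "a2", "Dep", "M"),
            ("D3", "a3", "Dep", "F"), ("D4", "a4", "Dep", "M"),
            ("N1", "a5", "NonDep", "F"), ("N2", "a6", "NonDep", "M"),
            ("N3", "a7", "NonDep", "F"), ("N4", "a8", "NonDep", "M"),
            ("N5", "a9", "NonDep", "F")]
    return pd.DataFrame(rows, columns=["run_id", "animal_id", "group", "sex"])


def make_records(rows):
    """Canonical record frame from (run, protein, precursor, quantity) tuples,
    with clean q-values."""
    data = []
    for run, protein, precursor, quantity in rows:
        data.append({
            "run_id": run, "protein_group": protein, "genes": "",
            "precursor_id": f"{precursor}2", "modified_sequence": precursor,
            "charge": 2, "q_value": 0.001, "pg_q_value": 0.001,
            "global_q_value": 0.001, "global_pg_q_value": 0.001,
            "quantity": quantity,
        })
    return pd.DataFrame(data)


def write_tsv_report(path, rows):
    """Write a DIA-NN dialect TSV from dicts of canonical fields (raw strings allowed)."""
    defaults = {
        "run_id": "D1", "protein_group": "P1", "genes": "G1",
        "precursor_id": "PEPTIDEK2", "modified_sequence": "PEPTIDEK", "charge": "2",
        "q_value": "0.001", "pg_q_value": "0.001", "global_q_value": "0.001",
        "global_pg_q_value": "0.001", "quantity": "1000",
    }
    header = [DIANN_DIALECT[c] for c in defaults]
    lines = ["\t".join(header)]
    for row in rows:
        merged = {**defaults, **row}
        lines.append("\t".join(str(merged[c]) for c in defaults))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
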