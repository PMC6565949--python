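"""Shared fixtures: printed reference tables and seeded synthetic data.

The TSVs under ``tests/data`` are the published group-mean/adjusted-p tables
and the hub-degree table of the murine CD4+ T-cell acute-asthma profiling
experiment this pipeline re-implements; a printed ``<0.0001`` is parsed as
its bound 0.0001.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import lncnet as L

DATA = Path(__file__).parent / "data"


def parse_p(token: str) -> float:
    token = str(token).strip()
    return float(token[1:]) if token.startswith("<") else float(token)


def de_records_from_printed(path: Path) -> pd.DataFrame:
    """Printed group means + p into a DE-record-shaped table.

    The printed p is treated as the adjusted p; ratio/sign/direction are
    recomputed from the printed means exactly as the pipeline defines them.
    """
    raw = pd.read_csv(path, sep="\t")
    mc = raw["control"].astype(float).to_numpy()
    ma = raw["asthma"].astype(float).to_numpy()
    p = raw["p_value"].map(parse_p).to_numpy()
    hi, lo = np.maximum(mc, ma), np.minimum(mc, ma)
    ratio = np.where(lo > 0, hi / lo, np.inf)
    return pd.DataFrame(
        {
            "transcript_id": raw["transcript_id"],
            "mean_control": mc,
            "mean_case": ma,
            "ratio": ratio,
            "ratio_capped": ~np.isfinite(ratio),
            "signed_fc": np.where(ma >= mc, ratio, -ratio),
            "log2fc": np.log2((ma + 1.0) / (mc + 1.0)),
            "p_raw": p,
            "p_adj": p,
            "direction": np.where(ma > mc, "up", "down"),
            "passes_filter": (ratio >= 2.0) & (p < 0.05),
        }
    )


@pytest.fixture(scope="session")
def printed_lncrna_table() -> pd.DataFrame:
    return de_records_from_printed(DATA / "top20_lncrna.tsv")


@pytest.fixture(scope="session")
def printed_mrna_table() -> pd.DataFrame:
    return de_records_from_printed(DATA / "top20_mrna.tsv")


@pytest.fixture(scope="session")
def printed_degree_table() -> pd.DataFrame:
    nodes = pd.read_csv(DATA / "lncrna_degrees.tsv", sep="\t")
    nodes["role"] = "lncRNA"
    return nodes[["id", "role", "direction", "degree"]]


@pytest.fixture(scope="session")
def default_fixture():
    """One seeded default synthetic experiment shared across tests."""
    config = L.SimulationConfig(seed=11)
    counts, annotation, truth = L.simulate_fixture(config)
    return config, counts, annotation, truth


@pytest.fixture(scope="session")
def default_groups(default_fixture):
    _, counts, _, _ = default_fixture
    return {s: ("control" if s.startswith("ctrl") else "case") for s in counts.columns}
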