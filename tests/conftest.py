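import numpy as np
import pandas as pd
import pytest

from chdpath import simulate
from chdpath.connectome import PpiGraph
from chdpath.io import DNV_COLUMNS


@pytest.fixture(scope="session")
def sim_config():
    return simulate.SimConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(sim_config):
    """One default synthetic cohort shared across the suite."""
    dnvs, annotations, truth = simulate.generate_cohort(sim_config)
    return dnvs, annotations, truth


@pytest.fixture()
def dnv_row():
    """A single fully-passing DNV record as a keyword-overridable factory."""

    def make(**overrides):
        row = {
            "sample_id": "S1", "cohort": "case", "phenotype1": "isolated",
            "phenotype2": "CTD", "gene": "GENE1", "chrom": "1",
            "pos": 1_000_000, "ref": "A", "alt": "G",
            "mol_class": "missense", "pb_tot": 40, "pb_alt": 12,
            "f_ref": 30, "f_altratio": 0.0, "m_ref": 30, "m_altratio": 0.0,
            "cohort_af": 0.0, "cadd": 25.0, "maf_exac": np.nan,
            "maf_esp": np.nan, "maf_gnomad": np.nan, "maf_1kg": np.nan,
            "sex": "female", "blacklisted": False,
        }
        row.update(overrides)
        return row

    return make


@pytest.fixture()
def dnv_table(dnv_row):
    def make(rows):
        return pd.DataFrame(
            [dnv_row(**r) for r in rows], columns=DNV_COLUMNS + ["blacklisted"])

    return make


@pytest.fixture()
def triangle_graph():
    """A-B=1, B-C=1, A-C=3 (confidences 1, 1, 1/3)."""
    return PpiGraph.from_edges(
        [("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1 / 3)])
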