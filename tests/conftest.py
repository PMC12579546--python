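import math

import pytest

from phoszsl import synthetic
from phoszsl.dataset import (
    AssociationTable,
    Dataset,
    KinaseRecord,
    PhosphositeRecord,
)


@pytest.fixture(scope="session")
def small_bench():
    """A small synthetic benchmark shared by read-only tests."""
    spec = synthetic.SyntheticSpec(
        n_groups=3,
        kinases_per_group=4,
        dim=8,
        sites_per_kinase=synthetic.SitesPerKinase(
            mu=math.log(10), sigma=0.6, maximum=40
        ),
        seq_length=80,
        seed=11,
    )
    return synthetic.generate(spec)


@pytest.fixture
def tiny_dataset():
    """Hand-built dataset: 2 kinases, 3 sites, 4 pairs."""
    kinases = {
        "K1": KinaseRecord("K1", "ACDEFGHIKLMNPQRSTVWY", "TK", "TK_F1",
                           frozenset({"2.7.10.2"})),
        "K2": KinaseRecord("K2", "YWVTSRQPNMLKIHGFEDCA", "CMGC", "CMGC_F1"),
    }
    sites = {
        "SUB1_10": PhosphositeRecord("SUB1_10", "SUB1", 10, "S",
                                     "ACDEFGHSIKLMNPQ"),
        "SUB1_20": PhosphositeRecord("SUB1_20", "SUB1", 20, "T",
                                     "CDEFGHITKLMNPQR"),
        "SUB2_5": PhosphositeRecord("SUB2_5", "SUB2", 5, "Y",
                                    "____AGHYIKLMNPQ"),
    }
    table = AssociationTable(
        [("SUB1_10", "K1"), ("SUB1_20", "K1"), ("SUB2_5", "K2"),
         ("SUB1_10", "K2")]
    )
    ds = Dataset(kinases=kinases, sites=sites, table=table)
    ds.validate()
    return ds
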