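import numpy as np
import pytest

from mecaf.compositions import AbundanceTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def lineage_table():
    """Small count table with MetaPhlAn-style lineage strings."""
    lineages = [
        "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia;s__Blautia_obeum",
        "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia;s__Blautia_producta",
        "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Streptococcaceae;g__Streptococcus;s__Streptococcus_mitis",
        "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides;s__Bacteroides_fragilis",
        "k__Bacteria;p__Proteobacteria",
    ]
    values = np.array(
        [
            [3.0, 5.0, 2.0, 10.0, 1.0],
            [1.0, 0.0, 4.0, 6.0, 2.0],
            [2.0, 2.0, 2.0, 2.0, 2.0],
            [0.0, 1.0, 8.0, 3.0, 5.0],
        ]
    )
    return AbundanceTable(
        values,
        sample_ids=[f"S{i}" for i in range(4)],
        taxon_ids=[f"t{j}" for j in range(5)],
        lineages=lineages,
    )


@pytest.fixture
def positive_table(rng):
    """Random strictly positive abundance table with two groups."""
    values = rng.gamma(2.0, 3.0, size=(12, 7)) + 0.1
    group = np.array(["a"] * 6 + ["b"] * 6)
    return AbundanceTable(values, group=group)
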