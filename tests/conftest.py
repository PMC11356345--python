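import numpy as np
import pandas as pd
import pytest

from rarenet import AsvTable, TaxonomyMap, SampleMetadata


@pytest.fixture
def tiny_table():
    """3 ASVs x 2 samples with column sums [6, 9]."""
    counts = pd.DataFrame(
        [[5, 0], [1, 2], [0, 7]],
        index=["ASV_1", "ASV_2", "ASV_3"],
        columns=["S1", "S2"],
    )
    return AsvTable(counts)


@pytest.fixture
def small_table():
    """Random 40-taxon x 8-sample table, seeded."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 200, size=(40, 8))
    return AsvTable(
        pd.DataFrame(counts, index=[f"ASV_{i}" for i in range(40)],
                     columns=[f"S{j}" for j in range(8)])
    )


@pytest.fixture
def mini_taxonomy():
    lineages = {
        "ASV_1": "Bacteria;Proteobacteria;Gammaproteobacteria;;;Dechloromonas",
        "ASV_2": "Bacteria;Cyanobacteria;Oxyphotobacteria;Chloroplast",
        "ASV_3": "Bacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;Mitochondria",
        "ASV_4": ";;;;;;",
        "ASV_5": "Bacteria;Bacteroidetes",
    }
    return TaxonomyMap.from_lineage_strings(lineages)


@pytest.fixture
def five_asv_table():
    """5 ASVs x 3 samples matching mini_taxonomy ids."""
    rng = np.random.default_rng(7)
    counts = rng.integers(1, 50, size=(5, 3))
    return AsvTable(
        pd.DataFrame(counts, index=[f"ASV_{i}" for i in range(1, 6)],
                     columns=["S1", "S2", "S3"])
    )


@pytest.fixture
def mini_metadata():
    data = pd.DataFrame(
        {
            "SD": [1.0, 0.8, 1.5, 2.0],
            "Chl-a": [5.0, 12.0, 3.0, 8.0],
            "TP": [0.025, 0.035, 0.022, 0.030],
            "TN": [0.55, 0.65, 0.52, 0.60],
            "PI": [3.0, 4.5, 2.5, 3.8],
        },
        index=["S1", "S2", "S3", "S4"],
    )
    return SampleMetadata(data, units={"SD": "m", "Chl-a": "ug/L", "TP": "mg/L",
                                       "TN": "mg/L", "PI": "mg/L"})
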