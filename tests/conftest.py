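import numpy as np
import pandas as pd
import pytest

from metstab import METDataset, SyntheticSpec, TwoWayTable, generate_met


def make_long_frame(values, trait="yield"):
    """Build a long-format frame from a dict {(geno, loc, year): [rep values]}."""
    rows = []
    for (g, l, y), reps in values.items():
        for k, v in enumerate(reps):
            rows.append((g, l, y, k + 1, trait, float(v)))
    return pd.DataFrame(
        rows, columns=["genotype", "location", "year", "rep", "trait", "value"]
    )


def random_table(rng, g=6, e=5, r=2, mse=0.04, scale=1.0):
    """Random balanced TwoWayTable (cell means drawn directly)."""
    means = rng.normal(5.0, scale, size=(g, e))
    return TwoWayTable(
        trait="t",
        genotypes=[f"G{i}" for i in range(g)],
        environments=[f"E{j}" for j in range(e)],
        means=means,
        replicates=r,
        pooled_error_ms=mse,
    )


@pytest.fixture
def toy_222():
    """2 genotypes x 2 locations x 2 years x 2 reps with enumerated values."""
    vals = {
        ("A", "L1", "Y1"): [1.0, 3.0],
        ("A", "L1", "Y2"): [2.0, 2.0],
        ("A", "L2", "Y1"): [4.0, 6.0],
        ("A", "L2", "Y2"): [0.0, 2.0],
        ("B", "L1", "Y1"): [5.0, 5.0],
        ("B", "L1", "Y2"): [3.0, 7.0],
        ("B", "L2", "Y1"): [2.0, 4.0],
        ("B", "L2", "Y2"): [6.0, 8.0],
    }
    return METDataset.from_frame(make_long_frame(vals))


@pytest.fixture
def study_design_dataset():
    """Synthetic trial with the study's 13 x 8 x 3 balanced layout."""
    data, truth = generate_met(SyntheticSpec(seed=42))
    return data, truth


@pytest.fixture
def study_yield_stability():
    """Printed univariate stability statistics for grain yield (kg/plot):
    columns Sd, CV, bi, s2di, Bi, dji, wi for the 13 genotypes."""
    rows = [
        ("BWL6228", 1.1151, 22.1484, 0.8590, 1.0742, -0.1410, 1.1049, 6.6854),
        ("BWL6964", 1.2438, 23.5916, 1.7120, 0.4009, 0.7120, 0.4316, 4.0149),
        ("BWL7493", 1.1008, 21.2189, 1.1536, 0.7595, 0.1536, 0.7902, 4.8076),
        ("BWL7495", 0.5786, 11.9541, 0.7491, 0.0970, -0.2509, 0.1277, 0.9433),
        ("BWL7497", 1.0779, 20.1607, 1.3935, 0.4150, 0.3935, 0.4457, 3.1097),
        ("BWL7504", 1.0069, 20.0641, 1.3718, 0.2704, 0.3718, 0.3011, 2.1953),
        ("BWL7506", 1.2240, 23.8780, 1.2797, 0.9499, 0.2797, 0.9806, 6.1036),
        ("BWL7508", 0.8715, 16.6017, 1.1553, 0.2299, 0.1553, 0.2606, 1.6313),
        ("BWL7509", 0.4870, 9.2235, 0.5863, 0.0850, -0.4137, 0.1157, 1.1753),
        ("BWL7511", 0.7742, 14.8713, 1.1432, 0.0562, 0.1432, 0.0869, 0.5791),
        ("HD3086", 0.7772, 14.9953, 0.1619, 0.6618, -0.8381, 0.6925, 6.1301),
        ("PBW725", 0.9882, 17.4926, 0.8277, 0.7876, -0.1723, 0.8183, 4.9930),
        ("PBW761", 0.4629, 8.6203, 0.6070, 0.0467, -0.3930, 0.0773, 0.8983),
    ]
    return pd.DataFrame(
        rows, columns=["genotype", "sd", "cv", "bi", "s2di", "Bi", "dji", "wi"]
    ).set_index("genotype")
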