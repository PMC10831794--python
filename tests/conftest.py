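"""Shared fixtures: small synthetic studies, matrices and reference data.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

import numpy as np
import pandas as pd
import pytest

from metaline import simdata
from metaline.features import DataMatrix, Feature


def make_matrix(data: dict[str, dict[str, float]], rt: float = 1.0,
                mz_start: float = 100.0) -> DataMatrix:
    """Build a DataMatrix from {feature_label: {sample: area}} with synthetic
    m/z values; NaN cells are missing."""
    df = pd.DataFrame(data)
    feats = {}
    rename = {}
    for i, col in enumerate(df.columns):
        f = Feature(mz=mz_start + 10.0 * i, rt=rt)
        rename[col] = f.name
        feats[f.name] = f
    df = df.rename(columns=rename)
    return DataMatrix(areas=df, features=feats)


@pytest.fixture(scope="session")
def small_study():
    """6 compounds x (3 adducts + water-loss ISF), 2 groups x 3 replicates,
    zero noise: the deterministic end-to-end identification substrate."""
    compounds = simdata.default_compound_library(6)
    for i, c in enumerate(compounds):
        c.adducts = ("[M+H]+", "[M+Na]+", "[M+K]+")
        c.isf_losses = ("H2O",)
        c.group_means = {"A": 1.0, "B": 1.0 + 0.4 * (i % 3)}
    runs, gt = simdata.simulate_study(compounds, {"A": 3, "B": 3},
                                      noise_sigma=0.0, seed=11,
                                      k_isotopologues=2)
    return compounds, runs, gt


@pytest.fixture(scope="session")
def small_matrix(small_study):
    from metaline import features

    _, runs, _ = small_study
    return features.process_study(runs, {"snr_min": 3.0})


@pytest.fixture
def trp_pathway():
    """Synthetic 5-node toy map of tryptophan degradation (stand-in for a
    curated pathway collection; node ids follow the HMDB accession style)."""
    return {
        "nodes": [
            {"id": "HMDB0000929", "name": "Tryptophan", "type": "metabolite", "human": True},
            {"id": "HMDB0000684", "name": "Kynurenine", "type": "metabolite", "human": True},
            {"id": "HMDB0000472", "name": "5-Hydroxytryptophan", "type": "metabolite", "human": True},
            {"id": "ENZ_IDO1", "name": "IDO1", "type": "enzyme", "human": True},
            {"id": "HMDB0000748", "name": "Indole", "type": "metabolite", "human": True},
        ],
        "edges": [
            {"src": "HMDB0000929", "dst": "ENZ_IDO1", "relation": "substrate"},
            {"src": "ENZ_IDO1", "dst": "HMDB0000684", "relation": "product"},
            {"src": "HMDB0000929", "dst": "HMDB0000472", "relation": "reaction"},
            {"src": "HMDB0000929", "dst": "HMDB0000748", "relation": "reaction"},
        ],
    }
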