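import numpy as np
import pandas as pd
import pytest

from phosflow.tables_io import QuantTable


def make_table(values, columns, feature_ids=None, **feature_cols):
    """Build a small QuantTable from a 2-D array and canonical sample names."""
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"P{i:03d}_S{10 + i}" for i in range(values.shape[0])]
    idx = pd.Index(feature_ids, name="feature_id")
    feats = pd.DataFrame(index=idx)
    n = len(idx)
    feats["protein_id"] = feature_cols.get("protein_id", [f.split("_")[0] for f in feature_ids])
    feats["residue"] = feature_cols.get("residue", ["S"] * n)
    feats["position"] = pd.array(feature_cols.get("position", range(10, 10 + n)), dtype="Int64")
    feats["multiplicity"] = pd.array(feature_cols.get("multiplicity", [1] * n), dtype="Int64")
    feats["window"] = feature_cols.get("window", pd.NA)
    return QuantTable(pd.DataFrame(values, index=idx, columns=columns), feats)


@pytest.fixture
def mating_columns():
    """30 canonical sample names: 2 conditions x 5 times x 3 replicates."""
    return [
        f"{cond}_{t}min_R{r}"
        for r in (1, 2, 3)
        for cond in ("control", "mating")
        for t in (0, 45, 90, 135, 180)
    ]


@pytest.fixture
def small_experiment():
    """A small seeded mating-design simulation shared across tests."""
    from phosflow.synthetic_data import mating_config, simulate_experiment

    cfg = mating_config(n_sites=800, seed=42)
    proteome, phospho, truth = simulate_experiment(cfg)
    return cfg, proteome, phospho, truth
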