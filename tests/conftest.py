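import numpy as np
import pandas as pd
import pytest

import lncmeth as L


@pytest.fixture(scope="session")
def small_cohort():
    """Two-cancer cohort with planted DM/coupling/ceRNA/prognostic structure."""
    cfg = L.SimulationConfig(
        n_cancers=2,
        n_tumor=40,
        n_normal=15,
        n_lnc=80,
        n_mrna=60,
        n_mirna=100,
        planted_dm=[
            L.PlantedDM(tuple(range(4)), 0.25, "up", coupled=True),
            L.PlantedDM((10, 11), 0.3, "down", coupled=True),
        ],
        planted_cerna=[L.PlantedCeRNA(0, 30, 5, 0.6)],
        planted_prognostic=[0],
        seed=42,
    )
    return L.simulate_cohort(cfg)


@pytest.fixture()
def beta_matrix():
    """Tiny probe matrix with known zeros, 4 tumor / 3 normal samples."""
    values = pd.DataFrame(
        {
            "t1": [0.2, 0.5, 0.0, 0.9],
            "t2": [0.0, 0.5, 0.0, 0.8],
            "t3": [0.4, 0.5, 0.0, 0.7],
            "t4": [0.2, 0.5, 0.1, 0.0],
            "n1": [0.3, 0.5, 0.0, 0.6],
            "n2": [0.1, 0.5, 0.0, 0.5],
            "n3": [0.5, 0.5, 0.2, 0.4],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    groups = pd.Series(
        ["tumor"] * 4 + ["normal"] * 3, index=values.columns
    )
    return L.FeatureMatrix(values, groups, "beta")


def group_series(n_tumor: int, n_normal: int, prefix: str = "s") -> pd.Series:
    ids = [f"{prefix}{i}" for i in range(n_tumor + n_normal)]
    return pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=ids)


@pytest.fixture()
def make_expr_matrix():
    """Factory for random two-group log2-scale matrices with optional shift."""

    def _make(n_features=50, n_tumor=20, n_normal=15, shift=0.0, seed=0, scale="log2rpkm"):
        rng = np.random.default_rng(seed)
        groups = group_series(n_tumor, n_normal)
        vals = rng.normal(5.0, 1.0, size=(n_features, n_tumor + n_normal))
        vals[:, :n_tumor] += shift
        vals = np.maximum(vals, 0.0)
        df = pd.DataFrame(
            vals, index=[f"f{i}" for i in range(n_features)], columns=groups.index
        )
        return L.FeatureMatrix(df, groups, scale)

    return _make
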