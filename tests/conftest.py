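import numpy as np
import pandas as pd
import pytest

from hdmediation import (
    HaplotypeDosages,
    OmicsMatrix,
    normalize_features,
)
from hdmediation.simulate import SimulationConfig, simulate_dataset


def make_dosages(n, markers, rng, n_founders=8):
    """Random valid founder dosages for a hand-specified marker map.

    ``markers`` is a list of (chrom, pos_bp) tuples.
    """
    m = len(markers)
    a = rng.integers(n_founders, size=(n, m))
    b = rng.integers(n_founders, size=(n, m))
    dos = np.eye(n_founders)[a] + np.eye(n_founders)[b]
    marker_map = pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(m)],
            "chrom": [str(c) for c, _ in markers],
            "pos_bp": [p for _, p in markers],
        }
    )
    return HaplotypeDosages(
        individual_ids=[f"i{k}" for k in range(n)], marker_map=marker_map, dosages=dos
    )


def make_omics(X, name="omics", prefix="f", individual_ids=None):
    n, m = np.asarray(X).shape
    ids = individual_ids or [f"i{k}" for k in range(n)]
    return OmicsMatrix(
        values=pd.DataFrame(np.asarray(X, dtype=float), index=ids,
                            columns=[f"{prefix}{j}" for j in range(m)]),
        name=name,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One modest discovery-population draw shared by read-only tests."""
    cfg = SimulationConfig(
        n_individuals=100, n_markers=150, n_transcripts=120, n_core_transcripts=15,
        n_traits=6, seed=42,
    )
    dosages, expr, pheno, truth = simulate_dataset(cfg)
    return {
        "config": cfg,
        "dosages": dosages,
        "expression": expr,
        "phenotypes": pheno,
        "truth": truth,
        "expression_norm": normalize_features(expr),
        "phenotypes_norm": normalize_features(pheno),
    }
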