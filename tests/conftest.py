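import numpy as np
import pandas as pd
import pytest

from mrmed import SimulationConfig, TraitTable, simulate_triplet
from mrmed.instruments import HarmonizedSet


@pytest.fixture
def make_harmonized():
    """Factory building a HarmonizedSet directly from per-SNP arrays."""

    def _make(beta_exp, se_exp, beta_out, se_out, n_exp=10_000.0, n_out=10_000.0,
              snp_ids=None, pval_exp=None):
        beta_exp = np.asarray(beta_exp, dtype=float)
        m = len(beta_exp)
        table = pd.DataFrame(
            {
                "snp_id": snp_ids if snp_ids is not None else [f"rs{i:04d}" for i in range(m)],
                "chrom": "1",
                "pos": np.arange(m) * 10_000_000 + 1,
                "beta_exp": beta_exp,
                "se_exp": np.broadcast_to(np.asarray(se_exp, dtype=float), (m,)).copy(),
                "pval_exp": pval_exp if pval_exp is not None else np.full(m, 1e-8),
                "beta_out": np.asarray(beta_out, dtype=float),
                "se_out": np.broadcast_to(np.asarray(se_out, dtype=float), (m,)).copy(),
                "n_exp": float(n_exp),
                "n_out": float(n_out),
                "flipped": False,
            }
        )
        return HarmonizedSet(exposure_id="exp", outcome_id="out", table=table)

    return _make


@pytest.fixture
def make_trait():
    """Factory for a small validated TraitTable from keyword columns."""

    def _make(trait_id="t", trait_type="exposure", **cols):
        n_rows = len(next(iter(cols.values()))) if cols else 1
        base = {
            "snp_id": [f"rs{i}" for i in range(n_rows)],
            "chrom": ["1"] * n_rows,
            "pos": list(range(1, n_rows + 1)),
            "effect_allele": ["A"] * n_rows,
            "other_allele": ["G"] * n_rows,
            "eaf": [0.3] * n_rows,
            "beta": [0.1] * n_rows,
            "se": [0.01] * n_rows,
            "pval": [1e-8] * n_rows,
            "n": [10_000] * n_rows,
        }
        base.update(cols)
        return TraitTable(trait_id=trait_id, trait_type=trait_type,
                          records=pd.DataFrame(base))

    return _make


@pytest.fixture(scope="session")
def default_triplet():
    """One study-scale triplet shared across read-only tests."""
    cfg = SimulationConfig(seed=7)
    return simulate_triplet(cfg)
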