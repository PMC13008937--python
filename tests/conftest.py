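import numpy as np
import pandas as pd
import pytest

from mrmediation.gwas_data import SummaryStats
from mrmediation.instruments import HarmonizedSet


def make_stats(
    trait_id="trait",
    trait_type="continuous",
    rsids=None,
    betas=None,
    ses=None,
    pvals=None,
    eafs=None,
    chroms=None,
    poss=None,
    effect=None,
    other=None,
    n=10_000,
    n_cases=None,
    n_controls=None,
):
    """Hand-build a small SummaryStats from parallel lists."""
    m = len(betas)
    rsids = rsids or [f"rs{i:03d}" for i in range(m)]
    table = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": chroms or ["1"] * m,
            "pos": poss or [1_000_000 * (i + 1) for i in range(m)],
            "effect_allele": effect or ["A"] * m,
            "other_allele": other or ["G"] * m,
            "eaf": eafs if eafs is not None else [0.3] * m,
            "beta": betas,
            "se": ses,
            "pval": pvals if pvals is not None else [0.5] * m,
            "n": n,
        }
    )
    if n_cases is not None:
        table["n_cases"] = n_cases
        table["n_controls"] = n_controls
    return SummaryStats(trait_id, trait_type, table)


def make_hset(beta_exp, se_exp, beta_out, se_out, rsids=None, eaf=0.3):
    """Hand-build a HarmonizedSet from effect arrays."""
    m = len(beta_exp)
    rsids = rsids or [f"rs{i:03d}" for i in range(m)]
    table = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": ["1"] * m,
            "pos": np.arange(m) * 1_000_000 + 1,
            "beta_exp": np.asarray(beta_exp, float),
            "se_exp": np.asarray(se_exp, float),
            "beta_out": np.asarray(beta_out, float),
            "se_out": np.asarray(se_out, float),
            "eaf": eaf,
            "flipped": False,
        }
    )
    return HarmonizedSet("exposure", "outcome", table)


@pytest.fixture
def hset_five():
    """Five instruments with heterogeneous effects and weights."""
    return make_hset(
        beta_exp=[0.20, 0.15, 0.30, 0.25, 0.10],
        se_exp=[0.02, 0.02, 0.03, 0.02, 0.01],
        beta_out=[0.06, 0.05, 0.08, 0.09, 0.02],
        se_out=[0.010, 0.015, 0.020, 0.012, 0.008],
    )
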