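import numpy as np
import pandas as pd
import pytest

from mrscreen.sumstats import AssociationTable, HarmonizedSet


def make_table(rows, **kwargs) -> AssociationTable:
    """Build an AssociationTable from a list of row dicts with defaults."""
    defaults = {
        "chrom": "1", "pos": 1000, "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": 0.1, "se": 0.05, "pvalue": 0.05, "n": 10_000,
    }
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.setdefault("snp", f"rs{i + 1}")
        rec.update(row)
        records.append(rec)
    from mrscreen.sumstats import CANONICAL_COLUMNS
    df = pd.DataFrame.from_records(records)[CANONICAL_COLUMNS]
    return AssociationTable(df, **kwargs)


def make_hset(j=5, seed=0, beta_exp=None, beta_out=None, se_exp=None,
              se_out=None) -> HarmonizedSet:
    """Random (or partially fixed) harmonized instrument set."""
    rng = np.random.default_rng(seed)
    if beta_exp is None:
        beta_exp = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
    beta_exp = np.asarray(beta_exp, dtype=float)
    j = beta_exp.size
    if se_exp is None:
        se_exp = rng.uniform(0.005, 0.02, j)
    if se_out is None:
        se_out = rng.uniform(0.01, 0.05, j)
    if beta_out is None:
        beta_out = 0.2 * beta_exp + rng.normal(0, se_out)
    return HarmonizedSet([f"rs{i + 1}" for i in range(j)], beta_exp,
                         np.asarray(se_exp, float), np.asarray(beta_out, float),
                         np.asarray(se_out, float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
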