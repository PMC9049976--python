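import numpy as np
import pandas as pd
import pytest

from clockmr.sumstats import SummaryDataset


def make_dataset(rows, trait_name="trait", trait_type="continuous"):
    """Build a SummaryDataset from a list of dicts with minimal typing."""
    return SummaryDataset(trait_name, trait_type, pd.DataFrame(rows))


def random_dataset(rng, n=20, trait_name="trait", trait_type="continuous",
                   alleles=("A", "G"), n_samples=10_000):
    """A random but valid summary dataset with non-palindromic alleles."""
    eaf = rng.uniform(0.05, 0.95, n)
    beta = rng.normal(0, 0.05, n)
    se = rng.uniform(0.005, 0.02, n)
    p = 2 * (1 - _norm_cdf(np.abs(beta / se)))
    return make_dataset([
        {"rsid": f"rs{i}", "effect_allele": alleles[0], "other_allele": alleles[1],
         "eaf": eaf[i], "beta": beta[i], "se": se[i],
         "pvalue": max(p[i], 1e-300), "n": n_samples}
        for i in range(n)
    ], trait_name=trait_name, trait_type=trait_type)


def _norm_cdf(x):
    from scipy.stats import norm
    return norm.cdf(x)


def instrument_frame(gamma, Gamma, se_Gamma, se_gamma=None, **extra):
    """A bare harmonised-instrument table for the estimators."""
    gamma = np.asarray(gamma, float)
    df = pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(len(gamma))],
        "gamma": gamma,
        "se_gamma": se_gamma if se_gamma is not None else np.full(len(gamma), 1e-6),
        "Gamma": np.asarray(Gamma, float),
        "se_Gamma": np.asarray(se_Gamma, float),
    })
    for k, v in extra.items():
        df[k] = v
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)
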