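import numpy as np
import pandas as pd
import pytest

from mrtri import HarmonizedSet, LDLookup, SimConfig, harmonize, simulate_sumstats


def make_table(snps, trait="x", trait_type="continuous", **cols):
    """Minimal native-dialect table from parallel lists."""
    k = len(snps)
    base = {
        "SNP": snps,
        "CHR": cols.get("chrom", ["1"] * k),
        "BP": cols.get("pos", list(range(1_000_000, 1_000_000 + k))),
        "EA": cols.get("ea", ["A"] * k),
        "OA": cols.get("oa", ["G"] * k),
        "EAF": cols.get("eaf", [0.3] * k),
        "BETA": cols.get("beta", [0.1] * k),
        "SE": cols.get("se", [0.01] * k),
        "P": cols.get("p", [1e-10] * k),
        "N": cols.get("n", [100_000] * k),
        "TRAIT": trait,
        "TRAIT_TYPE": trait_type,
    }
    return pd.DataFrame(base)


def make_hset(gamma, gamma_se, Gamma, Gamma_se, outcome_type="continuous",
              exposure_names=None):
    """HarmonizedSet straight from effect arrays (single or multi exposure)."""
    gamma = np.atleast_2d(np.asarray(gamma, float))
    if gamma.shape[0] == 1 and len(np.asarray(Gamma).ravel()) > 1:
        gamma = gamma.T
    gamma_se = np.asarray(gamma_se, float)
    if gamma_se.ndim == 0:
        gamma_se = np.full(gamma.shape, float(gamma_se))
    else:
        gamma_se = gamma_se.reshape(gamma.shape)
    k, m = gamma.shape
    names = exposure_names or [f"x{j+1}" for j in range(m)]
    return HarmonizedSet(
        snp_ids=[f"rs{i}" for i in range(k)],
        exposure_names=list(names),
        exposure_beta=gamma, exposure_se=np.asarray(gamma_se, float),
        outcome_name="y",
        outcome_beta=np.asarray(Gamma, float),
        outcome_se=np.asarray(Gamma_se, float),
        outcome_type=outcome_type,
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Strong-instrument, no-pleiotropy two-exposure simulation + truth."""
    cfg = SimConfig(n_snps=60, causal_effects=(0.0, 0.5), seed=11)
    tables, truth = simulate_sumstats(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def clean_hset(clean_sim):
    _, tables, _ = clean_sim
    return harmonize([tables["wc"]], tables["outcome"])


@pytest.fixture(scope="session")
def clean_mv_hset(clean_sim):
    _, tables, _ = clean_sim
    return harmonize([tables["bmi"], tables["wc"]], tables["outcome"])


@pytest.fixture()
def ld_from_pairs():
    def build(pairs):
        return LDLookup(pd.DataFrame(pairs, columns=["snp_a", "snp_b", "r2"]))
    return build
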