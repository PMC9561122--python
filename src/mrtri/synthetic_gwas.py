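"""Seeded multi-trait GWAS summary-statistics generator with known truth.

Emulates the structure of the real inputs this kind of analysis consumes:
two correlated anthropometric exposures (a BMI-like and a WC-like trait
sharing genetic architecture), a continuous or binary (liability/logistic)
outcome, optional horizontal pleiotropy (balanced or directional), LD blocks,
weak instruments, and exposure/outcome sample overlap.  Every draw is
controlled by ``SimConfig.seed``; the hidden parameters are returned as a
:class:`TruthRecord` so downstream estimators can be tested for parameter
recovery.

The model works on standardized scales.  Per-allele exposure effects
``gamma`` are drawn with within-LD-block correlation and scaled so the
instruments jointly explain ``exposure_h2`` of each exposure; the second
exposure's effects are ``shared_loading`` times the first's plus an
independent component.  A SNP's true marginal outcome effect is
``sum_i beta_i * gamma_ij + alpha_j`` with ``alpha_j`` the direct
(pleiotropic) effect, present with probability ``pleiotropy_prob``.
Estimated effects are the true effects plus sampling noise with
``SE = 1/sqrt(2 * n * EAF * (1-EAF))`` on the standardized scale (binary
outcomes divide further by ``sqrt(v*(1-v))`` with ``v`` the case fraction).
Sample overlap correlates the exposure and outcome noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .sumstats import NATIVE_COLUMNS

#: individual-level logistic simulation above this n is replaced by the
#: normal approximation on the log-odds scale
LOGISTIC_SIM_MAX_N = 50_000

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class SimConfig:
    """Generator settings; the seed fully determines the output."""

    n_snps: int = 150
    n_exposure_samples: int = 460_000
    n_outcome_samples: int = 500_000
    overlap_fraction: float = 0.0
    eaf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2: tuple[float, ...] = (0.05, 0.05)
    shared_loading: float = 0.7
    causal_effects: tuple[float, ...] = (0.0, 0.5)
    pleiotropy_prob: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.1
    outcome_type: str = "continuous"
    prevalence: float | None = None
    ld_block_size: int = 1
    ld_r2_within: float = 0.0
    scramble_alleles: bool = False
    exposure_names: tuple[str, ...] = ("bmi", "wc")
    outcome_name: str = "outcome"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.exposure_h2, (int, float)):
            self.exposure_h2 = tuple([float(self.exposure_h2)]
                                     * len(self.exposure_names))
        if isinstance(self.causal_effects, (int, float)):
            self.causal_effects = (float(self.causal_effects),)
        self.exposure_h2 = tuple(self.exposure_h2)
        self.causal_effects = tuple(self.causal_effects)
        m = len(self.causal_effects)
        if len(self.exposure_names) != m:
            self.exposure_names = tuple(f"exposure{i+1}" for i in range(m)) \
                if m != len(self.exposure_names) else self.exposure_names
        if len(self.exposure_h2) != m:
            raise ValueError("exposure_h2 and causal_effects lengths differ")
        if self.n_exposure_samples <= 0 or self.n_outcome_samples <= 0:
            raise ValueError("sample sizes must be positive")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if not (0 <= self.pleiotropy_prob <= 1):
            raise ValueError("pleiotropy_prob must be in [0, 1]")
        if any(h < 0 for h in self.exposure_h2):
            raise ValueError("exposure_h2 must be >= 0")
        lo, hi = self.eaf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("eaf_range must sit inside (0, 1)")
        if not (0 <= self.ld_r2_within <= 1):
            raise ValueError("ld_r2_within must be in [0, 1]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError("outcome_type must be continuous or binary")
        if self.outcome_type == "binary":
            if self.prevalence is None or not (0 < self.prevalence < 1):
                raise ValueError("binary outcome requires prevalence in (0,1)")

    @property
    def n_exposures(self) -> int:
        return len(self.causal_effects)


@dataclass
class TruthRecord:
    """The generator's hidden parameters, for recovery tests."""

    gamma: np.ndarray            # (n_snps, m) true per-allele exposure effects
    alpha: np.ndarray            # (n_snps,) direct (pleiotropic) outcome effects
    causal_effects: np.ndarray   # (m,) true direct effects on the outcome
    invalid_snps: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)

    @property
    def marginal_outcome_effects(self) -> np.ndarray:
        return self.gamma @ self.causal_effects + self.alpha

    def to_frame(self) -> pd.DataFrame:
        d = {"SNP": self.snp_ids}
        for j in range(self.gamma.shape[1]):
            d[f"gamma{j+1}"] = self.gamma[:, j]
        d["alpha"] = self.alpha
        d["invalid"] = [s in set(self.invalid_snps) for s in self.snp_ids]
        return pd.DataFrame(d)


def _block_ids(n_snps: int, block_size: int) -> np.ndarray:
    return np.arange(n_snps) // block_size


def _correlated_draws(rng, blocks: np.ndarray, rho: float, size_extra=()):
    """Standard-normal draws with within-block correlation ``rho``."""
    n = len(blocks)
    shape = (*size_extra, n)
    e = rng.normal(size=shape)
    if rho <= 0:
        return e
    n_blocks = blocks.max() + 1
    b = rng.normal(size=(*size_extra, n_blocks))
    a = np.sqrt(rho)
    return a * b[..., blocks] + np.sqrt(1 - rho) * e


def _snp_map(n_snps: int, block_size: int):
    """Chromosome/position layout: one block per locus, 22 chromosomes.

    Within-block SNPs sit 10 kb apart (inside any clumping window); blocks on
    the same chromosome are 20 Mb apart (outside the default 10 Mb window).
    """
    blocks = _block_ids(n_snps, block_size)
    chrom = (blocks % 22) + 1
    within = np.arange(n_snps) % block_size
    pos = 1_000_000 + (blocks // 22) * 20_000_000 + within * 10_000
    return chrom.astype(str), pos.astype(int), blocks


def simulate_sumstats(config: SimConfig
                      ) -> tuple[dict[str, pd.DataFrame], TruthRecord]:
    """Generate per-trait summary-statistics tables plus the hidden truth.

    Returns a dict mapping trait id -> native-dialect DataFrame (one per
    exposure and one for the outcome) and the :class:`TruthRecord`.
    """
    rng = np.random.default_rng(config.seed)
    k, m = config.n_snps, config.n_exposures
    eaf = rng.uniform(*config.eaf_range, size=k)
    var_g = 2 * eaf * (1 - eaf)  # per-SNP genotype variance (allele count)
    chrom, pos, blocks = _snp_map(k, config.ld_block_size)
    snp_ids = [f"rs{i+1:05d}" for i in range(k)]
    rho_eff = np.sqrt(config.ld_r2_within) if config.ld_r2_within > 0 else 0.0

    # true per-allele exposure effects
    gamma = np.zeros((k, m))
    u = _correlated_draws(rng, blocks, rho_eff)
    gamma[:, 0] = _scale_to_h2(u, var_g, config.exposure_h2[0])
    for j in range(1, m):
        shared_h2 = config.shared_loading**2 * config.exposure_h2[0]
        resid_h2 = config.exposure_h2[j] - shared_h2
        if resid_h2 < 0:
            raise ValueError(
                "shared_loading^2 * h2[0] exceeds exposure_h2 of exposure "
                f"{j+1}; reduce shared_loading")
        d = _correlated_draws(rng, blocks, rho_eff)
        # orthogonalize against exposure 1 in the genotype-variance metric so
        # the variance budget h2[j] = shared + residual holds exactly
        g1 = gamma[:, 0]
        denom = np.sum(var_g * g1**2)
        if denom > 0:
            d = d - (np.sum(var_g * d * g1) / denom) * g1
        gamma[:, j] = (config.shared_loading * gamma[:, 0]
                       + _scale_to_h2(d, var_g, resid_h2))

    # direct (pleiotropic) outcome effects; "directional" means directional
    # with respect to the exposure-raising allele, so the mean is applied in
    # the orientation where the first exposure's effect is positive
    is_pleio = rng.uniform(size=k) < config.pleiotropy_prob
    orient = np.where(gamma[:, 0] < 0, -1.0, 1.0)
    alpha = np.where(is_pleio,
                     orient * rng.normal(config.pleiotropy_mean,
                                         config.pleiotropy_sd, size=k), 0.0)
    beta = np.asarray(config.causal_effects, float)
    Gamma_true = gamma @ beta + alpha

    # sampling noise, correlated within LD blocks and across overlapping samples
    se_x = 1.0 / np.sqrt(config.n_exposure_samples * var_g)
    z_x = [_correlated_draws(rng, blocks, rho_eff) for _ in range(m)]

    tables: dict[str, pd.DataFrame] = {}
    ea, oa = _alleles(rng, k)
    for j, name in enumerate(config.exposure_names):
        beta_hat = gamma[:, j] + se_x * z_x[j]
        tables[name] = _table(snp_ids, chrom, pos, ea, oa, eaf, beta_hat,
                              se_x, config.n_exposure_samples, name,
                              "continuous")

    if config.outcome_type == "continuous" or \
            config.n_outcome_samples > LOGISTIC_SIM_MAX_N:
        tables[config.outcome_name] = _outcome_approx(
            config, rng, snp_ids, chrom, pos, ea, oa, eaf, var_g,
            Gamma_true, blocks, rho_eff, z_x)
    else:
        tables[config.outcome_name] = _outcome_logistic(
            config, rng, snp_ids, chrom, pos, ea, oa, eaf, gamma, alpha)

    if config.scramble_alleles:
        for name, t in tables.items():
            flip = rng.uniform(size=k) < 0.5
            t.loc[flip, ["EA", "OA"]] = t.loc[flip, ["OA", "EA"]].values
            t.loc[flip, "BETA"] = -t.loc[flip, "BETA"]
            t.loc[flip, "EAF"] = 1 - t.loc[flip, "EAF"]

    truth = TruthRecord(
        gamma=gamma, alpha=alpha, causal_effects=beta,
        invalid_snps=[snp_ids[i] for i in np.flatnonzero(is_pleio)],
        snp_ids=snp_ids)
    return tables, truth


def _scale_to_h2(u: np.ndarray, var_g: np.ndarray, h2: float) -> np.ndarray:
    if h2 <= 0:
        return np.zeros_like(u)
    raw = np.sum(var_g * u**2)
    return u * np.sqrt(h2 / raw)


def _alleles(rng, k):
    idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in idx])
    return ea, oa


def _table(snp_ids, chrom, pos, ea, oa, eaf, beta, se, n, trait, trait_type):
    se = np.broadcast_to(se, beta.shape).astype(float)
    with np.errstate(divide="ignore"):
        p = 2 * stats.norm.sf(np.abs(beta / se))
    p = np.maximum(p, 1e-320)
    df = pd.DataFrame({
        "SNP": snp_ids, "CHR": chrom, "BP": pos, "EA": ea, "OA": oa,
        "EAF": eaf, "BETA": beta, "SE": se, "P": p,
        "N": int(n), "TRAIT": trait, "TRAIT_TYPE": trait_type,
    })
    return df[NATIVE_COLUMNS]


def _outcome_approx(config, rng, snp_ids, chrom, pos, ea, oa, eaf, var_g,
                    Gamma_true, blocks, rho_eff, z_x):
    """Normal-approximation outcome: SD scale, or log-odds for binary."""
    n_y = config.n_outcome_samples
    if config.outcome_type == "binary":
        v = config.prevalence
        se_y = 1.0 / np.sqrt(n_y * var_g * v * (1 - v))
        trait_type = "binary"
    else:
        se_y = 1.0 / np.sqrt(n_y * var_g)
        trait_type = "continuous"
    e_y = _correlated_draws(rng, blocks, rho_eff)
    if config.overlap_fraction > 0:
        rho = config.overlap_fraction
        z_y = rho * z_x[0] + np.sqrt(1 - rho**2) * e_y
    else:
        z_y = e_y
    beta_hat = Gamma_true + se_y * z_y
    return _table(snp_ids, chrom, pos, ea, oa, eaf, beta_hat, se_y,
                  n_y, config.outcome_name, trait_type)


def _outcome_logistic(config, rng, snp_ids, chrom, pos, ea, oa, eaf,
                      gamma, alpha):
    """Individual-level logistic simulation for small binary outcomes.

    Genotypes are drawn per SNP under HWE; each exposure is its genetic score
    plus environmental noise (unit total variance); disease status follows a
    logistic model whose intercept is solved to hit the target prevalence;
    per-SNP marginal log-odds effects come from single-SNP logistic fits via
    Newton iterations.
    """
    n = config.n_outcome_samples
    k, m = gamma.shape
    G = rng.binomial(2, eaf[None, :], size=(n, k)).astype(float)
    X = np.empty((n, m))
    for j in range(m):
        gscore = G @ gamma[:, j]
        env_var = max(1.0 - np.var(gscore), 1e-6)
        X[:, j] = gscore + rng.normal(0, np.sqrt(env_var), size=n)
    eta_base = X @ np.asarray(config.causal_effects) + G @ alpha

    def mean_prev(b0):
        return special.expit(b0 + eta_base).mean() - config.prevalence

    b0 = optimize.brentq(mean_prev, -30, 30)
    y = rng.uniform(size=n) < special.expit(b0 + eta_base)
    y = y.astype(float)

    beta_hat = np.empty(k)
    se_hat = np.empty(k)
    for s in range(k):
        beta_hat[s], se_hat[s] = _logit_1d(G[:, s], y)
    return _table(snp_ids, chrom, pos, ea, oa, eaf, beta_hat, se_hat,
                  n, config.outcome_name, "binary")


def _logit_1d(g, y, n_iter=25):
    """Newton-Raphson logistic fit of y on (1, g)."""
    X = np.column_stack([np.ones_like(g), g])
    b = np.zeros(2)
    for _ in range(n_iter):
        mu = special.expit(X @ b)
        wt = mu * (1 - mu)
        h = X.T @ (X * wt[:, None])
        grad = X.T @ (y - mu)
        step = np.linalg.solve(h, grad)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = special.expit(X @ b)
    wt = mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (X * wt[:, None]))
    return b[1], np.sqrt(cov[1, 1])


def simulate_ld_reference(config: SimConfig) -> pd.DataFrame:
    """Pairwise-r^2 records matching the generator's block structure.

    SNPs fall into consecutive blocks of ``ld_block_size``; every within-block
    pair carries ``r2 = ld_r2_within`` and cross-block pairs are absent
    (read as r^2 = 0 by the lookup, which also returns 1 for self-pairs and
    is symmetric in its arguments).
    """
    k = config.n_snps
    blocks = _block_ids(k, config.ld_block_size)
    snp_ids = [f"rs{i+1:05d}" for i in range(k)]
    rows = []
    for b in range(blocks.max() + 1):
        members = np.flatnonzero(blocks == b)
        for i_idx, i in enumerate(members):
            for j in members[i_idx + 1:]:
                rows.append((snp_ids[i], snp_ids[j], config.ld_r2_within))
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])
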