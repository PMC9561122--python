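"""Univariable two-sample MR estimators.

Seven estimators over a single-exposure :class:`~mrtri.sumstats.HarmonizedSet`
of k SNP effects (gamma on the exposure, Gamma on the outcome):

- :func:`ivw` — inverse-variance-weighted, multiplicative random effects with
  the under-dispersion correction (residual scale floored at 1);
- :func:`egger` — weighted regression with an intercept capturing directional
  pleiotropy;
- :func:`weighted_median` / :func:`weighted_mode` — order/mode statistics on
  per-SNP Wald ratios, robust to up to 50% / a plurality of invalid SNPs;
- :func:`mr_raps` — robust adjusted profile score with optional Huber loss
  and overdispersion;
- :func:`contamination_mixture` — profile likelihood over a grid classifying
  each SNP as valid or pleiotropic;
- :func:`mr_presso` — residual-sum-of-squares global test, per-SNP outlier
  detection and outlier-corrected IVW.

All estimators report on the outcome's scale (SD units, or log-odds for
binary outcomes) and are invariant to jointly negating gamma and Gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .sumstats import HarmonizedSet, MREstimate, make_estimate

logger = logging.getLogger(__name__)

HUBER_C = 1.345  # 95% Gaussian efficiency tuning constant


@dataclass
class RatioEstimates:
    """Per-SNP Wald ratios and their variances."""

    ratios: np.ndarray
    variances: np.ndarray  # first-order by default

    def __post_init__(self) -> None:
        if np.any(self.variances <= 0):
            raise ValueError("ratio variances must be > 0")


def _unpack(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                       np.ndarray]:
    if h.n_exposures != 1:
        raise ValueError("univariable estimator requires exactly one exposure; "
                         "use h.single_exposure(name)")
    g = h.exposure_beta[:, 0].copy()
    gse = h.exposure_se[:, 0].copy()
    G = h.outcome_beta.copy()
    Gse = h.outcome_se.copy()
    keep = g != 0
    if not keep.all():
        logger.warning("dropping %d SNPs with zero exposure effect",
                       int((~keep).sum()))
    return g[keep], gse[keep], G[keep], Gse[keep]


def wald_ratios(h: HarmonizedSet, second_order: bool = False) -> RatioEstimates:
    """Per-SNP ratio estimates Gamma_j / gamma_j with first-order variances.

    ``second_order`` adds the exposure-uncertainty term
    ``Gamma_j^2 * gamma_se_j^2 / gamma_j^4``.
    """
    g, gse, G, Gse = _unpack(h)
    r = G / g
    v = Gse**2 / g**2
    if second_order:
        v = v + G**2 * gse**2 / g**4
    return RatioEstimates(ratios=r, variances=v)


def _wald(g, G, Gse, h, tag="wald_ratio") -> MREstimate:
    est = G[0] / g[0]
    se = Gse[0] / abs(g[0])
    return make_estimate(tag, est, se, 1, scale=h.scale,
                         exposure=h.exposure_names[0], outcome=h.outcome_name)


def _ivw_core(g, G, Gse):
    """Weighted through-origin fit; returns (beta, fixed_se, rss, phi)."""
    w = 1.0 / Gse**2
    s_gg = np.sum(w * g * g)
    beta = np.sum(w * g * G) / s_gg
    fixed_se = np.sqrt(1.0 / s_gg)
    rss = float(np.sum(w * (G - beta * g) ** 2))
    k = len(g)
    phi = np.sqrt(rss / (k - 1)) if k > 1 else 1.0
    return float(beta), float(fixed_se), rss, float(phi)


def ivw(h: HarmonizedSet) -> MREstimate:
    """IVW with multiplicative random effects and under-dispersion correction.

    Weighted regression of Gamma on gamma through the origin with weights
    1/Gamma_se^2.  The reported SE is the fixed-effect SE times
    ``max(phi, 1)`` with ``phi = sqrt(RSS / (k-1))``, so the random-effects
    model can widen but never narrow the fixed-effect interval.  k = 1
    degenerates to the Wald ratio (tagged ``wald_ratio``).
    """
    g, gse, G, Gse = _unpack(h)
    k = len(g)
    if k == 0:
        raise ValueError("no usable SNPs")
    if k == 1:
        return _wald(g, G, Gse, h)
    beta, fixed_se, rss, phi = _ivw_core(g, G, Gse)
    se = fixed_se * max(phi, 1.0)
    return make_estimate(
        "ivw", beta, se, k, scale=h.scale,
        exposure=h.exposure_names[0], outcome=h.outcome_name,
        diagnostics={"cochran_q": rss, "cochran_q_df": k - 1,
                     "cochran_q_p": float(stats.chi2.sf(rss, k - 1)),
                     "residual_scale": phi})


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression with a pleiotropy intercept.

    Rows are first oriented so every exposure effect is positive (the
    estimator is not invariant to per-SNP sign conventions).  The slope is
    the causal estimate; a nonzero intercept indicates directional
    pleiotropy.  SEs use the estimated residual scale ``phi^2 = RSS/(k-2)``
    with no flooring — the weighted-regression t statistics then follow
    their exact t reference, keeping the intercept test calibrated.
    """
    g, gse, G, Gse = _unpack(h)
    k = len(g)
    if k < 3:
        raise ValueError("MR-Egger requires k >= 3 SNPs")
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    w = 1.0 / Gse**2
    X = np.column_stack([np.ones(k), g])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ G)
    resid = G - X @ coef
    rss = float(np.sum(w * resid**2))
    phi = np.sqrt(rss / (k - 2))
    cov = np.linalg.inv(xtwx) * phi**2
    slope, slope_se = coef[1], np.sqrt(cov[1, 1])
    icept, icept_se = coef[0], np.sqrt(cov[0, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        icept_p = 2 * stats.t.sf(abs(icept / icept_se), k - 2) \
            if icept_se > 0 else (1.0 if icept == 0 else 0.0)
    return make_estimate(
        "egger", slope, slope_se, k, scale=h.scale,
        exposure=h.exposure_names[0], outcome=h.outcome_name,
        diagnostics={"egger_intercept": float(icept),
                     "egger_intercept_se": float(icept_se),
                     "egger_intercept_p": float(icept_p),
                     "cochran_q": rss, "residual_scale": float(phi)})


def _weighted_median_stat(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r)
    r, w = r[order], w[order] / w.sum()
    s = np.cumsum(w) - 0.5 * w  # cumulative midpoints
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(s, 0.5))
    return float(r[j - 1] + (r[j] - r[j - 1]) * (0.5 - s[j - 1])
                 / (s[j] - s[j - 1]))


def _bootstrap_draws(g, gse, G, Gse, statistic, n_boot, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    k = len(g)
    gs = rng.normal(g, gse, size=(n_boot, k))
    Gs = rng.normal(G, Gse, size=(n_boot, k))
    ests = np.empty(n_boot)
    for b in range(n_boot):
        ests[b] = statistic(gs[b], Gs[b])
    return ests


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted median of Wald ratios; consistent if >=50% of weight is valid.

    The estimate interpolates the ordered ratios at cumulative weight 0.5
    using weight midpoints; its SE is the standard deviation of ``n_boot``
    parametric-bootstrap re-estimates.  k < 3 falls back to the Wald ratio
    (k = 1) or IVW (k = 2), tagged accordingly.
    """
    g, gse, G, Gse = _unpack(h)
    k = len(g)
    if k == 1:
        return _wald(g, G, Gse, h)
    if k == 2:
        est = ivw(h)
        est.method = "weighted_median(ivw_fallback)"
        return est

    def statistic(gb, Gb):
        ok = gb != 0
        rb = Gb[ok] / gb[ok]
        wb = gb[ok] ** 2 / Gse[ok] ** 2
        return _weighted_median_stat(rb, wb)

    r = G / g
    w = g**2 / Gse**2  # 1 / first-order ratio variance
    est = _weighted_median_stat(r, w)
    se = float(np.std(_bootstrap_draws(g, gse, G, Gse, statistic,
                                       n_boot, seed), ddof=1))
    return make_estimate("weighted_median", est, se, k, scale=h.scale,
                         exposure=h.exposure_names[0], outcome=h.outcome_name,
                         diagnostics={"n_boot": n_boot})


def _mode_bandwidth(r: np.ndarray) -> float:
    s = np.std(r, ddof=1)
    mad = stats.median_abs_deviation(r, scale="normal")
    spread = min(s, mad) if mad > 0 else s
    if spread == 0:
        return 1e-6
    return 0.9 * spread * len(r) ** (-0.2)


def _weighted_mode_stat(r, w, bandwidth_factor, n_grid=2048) -> float:
    h_bw = bandwidth_factor * _mode_bandwidth(r)
    lo, hi = r.min() - 3 * h_bw, r.max() + 3 * h_bw
    grid = np.linspace(lo, hi, n_grid)
    dens = (w[None, :] * stats.norm.pdf((grid[:, None] - r[None, :]) / h_bw)
            ).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(h: HarmonizedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode of the weighted kernel density over Wald ratios.

    Consistent when the largest cluster of SNPs shares the true ratio (the
    plurality-valid assumption).  Bandwidth follows the 0.9 * min(SD, MAD) *
    k^(-1/5) rule scaled by ``bandwidth_factor``; SE via parametric bootstrap.
    """
    g, gse, G, Gse = _unpack(h)
    k = len(g)
    if k == 1:
        return _wald(g, G, Gse, h)
    if k == 2:
        est = ivw(h)
        est.method = "weighted_mode(ivw_fallback)"
        return est
    r = G / g
    w = g**2 / Gse**2
    w = w / w.sum()
    est = _weighted_mode_stat(r, w, bandwidth_factor)

    def statistic(gb, Gb):
        ok = gb != 0
        rb = Gb[ok] / gb[ok]
        wb = gb[ok] ** 2 / Gse[ok] ** 2
        return _weighted_mode_stat(rb, wb / wb.sum(), bandwidth_factor)

    # MAD-scaled bootstrap spread: the mode can hop between density bumps
    # across draws, so a robust scale is the conventional choice here
    draws = _bootstrap_draws(g, gse, G, Gse, statistic, n_boot, seed)
    se = float(stats.median_abs_deviation(draws, scale="normal"))
    return make_estimate("weighted_mode", est, se, k, scale=h.scale,
                         exposure=h.exposure_names[0], outcome=h.outcome_name,
                         diagnostics={"n_boot": n_boot,
                                      "bandwidth_factor": bandwidth_factor})


def _raps_score(beta, g, gse, G, Gse, tau2, psi):
    """Profile-score estimating function for beta.

    Derivative of the robustified profile log-likelihood: the second term in
    the bracket (t_j * beta * gamma_se^2 / sigma^2) comes from sigma's own
    dependence on beta and is what removes weak-instrument dilution.
    """
    sig = np.sqrt(Gse**2 + beta**2 * gse**2 + tau2)
    t = (G - beta * g) / sig
    u = g / sig + t * beta * gse**2 / sig**2
    return float(np.sum(psi(t) * u)), t, sig, u


def mr_raps(h: HarmonizedSet, robust_loss: str = "huber",
            overdispersion: bool = True) -> MREstimate:
    """Robust adjusted profile score estimator.

    Solves the profile-score equation ``sum_j psi(t_j) * gamma_j / sigma_j = 0``
    with ``t_j = (Gamma_j - beta*gamma_j) / sigma_j`` and ``sigma_j^2 =
    Gamma_se^2 + beta^2*gamma_se^2 + tau^2``; unlike IVW it accounts for
    exposure-side sampling error, removing weak-instrument bias.  ``tau^2``
    (systematic balanced pleiotropy) is profiled out when ``overdispersion``
    is on; ``psi`` is the identity or a Huber score (c = 1.345).  SE from a
    sandwich variance.  Raises ``RuntimeError`` if no root is bracketed after
    bounded expansion.
    """
    g, gse, G, Gse = _unpack(h)
    k = len(g)
    if k == 1:
        return _wald(g, G, Gse, h)
    if robust_loss == "huber":
        def psi(t):
            return np.clip(t, -HUBER_C, HUBER_C)
    elif robust_loss in ("none", None):
        def psi(t):
            return t
    else:
        raise ValueError(f"unknown robust_loss {robust_loss!r}")

    beta0, _, _, _ = _ivw_core(g, G, Gse)
    tau2 = 0.0

    if robust_loss == "huber":
        def rho(t):
            a = np.abs(t)
            return np.where(a <= HUBER_C, 0.5 * t**2,
                            HUBER_C * a - 0.5 * HUBER_C**2)
    else:
        def rho(t):
            return 0.5 * t**2

    def solve_beta(tau2):
        # minimize the robustified profile objective; its stationary point
        # is the score root, and minimization survives the flat tails where
        # the score decays to zero without changing sign
        def obj(b):
            sig2 = Gse**2 + b**2 * gse**2 + tau2
            return float(np.sum(rho((G - b * g) / np.sqrt(sig2))))
        span = max(abs(beta0), 1.0)
        for _ in range(40):
            grid = np.linspace(beta0 - span, beta0 + span, 201)
            vals = [obj(b) for b in grid]
            i = int(np.argmin(vals))
            if 0 < i < len(grid) - 1:
                res = optimize.minimize_scalar(
                    obj, bracket=(grid[i - 1], grid[i], grid[i + 1]),
                    method="brent", options={"xtol": 1e-12})
                return float(res.x)
            span *= 2.0
        raise RuntimeError("MR-RAPS: no interior optimum after bracket "
                           "expansion")

    beta = solve_beta(tau2)
    if overdispersion:
        for _ in range(100):
            # moment equation: standardized residuals have unit variance
            def gfun(t2):
                t = _raps_score(beta, g, gse, G, Gse, t2, psi)[1]
                return float(np.sum(t**2) - (k - 1))
            if gfun(0.0) <= 0:
                tau2_new = 0.0
            else:
                hi = 1.0
                while gfun(hi) > 0 and hi < 1e6:
                    hi *= 4.0
                tau2_new = optimize.brentq(gfun, 0.0, hi, xtol=1e-12)
            beta_new = solve_beta(tau2_new)
            if abs(beta_new - beta) < 1e-10 and abs(tau2_new - tau2) < 1e-12:
                beta, tau2 = beta_new, tau2_new
                break
            beta, tau2 = beta_new, tau2_new

    score, t, sig, u = _raps_score(beta, g, gse, G, Gse, tau2, psi)
    eps = 1e-6 * max(abs(beta), 1.0)
    a = (_raps_score(beta + eps, g, gse, G, Gse, tau2, psi)[0]
         - _raps_score(beta - eps, g, gse, G, Gse, tau2, psi)[0]) / (2 * eps)
    b_var = float(np.sum((psi(t) * u) ** 2))
    se = np.sqrt(b_var) / abs(a)
    return make_estimate("mr_raps", beta, se, k, scale=h.scale,
                         exposure=h.exposure_names[0], outcome=h.outcome_name,
                         diagnostics={"tau2": tau2, "robust_loss": robust_loss,
                                      "overdispersion": overdispersion})


def contamination_mixture(h: HarmonizedSet, psi: float = 0.0,
                          grid_halfwidth: float | None = None,
                          grid_points: int = 2001) -> MREstimate:
    """Contamination-mixture estimator via profile likelihood on a grid.

    Each SNP's likelihood at candidate beta is the better of 'valid'
    (ratio ~ N(beta, v_j)) and 'invalid' (ratio ~ N(0, v_j + psi^2)); the
    estimate maximizes the summed profile log-likelihood over a uniform grid.
    ``psi = 0`` selects the default 1.5 x weighted SD of the ratios.  The 95%
    CI collects grid points within chi2_1(0.95)/2 of the maximum; a
    non-contiguous set is reported as its spanning interval with a
    multimodality flag.  The grid auto-widens once if the maximum lands on a
    boundary.
    """
    g, gse, G, Gse = _unpack(h)
    k = len(g)
    if k == 0:
        raise ValueError("no usable SNPs")
    r = G / g
    v = Gse**2 / g**2
    w = 1.0 / v
    if psi <= 0:
        mean_w = np.sum(w * r) / np.sum(w)
        sd_w = np.sqrt(np.sum(w * (r - mean_w) ** 2) / np.sum(w))
        psi = 1.5 * sd_w if sd_w > 0 else 1.5 * np.sqrt(v.mean())
    # search a bounded plausible-effect range around a robust center: a grid
    # wide enough to cover every extreme weak-instrument ratio would let a
    # far-off beta "rescue" single outlying ratios the invalid component
    # explains poorly, creating spurious distant maxima
    center = _weighted_median_stat(r, w) if k > 1 else float(r[0])
    if grid_halfwidth is None:
        grid_halfwidth = max(1.0, 3.0 * psi)

    def profile(center, half, seed_points=None):
        grid = np.linspace(center - half, center + half, grid_points)
        if seed_points is not None:
            # the likelihood peaks near ratio estimates, which a coarse
            # uniform grid can step right over; evaluate at those falling
            # inside the search range too
            sp = seed_points[(seed_points >= grid[0])
                             & (seed_points <= grid[-1])]
            grid = np.unique(np.concatenate([grid, sp]))
        ll_valid = stats.norm.logpdf(r[None, :], loc=grid[:, None],
                                     scale=np.sqrt(v)[None, :])
        ll_invalid = stats.norm.logpdf(r, loc=0.0, scale=np.sqrt(v + psi**2))
        ll = np.maximum(ll_valid, ll_invalid[None, :]).sum(axis=1)
        return grid, ll, ll_valid, ll_invalid

    grid, ll, ll_valid, ll_invalid = profile(center, grid_halfwidth,
                                             seed_points=r)
    imax = int(np.argmax(ll))
    if imax in (0, len(grid) - 1):
        grid, ll, ll_valid, ll_invalid = profile(center, 4 * grid_halfwidth,
                                                 seed_points=r)
        imax = int(np.argmax(ll))
        if imax in (0, len(grid) - 1):
            raise ValueError("contamination mixture: grid too narrow even "
                             "after widening")
    cutoff_drop = stats.chi2.ppf(0.95, 1) / 2.0
    # iteratively refine around the maximum until the 95% confidence set is
    # resolved by plenty of grid points (the initial span must cover every
    # ratio, which can leave the likelihood peak between coarse points)
    multimodal = False
    for _ in range(8):
        idx = np.flatnonzero(ll >= ll[imax] - cutoff_drop)
        multimodal = multimodal or bool(np.any(np.diff(idx) > 1))
        if idx[-1] - idx[0] >= 40:
            break
        step = grid[1] - grid[0]
        half_new = max((grid[idx[-1]] - grid[idx[0]]) * 3, 60 * step)
        grid, ll, ll_valid, ll_invalid = profile(float(grid[imax]), half_new)
        imax = int(np.argmax(ll))
    est = float(grid[imax])
    cutoff = ll[imax] - cutoff_drop
    in_ci = ll >= cutoff
    idx = np.flatnonzero(in_ci)
    ci_low, ci_high = float(grid[idx[0]]), float(grid[idx[-1]])
    multimodal = multimodal or bool(np.any(np.diff(idx) > 1))
    valid = ll_valid[imax] >= ll_invalid
    se = (ci_high - ci_low) / (2 * stats.norm.ppf(0.975))
    z = est / se if se > 0 else np.inf
    pval = float(2 * stats.norm.sf(abs(z)))
    return MREstimate(
        method="contamination_mixture", estimate=est, se=float(se),
        ci_low=ci_low, ci_high=ci_high, pval=pval, n_snps=k, scale=h.scale,
        exposure=h.exposure_names[0], outcome=h.outcome_name,
        diagnostics={"psi": float(psi), "multimodal": multimodal,
                     "valid_snps": [h.snp_ids[i] for i in np.flatnonzero(valid)]
                     if len(h.snp_ids) == k else [],
                     "n_valid": int(valid.sum())})


def _loo_betas(g, G, w):
    """Leave-one-out IVW slopes, vectorized over SNPs."""
    s1 = np.sum(w * g * g)
    s2 = np.sum(w * g * G)
    return (s2 - w * g * G) / (s1 - w * g * g)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
              alpha: float = 0.05) -> MREstimate:
    """MR-PRESSO: pleiotropy residual sum of squares and outlier correction.

    The global test compares the observed leave-one-out weighted RSS with its
    parametric-simulation null; the outlier test compares each SNP's residual
    with its simulated distribution (Bonferroni over k); the distortion test
    compares the all-SNP and outlier-corrected IVW estimates against random
    same-size removals.  Returns the outlier-corrected IVW when outliers are
    found, the ordinary IVW otherwise; the full report sits in diagnostics.
    """
    g, gse, G, Gse = _unpack(h)
    k = len(g)
    if k < 4:
        raise ValueError("MR-PRESSO requires k >= 4 SNPs")
    rng = np.random.default_rng(seed)
    w = 1.0 / Gse**2

    beta_loo = _loo_betas(g, G, w)
    obs_res = w * (G - beta_loo * g) ** 2
    rss_obs = float(np.sum(obs_res))

    # parametric null: effects resampled about the LOO no-pleiotropy model
    gs = rng.normal(g, gse, size=(n_sim, k))
    Gs = rng.normal(beta_loo * g, Gse, size=(n_sim, k))
    s1 = np.sum(w * gs * gs, axis=1, keepdims=True)
    s2 = np.sum(w * gs * Gs, axis=1, keepdims=True)
    beta_loo_sim = (s2 - w * gs * Gs) / (s1 - w * gs * gs)
    sim_res = w * (Gs - beta_loo_sim * gs) ** 2
    rss_sim = sim_res.sum(axis=1)
    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))

    # raw empirical exceedance (no +1 smoothing): the Bonferroni-corrected
    # outlier test needs p-values that can fall below alpha/k
    outlier_p = np.mean(sim_res >= obs_res[None, :], axis=0)
    outliers = np.flatnonzero(outlier_p * k < alpha)

    beta_all, fixed_se, rss, phi = _ivw_core(g, G, Gse)
    diagnostics = {
        "global_rss": rss_obs, "global_p": global_p,
        "outlier_p": outlier_p.tolist(),
        "outlier_ids": [h.snp_ids[i] for i in outliers],
        "n_sim": n_sim,
    }
    if len(outliers) == 0 or len(outliers) == k:
        if len(outliers) == k:
            raise ValueError("MR-PRESSO flagged every SNP as an outlier")
        est = ivw(h)
        est.method = "mr_presso"
        est.diagnostics.update(diagnostics)
        return est

    keep = np.setdiff1d(np.arange(k), outliers)
    sub = h.subset(keep.tolist())
    corrected = ivw(sub)
    # distortion: observed shift vs random same-size removals
    d_obs = (beta_all - corrected.estimate) / abs(corrected.estimate)
    n_out = len(outliers)
    d_null = np.empty(n_sim)
    for b in range(n_sim):
        drop = rng.choice(k, size=n_out, replace=False)
        kp = np.setdiff1d(np.arange(k), drop)
        bb, _, _, _ = _ivw_core(g[kp], G[kp], Gse[kp])
        d_null[b] = (beta_all - bb) / abs(bb)
    distortion_p = float((np.sum(np.abs(d_null) >= abs(d_obs)) + 1)
                         / (n_sim + 1))
    diagnostics.update({"distortion_coef": float(d_obs),
                        "distortion_p": distortion_p,
                        "raw_estimate": beta_all})
    corrected.method = "mr_presso"
    corrected.diagnostics.update(diagnostics)
    return corrected


#: name -> callable registry for the pipeline and scripts.
UNIVARIABLE_METHODS = {
    "ivw": ivw,
    "egger": egger,
    "weighted_median": weighted_median,
    "weighted_mode": weighted_mode,
    "mr_raps": mr_raps,
    "contamination_mixture": contamination_mixture,
    "mr_presso": mr_presso,
}
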