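"""Multivariable MR estimators and conditional instrument strength.

With m >= 2 exposures whose SNP effects form a k x m matrix gamma, each
estimator regresses the outcome effects Gamma on gamma jointly and reports
per-exposure DIRECT effects, i.e. the effect of each exposure conditional on
the others — the summary-data analogue of mutually adjusted covariates.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.regression.quantile_regression import QuantReg

from .sumstats import HarmonizedSet, MREstimate, make_estimate

__all__ = ["mvmr_ivw", "mvmr_egger", "mvmr_median", "mvmr_lasso",
           "conditional_f", "MVMR_METHODS"]


def _unpack(h: HarmonizedSet):
    X = np.asarray(h.exposure_beta, float)
    Xse = np.asarray(h.exposure_se, float)
    G = np.asarray(h.outcome_beta, float)
    Gse = np.asarray(h.outcome_se, float)
    return X, Xse, G, Gse


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"exposure effect matrix is rank-deficient: the columns "
            f"{names} are linearly dependent; MVMR cannot separate them")


def _wls(X, G, w, phi_df, floor_phi=True):
    """Weighted LS; SEs scaled by phi (floored at 1 unless ``floor_phi``
    is off); returns coef, se, rss, phi."""
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ G)
    resid = G - X @ coef
    rss = float(np.sum(w * resid**2))
    phi = np.sqrt(rss / phi_df) if phi_df > 0 else 1.0
    scale = max(phi, 1.0) if floor_phi else phi
    cov = np.linalg.inv(xtwx) * scale**2
    return coef, np.sqrt(np.diag(cov)), rss, float(phi)


def _per_exposure(h, method, coef, se, k, extra=None) -> list[MREstimate]:
    out = []
    for j, name in enumerate(h.exposure_names):
        est = make_estimate(method, coef[j], se[j], k, scale=h.scale,
                            exposure=name, outcome=h.outcome_name,
                            diagnostics=dict(extra or {}))
        out.append(est)
    return out


def mvmr_ivw(h: HarmonizedSet) -> list[MREstimate]:
    """Multivariable IVW: weighted regression of Gamma on the gamma matrix.

    No intercept, weights 1/Gamma_se^2; per-exposure SEs inflated by
    ``max(phi, 1)`` with ``phi^2 = RSS/(k - m)``.  With m = 1 this reduces
    exactly to univariable IVW.
    """
    X, Xse, G, Gse = _unpack(h)
    k, m = X.shape
    if k < m + 1:
        raise ValueError(f"MVMR-IVW requires k >= m+1 (k={k}, m={m})")
    if k < m + 2:
        import logging
        logging.getLogger(__name__).warning(
            "k = m+1: MVMR has no residual degrees of freedom to spare")
    _check_rank(X, h.exposure_names)
    w = 1.0 / Gse**2
    coef, se, rss, phi = _wls(X, G, w, k - m)
    extra = {"cochran_q": rss, "cochran_q_df": k - m,
             "cochran_q_p": float(stats.chi2.sf(rss, k - m)),
             "residual_scale": phi}
    return _per_exposure(h, "mvmr_ivw", coef, se, k, extra)


def mvmr_egger(h: HarmonizedSet, orient_exposure: str | None = None,
               ) -> list[MREstimate]:
    """Multivariable MR-Egger: adds a directional-pleiotropy intercept.

    Rows are oriented so the designated primary exposure's effects (default:
    the first exposure) are all positive before fitting.  SEs use the
    estimated residual scale without flooring, keeping the intercept t test
    calibrated.
    """
    X, Xse, G, Gse = _unpack(h)
    k, m = X.shape
    if k < m + 2:
        raise ValueError(f"MVMR-Egger requires k >= m+2 (k={k}, m={m})")
    _check_rank(X, h.exposure_names)
    j0 = (0 if orient_exposure is None
          else h.exposure_names.index(orient_exposure))
    sign = np.where(X[:, j0] < 0, -1.0, 1.0)
    Xo, Go = X * sign[:, None], G * sign
    w = 1.0 / Gse**2
    D = np.column_stack([np.ones(k), Xo])
    coef, se, rss, phi = _wls(D, Go, w, k - m - 1, floor_phi=False)
    icept, icept_se = coef[0], se[0]
    icept_p = float(2 * stats.t.sf(abs(icept / icept_se), k - m - 1)) \
        if icept_se > 0 else (1.0 if icept == 0 else 0.0)
    extra = {"egger_intercept": float(icept),
             "egger_intercept_se": float(icept_se),
             "egger_intercept_p": icept_p,
             "cochran_q": rss, "residual_scale": phi,
             "orient_exposure": h.exposure_names[j0]}
    return _per_exposure(h, "mvmr_egger", coef[1:], se[1:], k, extra)


def _lad_fit(X, G, w):
    """Weighted least-absolute-deviations via median regression on scaled rows.

    Minimizing sum_j w_j |G_j - X_j beta| equals L1 regression of (w_j G_j)
    on (w_j X_j) rows, solved by iteratively reweighted least squares inside
    statsmodels' QuantReg at the median.
    """
    mod = QuantReg(G * w, X * w[:, None])
    res = mod.fit(q=0.5, max_iter=5000)
    return np.asarray(res.params)


def mvmr_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0,
                ) -> list[MREstimate]:
    """Multivariable median: weighted LAD fit of Gamma on gamma.

    Robust to a minority of pleiotropic SNPs (the L1 loss bounds their
    influence).  Weights are 1/Gamma_se^2; SEs from a parametric bootstrap.
    """
    X, Xse, G, Gse = _unpack(h)
    k, m = X.shape
    if k < m + 2:
        raise ValueError(f"MVMR-median requires k >= m+2 (k={k}, m={m})")
    _check_rank(X, h.exposure_names)
    w = 1.0 / Gse**2
    coef = _lad_fit(X, G, w)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, m))
    for b in range(n_boot):
        Xb = rng.normal(X, Xse)
        Gb = rng.normal(G, Gse)
        try:
            boots[b] = _lad_fit(Xb, Gb, w)
        except Exception:
            boots[b] = np.nan
    se = np.nanstd(boots, axis=0, ddof=1)
    return _per_exposure(h, "mvmr_median", coef, se, k,
                         {"n_boot": n_boot})


def mvmr_lasso(h: HarmonizedSet, n_lambda: int = 50) -> list[MREstimate]:
    """Multivariable MR-Lasso: per-SNP pleiotropy intercepts with L1 penalty.

    The working model gives every SNP its own intercept theta_0j, penalized
    by lambda * sum_j |theta_0j| and fitted by coordinate descent (exposure
    coefficients by weighted LS on the de-pleiotropized outcome, intercepts
    by soft-thresholding the weighted residuals).  Scanning a descending
    logarithmic lambda grid, the chosen lambda is the largest whose retained
    set (zero-intercept SNPs) passes the heterogeneity criterion
    Q <= chi2_{0.95}(k_valid - m) — i.e. the most SNPs consistent with
    homogeneity.  Final estimates are MVMR-IVW on the retained set, which is
    reported in the diagnostics.
    """
    X, Xse, G, Gse = _unpack(h)
    k, m = X.shape
    if k < m + 2:
        raise ValueError(f"MVMR-Lasso requires k >= m+2 (k={k}, m={m})")
    _check_rank(X, h.exposure_names)
    w = 1.0 / Gse**2

    def cd_fit(lam, theta0=None, beta=None, n_iter=500):
        theta0 = np.zeros(k) if theta0 is None else theta0.copy()
        for _ in range(n_iter):
            coef, _, _, _ = _wls(X, G - theta0, w, max(k - m, 1))
            resid = G - X @ coef
            # soft-threshold per SNP: argmin w_j (resid_j - t)^2 + lam |t|
            thresh = lam / (2 * w)
            new_theta = np.sign(resid) * np.maximum(np.abs(resid) - thresh, 0)
            if np.allclose(new_theta, theta0, atol=1e-12):
                theta0 = new_theta
                break
            theta0 = new_theta
        return coef, theta0

    # lambda_max: smallest penalty forcing all intercepts to zero
    coef0, _, _, _ = _wls(X, G, w, max(k - m, 1))
    resid0 = G - X @ coef0
    lam_max = float(np.max(2 * w * np.abs(resid0))) * 1.01
    if lam_max <= 0:
        lam_max = 1.0
    lams = np.geomspace(lam_max, lam_max * 1e-4, n_lambda)

    chosen = None
    for lam in lams:
        coef, theta0 = cd_fit(lam)
        retained = np.flatnonzero(np.abs(theta0) < 1e-10)
        if len(retained) < m + 1:
            break
        sub = h.subset(retained.tolist())
        q = _mvmr_q(sub)
        q_crit = stats.chi2.ppf(0.95, max(len(retained) - m, 1))
        if q <= q_crit:
            chosen = (lam, retained, q, q_crit)
            break
    if chosen is None:
        raise ValueError("MR-Lasso: no lambda yields >= m+1 homogeneous "
                         "retained SNPs")
    lam, retained, q, q_crit = chosen
    sub = h.subset(retained.tolist())
    ests = mvmr_ivw(sub)
    extra = {"lambda": float(lam), "retained_snps":
             [h.snp_ids[i] for i in retained],
             "n_retained": int(len(retained)),
             "retained_q": float(q), "q_crit": float(q_crit)}
    out = []
    for e in ests:
        e.method = "mvmr_lasso"
        e.n_snps = k
        e.diagnostics.update(extra)
        out.append(e)
    return out


def _mvmr_q(h: HarmonizedSet) -> float:
    X, _, G, Gse = _unpack(h)
    w = 1.0 / Gse**2
    _, _, rss, _ = _wls(X, G, w, max(X.shape[0] - X.shape[1], 1))
    return rss


def conditional_f(h: HarmonizedSet,
                  cov_between: np.ndarray | None = None) -> dict[str, float]:
    """Conditional F statistics: instrument strength per exposure given the rest.

    For exposure j, its SNP-effect vector is regressed on the other
    exposures' SNP effects with weights 1/gamma_se_j^2 (the delta-method
    variance; cross-exposure sampling covariance is taken as 0 unless a
    k x m x m array is supplied).  The conditional F is Q_xj / (k - m + 1)
    where Q_xj is that regression's weighted residual sum of squares: effects
    fully predictable from the other exposures contribute no conditional
    strength.  Values below ~10 signal weak-instrument bias in MVMR.
    """
    X, Xse, G, Gse = _unpack(h)
    k, m = X.shape
    if k <= m:
        raise ValueError(f"conditional F requires k > m (k={k}, m={m})")
    out: dict[str, float] = {}
    for j, name in enumerate(h.exposure_names):
        others = [i for i in range(m) if i != j]
        var_j = Xse[:, j] ** 2
        if cov_between is not None:
            # delta-method variance of the residual gamma_j - A gamma_others
            var_j = np.asarray([cov_between[s][j, j] for s in range(k)])
        w = 1.0 / var_j
        if others:
            Z = X[:, others]
            WZ = Z * w[:, None]
            a = np.linalg.lstsq(WZ.T @ Z, WZ.T @ X[:, j], rcond=None)[0]
            resid = X[:, j] - Z @ a
        else:
            resid = X[:, j]
        q = float(np.sum(w * resid**2))
        out[name] = q / (k - m + 1)
    return out


MVMR_METHODS = {
    "mvmr_ivw": mvmr_ivw,
    "mvmr_egger": mvmr_egger,
    "mvmr_median": mvmr_median,
    "mvmr_lasso": mvmr_lasso,
}
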