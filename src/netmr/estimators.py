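"""Two-sample MR estimators.

All estimators consume per-SNP harmonized effect pairs: the SNP-exposure
effect gamma_j with standard error sigma_xj and the SNP-outcome effect
Gamma_j with standard error sigma_yj.  The per-SNP Wald ratio
Gamma_j / gamma_j estimates the causal effect under the instrumental-variable
assumptions; the estimators differ in how they pool ratios and in which
violations (horizontal pleiotropy, weak instruments, outliers) they
tolerate:

* ``ivw`` — inverse-variance-weighted meta-analysis of Wald ratios,
  equivalently weighted regression through the origin; the primary method.
* ``maximum_likelihood`` — joint normal likelihood over the causal effect
  and the true SNP-exposure effects; accounts for exposure-side noise.
* ``weighted_median`` — consistent when >= 50% of weight is on valid SNPs.
* ``egger`` — weighted regression with an intercept; the intercept estimates
  directional pleiotropy under InSIDE.
* ``mr_presso`` — residual-sum-of-squares global pleiotropy test with
  simulation-based outlier detection and an outlier-corrected estimate.
* ``divw`` — debiased IVW, consistent under many weak instruments.
* ``conmix`` — contamination-mixture profile likelihood over a grid,
  classifying SNPs as valid/invalid.
* ``raps`` — robust adjusted profile score with overdispersion.
* ``cml_ma`` — constrained maximum likelihood with model averaging over the
  number of invalid instruments.

Estimate containers carry beta, SE, 95% CI, a two-sided normal p-value,
the SNP count and method-specific extras.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

Z95 = stats.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    """Fewer SNPs than the estimator's minimum."""


class NumericalFailureError(RuntimeError):
    """Optimizer or root finder failed; message carries diagnostics."""


class WeakInstrumentSignal(RuntimeError):
    """dIVW denominator non-positive: instruments pathologically weak."""


@dataclass
class MREstimate:
    """One estimator's causal-effect estimate."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extras: dict = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"{self.method}: beta={self.beta:.4g} "
                f"(95% CI {self.ci_low:.4g}, {self.ci_high:.4g}), "
                f"p={self.pval:.3g}, nSNP={self.n_snp}")


def _finish(method: str, beta: float, se: float, n_snp: int,
            extras: dict | None = None) -> MREstimate:
    beta, se = float(beta), float(se)
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    p = max(p, np.nextafter(0, 1))
    return MREstimate(method=method, beta=beta, se=se,
                      ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
                      pval=min(p, 1.0), n_snp=int(n_snp),
                      extras=dict(extras or {}))


def _unpack(h):
    """Accept an InstrumentSet, HarmonizedSet or 4-tuple of arrays."""
    if hasattr(h, "arrays"):
        bx, bxse, by, byse = h.arrays()
    else:
        bx, bxse, by, byse = h
    bx = np.asarray(bx, float)
    bxse = np.asarray(bxse, float)
    by = np.asarray(by, float)
    byse = np.asarray(byse, float)
    if np.any(bxse <= 0) or np.any(byse <= 0):
        raise ValueError("standard errors must be strictly positive")
    return bx, bxse, by, byse


def _require(n: int, minimum: int, method: str) -> None:
    if n < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {minimum} SNPs, got {n}")


# ---------------------------------------------------------------------------
# Wald ratios and IVW
# ---------------------------------------------------------------------------


def wald_ratios(h):
    """Per-SNP Wald ratios Gamma/gamma with first-order SEs sigma_y/|gamma|."""
    bx, bxse, by, byse = _unpack(h)
    if np.any(bx == 0):
        raise ZeroDivisionError("Wald ratio undefined for gamma = 0")
    return by / bx, byse / np.abs(bx)


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float,
               se_out: float) -> MREstimate:
    """Single-SNP causal estimate."""
    r, s = wald_ratios(([beta_exp], [se_exp], [beta_out], [se_out]))
    return _finish("wald_ratio", r[0], s[0], 1)


def _ivw_core(bx, by, byse):
    w = 1.0 / byse ** 2
    sxx = float(np.sum(w * bx ** 2))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx ** -0.5
    ratios = by / np.where(bx == 0, np.nan, bx)
    wq = bx ** 2 * w
    q = float(np.nansum(wq * (ratios - beta) ** 2))
    return beta, se_fixed, q


def ivw(h, effects_model: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted regression of outcome effects on exposure effects through the
    origin with weights 1/sigma_y^2.  ``effects_model`` selects the SE:
    ``fixed``, ``random`` (multiplicative random effects, SE inflated by
    sqrt(Q/(n-1)) when overdispersed) or ``auto`` (random when
    Q/(n-1) > 1).  Extras carry Cochran's Q and its chi-square p-value.
    """
    bx, bxse, by, byse = _unpack(h)
    _require(len(bx), 2, "ivw")
    beta, se_fixed, q = _ivw_core(bx, by, byse)
    n = len(bx)
    df_q = n - 1
    q_pval = float(stats.chi2.sf(q, df_q))
    phi = q / df_q if df_q > 0 else 1.0
    if effects_model == "fixed":
        se = se_fixed
    elif effects_model in ("random", "auto"):
        se = se_fixed * max(1.0, np.sqrt(phi))
    else:
        raise ValueError(f"unknown effects model {effects_model!r}")
    return _finish("ivw", beta, se, n,
                   {"q": q, "q_df": df_q, "q_pval": q_pval,
                    "se_fixed": se_fixed,
                    "effects_model": ("random" if effects_model != "fixed"
                                      and phi > 1 else "fixed")})


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------


def _ml_profile(beta, bx, bxse, by, byse):
    return np.sum((by - beta * bx) ** 2 / (byse ** 2 + beta ** 2 * bxse ** 2))


def maximum_likelihood(h) -> MREstimate:
    """Joint-normal ML estimate profiling out the true SNP-exposure effects.

    For fixed beta the per-SNP nuisance effect has a closed-form optimum,
    leaving the profile objective
    sum_j (Gamma_j - beta*gamma_j)^2 / (sigma_yj^2 + beta^2 sigma_xj^2),
    minimized numerically from the IVW start point.  SE from the observed
    information (profile curvature).
    """
    bx, bxse, by, byse = _unpack(h)
    _require(len(bx), 2, "maximum_likelihood")
    b0, _, _ = _ivw_core(bx, by, byse)
    span = 1.0 + 10.0 * abs(b0)
    res = optimize.minimize_scalar(
        _ml_profile, bounds=(b0 - span, b0 + span), method="bounded",
        args=(bx, bxse, by, byse), options={"xatol": 1e-12})
    if not res.success:
        raise NumericalFailureError(f"ML optimizer failed: {res.message}")
    beta = float(res.x)
    hstep = 1e-5 * (1.0 + abs(beta))
    f0 = _ml_profile(beta, bx, bxse, by, byse)
    fp = _ml_profile(beta + hstep, bx, bxse, by, byse)
    fm = _ml_profile(beta - hstep, bx, bxse, by, byse)
    d2 = (fp - 2 * f0 + fm) / hstep ** 2
    if d2 <= 0:
        raise NumericalFailureError("ML information matrix not positive")
    se = float(np.sqrt(2.0 / d2))
    return _finish("ml", beta, se, len(bx), {"neg2loglik": float(f0)})


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------


def _weighted_median_point(ratios, weights):
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w)
    p = s - w / 2.0
    return float(np.interp(0.5, p, r))


def weighted_median(h, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    The estimate interpolates the IVW-weighted percentile function of the
    sorted Wald ratios at 50%; it is consistent as long as valid
    instruments carry at least half the weight.  The SE is the standard
    deviation of the estimate over ``n_boot`` parametric resamples drawn
    from the fitted model (exposure effects about their estimates, outcome
    effects about the fitted ratio line); centering the outcome draws on
    the fit rather than the observations avoids the noise double-counting
    that makes the observation-centered bootstrap SE of a median
    anticonservative.
    """
    bx, bxse, by, byse = _unpack(h)
    n = len(bx)
    _require(n, 3, "weighted_median")
    ratios = by / bx
    weights = bx ** 2 / byse ** 2
    beta = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, bxse, size=(n_boot, n))
    by_b = rng.normal(beta * bx, byse, size=(n_boot, n))
    ratios_b = by_b / bx_b
    weights_b = bx_b ** 2 / byse ** 2
    order = np.argsort(ratios_b, axis=1, kind="stable")
    r_sorted = np.take_along_axis(ratios_b, order, axis=1)
    w_sorted = np.take_along_axis(weights_b, order, axis=1)
    w_sorted /= w_sorted.sum(axis=1, keepdims=True)
    s = np.cumsum(w_sorted, axis=1)
    p = s - w_sorted / 2.0
    # row-wise interpolation of the 50% point
    idx = np.sum(p < 0.5, axis=1)
    idx = np.clip(idx, 1, n - 1)
    rows = np.arange(n_boot)
    p_lo, p_hi = p[rows, idx - 1], p[rows, idx]
    r_lo, r_hi = r_sorted[rows, idx - 1], r_sorted[rows, idx]
    frac = np.where(p_hi > p_lo, (0.5 - p_lo) / (p_hi - p_lo), 0.0)
    boots = r_lo + frac * (r_hi - r_lo)
    # clamp the degenerate edges (all mass below/above 0.5)
    boots = np.where(np.sum(p < 0.5, axis=1) == 0, r_sorted[:, 0], boots)
    boots = np.where(np.sum(p < 0.5, axis=1) == n, r_sorted[:, -1], boots)
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", beta, se, n, {"n_boot": n_boot})


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------


def egger(h) -> MREstimate:
    """MR-Egger regression: weighted fit of Gamma on gamma with intercept.

    The slope estimates the causal effect under InSIDE; the intercept and
    its p-value test directional horizontal pleiotropy.  SEs use the same
    multiplicative random-effects inflation as IVW (residual variance
    floored at 1).
    """
    bx, bxse, by, byse = _unpack(h)
    n = len(bx)
    _require(n, 3, "egger")
    w = 1.0 / byse ** 2
    sw = np.sqrt(w)
    X = np.column_stack([np.ones(n), bx]) * sw[:, None]
    y = by * sw
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    q = float(np.sum(resid ** 2))
    df = n - 2
    phi = max(1.0, q / df)
    xtx_inv = np.linalg.inv(X.T @ X)
    ses = np.sqrt(np.diag(xtx_inv) * phi)
    intercept, slope = coef
    int_se, slope_se = ses
    int_p = float(2.0 * stats.norm.sf(abs(intercept) / int_se))
    return _finish("egger", slope, slope_se, n,
                   {"intercept": float(intercept),
                    "intercept_se": float(int_se),
                    "intercept_pval": int_p,
                    "q": q, "q_df": df,
                    "q_pval": float(stats.chi2.sf(q, df))})


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------


def _loo_ivw_betas(bx, by, w):
    """Leave-one-out IVW slopes via sum updates (vectorized)."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx ** 2)
    return (sxy - w * bx * by) / (sxx - w * bx ** 2)


def mr_presso(h, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int = 0, n_distortion: int = 500) -> MREstimate:
    """MR-PRESSO global pleiotropy test, outlier flagging and correction.

    The observed residual sum of squares compares each SNP's outcome effect
    with its leave-one-out IVW prediction; its null distribution comes from
    ``n_sim`` parametric simulations under the no-pleiotropy model.  Per-SNP
    outlier p-values are Bonferroni-corrected over SNPs.  The corrected
    estimate is IVW after removing flagged outliers; a distortion test
    compares the raw-vs-corrected shift against random removals of the same
    size.
    """
    if n_sim <= 0:
        raise ValueError("n_sim must be positive")
    bx, bxse, by, byse = _unpack(h)
    n = len(bx)
    _require(n, 4, "mr_presso")
    w = 1.0 / byse ** 2
    beta_loo = _loo_ivw_betas(bx, by, w)
    resid_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, bxse, size=(n_sim, n))
    by_s = rng.normal(beta_loo * bx, byse, size=(n_sim, n))
    sxy = np.sum(w * bx_s * by_s, axis=1, keepdims=True)
    sxx = np.sum(w * bx_s ** 2, axis=1, keepdims=True)
    beta_loo_s = (sxy - w * bx_s * by_s) / (sxx - w * bx_s ** 2)
    resid_s = w * (by_s - beta_loo_s * bx_s) ** 2
    rss_s = resid_s.sum(axis=1)
    global_p = float((np.sum(rss_s >= rss_obs) + 1) / (n_sim + 1))

    # per-SNP outlier test against its simulated residual distribution
    p_snp = (np.sum(resid_s >= resid_obs[None, :], axis=0) + 1) / (n_sim + 1)
    outliers = np.flatnonzero(p_snp * n < outlier_alpha)

    raw = ivw((bx, bxse, by, byse))
    extras = {"global_pval": global_p, "outlier_indices": outliers.tolist(),
              "outlier_pvals": p_snp.tolist(), "raw": raw}
    if len(outliers) and n - len(outliers) >= 2:
        keep = np.ones(n, dtype=bool)
        keep[outliers] = False
        corrected = ivw((bx[keep], bxse[keep], by[keep], byse[keep]))
        # distortion: shift from removing the flagged set vs random sets
        shift_obs = abs(corrected.beta - raw.beta)
        shifts = np.empty(n_distortion)
        for b in range(n_distortion):
            drop = rng.choice(n, size=len(outliers), replace=False)
            m = np.ones(n, dtype=bool)
            m[drop] = False
            bb, _, _ = _ivw_core(bx[m], by[m], byse[m])
            shifts[b] = abs(bb - raw.beta)
        extras["distortion_pval"] = float(
            (np.sum(shifts >= shift_obs) + 1) / (n_distortion + 1))
        est = corrected
    else:
        est = raw
        extras["distortion_pval"] = None
    return _finish("mr_presso", est.beta, est.se, est.n_snp, extras)


# ---------------------------------------------------------------------------
# dIVW
# ---------------------------------------------------------------------------


def divw(h) -> MREstimate:
    """Debiased IVW: corrects the weak-instrument bias of IVW.

    beta = sum(gamma*Gamma/sigma_y^2) / sum((gamma^2 - sigma_x^2)/sigma_y^2);
    the denominator subtracts the exposure-side sampling variance so the
    estimator stays consistent under many weak instruments.  SE by the
    sandwich (estimating-equation) variance.  Reduces to IVW when
    sigma_x = 0.
    """
    bx, bxse, by, byse = _unpack(h)
    _require(len(bx), 2, "divw")
    w = 1.0 / byse ** 2
    num = float(np.sum(w * bx * by))
    den = float(np.sum(w * (bx ** 2 - bxse ** 2)))
    if den <= 0:
        raise WeakInstrumentSignal(
            "dIVW denominator non-positive: instruments too weak")
    beta = num / den
    # Var of the per-SNP estimating function gamma*Gamma - beta*(gamma^2 -
    # sigma_x^2), scaled by 1/sigma_y^2, with gamma^2 plugged in debiased
    g2 = np.maximum(bx ** 2 - bxse ** 2, 0.0)
    vterm = (g2 * byse ** 2 + bxse ** 2 * byse ** 2
             + beta ** 2 * bxse ** 2 * g2 + 2.0 * beta ** 2 * bxse ** 4)
    var = float(np.sum(vterm / byse ** 4)) / den ** 2
    return _finish("divw", beta, np.sqrt(var), len(bx),
                   {"effective_denominator": den})


# ---------------------------------------------------------------------------
# contamination mixture
# ---------------------------------------------------------------------------


def conmix(h, psi_scale: float = 1.5, n_grid: int = 2001) -> MREstimate:
    """Contamination-mixture estimate over a profile-likelihood grid.

    Each SNP's Wald ratio contributes the larger of a valid-component
    likelihood N(beta, se_j^2) and an invalid-component likelihood
    N(0, se_j^2 + psi^2), where psi = ``psi_scale`` times the SD of the
    ratio estimates.  The estimate maximizes the profile log-likelihood on
    a grid spanning the ratio range plus three SE; the 95% CI is the grid
    region within qchisq(0.95, 1)/2 of the maximum.
    """
    bx, bxse, by, byse = _unpack(h)
    _require(len(bx), 3, "conmix")
    ratios, ses = wald_ratios((bx, bxse, by, byse))
    psi = psi_scale * float(np.std(ratios, ddof=1))
    if psi <= 0:
        psi = psi_scale * float(np.max(ses))
    lo = float(np.min(ratios) - 3.0 * np.max(ses))
    hi = float(np.max(ratios) + 3.0 * np.max(ses))
    if not hi > lo or n_grid < 3:
        raise ValueError("degenerate ConMix grid")
    grid = np.linspace(lo, hi, n_grid)
    ll_valid = stats.norm.logpdf(ratios[None, :], grid[:, None], ses[None, :])
    ll_invalid = stats.norm.logpdf(ratios, 0.0,
                                   np.sqrt(ses ** 2 + psi ** 2))[None, :]
    ll = np.maximum(ll_valid, ll_invalid).sum(axis=1)
    k = int(np.argmax(ll))
    beta = float(grid[k])
    cut = ll[k] - stats.chi2.ppf(0.95, 1) / 2.0
    inside = grid[ll >= cut]
    ci_low, ci_high = float(inside.min()), float(inside.max())
    se = (ci_high - ci_low) / (2.0 * Z95)
    valid = ll_valid[k] >= ll_invalid[0]
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return MREstimate(method="conmix", beta=beta, se=se, ci_low=ci_low,
                      ci_high=ci_high, pval=max(min(p, 1.0), 1e-300),
                      n_snp=len(bx),
                      extras={"psi": psi, "valid_snps":
                              np.flatnonzero(valid).tolist()})


# ---------------------------------------------------------------------------
# MR-RAPS
# ---------------------------------------------------------------------------

_HUBER_K = 1.345
_TUKEY_C = 4.685


def _rho_funcs(loss: str):
    if loss == "l2":
        return (lambda t: 0.5 * t ** 2, lambda t: t, lambda t: np.ones_like(t),
                1.0)
    if loss == "huber":
        k = _HUBER_K
        delta = 2.0 * stats.norm.cdf(k) - 1.0

        def rho(t):
            a = np.abs(t)
            return np.where(a <= k, 0.5 * t ** 2, k * a - 0.5 * k ** 2)

        return rho, lambda t: np.clip(t, -k, k), \
            lambda t: (np.abs(t) <= k).astype(float), delta
    if loss == "tukey":
        c = _TUKEY_C

        def rho(t):
            u = np.clip(t / c, -1, 1)
            return c ** 2 / 6.0 * (1 - (1 - u ** 2) ** 3)

        def psi(t):
            u = t / c
            return np.where(np.abs(u) <= 1, t * (1 - u ** 2) ** 2, 0.0)

        def dpsi(t):
            u = t / c
            return np.where(np.abs(u) <= 1, (1 - u ** 2) * (1 - 5 * u ** 2),
                            0.0)

        z = np.linspace(-8, 8, 4001)
        delta = float(np.trapezoid(psi(z) * z * stats.norm.pdf(z), z))
        return rho, psi, dpsi, delta
    raise ValueError(f"unknown RAPS loss {loss!r}")


def raps(h, loss: str = "huber", overdispersion: bool = True) -> MREstimate:
    """Robust adjusted profile score estimate.

    Standardized residuals t_j = (Gamma_j - beta*gamma_j) /
    sqrt(sigma_yj^2 + beta^2 sigma_xj^2 + tau^2) enter a robust loss
    (huber/tukey/l2); the causal effect and the overdispersion variance
    tau^2 are fitted jointly.  SE by the M-estimator sandwich formula.
    """
    bx, bxse, by, byse = _unpack(h)
    n = len(bx)
    _require(n, 3, "raps")
    rho, psi, dpsi, delta = _rho_funcs(loss)

    def sig2(beta, tau2):
        return byse ** 2 + beta ** 2 * bxse ** 2 + tau2

    def objective(beta, tau2):
        return float(np.sum(rho((by - beta * bx) / np.sqrt(sig2(beta, tau2)))))

    ratios = by / np.where(bx == 0, np.nan, bx)
    span = float(np.nanmax(np.abs(ratios))) + 3.0 * float(np.max(byse / np.abs(bx).min()))
    b0, _, _ = _ivw_core(bx, by, byse)
    tau2 = 0.0
    beta = b0
    for _ in range(50):
        res = optimize.minimize_scalar(objective, bounds=(-span - abs(b0),
                                                          span + abs(b0)),
                                       method="bounded", args=(tau2,),
                                       options={"xatol": 1e-12})
        if not res.success:
            raise NumericalFailureError("RAPS beta step failed")
        beta_new = float(res.x)
        if overdispersion:
            def tau_eq(t2):
                t = (by - beta_new * bx) / np.sqrt(sig2(beta_new, t2))
                return float(np.sum((psi(t) * t - delta) / sig2(beta_new, t2)))

            if tau_eq(0.0) <= 0:
                tau2_new = 0.0
            else:
                hi = float(np.var(by - beta_new * bx)) * 10 + 1.0
                while tau_eq(hi) > 0 and hi < 1e6:
                    hi *= 10
                tau2_new = optimize.brentq(tau_eq, 0.0, hi, xtol=1e-12)
        else:
            tau2_new = 0.0
        if abs(beta_new - beta) < 1e-10 and abs(tau2_new - tau2) < 1e-12:
            beta, tau2 = beta_new, tau2_new
            break
        beta, tau2 = beta_new, tau2_new

    # expected-information sandwich: under the fitted model the
    # standardized residuals are standard normal, so the score variance
    # uses E[psi(Z)^2] and the slope uses E[psi'(Z)] = E[Z psi(Z)] = delta
    # (Stein's identity for the odd psi); the information weight per SNP
    # is the debiased instrument strength over the total residual variance
    s2 = sig2(beta, tau2)
    z = np.linspace(-8, 8, 4001)
    c_psi2 = float(np.trapezoid(psi(z) ** 2 * stats.norm.pdf(z), z))
    info = float(np.sum((bx ** 2 - bxse ** 2) / s2))
    if info <= 0:
        info = float(np.sum(bx ** 2 / s2))
    var = c_psi2 / (delta ** 2 * info)
    if var <= 0:
        raise NumericalFailureError("RAPS variance not positive")
    return _finish("raps", beta, np.sqrt(var), n,
                   {"tau2": tau2, "loss": loss})


# ---------------------------------------------------------------------------
# cML-MA
# ---------------------------------------------------------------------------


def _cml_fit_k(bx, bxse, by, byse, k, beta0, max_iter=200, tol=1e-10):
    """Constrained ML allowing exactly k SNPs a free pleiotropy offset."""
    vx, vy = bxse ** 2, byse ** 2
    beta = beta0
    invalid = np.zeros(len(bx), dtype=bool)
    for _ in range(max_iter):
        # profile nuisance exposure effects with offsets fixed at optimum
        gain = (by - beta * bx) ** 2 / (vy + beta ** 2 * vx)
        invalid_new = np.zeros(len(bx), dtype=bool)
        if k > 0:
            invalid_new[np.argsort(gain)[::-1][:k]] = True
        gamma = np.where(
            invalid_new, bx,
            (bx / vx + beta * by / vy) / (1.0 / vx + beta ** 2 / vy))
        r = np.where(invalid_new, by - beta * bx, 0.0)
        denom = np.sum(gamma ** 2 / vy)
        if denom <= 0:
            raise NumericalFailureError("cML degenerate denominator")
        beta_new = float(np.sum(gamma * (by - r) / vy) / denom)
        if abs(beta_new - beta) < tol and np.array_equal(invalid_new, invalid):
            beta, invalid = beta_new, invalid_new
            break
        beta, invalid = beta_new, invalid_new
    gamma = np.where(invalid, bx,
                     (bx / vx + beta * by / vy) / (1.0 / vx + beta ** 2 / vy))
    r = np.where(invalid, by - beta * bx, 0.0)
    neg2ll = float(np.sum((bx - gamma) ** 2 / vx)
                   + np.sum((by - beta * gamma - r) ** 2 / vy))
    # SE from the profile information restricted to valid SNPs
    valid = ~invalid
    if valid.sum() < 2:
        raise NumericalFailureError("cML: fewer than 2 valid SNPs")
    bxv, bxsev = bx[valid], bxse[valid]
    byv, bysev = by[valid], byse[valid]
    h = 1e-5 * (1.0 + abs(beta))
    f = lambda b: _ml_profile(b, bxv, bxsev, byv, bysev)
    d2 = (f(beta + h) - 2 * f(beta) + f(beta - h)) / h ** 2
    if d2 <= 0:
        raise NumericalFailureError("cML information not positive")
    se = float(np.sqrt(2.0 / d2))
    return beta, se, neg2ll, invalid


def cml_ma(h, k_grid=None, n_perturb: int = 0, seed: int = 0) -> MREstimate:
    """Constrained-ML model average over the number of invalid instruments.

    For each candidate invalid count K the constrained ML lets exactly K
    SNPs carry a free pleiotropy offset (chosen by largest likelihood
    gain, iterated to convergence); per-K estimates are combined with
    BIC-derived weights.  The default is the deterministic
    no-data-perturbation variant (``n_perturb = 0``).
    """
    bx, bxse, by, byse = _unpack(h)
    n = len(bx)
    _require(n, 3, "cml_ma")
    if k_grid is None:
        k_grid = range(0, n - 1)
    k_grid = sorted(set(int(k) for k in k_grid))
    if any(k < 0 or k > n - 2 for k in k_grid):
        raise ValueError("k_grid entries must lie in [0, n-2]")
    b0, _, _ = _ivw_core(bx, by, byse)

    fits = []
    for k in k_grid:
        try:
            beta_k, se_k, neg2ll, invalid = _cml_fit_k(bx, bxse, by, byse,
                                                       k, b0)
        except NumericalFailureError:
            continue
        bic = neg2ll + k * np.log(n)
        fits.append((k, beta_k, se_k, bic, invalid))
    if not fits:
        raise NumericalFailureError("cML failed at every K")
    bics = np.array([f[3] for f in fits])
    wts = np.exp(-(bics - bics.min()) / 2.0)
    wts /= wts.sum()
    betas = np.array([f[1] for f in fits])
    ses = np.array([f[2] for f in fits])
    beta = float(np.sum(wts * betas))
    se = float(np.sqrt(np.sum(wts * (ses ** 2 + (betas - beta) ** 2))))
    k_weighted = float(np.sum(wts * np.array([f[0] for f in fits])))
    k_best = int(fits[int(np.argmin(bics))][0])
    return _finish("cml_ma", beta, se, n,
                   {"k_grid": [f[0] for f in fits],
                    "bic_weights": wts.tolist(),
                    "invalid_count_weighted": k_weighted,
                    "k_best": k_best})


#: registry used by the pipeline and CLI
METHODS = {
    "ivw": ivw,
    "ml": maximum_likelihood,
    "wm": weighted_median,
    "egger": egger,
    "presso": mr_presso,
    "divw": divw,
    "conmix": conmix,
    "raps": raps,
    "cml": cml_ma,
}
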