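"""Multivariable MR: conditional causal effects of several exposures.

Regressing SNP-outcome effects jointly on two (or more) exposures'
SNP-effects gives each exposure's direct effect conditional on the others.
In the two-step mediation design the coefficient on the mediator, adjusted
for the primary exposure, is the mediator-to-outcome effect (beta2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from netmr.estimators import MREstimate, _finish
from netmr.instruments import (EmptySelection, InstrumentConfig, LdPanel,
                               clump, filter_significance)
from netmr.summary_io import SummaryStats, harmonize


class CollinearityError(ValueError):
    """Design matrix of exposure effects is rank-deficient."""


@dataclass
class MvmrSet:
    """Per-SNP effects for k exposures and one outcome on a shared allele."""

    exposure_ids: list[str]
    outcome_id: str
    df: pd.DataFrame  # snp_id, beta_exp{i}, se_exp{i}, beta_out, se_out

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_ids)

    def design(self):
        X = np.column_stack([
            self.df[f"beta_exp{i + 1}"].to_numpy(float)
            for i in range(self.n_exposures)])
        sx = np.column_stack([
            self.df[f"se_exp{i + 1}"].to_numpy(float)
            for i in range(self.n_exposures)])
        return X, sx, self.df["beta_out"].to_numpy(float), \
            self.df["se_out"].to_numpy(float)


def _check_rank(X: np.ndarray) -> None:
    """Reject collinear designs; an all-zero column is tolerated (its
    coefficient is identically zero under the pseudo-inverse solve)."""
    nonzero = np.any(X != 0, axis=0)
    sub = X[:, nonzero]
    if sub.shape[1] and np.linalg.matrix_rank(sub) < sub.shape[1]:
        raise CollinearityError("exposure effect columns are collinear")


def build_mvmr_set(exposures: list[SummaryStats], outcome: SummaryStats,
                   panel: LdPanel | None,
                   config: InstrumentConfig | None = None,
                   selection: str = "union") -> MvmrSet:
    """Construct the joint instrument set for multivariable MR.

    Instruments are selected per exposure with the univariable cascade's
    significance filter; the union (default; ``selection='intersection'``
    available) is re-clumped jointly with ties on p-value resolved by the
    smallest p across exposures, then harmonized pairwise to the outcome
    and to each exposure's records.
    """
    cfg = config or InstrumentConfig()
    per_exp = []
    for ss in exposures:
        try:
            per_exp.append(set(filter_significance(
                ss, cfg.p_threshold, cfg.maf_min).df["snp_id"]))
        except EmptySelection:
            per_exp.append(set())
    if selection == "union":
        chosen = set().union(*per_exp)
    elif selection == "intersection":
        chosen = set.intersection(*per_exp) if per_exp else set()
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if not chosen:
        raise EmptySelection("no instruments selectable for any exposure")

    # joint re-clump keyed by min p across exposures
    frames = [ss.df[ss.df["snp_id"].isin(chosen)] for ss in exposures]
    minp = pd.concat(frames)[["snp_id", "chrom", "pos", "effect_allele",
                              "other_allele", "eaf", "beta", "se", "pval", "n"]]
    minp = minp.sort_values("pval", kind="stable").drop_duplicates("snp_id")
    joint = dataclasses.replace(exposures[0], df=minp.reset_index(drop=True),
                                trait_id="joint", load_report=None)
    if panel is not None:
        joint = clump(joint, panel, cfg.clump_r2, cfg.clump_kb)
    chosen = set(joint.df["snp_id"])

    # harmonize each exposure and the outcome onto the first exposure's alleles
    ref = exposures[0].subset(chosen)
    h_out = harmonize(ref, outcome, cfg.palindrome_maf_max)
    rows = h_out.df[["snp_id", "effect_allele", "other_allele",
                     "beta_exp", "se_exp", "beta_out", "se_out"]].rename(
        columns={"beta_exp": "beta_exp1", "se_exp": "se_exp1"})
    for i, ss in enumerate(exposures[1:], start=2):
        h_i = harmonize(ref, ss, cfg.palindrome_maf_max)
        # h_i rows are oriented on the reference exposure; merge on snp_id
        # and re-express on the allele orientation used by h_out
        sub = h_i.df[["snp_id", "effect_allele", "beta_out", "se_out"]].rename(
            columns={"beta_out": f"beta_exp{i}", "se_out": f"se_exp{i}",
                     "effect_allele": "ea_i"})
        rows = rows.merge(sub, on="snp_id", how="inner")
        flip = rows["ea_i"] != rows["effect_allele"]
        rows.loc[flip, f"beta_exp{i}"] *= -1.0
        rows = rows.drop(columns=["ea_i"])

    rows = rows.reset_index(drop=True)
    if rows.empty:
        raise EmptySelection("no SNPs shared across all traits after "
                             "harmonization")
    m = MvmrSet(exposure_ids=[ss.trait_id for ss in exposures],
                outcome_id=outcome.trait_id, df=rows)
    X, _, _, _ = m.design()
    _check_rank(X)
    return m


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, df_resid: int,
         effects_model: str = "auto"):
    sw = np.sqrt(w)
    Xw, yw = X * sw[:, None], y * sw
    xtx = Xw.T @ Xw
    xtx_inv = np.linalg.pinv(xtx)
    coef = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ coef
    q = float(resid @ resid)
    phi = 1.0
    if effects_model != "fixed" and df_resid > 0:
        phi = max(1.0, q / df_resid)
    ses = np.sqrt(np.diag(xtx_inv) * phi)
    return coef, ses, q


def _wls_debiased(X, sx, y, w, df_resid, effects_model="auto"):
    """Weighted normal equations with the exposure-effect sampling
    variance subtracted from the Gram matrix (errors-in-variables
    correction)."""
    Xw = X * w[:, None]
    A = X.T @ Xw - np.diag(np.sum(sx ** 2 * w[:, None], axis=0))
    b = Xw.T @ y
    try:
        a_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(str(exc)) from exc
    coef = a_inv @ b
    resid = (y - X @ coef) * np.sqrt(w)
    q = float(resid @ resid)
    phi = 1.0
    if effects_model != "fixed" and df_resid > 0:
        phi = max(1.0, q / df_resid)
    gram = X.T @ (X * w[:, None])
    cov = a_inv @ gram @ a_inv.T
    ses = np.sqrt(np.diag(cov) * phi)
    return coef, ses, q


def conditional_f(m: MvmrSet) -> np.ndarray:
    """Conditional instrument-strength F per exposure (informational).

    Regresses each exposure's SNP effects on the others' with IVW weights;
    the conditional F is the mean weighted squared residual scaled by the
    exposure's own sampling variance.
    """
    X, sx, _, byse = m.design()
    w = 1.0 / byse ** 2
    k = X.shape[1]
    out = np.empty(k)
    for i in range(k):
        others = np.delete(X, i, axis=1)
        if others.shape[1]:
            sw = np.sqrt(w)[:, None]
            coef, *_ = np.linalg.lstsq(others * sw, X[:, i] * sw.ravel(),
                                       rcond=None)
            resid = X[:, i] - others @ coef
        else:
            resid = X[:, i]
        out[i] = float(np.mean(resid ** 2 / sx[:, i] ** 2))
    return out


def mvmr_ivw(m: MvmrSet, effects_model: str = "auto",
             debias: bool = False) -> list[MREstimate]:
    """Multivariable IVW: weighted regression of outcome effects on all
    exposures' effects without intercept, weights 1/se_out^2, with the
    multiplicative random-effects SE inflation (``effects_model='fixed'``
    disables it).

    ``debias=True`` subtracts the exposure-side sampling covariance from
    the weighted normal equations (the multivariable analogue of debiased
    IVW): measurement error in one exposure's effects otherwise attenuates
    its own coefficient and leaks signal into correlated co-exposures.
    """
    X, sx, y, byse = m.design()
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more SNPs ({n}) than exposures ({k})")
    _check_rank(X)
    if debias:
        coef, ses, q = _wls_debiased(X, sx, y, 1.0 / byse ** 2, n - k,
                                     effects_model)
    else:
        coef, ses, q = _wls(X, y, 1.0 / byse ** 2, n - k, effects_model)
    cond_f = conditional_f(m)
    return [_finish(f"mvmr_ivw[{m.exposure_ids[i]}]", coef[i], ses[i], n,
                    {"q": q, "q_df": n - k, "conditional_f": float(cond_f[i]),
                     "q_pval": float(stats.chi2.sf(q, n - k))})
            for i in range(k)]


def mvmr_egger(m: MvmrSet, orient_on: str | None = None) -> list[MREstimate]:
    """Multivariable MR-Egger: adds an intercept as the pleiotropy check.

    Rows are oriented so the chosen exposure's effects are non-negative
    (defaults to the first exposure); slopes are reported per exposure and
    every estimate's extras carry the shared intercept test.
    """
    X, _, y, byse = m.design()
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need more SNPs ({n}) than exposures + 1 ({k + 1})")
    idx = 0 if orient_on is None else m.exposure_ids.index(orient_on)
    sign = np.where(X[:, idx] < 0, -1.0, 1.0)
    Xo, yo = X * sign[:, None], y * sign
    D = np.column_stack([np.ones(n), Xo])
    coef, ses, q = _wls(D, yo, 1.0 / byse ** 2, n - k - 1)
    icpt, icpt_se = float(coef[0]), float(ses[0])
    icpt_p = float(2.0 * stats.norm.sf(abs(icpt) / icpt_se))
    extras = {"intercept": icpt, "intercept_se": icpt_se,
              "intercept_pval": icpt_p, "q": q, "q_df": n - k - 1}
    return [_finish(f"mvmr_egger[{m.exposure_ids[i]}]", coef[i + 1],
                    ses[i + 1], n, extras) for i in range(k)]
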