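"""Sensitivity battery for univariable MR results.

Six checks, each summarized as a machine-readable flag:

1. cross-method agreement (computed by the caller from the estimator suite);
2. Cochran's Q heterogeneity test on the IVW ratio estimates;
3. horizontal pleiotropy via the MR-Egger intercept p-value and the
   MR-PRESSO global test p-value;
4. MR-PRESSO outlier exclusion and re-analysis;
5. leave-one-out IVW, flagging results driven by a single SNP;
6. reverse MR (outcome as exposure) for reverse causation.

Flag conventions (configurable alpha = 0.05): heterogeneity when Q p < alpha;
pleiotropy when either the Egger-intercept p or the PRESSO global p < alpha;
outliers when PRESSO flags SNPs and the corrected estimate disagrees with
the raw one in sign or significance; reverse causation when the reverse IVW
p < alpha or fewer than half the instruments survive Steiger filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from netmr import estimators as est
from netmr.instruments import (EmptySelection, InstrumentConfig,
                               InstrumentSet, build_instrument_set)


@dataclass
class SensitivityReport:
    """Aggregated sensitivity statistics and their boolean flags."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_p: float
    presso_global_p: float
    presso_outliers: list[int]
    presso_corrected: est.MREstimate | None
    loo_estimates: pd.DataFrame
    loo_driver_flag: bool
    steiger_kept: int
    steiger_dropped: int
    reverse_ivw: est.MREstimate | None
    reverse_evaluable: bool
    alpha: float = 0.05
    flags: dict = field(default_factory=dict)

    def compute_flags(self, raw_ivw: est.MREstimate) -> dict:
        """Re-derive the flags from the stored statistics (pure function)."""
        a = self.alpha
        heterogeneity = self.q_pval < a
        pleiotropy = (self.egger_intercept_p < a
                      or self.presso_global_p < a)
        if not self.presso_outliers:
            outliers = False
        elif self.presso_corrected is None:
            outliers = True
        else:
            c = self.presso_corrected
            same_sign = np.sign(c.beta) == np.sign(raw_ivw.beta)
            same_sig = (c.pval < a) == (raw_ivw.pval < a)
            outliers = not (same_sign and same_sig)
        total = self.steiger_kept + self.steiger_dropped
        steiger_ok = total == 0 or self.steiger_kept >= 0.5 * total
        if not self.reverse_evaluable:
            reverse = False
        else:
            reverse = (self.reverse_ivw.pval < a) or not steiger_ok
        return {"heterogeneity": bool(heterogeneity),
                "pleiotropy": bool(pleiotropy),
                "outliers": bool(outliers),
                "reverse_causation": bool(reverse),
                "single_snp_driver": bool(self.loo_driver_flag)}


def cochran_q(h) -> tuple[float, int, float]:
    """Cochran's Q over Wald ratios with IVW weights; p from chi2(n-1)."""
    bx, bxse, by, byse = est._unpack(h)
    est._require(len(bx), 2, "cochran_q")
    beta, _, q = est._ivw_core(bx, by, byse)
    df = len(bx) - 1
    return float(q), df, float(stats.chi2.sf(q, df))


def leave_one_out(h, alpha: float = 0.05):
    """IVW re-estimated with each SNP left out in turn.

    The driver flag is set when the full-set IVW is significant at
    ``alpha`` but some leave-one-out estimate is not: the signal then
    hinges on a single SNP.
    """
    bx, bxse, by, byse = est._unpack(h)
    n = len(bx)
    est._require(n, 3, "leave_one_out")
    full = est.ivw((bx, bxse, by, byse))
    rows = []
    for j in range(n):
        m = np.ones(n, dtype=bool)
        m[j] = False
        e = est.ivw((bx[m], bxse[m], by[m], byse[m]))
        rows.append({"left_out": j, "beta": e.beta, "se": e.se,
                     "pval": e.pval})
    loo = pd.DataFrame(rows)
    driver = bool(full.pval < alpha and (loo["pval"] >= alpha).any())
    return loo, driver


def reverse_mr(exposure, outcome, panel, config: InstrumentConfig | None = None):
    """IVW of outcome -> exposure after re-running the selection cascade.

    Returns ``(estimate or None, evaluable flag)``; an empty reverse
    instrument set yields ``(None, False)`` rather than an error.
    """
    try:
        inst = build_instrument_set(outcome, exposure, panel, config)
        if inst.n_snps < 2:
            return None, False
        return est.ivw(inst), True
    except EmptySelection:
        return None, False


def run_sensitivity_suite(inst: InstrumentSet, exposure, outcome, panel,
                          config: InstrumentConfig | None = None,
                          alpha: float = 0.05, seed: int = 0,
                          presso_nsim: int = 1000) -> SensitivityReport:
    """Assemble the full sensitivity report for one exposure-outcome pair."""
    q, df, q_p = cochran_q(inst)
    eg = est.egger(inst) if inst.n_snps >= 3 else None
    pr = est.mr_presso(inst, n_sim=presso_nsim, seed=seed) \
        if inst.n_snps >= 4 else None
    loo, driver = leave_one_out(inst, alpha)
    rev, rev_ok = reverse_mr(exposure, outcome, panel, config)

    steiger_dropped = sum(n for name, n in inst.provenance
                          if name.startswith("steiger"))
    report = SensitivityReport(
        q_stat=q, q_df=df, q_pval=q_p,
        egger_intercept=eg.extras["intercept"] if eg else float("nan"),
        egger_intercept_p=eg.extras["intercept_pval"] if eg else 1.0,
        presso_global_p=pr.extras["global_pval"] if pr else 1.0,
        presso_outliers=pr.extras["outlier_indices"] if pr else [],
        presso_corrected=pr,
        loo_estimates=loo, loo_driver_flag=driver,
        steiger_kept=inst.n_snps, steiger_dropped=steiger_dropped,
        reverse_ivw=rev, reverse_evaluable=rev_ok, alpha=alpha)
    report.flags = report.compute_flags(est.ivw(inst))
    return report
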