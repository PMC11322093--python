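"""Panel-scale orchestration: UVMR screen, evidence tiers, mediation.

The screen runs the full instrument cascade and nine-estimator suite for
every exposure against one outcome, gates positives through the
sensitivity battery, labels evidence tiers with a Bonferroni denominator
equal to the number of exposures actually screened, and (in the full
study) runs two-step mediation for every tier-passing pair and candidate
mediator.  Per-pair failures are isolated: one pair's error never touches
another pair's numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from netmr import estimators as est
from netmr.instruments import (EmptySelection, InstrumentConfig,
                               build_instrument_set)
from netmr.mediation import MediationResult, classify_evidence, run_network_mr
from netmr.sensitivity import run_sensitivity_suite

log = logging.getLogger("netmr")

#: secondary methods counted for "probable causality" support
SECONDARY = ("ml", "wm", "egger", "presso")
SUPPLEMENTARY = ("cml", "conmix", "divw", "raps")


@dataclass
class PairResult:
    exposure_id: str
    outcome_id: str
    evaluable: bool
    estimates: dict = field(default_factory=dict)
    sensitivity: object = None
    label: object = None
    note: str = ""


@dataclass
class ScreenResult:
    """One row per (exposure, outcome) pair."""

    pairs: list[PairResult]
    n_exposures: int

    def table(self) -> pd.DataFrame:
        """Long-format report: one row per pair and method."""
        rows = []
        for p in self.pairs:
            if not p.evaluable:
                rows.append({"exposure": p.exposure_id,
                             "outcome": p.outcome_id, "method": "-",
                             "n_snp": 0, "pval": float("nan"),
                             "beta": float("nan"), "ci_low": float("nan"),
                             "ci_high": float("nan"),
                             "judgment": "not evaluable"})
                continue
            for name, e in p.estimates.items():
                if e is None:
                    continue
                rows.append({"exposure": p.exposure_id,
                             "outcome": p.outcome_id, "method": name,
                             "n_snp": e.n_snp, "pval": e.pval,
                             "beta": e.beta, "ci_low": e.ci_low,
                             "ci_high": e.ci_high,
                             "judgment": p.label.tier if name == "ivw"
                             else ""})
        return pd.DataFrame(rows)


def analyse_pair(exposure, outcome, panel, config=None, seed: int = 0,
                 methods=None, sensitivity: bool = True,
                 n_exposures: int = 1, alpha: float = 0.05,
                 presso_nsim: int = 1000, wm_nboot: int = 1000) -> PairResult:
    """Full cascade, estimator suite, sensitivity and tier for one pair."""
    cfg = config or InstrumentConfig()
    methods = list(methods or est.METHODS)
    try:
        inst = build_instrument_set(exposure, outcome, panel, cfg)
    except EmptySelection as exc:
        for name, removed in exc.provenance:
            log.info("%s->%s filter=%s removed=%d", exposure.trait_id,
                     outcome.trait_id, name, removed)
        return PairResult(exposure.trait_id, outcome.trait_id,
                          evaluable=False, note=str(exc))
    for name, removed in inst.provenance:
        log.info("%s->%s filter=%s removed=%d", exposure.trait_id,
                 outcome.trait_id, name, removed)

    kwargs = {"wm": {"n_boot": wm_nboot, "seed": seed},
              "presso": {"n_sim": presso_nsim, "seed": seed},
              "cml": {"seed": seed}}
    estimates: dict[str, est.MREstimate | None] = {}
    for name in methods:
        try:
            estimates[name] = est.METHODS[name](inst, **kwargs.get(name, {}))
        except (est.InsufficientInstrumentsError, est.NumericalFailureError,
                est.WeakInstrumentSignal) as exc:
            log.warning("%s->%s method=%s failed: %s", exposure.trait_id,
                        outcome.trait_id, name, exc)
            estimates[name] = None

    sens = None
    flags = {}
    if sensitivity and estimates.get("ivw") is not None:
        sens = run_sensitivity_suite(inst, exposure, outcome, panel, cfg,
                                     alpha, seed, presso_nsim)
        flags = sens.flags
    label = None
    if estimates.get("ivw") is not None:
        secondary = {k: estimates.get(k) for k in SECONDARY}
        label = classify_evidence(estimates["ivw"], secondary, flags,
                                  n_exposures=n_exposures, alpha=alpha)
    return PairResult(exposure.trait_id, outcome.trait_id, evaluable=True,
                      estimates=estimates, sensitivity=sens, label=label)


def run_uvmr_screen(exposures, outcome, panel, config=None, seed: int = 0,
                    methods=None, sensitivity: bool = True,
                    alpha: float = 0.05, presso_nsim: int = 1000,
                    wm_nboot: int = 1000) -> ScreenResult:
    """Screen many exposures against one outcome.

    The Bonferroni denominator for the "causality" tier is the number of
    exposures screened.  Exceptions in one pair are caught, logged and
    reported as "not evaluable" without touching the other pairs.
    """
    n_exp = len(exposures)
    pairs = []
    for ss in exposures:
        try:
            pairs.append(analyse_pair(ss, outcome, panel, config, seed,
                                      methods, sensitivity, n_exp, alpha,
                                      presso_nsim, wm_nboot))
        except Exception as exc:  # pair isolation
            log.error("pair %s->%s failed: %s", ss.trait_id,
                      outcome.trait_id, exc)
            pairs.append(PairResult(ss.trait_id, outcome.trait_id,
                                    evaluable=False, note=str(exc)))
    return ScreenResult(pairs=pairs, n_exposures=n_exp)


def run_full_study(exposures, mediators, outcome, panel, config=None,
                   seed: int = 0, alpha: float = 0.05,
                   sensitivity: bool = True, presso_nsim: int = 1000,
                   wm_nboot: int = 1000):
    """Screen, then mediation for tier-passing exposures.

    Returns ``(ScreenResult, list[MediationResult])``; the mediation table
    covers every (tier-passing exposure, candidate mediator) pair.
    """
    screen = run_uvmr_screen(exposures, outcome, panel, config, seed,
                             sensitivity=sensitivity,
                             alpha=alpha, presso_nsim=presso_nsim,
                             wm_nboot=wm_nboot)
    by_id = {ss.trait_id: ss for ss in exposures}
    med_results: list[MediationResult] = []
    for pair in screen.pairs:
        if not pair.evaluable or pair.label is None or \
                pair.label.tier == "none":
            continue
        for med in mediators:
            med_results.append(run_network_mr(by_id[pair.exposure_id], med,
                                              outcome, panel, config, alpha,
                                              seed))
    return screen, med_results


def mediation_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"exposure": r.exposure_id, "mediator": r.mediator_id,
               "outcome": r.outcome_id, "evaluable": r.evaluable}
        if r.evaluable:
            row.update({
                "beta1": r.beta1.beta, "beta1_se": r.beta1.se,
                "beta2": r.beta2.beta, "beta2_se": r.beta2.se,
                "total": r.total.beta, "total_se": r.total.se,
                "indirect": r.indirect.beta, "indirect_se": r.indirect.se,
                "screen_passed": r.screen.passed,
                "proportion": r.proportion.beta if r.proportion else
                float("nan"),
                "proportion_ci_low": r.proportion.ci[0] if r.proportion else
                float("nan"),
                "proportion_ci_high": r.proportion.ci[1] if r.proportion else
                float("nan")})
        else:
            row["note"] = r.note
        rows.append(row)
    return pd.DataFrame(rows)
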