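"""Two-step (network) MR mediation calculus and the evidence-tier classifier.

The mediation pathway exposure -> mediator -> outcome is quantified in two
steps: beta1, the exposure's effect on the mediator (univariable MR), and
beta2, the mediator's effect on the outcome conditional on the exposure
(multivariable MR).  The indirect effect is the product beta1*beta2 with a
first-order delta-method SE; the mediation proportion divides the indirect
effect by the total (univariable exposure -> outcome) effect.

Evidence tiers follow a pre-registered rule: "probable causality" requires
a significant primary (IVW) estimate supported by at least three of four
secondary methods with clean sensitivity flags; "causality" additionally
requires the IVW p-value to clear a Bonferroni bar of 0.05 divided by the
number of exposures screened (196 for the full named-taxa panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from netmr import estimators as est
from netmr.instruments import (EmptySelection, InstrumentConfig,
                               build_instrument_set)
from netmr.mvmr import build_mvmr_set, mvmr_ivw
from netmr.sensitivity import SensitivityReport, run_sensitivity_suite

Z95 = stats.norm.ppf(0.975)


@dataclass
class Estimate:
    """A bare (beta, se) pair with derived CI and p."""

    beta: float
    se: float

    @property
    def ci(self):
        return self.beta - Z95 * self.se, self.beta + Z95 * self.se

    @property
    def pval(self) -> float:
        if self.se <= 0:
            return 1.0
        return float(2.0 * stats.norm.sf(abs(self.beta) / self.se))


def mediation_effect(beta1, se1, beta2, se2) -> Estimate:
    """Indirect effect beta1*beta2 with first-order delta-method SE.

    Treats the two-step estimates as independent (they come from separate
    regressions on separate samples):
    SE = sqrt(beta2^2 se1^2 + beta1^2 se2^2).
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    ie = beta1 * beta2
    se = float(np.sqrt(beta2 ** 2 * se1 ** 2 + beta1 ** 2 * se2 ** 2))
    return Estimate(float(ie), se)


def mediation_effect_mc(beta1, se1, beta2, se2, n_draws: int = 10_000,
                        seed: int = 0) -> Estimate:
    """Monte-Carlo cross-check of the delta-method SE for beta1*beta2."""
    rng = np.random.default_rng(seed)
    prod = rng.normal(beta1, se1, n_draws) * rng.normal(beta2, se2, n_draws)
    return Estimate(float(np.mean(prod)), float(np.std(prod, ddof=1)))


def mediation_proportion(indirect: Estimate, total: Estimate,
                         method: str = "delta") -> Estimate:
    """Proportion mediated = indirect / total, with a delta-method CI.

    The ratio variance treats the two estimates as independent:
    Var ~= Var(IE)/TE^2 + IE^2 Var(TE)/TE^4.  ``method='montecarlo'``
    replaces the delta SE with a 10,000-draw simulation SE.
    """
    if total.beta == 0:
        raise ZeroDivisionError("mediation proportion undefined: total "
                                "effect is zero")
    prop = indirect.beta / total.beta
    if method == "delta":
        var = (indirect.se ** 2 / total.beta ** 2
               + indirect.beta ** 2 * total.se ** 2 / total.beta ** 4)
        se = float(np.sqrt(var))
    elif method == "montecarlo":
        rng = np.random.default_rng(0)
        draws = (rng.normal(indirect.beta, indirect.se, 10_000)
                 / rng.normal(total.beta, total.se, 10_000))
        se = float(np.std(draws, ddof=1))
    else:
        raise ValueError(f"unknown proportion CI method {method!r}")
    return Estimate(float(prop), se)


@dataclass
class ScreenDecision:
    """Three mediator criteria with machine-readable reasons."""

    passed: bool
    criteria: dict
    reasons: list[str]


def screen_mediators(p_exp_to_med: float, p_med_on_out: float,
                     indirect_sign: float, total_sign: float,
                     alpha: float = 0.05) -> ScreenDecision:
    """Apply the three mediator criteria.

    1. the exposure influences the mediator (UVMR p < alpha);
    2. the mediator affects the outcome after adjustment (MVMR p < alpha);
    3. the indirect effect's sign matches the total effect's.
    """
    c1 = p_exp_to_med < alpha
    c2 = p_med_on_out < alpha
    c3 = np.sign(indirect_sign) == np.sign(total_sign) and indirect_sign != 0
    reasons = []
    if not c1:
        reasons.append("exposure does not influence mediator "
                       f"(p = {p_exp_to_med:.3g})")
    if not c2:
        reasons.append("mediator does not independently affect outcome "
                       f"(p = {p_med_on_out:.3g})")
    if not c3:
        reasons.append("indirect effect direction inconsistent with total")
    return ScreenDecision(passed=bool(c1 and c2 and c3),
                          criteria={"exposure_to_mediator": bool(c1),
                                    "mediator_to_outcome": bool(c2),
                                    "sign_consistency": bool(c3)},
                          reasons=reasons)


@dataclass
class EvidenceLabel:
    """Tiered causal-evidence label for one exposure-outcome pair."""

    tier: str  # none | probable_causality | causality
    support_count: int
    bonferroni_threshold: float
    ivw_pval: float
    flags: dict = field(default_factory=dict)


def classify_evidence(primary: est.MREstimate,
                      secondary: dict[str, est.MREstimate | None],
                      sens_flags: dict[str, bool] | None = None,
                      n_exposures: int = 196,
                      alpha: float = 0.05) -> EvidenceLabel:
    """Label a result none / probable_causality / causality.

    "Probable causality": IVW p < alpha, at least three of the four
    secondary methods support it (p < alpha with the same effect sign),
    and no sensitivity flag (heterogeneity, pleiotropy, outliers, reverse
    causation) is raised.  "Causality" additionally requires
    IVW p < alpha / n_exposures.  Missing secondary estimates count as
    unsupportive.
    """
    flags = dict(sens_flags or {})
    gating = {k: flags.get(k, False) for k in
              ("heterogeneity", "pleiotropy", "outliers", "reverse_causation")}
    support = 0
    for e in secondary.values():
        if e is None:
            continue
        if e.pval < alpha and np.sign(e.beta) == np.sign(primary.beta):
            support += 1
    bonf = alpha / n_exposures
    probable = (primary.pval < alpha and support >= 3
                and not any(gating.values()))
    tier = "none"
    if probable:
        tier = "causality" if primary.pval < bonf else "probable_causality"
    return EvidenceLabel(tier=tier, support_count=support,
                         bonferroni_threshold=bonf, ivw_pval=primary.pval,
                         flags=gating)


@dataclass
class MediationResult:
    """Full two-step mediation output for one exposure/mediator/outcome."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: Estimate | None
    beta2: Estimate | None
    total: Estimate | None
    indirect: Estimate | None
    proportion: Estimate | None
    screen: ScreenDecision | None
    evaluable: bool = True
    note: str = ""
    sensitivity: dict = field(default_factory=dict)


def run_network_mr(exposure, mediator, outcome, panel,
                   config: InstrumentConfig | None = None,
                   alpha: float = 0.05, seed: int = 0,
                   sensitivity: bool = False,
                   proportion_method: str = "delta") -> MediationResult:
    """Orchestrate the two-step mediation analysis.

    Computes the total effect (UVMR exposure -> outcome), beta1 (UVMR
    exposure -> mediator), beta2 (MVMR mediator -> outcome adjusted for the
    exposure), the mediator screen, the indirect effect and the mediation
    proportion.  An empty instrument set on any leg returns a structured
    "not evaluable" result.
    """
    import dataclasses

    from netmr.estimators import InsufficientInstrumentsError

    cfg = config or InstrumentConfig()
    # on the exposure -> mediator leg a valid instrument is *expected* to
    # associate with the mediator (it sits downstream), so the
    # outcome-association exclusion is suspended there; Steiger filtering
    # still guards the direction
    med_cfg = dataclasses.replace(cfg, outcome_p_threshold=0.0)

    def uvmr(exp, out, c):
        inst = build_instrument_set(exp, out, panel, c)
        e = est.ivw(inst)
        return Estimate(e.beta, e.se), inst

    try:
        total, inst_total = uvmr(exposure, outcome, cfg)
        beta1, inst_b1 = uvmr(exposure, mediator, med_cfg)
        mset = build_mvmr_set([exposure, mediator], outcome, panel, cfg)
        coefs = mvmr_ivw(mset)
        beta2 = Estimate(coefs[1].beta, coefs[1].se)
    except (EmptySelection, InsufficientInstrumentsError) as exc:
        return MediationResult(
            exposure_id=exposure.trait_id, mediator_id=mediator.trait_id,
            outcome_id=outcome.trait_id, beta1=None, beta2=None, total=None,
            indirect=None, proportion=None, screen=None, evaluable=False,
            note=f"not evaluable: {exc}")

    indirect = mediation_effect(beta1.beta, beta1.se, beta2.beta, beta2.se)
    screen = screen_mediators(beta1.pval, beta2.pval, indirect.beta,
                              total.beta, alpha)
    proportion = None
    if screen.passed and total.beta != 0:
        proportion = mediation_proportion(indirect, total, proportion_method)

    sens = {}
    if sensitivity:
        sens["exposure_outcome"] = run_sensitivity_suite(
            inst_total, exposure, outcome, panel, cfg, alpha, seed)
        sens["exposure_mediator"] = run_sensitivity_suite(
            inst_b1, exposure, mediator, panel, med_cfg, alpha, seed)

    return MediationResult(
        exposure_id=exposure.trait_id, mediator_id=mediator.trait_id,
        outcome_id=outcome.trait_id, beta1=beta1, beta2=beta2, total=total,
        indirect=indirect, proportion=proportion, screen=screen,
        sensitivity=sens)
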