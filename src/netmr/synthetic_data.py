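"""Synthetic two-sample GWAS summary statistics under a known causal graph.

The generator emulates the statistical shape of the study design the
package targets: a microbial-abundance exposure GWAS (modest sample size,
sub-genome-wide instruments), a risk-factor mediator GWAS and a disease
outcome GWAS (biobank-scale), linked by the linear causal graph

    exposure --beta_EM--> mediator --beta_MO--> outcome
        \\------------- beta_EO_direct ------------^

Per SNP j a true instrument effect gamma_j acts on the exposure; the
implied true associations are gamma_j*beta_EM on the mediator and
gamma_j*(beta_EO_direct + beta_EM*beta_MO) + alpha_j on the outcome, where
alpha_j is a horizontal-pleiotropy offset carried by a configurable
fraction of invalid SNPs.  Sampling noise follows the standardized-trait
approximation SE_j = 1/sqrt(2*MAF_j*(1-MAF_j)*n), independent across the
three (non-overlapping) samples.  Optional block-diagonal LD induces
correlated marginal effects plus a matching r^2 reference panel; an
optional reverse path makes a fraction of SNPs primarily outcome-associated
so that directionality filters have something to catch.

Defaults mirror the target study's scale: exposure n = 14,306
(microbiome consortium), mediator n = 218,369 (biobank risk factor),
outcome n = 462,341 (biobank disease), 100 instruments with mean F
targeted at 30, and the mediated-pathway effects beta_EM = 0.5,
beta_MO = 0.1, beta_EO_direct = 0.15 (true mediation proportion 25%).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from netmr.instruments import LdPanel
from netmr.summary_io import SummaryStats, two_sided_p

#: non-complementary allele pairs (no palindromes unless asked for)
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class PleiotropySpec:
    """Horizontal pleiotropy on the outcome leg.

    ``fraction_invalid`` of SNPs receive an offset alpha ~ N(mean_alpha,
    sd_alpha^2); ``inside_violation`` correlates alpha with the instrument
    strength gamma (correlation 0.5), breaking the InSIDE assumption that
    MR-Egger needs.
    """

    fraction_invalid: float = 0.0
    mean_alpha: float = 0.0
    sd_alpha: float = 0.0
    inside_violation: bool = False


@dataclass
class LdSpec:
    """Block-diagonal LD: equicorrelated blocks of ``block_size`` SNPs."""

    block_size: int = 1
    block_r2: float = 0.0


@dataclass
class SimConfig:
    """Full specification of one synthetic study."""

    n_snps: int = 100
    n_exp: int = 14_306
    n_med: int = 218_369
    n_out: int = 462_341
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_mean_f: float = 30.0
    beta_em: float = 0.5        # exposure -> mediator
    beta_mo: float = 0.1        # mediator -> outcome (conditional)
    beta_eo_direct: float = 0.15
    #: fraction of SNPs that are the mediator's own instruments (no effect
    #: on the exposure); without them the mediator's conditional effect is
    #: unidentifiable in multivariable MR, exactly as in real two-step
    #: designs where the mediator GWAS contributes its own loci
    mediator_instrument_fraction: float = 0.3
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    reverse_effect: float = 0.0
    reverse_fraction: float = 0.5
    ld: LdSpec = field(default_factory=LdSpec)
    seed: int = 0

    @property
    def beta_total(self) -> float:
        return self.beta_eo_direct + self.beta_em * self.beta_mo

    def __post_init__(self) -> None:
        if not (0 <= self.pleiotropy.fraction_invalid <= 1):
            raise ValueError("fraction_invalid must lie in [0, 1]")
        for n in (self.n_exp, self.n_med, self.n_out):
            if n < 100:
                raise ValueError("sample sizes must be >= 100")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.ld.block_size < 1 or not (0 <= self.ld.block_r2 < 1):
            raise ValueError("invalid LD block spec")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["pleiotropy"] = PleiotropySpec(**d.get("pleiotropy", {}))
        d["ld"] = LdSpec(**d.get("ld", {}))
        d["maf_range"] = tuple(d.get("maf_range", (0.05, 0.5)))
        return cls(**d)


@dataclass
class SimTruth:
    """Everything the generator knows: the acceptance oracle."""

    config: SimConfig
    gamma: np.ndarray            # marginal true SNP-exposure effects
    xi: np.ndarray               # mediator-instrument effects (0 elsewhere)
    alpha: np.ndarray            # pleiotropy offsets (0 for valid SNPs)
    delta: np.ndarray            # primary outcome effects on reverse SNPs
    invalid_indices: np.ndarray
    mediator_instrument_indices: np.ndarray
    exposure_instrument_indices: np.ndarray
    reverse_indices: np.ndarray
    beta_total: float
    true_proportion: float | None

    def write(self, path) -> None:
        d = {"beta_em": self.config.beta_em, "beta_mo": self.config.beta_mo,
             "beta_eo_direct": self.config.beta_eo_direct,
             "beta_total": self.beta_total,
             "true_proportion": self.true_proportion,
             "invalid_indices": self.invalid_indices.tolist(),
             "reverse_indices": self.reverse_indices.tolist(),
             "gamma": self.gamma.tolist(), "alpha": self.alpha.tolist()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def make_null_config(base: SimConfig) -> SimConfig:
    """Zero every causal effect, keeping pleiotropy and noise structure."""
    return dataclasses.replace(base, beta_em=0.0, beta_mo=0.0,
                               beta_eo_direct=0.0)


def _equicorr_noise(rng, n_snps, block_size, r):
    """Unit-variance noise with equicorrelation r inside LD blocks."""
    if block_size <= 1 or r == 0.0:
        return rng.standard_normal(n_snps)
    shared = rng.standard_normal(int(np.ceil(n_snps / block_size)))
    shared = np.repeat(shared, block_size)[:n_snps]
    own = rng.standard_normal(n_snps)
    return np.sqrt(r) * shared + np.sqrt(1 - r) * own


def simulate_arrays(config: SimConfig, rng: np.random.Generator | None = None):
    """Core generator returning plain arrays (fast path for replication
    loops).  Returns a dict with mafs, per-trait true effects, estimates
    and SEs, plus the :class:`SimTruth`."""
    cfg = config
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_snps

    maf = rng.uniform(*cfg.maf_range, size=n)
    se_exp = 1.0 / np.sqrt(2.0 * maf * (1 - maf) * cfg.n_exp)
    se_med = 1.0 / np.sqrt(2.0 * maf * (1 - maf) * cfg.n_med)
    se_out = 1.0 / np.sqrt(2.0 * maf * (1 - maf) * cfg.n_out)

    # instrument-effect SD calibrated so realized mean F ~= target:
    # E[F_j] = gamma^2/se^2 + 1 averaged over SNPs
    gamma_sd = np.sqrt(max(cfg.target_mean_f - 1.0, 0.1)
                       / np.mean(1.0 / se_exp ** 2))
    gamma_c = rng.normal(0.0, gamma_sd, size=n)

    # mediator's own instruments: no exposure effect, own effect xi with
    # strength matched to the exposure instruments'
    n_mi = int(round(cfg.mediator_instrument_fraction * n))
    mi = rng.choice(n, size=n_mi, replace=False) if n_mi else \
        np.empty(0, dtype=int)
    xi = np.zeros(n)
    if n_mi:
        xi[mi] = rng.normal(0.0, gamma_sd, size=n_mi)
        gamma_c[mi] = 0.0

    b, r2 = cfg.ld.block_size, cfg.ld.block_r2
    r = np.sqrt(r2)
    if b > 1 and r > 0:
        # marginal effect = causal + r * sum of block partners' causals
        gamma = gamma_c.copy()
        for start in range(0, n, b):
            blk = slice(start, min(start + b, n))
            s = gamma_c[blk].sum()
            gamma[blk] = gamma_c[blk] + r * (s - gamma_c[blk])
    else:
        gamma = gamma_c

    pl = cfg.pleiotropy
    n_invalid = int(round(pl.fraction_invalid * n))
    invalid = rng.choice(n, size=n_invalid, replace=False) if n_invalid else \
        np.empty(0, dtype=int)
    alpha = np.zeros(n)
    if n_invalid:
        z = rng.standard_normal(n_invalid)
        if pl.inside_violation and gamma_sd > 0:
            rho = 0.5
            z = rho * gamma[invalid] / gamma_sd + np.sqrt(1 - rho ** 2) * z
        alpha[invalid] = pl.mean_alpha + pl.sd_alpha * z

    delta = np.zeros(n)
    reverse = np.empty(0, dtype=int)
    if cfg.reverse_effect != 0.0:
        n_rev = int(round(cfg.reverse_fraction * n))
        reverse = rng.choice(n, size=n_rev, replace=False)
        delta[reverse] = rng.normal(0.0, gamma_sd, size=n_rev)
        gamma = gamma.copy()
        gamma[reverse] = cfg.reverse_effect * delta[reverse]

    true_exp = gamma
    true_med = gamma * cfg.beta_em + xi
    true_out = gamma * cfg.beta_total + xi * cfg.beta_mo + alpha + delta

    # estimation noise within an LD block is correlated with the LD r
    noise_e = _equicorr_noise(rng, n, b, r)
    noise_m = _equicorr_noise(rng, n, b, r)
    noise_o = _equicorr_noise(rng, n, b, r)
    bhat_exp = true_exp + se_exp * noise_e
    bhat_med = true_med + se_med * noise_m
    bhat_out = true_out + se_out * noise_o

    total = cfg.beta_total
    prop = (cfg.beta_em * cfg.beta_mo / total) if total != 0 else None
    not_exp = set(mi.tolist()) | set(reverse.tolist())
    exp_idx = np.array([j for j in range(n) if j not in not_exp], dtype=int)
    truth = SimTruth(config=cfg, gamma=gamma, xi=xi, alpha=alpha,
                     delta=delta, invalid_indices=np.sort(invalid),
                     mediator_instrument_indices=np.sort(mi),
                     exposure_instrument_indices=exp_idx,
                     reverse_indices=np.sort(reverse),
                     beta_total=total, true_proportion=prop)
    return {"maf": maf,
            "beta_exp": bhat_exp, "se_exp": se_exp,
            "beta_med": bhat_med, "se_med": se_med,
            "beta_out": bhat_out, "se_out": se_out,
            "truth": truth}


def _positions(cfg: SimConfig):
    """Lay blocks out far apart so clumping windows never span blocks."""
    n, b = cfg.n_snps, cfg.ld.block_size
    chroms, pos = [], []
    gap_within, gap_between = 5_000, 50_000_000
    for j in range(n):
        block, offset = divmod(j, b)
        chroms.append(str(block % 22 + 1))
        pos.append(1 + (block // 22) * gap_between + offset * gap_within)
    return np.array(chroms), np.array(pos, dtype=np.int64)


def _panel(cfg: SimConfig, snp_ids, chroms, pos) -> LdPanel:
    n, b, r2 = cfg.n_snps, cfg.ld.block_size, cfg.ld.block_r2
    mat = np.eye(n)
    if b > 1 and r2 > 0:
        for start in range(0, n, b):
            stop = min(start + b, n)
            mat[start:stop, start:stop] = r2
            np.fill_diagonal(mat[start:stop, start:stop], 1.0)
    positions = pd.DataFrame({"snp_id": snp_ids, "chrom": chroms,
                              "pos": pos})
    return LdPanel(snp_ids=list(snp_ids), r2=mat, positions=positions)


def _to_summary(trait_id, snp_ids, chroms, pos, ea, oa, eaf, beta, se, n):
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chroms, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": two_sided_p(beta, se),
        "n": float(n)})
    df["pval"] = df["pval"].clip(lower=np.nextafter(0, 1))
    return SummaryStats(trait_id=trait_id, df=df, sample_size=int(n))


def simulate_gwas_triplet(config: SimConfig):
    """Generate (exposure, mediator, outcome) summary statistics.

    Returns ``(exposure, mediator, outcome, panel, truth)``; fully
    reproducible from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    arr = simulate_arrays(cfg, rng)
    n = cfg.n_snps

    snp_ids = np.array([f"rs{j + 1:06d}" for j in range(n)])
    chroms, pos = _positions(cfg)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    flip = rng.random(n) < 0.5
    eaf = np.where(flip, 1.0 - arr["maf"], arr["maf"])

    exposure = _to_summary("sim_exposure", snp_ids, chroms, pos, ea, oa, eaf,
                           arr["beta_exp"], arr["se_exp"], cfg.n_exp)
    mediator = _to_summary("sim_mediator", snp_ids, chroms, pos, ea, oa, eaf,
                           arr["beta_med"], arr["se_med"], cfg.n_med)
    outcome = _to_summary("sim_outcome", snp_ids, chroms, pos, ea, oa, eaf,
                          arr["beta_out"], arr["se_out"], cfg.n_out)
    panel = _panel(cfg, snp_ids, chroms, pos)
    return exposure, mediator, outcome, panel, arr["truth"]


def spike_outliers(stats: SummaryStats, indices, shift_sd: float,
                   seed: int = 0) -> tuple[SummaryStats, list[int]]:
    """Shift chosen SNPs' effects by ``shift_sd`` standard errors.

    Returns a modified copy plus the list of planted outlier positions;
    p-values are recomputed for the shifted rows.
    """
    indices = list(indices)
    df = stats.df.copy()
    if indices and (min(indices) < 0 or max(indices) >= len(df)):
        raise IndexError("outlier index out of range")
    df.loc[indices, "beta"] = (df.loc[indices, "beta"]
                               + shift_sd * df.loc[indices, "se"])
    df.loc[indices, "pval"] = two_sided_p(df.loc[indices, "beta"],
                                          df.loc[indices, "se"])
    return dataclasses.replace(stats, df=df, load_report=None), indices
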