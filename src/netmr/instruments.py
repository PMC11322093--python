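"""Instrumental-variable selection for two-sample MR.

The selection cascade mirrors standard summary-level MR practice:

1. exposure significance filter (default p < 5e-5, the relaxed threshold
   used for microbial-abundance GWAS with few genome-wide hits) and a
   minor-allele-frequency floor (MAF >= 0.01);
2. greedy LD clumping against a reference panel (r^2 > 0.001 within
   10,000 kb removes the weaker SNP);
3. allele harmonization with the outcome (handled by
   :mod:`netmr.summary_io`), excluding ambiguous palindromes (MAF > 0.42);
4. exclusion of SNPs already associated with the outcome (p < 5e-5);
5. Steiger directionality filtering, keeping SNPs that explain more
   variance in the exposure than in the outcome.

Instrument strength is summarized by per-SNP F = (beta/se)^2 and its mean;
a mean F above 10 is the conventional bar for negligible weak-instrument
bias.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from netmr.summary_io import HarmonizedSet, SummaryStats, harmonize


class EmptySelection(Exception):
    """No instruments survive the cascade; carries the provenance trail."""

    def __init__(self, message: str, provenance=None):
        super().__init__(message)
        self.provenance = list(provenance or [])


class InsufficientSampleError(ValueError):
    """Sample size too small for the requested statistic."""


@dataclass
class LdPanel:
    """Squared-correlation reference panel for clumping.

    ``r2`` is a symmetric matrix with unit diagonal aligned to ``snp_ids``;
    ``positions`` maps each SNP to (chrom, pos).
    """

    snp_ids: list[str]
    r2: np.ndarray
    positions: pd.DataFrame  # columns snp_id, chrom, pos

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def index_of(self, snp_id: str) -> int | None:
        return self._index.get(snp_id)

    def write(self, matrix_path, positions_path, sep: str = "\t") -> None:
        pd.DataFrame(self.r2, columns=self.snp_ids).to_csv(
            matrix_path, sep=sep, index=False)
        self.positions.to_csv(positions_path, sep=sep, index=False)

    @classmethod
    def read(cls, matrix_path, positions_path) -> "LdPanel":
        mat = pd.read_csv(matrix_path, sep=None, engine="python")
        pos = pd.read_csv(positions_path, sep=None, engine="python")
        pos["chrom"] = pos["chrom"].astype(str)
        return cls(snp_ids=list(mat.columns), r2=mat.to_numpy(float),
                   positions=pos)


@dataclass
class InstrumentSet:
    """A harmonized set restricted to selected instruments, with diagnostics."""

    harmonized: HarmonizedSet
    per_snp_f: np.ndarray
    mean_f: float
    weak_flag: bool
    provenance: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return self.harmonized.n_snps

    def arrays(self):
        return self.harmonized.arrays()


# ---------------------------------------------------------------------------


def filter_significance(ss: SummaryStats, p_max: float = 5e-5,
                        maf_min: float = 0.01,
                        strict_missing_eaf: bool = False) -> SummaryStats:
    """Keep records with p < ``p_max`` and MAF >= ``maf_min``.

    Records lacking an EAF pass the MAF filter with a warning unless
    ``strict_missing_eaf`` is set.  Raises :class:`EmptySelection` when
    nothing survives.
    """
    df = ss.df
    keep = df["pval"] < p_max
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    has_eaf = df["eaf"].notna()
    keep &= np.where(has_eaf, maf >= maf_min, not strict_missing_eaf)
    out = df[keep].reset_index(drop=True)
    if out.empty:
        raise EmptySelection(
            f"no SNPs pass p < {p_max:g} and MAF >= {maf_min:g} for "
            f"{ss.trait_id!r}",
            provenance=[("significance/MAF", len(df))])
    return dataclasses.replace(ss, df=out, load_report=None)


def compute_f_statistics(ss_or_df, f_min: float = 10.0):
    """Per-SNP F = (beta/se)^2, mean F, and a weak-instrument flag.

    Returns ``(per_snp_f, mean_f, weak_flag)``; the flag is set when the
    mean F is at or below ``f_min``.
    """
    df = ss_or_df.df if isinstance(ss_or_df, SummaryStats) else ss_or_df
    beta = df["beta_exp"] if "beta_exp" in df else df["beta"]
    se = df["se_exp"] if "se_exp" in df else df["se"]
    f = (beta.to_numpy(float) / se.to_numpy(float)) ** 2
    mean_f = float(np.mean(f)) if len(f) else float("nan")
    return f, mean_f, (len(f) > 0 and mean_f <= f_min)


def clump(ss: SummaryStats, panel: LdPanel, r2_max: float = 0.001,
          window_kb: float = 10_000.0) -> SummaryStats:
    """Greedy LD clumping.

    Repeatedly selects the remaining SNP with the smallest p-value and
    removes all unselected SNPs on the same chromosome within ``window_kb``
    whose r^2 with it exceeds ``r2_max``.  Ties on p-value break by
    (chrom, pos, snp_id).  SNPs absent from the panel are dropped.
    """
    df = ss.df
    in_panel = df["snp_id"].map(lambda s: panel.index_of(s) is not None)
    df = df[in_panel].copy()
    if df.empty:
        raise EmptySelection(f"no candidate SNPs present in LD panel for "
                             f"{ss.trait_id!r}",
                             provenance=[("clump: absent from panel",
                                          int((~in_panel).sum()))])
    pos = panel.positions.set_index("snp_id")
    snp = df["snp_id"].to_numpy()
    chrom = pos.loc[snp, "chrom"].to_numpy(str)
    bp = pos.loc[snp, "pos"].to_numpy(float)
    pval = df["pval"].to_numpy(float)
    pidx = np.array([panel.index_of(s) for s in snp])

    order = sorted(range(len(snp)),
                   key=lambda i: (pval[i], chrom[i], bp[i], snp[i]))
    alive = np.ones(len(snp), dtype=bool)
    selected = np.zeros(len(snp), dtype=bool)
    window_bp = window_kb * 1000.0
    for i in order:
        if not alive[i]:
            continue
        selected[i] = True
        near = (alive & ~selected & (chrom == chrom[i])
                & (np.abs(bp - bp[i]) <= window_bp))
        near &= panel.r2[pidx[i], pidx] > r2_max
        alive[near] = False

    return dataclasses.replace(ss, df=df[selected].reset_index(drop=True),
                               load_report=None)


def exclude_outcome_associated(h: HarmonizedSet,
                               p_max: float = 5e-5) -> HarmonizedSet:
    """Drop harmonized rows whose outcome association has p < ``p_max``.

    Guards against instruments whose primary association is with the
    outcome (reverse-causation channel)."""
    mask = h.df["pval_out"] >= p_max
    removed = h.df.loc[~mask, ["snp_id"]].copy()
    removed["reason"] = f"outcome-associated (p < {p_max:g})"
    out = h.subset(mask)
    out = dataclasses.replace(
        out, dropped=pd.concat([h.dropped, removed], ignore_index=True))
    return out


def steiger_r2_from_p(pval, n):
    """Variance explained from a p-value and sample size.

    Inverts the 1-df F test: F = qf(1 - p; 1, n - 2), r^2 = F / (F + n - 2).
    This route needs no variance model, so binary outcomes are handled on
    the same footing as quantitative ones.
    """
    pval = np.clip(np.asarray(pval, dtype=float), 1e-300, 1.0)
    n = np.asarray(n, dtype=float)
    f = stats.f.isf(pval, 1, n - 2)
    # scipy's F quantile overflows below ~1e-16; the 1-df chi-square
    # quantile is the large-n limit and stays finite
    bad = ~np.isfinite(f)
    if np.any(bad):
        f = np.where(bad, stats.chi2.isf(pval, 1), f)
    return f / (f + n - 2.0)


def steiger_filter(h: HarmonizedSet, n_exp: int | None = None,
                   n_out: int | None = None, alpha: float = 0.05,
                   drop_uncertain: bool = False):
    """Directionality filter: keep SNPs explaining more exposure variance.

    Per SNP the variance explained in each trait is recovered from
    (p-value, sample size); a SNP is kept iff r2_exp > r2_out.  The report
    carries a z-test on the difference of Fisher-transformed correlations
    for two independent samples; SNPs whose directionality test has
    p > ``alpha`` are marked "uncertain" (kept by default when the point
    inequality favours the exposure, dropped under ``drop_uncertain``).

    Returns ``(filtered HarmonizedSet, per-SNP report DataFrame)``.
    """
    df = h.df
    ne = df["n_exp"].to_numpy(float) if n_exp is None else np.full(len(df), float(n_exp))
    no = df["n_out"].to_numpy(float) if n_out is None else np.full(len(df), float(n_out))
    if len(df) and (np.nanmin(ne) <= 3 or np.nanmin(no) <= 3):
        raise InsufficientSampleError("Steiger filtering needs n > 3 per trait")

    r2_exp = steiger_r2_from_p(df["pval_exp"], ne)
    r2_out = steiger_r2_from_p(df["pval_out"], no)
    z_exp = np.arctanh(np.sqrt(r2_exp))
    z_out = np.arctanh(np.sqrt(r2_out))
    z = (z_exp - z_out) / np.sqrt(1.0 / (ne - 3) + 1.0 / (no - 3))
    p_dir = 2.0 * stats.norm.sf(np.abs(z))

    forward = r2_exp > r2_out
    uncertain = p_dir > alpha
    keep = forward & ~uncertain if drop_uncertain else forward

    report = pd.DataFrame({
        "snp_id": df["snp_id"], "r2_exp": r2_exp, "r2_out": r2_out,
        "direction": np.where(forward, "true", "false"),
        "steiger_z": z, "steiger_p": p_dir,
        "uncertain": uncertain, "kept": keep,
    })
    removed = df.loc[~keep, ["snp_id"]].copy()
    removed["reason"] = "steiger: r2_out >= r2_exp" if not drop_uncertain \
        else "steiger filter"
    out = h.subset(keep)
    out = dataclasses.replace(
        out, dropped=pd.concat([h.dropped, removed], ignore_index=True))
    return out, report


@dataclass
class InstrumentConfig:
    """Tunables for the selection cascade."""

    p_threshold: float = 5e-5
    maf_min: float = 0.01
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    palindrome_maf_max: float = 0.42
    outcome_p_threshold: float = 5e-5
    steiger: bool = True
    steiger_alpha: float = 0.05
    steiger_drop_uncertain: bool = False
    f_min: float | None = None  # set to drop individual weak SNPs


def build_instrument_set(exposure: SummaryStats, outcome: SummaryStats,
                         panel: LdPanel | None,
                         config: InstrumentConfig | None = None) -> InstrumentSet:
    """Run the full cascade and return the selected instruments.

    Order: significance/MAF filter -> LD clumping -> harmonization with the
    outcome (palindrome rule) -> outcome-association exclusion -> Steiger
    filtering.  Provenance records the SNPs removed at each step.
    """
    cfg = config or InstrumentConfig()
    prov: list[tuple[str, int]] = []

    n0 = exposure.n_snps
    try:
        sig = filter_significance(exposure, cfg.p_threshold, cfg.maf_min)
    except EmptySelection as exc:
        raise EmptySelection(str(exc), provenance=prov + exc.provenance)
    prov.append(("significance/MAF", n0 - sig.n_snps))

    if panel is not None:
        try:
            clumped = clump(sig, panel, cfg.clump_r2, cfg.clump_kb)
        except EmptySelection as exc:
            raise EmptySelection(str(exc), provenance=prov + exc.provenance)
        prov.append(("LD clumping", sig.n_snps - clumped.n_snps))
    else:
        clumped = sig

    h = harmonize(clumped, outcome, cfg.palindrome_maf_max)
    prov.append(("harmonization", clumped.n_snps - h.n_snps))

    n_h = h.n_snps
    h = exclude_outcome_associated(h, cfg.outcome_p_threshold)
    prov.append(("outcome-associated", n_h - h.n_snps))

    if cfg.steiger:
        n_s = h.n_snps
        h, _ = steiger_filter(h, alpha=cfg.steiger_alpha,
                              drop_uncertain=cfg.steiger_drop_uncertain)
        prov.append(("steiger", n_s - h.n_snps))

    if cfg.f_min is not None and h.n_snps:
        f = (h.df["beta_exp"] / h.df["se_exp"]) ** 2
        n_f = h.n_snps
        h = h.subset(f.to_numpy() > cfg.f_min)
        prov.append((f"per-SNP F <= {cfg.f_min:g}", n_f - h.n_snps))

    if h.n_snps == 0:
        raise EmptySelection(
            f"no instruments survive the cascade for "
            f"{exposure.trait_id!r} -> {outcome.trait_id!r}", provenance=prov)

    per_f, mean_f, weak = compute_f_statistics(h.df)
    return InstrumentSet(harmonized=h, per_snp_f=per_f, mean_f=mean_f,
                         weak_flag=weak, provenance=prov)
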