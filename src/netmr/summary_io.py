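"""Reading, validating, writing and harmonizing GWAS summary statistics.

A summary-statistics table holds one row per SNP: identifier, chromosome,
position, effect allele, other allele, effect-allele frequency (EAF), the
per-allele effect estimate (log-odds for binary traits), its standard error,
a two-sided p-value and the per-SNP sample size.  Harmonization aligns two
traits' records onto shared SNPs and a common effect allele, resolving
strand flips and dropping ambiguous palindromes, and finally orients every
row so the exposure effect is non-negative (the convention under which the
MR-Egger intercept has a defined sign).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for the writer
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class EmptyInputError(ValueError):
    """No rows survived validation, or no SNPs are shared between traits."""


@dataclass
class LoadReport:
    """Accounting for one file load: rows read, kept and dropped by reason."""

    n_read: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if not self.dropped:
            return f"{self.n_kept} records, 0 dropped"
        parts = ", ".join(f"{k}: {v}" for k, v in self.dropped.items())
        return f"{self.n_kept} records, {self.n_dropped} dropped ({parts})"


@dataclass
class SummaryStats:
    """Per-SNP association records for a single trait.

    Records live in a :class:`pandas.DataFrame` with the canonical columns
    (``snp_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval,
    n``).  SNP identifiers are unique, standard errors strictly positive,
    alleles single bases from {A,C,G,T}.
    """

    trait_id: str
    df: pd.DataFrame
    sample_size: int | None = None
    load_report: LoadReport | None = None

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def subset(self, snp_ids) -> "SummaryStats":
        sub = self.df[self.df["snp_id"].isin(set(snp_ids))].reset_index(drop=True)
        return dataclasses.replace(self, df=sub, load_report=None)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing canonical columns: {missing}")


def two_sided_p(beta, se):
    """Two-sided normal p-value for beta/se (GWAS convention)."""
    z = np.abs(np.asarray(beta, dtype=float) / np.asarray(se, dtype=float))
    return 2.0 * stats.norm.sf(z)


def _coerce_frame(raw: pd.DataFrame, column_map: dict[str, str] | None,
                  trait_id: str, sample_size: int | None) -> tuple[pd.DataFrame, LoadReport]:
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items() if v in raw.columns}
    df = raw.rename(columns=rename)

    required = ["snp_id", "effect_allele", "other_allele", "beta", "se"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"trait {trait_id!r}: required column(s) {missing} absent "
            f"(have {list(df.columns)})"
        )
    for opt, default in [("eaf", np.nan), ("pval", np.nan), ("chrom", ""),
                         ("pos", 0), ("n", np.nan)]:
        if opt not in df.columns:
            df[opt] = default

    report = LoadReport(n_read=len(df))
    df = df.copy()
    for col in ("beta", "se", "eaf", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").fillna(0).astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)
    df["snp_id"] = df["snp_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        n = int(mask.sum())
        if n:
            report.dropped[reason] += n
            df = df[~mask]

    drop(df["beta"].isna() | df["se"].isna(), "missing beta/se")
    drop(df["se"] <= 0, "non-positive se")
    # biallelic SNPs only: single-base alleles, effect != other
    drop(~df["effect_allele"].isin(VALID_BASES)
         | ~df["other_allele"].isin(VALID_BASES), "non-SNP alleles")
    drop(df["effect_allele"] == df["other_allele"], "identical alleles")
    drop(df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1)),
         "eaf outside (0,1)")
    drop(df["pval"].notna() & ((df["pval"] <= 0) | (df["pval"] > 1)),
         "pval outside (0,1]")

    # back-fill missing p-values from beta/se
    need_p = df["pval"].isna()
    if need_p.any():
        df.loc[need_p, "pval"] = two_sided_p(df.loc[need_p, "beta"],
                                             df.loc[need_p, "se"])
        df.loc[need_p & (df["pval"] == 0), "pval"] = np.nextafter(0, 1)

    if sample_size is not None:
        df["n"] = df["n"].fillna(float(sample_size))

    # duplicate snp_id: keep the most significant row
    if df["snp_id"].duplicated().any():
        before = len(df)
        df = df.sort_values("pval", kind="stable").drop_duplicates("snp_id")
        report.dropped["duplicate snp_id"] += before - len(df)
        df = df.sort_index()

    df = df[CANONICAL_COLUMNS].reset_index(drop=True)
    report.n_kept = len(df)
    return df, report


def summary_stats_from_frame(raw: pd.DataFrame, trait_id: str,
                             column_map: dict[str, str] | None = None,
                             sample_size: int | None = None) -> SummaryStats:
    """Validate an in-memory table into a :class:`SummaryStats`."""
    df, report = _coerce_frame(raw, column_map, trait_id, sample_size)
    if df.empty:
        raise EmptyInputError(f"trait {trait_id!r}: no rows survived validation "
                              f"({report})")
    return SummaryStats(trait_id=trait_id, df=df, sample_size=sample_size,
                        load_report=report)


def read_summary_stats(path, trait_id: str,
                       column_map: dict[str, str] | None = None,
                       sample_size: int | None = None) -> SummaryStats:
    """Read a delimited GWAS summary-statistics file.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    trait_id
        Label attached to the resulting records.
    column_map
        Mapping from canonical names (``snp_id``, ``beta``, ...) to the
        file's column names.  Columns already canonically named need no
        entry.  ``snp_id, effect_allele, other_allele, beta, se`` are
        required; the rest are optional.
    sample_size
        Trait-level sample size used to back-fill a missing ``n`` column.
    """
    try:
        raw = pd.read_csv(path, sep=None, engine="python")
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise OSError(f"cannot read summary statistics from {path}: {exc}") from exc
    return summary_stats_from_frame(raw, trait_id, column_map, sample_size)


def write_summary_stats(ss: SummaryStats, path, sep: str = "\t") -> None:
    """Write records in the canonical column order."""
    ss.df[CANONICAL_COLUMNS].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

HARMONIZED_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "eaf_exp", "pval_exp", "n_exp",
    "beta_out", "se_out", "eaf_out", "pval_out", "n_out",
    "palindromic",
]


@dataclass
class HarmonizedSet:
    """Exposure/outcome records aligned to a shared effect allele.

    Every retained row expresses both traits' effects on the same effect
    allele and is oriented so ``beta_exp >= 0``.  ``dropped`` records the
    SNPs excluded during alignment together with the reason.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    dropped: pd.DataFrame  # columns: snp_id, reason

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        d = self.df
        return (d["beta_exp"].to_numpy(float), d["se_exp"].to_numpy(float),
                d["beta_out"].to_numpy(float), d["se_out"].to_numpy(float))

    def subset(self, mask) -> "HarmonizedSet":
        return dataclasses.replace(self, df=self.df[np.asarray(mask)]
                                   .reset_index(drop=True))

    def write(self, path, sep: str = "\t") -> None:
        df = self.df.copy()
        df["dropped_reason"] = ""
        if len(self.dropped):
            drp = self.dropped.copy()
            for col in df.columns:
                if col not in drp.columns:
                    drp[col] = np.nan
            drp["dropped_reason"] = drp.pop("reason")
            df = pd.concat([df, drp[df.columns]], ignore_index=True)
        df.to_csv(path, sep=sep, index=False)


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              palindrome_maf_max: float = 0.42) -> HarmonizedSet:
    """Align outcome records onto the exposure's effect alleles.

    For each shared SNP the outcome's alleles are matched to the exposure's
    directly, after an effect/other swap (negating the outcome beta and
    complementing the EAF), after strand complement, or after
    complement-plus-swap.  Palindromic SNPs (A/T, C/G) are ambiguous: those
    with minor-allele frequency above ``palindrome_maf_max`` in either trait
    are excluded; the remainder are strand-resolved by requiring both
    traits' EAFs to agree on which allele is minor (dropped when either EAF
    is missing).  Finally every retained row is oriented so the exposure
    effect is non-negative.
    """
    exp = exposure.df.set_index("snp_id")
    out = outcome.df.set_index("snp_id")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise EmptyInputError(
            f"no shared SNPs between {exposure.trait_id!r} and {outcome.trait_id!r}")

    rows, dropped = [], []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        pal = _is_palindromic(ea_e, oa_e)

        beta_o, eaf_o = o["beta"], o["eaf"]
        if (ea_o, oa_o) == (ea_e, oa_e):
            pass
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_o = -beta_o
            eaf_o = 1.0 - eaf_o if not pd.isna(eaf_o) else np.nan
        elif not pal and (COMPLEMENT[ea_o], COMPLEMENT[oa_o]) == (ea_e, oa_e):
            pass  # strand flip only
        elif not pal and (COMPLEMENT[ea_o], COMPLEMENT[oa_o]) == (oa_e, ea_e):
            beta_o = -beta_o
            eaf_o = 1.0 - eaf_o if not pd.isna(eaf_o) else np.nan
        else:
            dropped.append((snp, "irreconcilable alleles"))
            continue

        if pal:
            eaf_e = e["eaf"]
            if pd.isna(eaf_e) or pd.isna(eaf_o):
                dropped.append((snp, "palindrome with missing EAF"))
                continue
            maf = min(min(eaf_e, 1 - eaf_e), min(eaf_o, 1 - eaf_o))
            if (min(eaf_e, 1 - eaf_e) > palindrome_maf_max
                    or min(eaf_o, 1 - eaf_o) > palindrome_maf_max):
                dropped.append((snp, f"palindrome MAF > {palindrome_maf_max}"))
                continue
            # strand resolution: both EAFs must point at the same minor allele
            if (eaf_e < 0.5) != (eaf_o < 0.5):
                # outcome strand is flipped relative to exposure: on the
                # exposure's strand the outcome effect allele is the complement
                # of itself, i.e. the *other* exposure allele
                beta_o = -beta_o
                eaf_o = 1.0 - eaf_o
            _ = maf
        rows.append({
            "snp_id": snp, "chrom": e["chrom"], "pos": e["pos"],
            "effect_allele": ea_e, "other_allele": oa_e,
            "beta_exp": e["beta"], "se_exp": e["se"], "eaf_exp": e["eaf"],
            "pval_exp": e["pval"], "n_exp": e["n"],
            "beta_out": beta_o, "se_out": o["se"], "eaf_out": eaf_o,
            "pval_out": o["pval"], "n_out": o["n"],
            "palindromic": pal,
        })

    df = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    df = orient_positive_exposure(df)
    dropped_df = pd.DataFrame(dropped, columns=["snp_id", "reason"])
    return HarmonizedSet(exposure_id=exposure.trait_id,
                         outcome_id=outcome.trait_id,
                         df=df, dropped=dropped_df)


def orient_positive_exposure(df: pd.DataFrame) -> pd.DataFrame:
    """Flip rows so every exposure effect is >= 0.

    Negates both betas, swaps the allele labels and complements both EAFs on
    flipped rows; per-SNP Wald ratios beta_out/beta_exp are unchanged.
    """
    df = df.copy()
    flip = df["beta_exp"] < 0
    if flip.any():
        df.loc[flip, ["beta_exp", "beta_out"]] *= -1.0
        ea = df.loc[flip, "effect_allele"].copy()
        df.loc[flip, "effect_allele"] = df.loc[flip, "other_allele"]
        df.loc[flip, "other_allele"] = ea
        for col in ("eaf_exp", "eaf_out"):
            df.loc[flip, col] = 1.0 - df.loc[flip, col]
    return df
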