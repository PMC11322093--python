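"""Generate the synthetic study: GWAS summary statistics for a panel of
gut-microbiota exposures, one risk-factor mediator and one sleep-disorder
outcome, under a known exposure -> mediator -> outcome causal graph.

One exposure carries a real mediated effect on the outcome (total effect
0.04 on the log-odds scale, 25% of it through the mediator — the
magnitude of the reported microbiome-insomnia estimates); the remaining
panel members are null exposures sharing the same SNPs with independent
instrument effects.  Writes the per-trait summary files, the LD reference
panel and the generating truth under results/data/.
"""

import dataclasses
from pathlib import Path

import numpy as np

from netmr.summary_io import two_sided_p, write_summary_stats
from netmr.synthetic_data import SimConfig, simulate_gwas_triplet

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
N_NULL = 9
SEED = 20240901


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(n_snps=200, target_mean_f=60.0, beta_em=0.5,
                    beta_mo=0.02, beta_eo_direct=0.03, seed=SEED)
    exposure, mediator, outcome, panel, truth = simulate_gwas_triplet(cfg)

    exposure = dataclasses.replace(exposure, trait_id="taxon_causal")
    write_summary_stats(exposure, OUT / "taxon_causal.tsv")
    write_summary_stats(mediator, OUT / "mediator.tsv")
    write_summary_stats(outcome, OUT / "outcome.tsv")
    panel.write(OUT / "ld_r2.tsv", OUT / "ld_positions.tsv")
    truth.write(OUT / "truth.yaml")
    cfg.to_yaml(OUT / "sim_config.yaml")

    rng = np.random.default_rng(SEED + 1)
    for i in range(N_NULL):
        df = exposure.df.copy()
        se = df["se"].to_numpy()
        gamma = rng.normal(0, np.abs(exposure.df["beta"]).mean(), len(df))
        df["beta"] = gamma + rng.normal(0, se)
        df["pval"] = np.clip(two_sided_p(df["beta"], se),
                             np.nextafter(0, 1), 1)
        null = dataclasses.replace(exposure, trait_id=f"taxon_null_{i:02d}",
                                   df=df)
        write_summary_stats(null, OUT / f"{null.trait_id}.tsv")

    print(f"wrote 1 causal + {N_NULL} null exposures, mediator, outcome, "
          f"LD panel ({cfg.n_snps} SNPs) to {OUT}")
    print(f"truth: beta_em={cfg.beta_em}, beta_mo={cfg.beta_mo}, "
          f"direct={cfg.beta_eo_direct}, total={truth.beta_total:.3f}, "
          f"mediation proportion={truth.true_proportion:.2%}")


if __name__ == "__main__":
    main()
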