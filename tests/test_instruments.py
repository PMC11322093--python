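import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netmr.instruments import (EmptySelection, InstrumentConfig, LdPanel,
                               build_instrument_set, clump,
                               compute_f_statistics,
                               exclude_outcome_associated,
                               filter_significance, steiger_filter,
                               steiger_r2_from_p)
from netmr.summary_io import harmonize
from netmr.synthetic_data import SimConfig, simulate_gwas_triplet
from tests.conftest import make_stats


def make_panel(snp_ids, r2=None, chrom=None, pos=None):
    k = len(snp_ids)
    mat = np.eye(k) if r2 is None else np.asarray(r2, float)
    positions = pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": chrom or ["1"] * k,
        "pos": pos or list(range(1000, 1000 + 1000 * k, 1000))})
    return LdPanel(snp_ids=list(snp_ids), r2=mat, positions=positions)


class TestFilters:
    def test_significance_threshold(self):
        ss = make_stats(pval=[1e-6, 1e-4], eaf=[0.3, 0.3])
        kept = filter_significance(ss)
        assert list(kept.df["snp_id"]) == ["rs1"]

    def test_maf_floor_removes_rare_snps(self):
        ss = make_stats(pval=[1e-6, 1e-6], eaf=[0.005, 0.995])
        with pytest.raises(EmptySelection):
            filter_significance(ss)

    def test_missing_eaf_passes_unless_strict(self):
        ss = make_stats(pval=[1e-6], eaf=[np.nan])
        assert filter_significance(ss).n_snps == 1
        with pytest.raises(EmptySelection):
            filter_significance(ss, strict_missing_eaf=True)

    def test_f_statistics_arithmetic(self):
        ss = make_stats(beta=[0.1, 0.02], se=[0.02, 0.02])
        f, mean_f, weak = compute_f_statistics(ss)
        assert f == pytest.approx([25.0, 1.0])
        assert mean_f == pytest.approx(13.0)
        assert not weak

    def test_weak_set_flagged(self):
        ss = make_stats(beta=[0.02], se=[0.02])
        _, mean_f, weak = compute_f_statistics(ss)
        assert mean_f == pytest.approx(1.0) and weak


class TestClump:
    def test_greedy_three_snp_example(self):
        # A(p 1e-8), B(p 1e-6, r2(A,B)=0.5, 50 kb away), C(independent)
        ss = make_stats(snp_id=["A", "B", "C"], pval=[1e-8, 1e-6, 1e-5])
        r2 = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        panel = make_panel(["A", "B", "C"], r2, pos=[1000, 51_000, 200_000])
        out = clump(ss, panel)
        assert sorted(out.df["snp_id"]) == ["A", "C"]

    def test_independent_snps_all_retained(self):
        ss = make_stats(snp_id=list("ABCD"), pval=[1e-8, 1e-7, 1e-6, 1e-5])
        out = clump(ss, make_panel(list("ABCD")))
        assert len(out.df) == 4

    def test_equal_p_tiebreak_by_position(self):
        ss = make_stats(snp_id=["B", "A"], pval=[1e-6, 1e-6])
        r2 = np.array([[1.0, 0.9], [0.9, 1.0]])
        panel = make_panel(["B", "A"], r2, pos=[2000, 1000])
        out = clump(ss, panel)
        assert list(out.df["snp_id"]) == ["A"]  # earlier position wins

    def test_window_limits_removal(self):
        # high r2 but beyond the window: both kept
        ss = make_stats(snp_id=["A", "B"], pval=[1e-8, 1e-6])
        r2 = np.array([[1.0, 0.9], [0.9, 1.0]])
        panel = make_panel(["A", "B"], r2, pos=[1, 20_000_001])
        assert len(clump(ss, panel).df) == 2

    def test_clumped_set_is_independent_brute_force(self, rng):
        # property: no retained pair has r2 > threshold within the window
        n = 40
        ids = [f"rs{i}" for i in range(n)]
        a = rng.uniform(-1, 1, (n, n))
        r = np.corrcoef(a @ a.T + np.eye(n) * 5)
        r2 = r ** 2
        pos = sorted(rng.choice(10**7, n, replace=False).tolist())
        ss = make_stats(snp_id=ids,
                        pval=list(rng.uniform(1e-10, 1e-4, n)))
        panel = make_panel(ids, r2, pos=pos)
        out = clump(ss, panel, r2_max=0.1, window_kb=1000)
        kept = list(out.df["snp_id"])
        for i, si in enumerate(kept):
            for sj in kept[i + 1:]:
                ii, jj = panel.index_of(si), panel.index_of(sj)
                dist = abs(pos[ii] - pos[jj])
                assert not (r2[ii, jj] > 0.1 and dist <= 1_000_000)


class TestOutcomeExclusionAndSteiger:
    def test_outcome_associated_rows_removed(self):
        exp = make_stats("exp", beta=[0.1, 0.1], pval=[1e-6, 1e-6])
        out = make_stats("out", beta=[0.01, 0.01], pval=[1e-6, 0.3])
        h = harmonize(exp, out)
        h2 = exclude_outcome_associated(h)
        assert list(h2.df["snp_id"]) == ["rs2"]
        assert (h2.dropped["reason"].str.contains("outcome")).any()

    def test_steiger_keeps_exposure_first_direction(self):
        exp = make_stats("exp", pval=[1e-20], n=[10_000])
        out = make_stats("out", beta=[0.01], pval=[0.5], n=[10_000])
        h = harmonize(exp, out)
        kept, report = steiger_filter(h)
        assert kept.n_snps == 1
        assert report["direction"].iloc[0] == "true"

    def test_steiger_boundary_equal_r2_dropped(self):
        exp = make_stats("exp", pval=[0.01], n=[10_000])
        out = make_stats("out", beta=[0.01], pval=[0.01], n=[10_000])
        h = harmonize(exp, out)
        kept, _ = steiger_filter(h)
        assert kept.n_snps == 0  # strict inequality required

    def test_steiger_derived_oracle_values(self):
        # frozen from an independent recomputation of the F-inversion and
        # Fisher-z two-sample test at p_exp=1e-20, p_out=0.5,
        # n = 14,306 / 462,341
        r2e = float(steiger_r2_from_p(1e-20, 14_306))
        r2o = float(steiger_r2_from_p(0.5, 462_341))
        assert r2e == pytest.approx(0.0060566155, rel=1e-6)
        assert r2o == pytest.approx(9.8398943e-07, rel=1e-6)
        exp = make_stats("exp", pval=[1e-20], n=[14_306])
        out = make_stats("out", beta=[0.001], pval=[0.5], n=[462_341])
        h = harmonize(exp, out)
        kept, report = steiger_filter(h)
        assert kept.n_snps == 1
        assert report["steiger_z"].iloc[0] == pytest.approx(9.06843, rel=1e-4)
        assert report["steiger_p"].iloc[0] < 0.05

    def test_steiger_direction_antisymmetric(self):
        exp = make_stats("exp", pval=[1e-12], n=[50_000])
        out = make_stats("out", beta=[0.01], pval=[1e-3], n=[50_000])
        fwd, _ = steiger_filter(harmonize(exp, out))
        rev, _ = steiger_filter(harmonize(out, exp))
        assert fwd.n_snps == 1 and rev.n_snps == 0

    def test_insufficient_sample_errors(self):
        exp = make_stats("exp", pval=[1e-6], n=[3])
        out = make_stats("out", beta=[0.01], pval=[0.5], n=[3])
        with pytest.raises(Exception):
            steiger_filter(harmonize(exp, out))


class TestCascade:
    def test_null_outcome_keeps_instruments_high_f(self, triplet):
        exp, _, out, panel, _ = triplet
        inst = build_instrument_set(exp, out, panel)
        assert inst.n_snps >= 20
        assert inst.mean_f > 10
        removed = sum(n for _, n in inst.provenance)
        assert removed == exp.n_snps - inst.n_snps

    def test_single_ld_block_collapses_to_one_survivor(self):
        from netmr.synthetic_data import LdSpec
        cfg = SimConfig(n_snps=8, target_mean_f=200.0, beta_em=0, beta_mo=0,
                        beta_eo_direct=0, seed=5,
                        ld=LdSpec(block_size=8, block_r2=0.9))
        exp, _, out, panel, _ = simulate_gwas_triplet(cfg)
        inst = build_instrument_set(exp, out, panel,
                                    InstrumentConfig(steiger=False))
        assert inst.n_snps == 1

    def test_reverse_structure_removed_by_steiger(self):
        cfg = SimConfig(n_snps=80, target_mean_f=100.0, beta_em=0,
                        beta_mo=0, beta_eo_direct=0, seed=9,
                        reverse_effect=0.3, reverse_fraction=1.0)
        exp, _, out, panel, truth = simulate_gwas_triplet(cfg)
        cfg_no = InstrumentConfig(steiger=False,
                                  outcome_p_threshold=0.0)
        cfg_yes = InstrumentConfig(steiger=True,
                                   outcome_p_threshold=0.0)
        before = build_instrument_set(exp, out, panel, cfg_no).n_snps
        try:
            after = build_instrument_set(exp, out, panel, cfg_yes).n_snps
        except EmptySelection:
            after = 0
        assert after < 0.5 * before

    def test_empty_cascade_signals_with_provenance(self):
        exp = make_stats("exp", pval=[0.5, 0.9])
        out = make_stats("out", beta=[0.01, 0.01], pval=[0.5, 0.5])
        with pytest.raises(EmptySelection) as exc:
            build_instrument_set(exp, out, None)
        assert exc.value.provenance


class TestLdPanelIO:
    def test_roundtrip(self, tmp_path, triplet):
        _, _, _, panel, _ = triplet
        panel.write(tmp_path / "r2.tsv", tmp_path / "pos.tsv")
        back = LdPanel.read(tmp_path / "r2.tsv", tmp_path / "pos.tsv")
        assert back.snp_ids == panel.snp_ids
        assert np.allclose(back.r2, panel.r2)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            make_panel(["a", "b"], r2=np.array([[1.0, 0.5], [0.4, 1.0]]))
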