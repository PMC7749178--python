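"""Determinism, bookkeeping and planted-effect realism of the generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epicircuit.simulate import (
    SimMethylomeConfig,
    gen_activity_matrix,
    gen_methylome_cohort,
    gen_sc_expression,
    gen_se_cohort,
    gen_state_annotation,
)


def planted(*rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cls", "mean_beta", "subtypes"]
    )


DMV_ALL = ("chr1", 50_000, 58_000, "DMV", 0.05, "all")


class TestMethylomeCohort:
    def base_cfg(self, **kw):
        defaults = dict(
            chrom_lengths={"chr1": 200_000},
            planted_features=planted(DMV_ALL),
            seed=42,
        )
        defaults.update(kw)
        return SimMethylomeConfig(**defaults)

    def test_determinism(self):
        t1, _ = gen_methylome_cohort(self.base_cfg())
        t2, _ = gen_methylome_cohort(self.base_cfg())
        for s in t1:
            pd.testing.assert_frame_equal(t1[s], t2[s])

    def test_zero_noise_dmv_is_exact(self):
        cfg = self.base_cfg(beta_noise_sd=0.0)
        tables, _ = gen_methylome_cohort(cfg)
        df = tables["IDH_1"]
        inside = df[(df["start"] >= 50_000) & (df["start"] < 58_000)]
        assert (inside["beta"] == 0.05).all()
        outside = df[(df["start"] < 50_000) | (df["start"] >= 58_000)]
        assert (outside["beta"] == cfg.baseline_beta).all()

    def test_truth_bookkeeping(self):
        _, truth = gen_methylome_cohort(self.base_cfg())
        # one DMV planted in all 4 subtypes x 3 samples
        assert len(truth.features) == 12
        assert (truth.features["cls"] == "DMV").all()

    def test_subtype_restricted_feature(self):
        cfg = self.base_cfg(
            planted_features=planted(
                ("chr1", 10_000, 12_000, "LMR", 0.1, ("MES",))
            )
        )
        tables, truth = gen_methylome_cohort(cfg)
        assert set(truth.features["sample"]) == {"MES_1", "MES_2", "MES_3"}
        mes = tables["MES_1"]
        idh = tables["IDH_1"]
        mes_in = mes[(mes["start"] >= 10_000) & (mes["start"] < 12_000)]["beta"].mean()
        idh_in = idh[(idh["start"] >= 10_000) & (idh["start"] < 12_000)]["beta"].mean()
        assert mes_in < 0.2 < 0.6 < idh_in

    def test_out_of_bounds_feature_rejected(self):
        with pytest.raises(ValueError, match="chr1:190000-210000"):
            self.base_cfg(
                planted_features=planted(("chr1", 190_000, 210_000, "DMV", 0.05, "all"))
            )

    def test_overlapping_same_class_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            self.base_cfg(
                planted_features=planted(
                    DMV_ALL, ("chr1", 55_000, 62_000, "DMV", 0.05, "all")
                )
            )

    def test_coverage_moments(self):
        tables, _ = gen_methylome_cohort(self.base_cfg())
        cov = np.concatenate([t["coverage"].to_numpy() for t in tables.values()])
        assert cov.mean() == pytest.approx(10, rel=0.05)
        # negative-binomial overdispersion: var = mu + disp * mu^2 = 40
        assert cov.var() == pytest.approx(10 + 0.3 * 100, rel=0.15)

    def test_spacing_is_geometric_with_requested_mean(self):
        tables, _ = gen_methylome_cohort(self.base_cfg())
        pos = tables["IDH_1"]["start"].to_numpy()
        gaps = np.diff(pos)
        assert gaps.mean() == pytest.approx(100, rel=0.1)


class TestStateAnnotation:
    def test_single_state_tiles_everything(self):
        df = gen_state_annotation({"chr1": 100_000}, {"E18": 1.0}, seed=0)
        assert (df["state"] == "E18").all()
        assert df["start"].iloc[0] == 0 and df["end"].iloc[-1] == 100_000
        assert (df["start"].iloc[1:].to_numpy() == df["end"].iloc[:-1].to_numpy()).all()

    def test_determinism(self):
        a = gen_state_annotation({"chr1": 500_000}, {"E09": 0.5, "E18": 0.5}, seed=3)
        b = gen_state_annotation({"chr1": 500_000}, {"E09": 0.5, "E18": 0.5}, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_realised_fractions_close_on_2mb(self):
        df = gen_state_annotation({"chr1": 2_000_000}, {"E09": 0.5, "E18": 0.5}, seed=7)
        widths = df["end"] - df["start"]
        frac = widths[df["state"] == "E09"].sum() / widths.sum()
        assert 0.45 <= frac <= 0.55

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            gen_state_annotation({"chr1": 1_000}, {"E01": 1.5, "E02": -0.5})
        with pytest.raises(ValueError, match="sum"):
            gen_state_annotation({"chr1": 1_000}, {"E01": 0.6})


class TestSECohort:
    def test_determinism(self):
        d1, _ = gen_se_cohort(n_ses=10, n_genes=60, seed=9)
        d2, _ = gen_se_cohort(n_ses=10, n_genes=60, seed=9)
        pd.testing.assert_frame_equal(d1["signal"], d2["signal"])
        pd.testing.assert_frame_equal(d1["expression"], d2["expression"])

    def test_zero_effect_empty_subtype_truth(self):
        _, truth = gen_se_cohort(n_ses=8, n_genes=40, effect_logfc=0.0, seed=1)
        assert truth.subtype_se == {}

    def test_rho_one_is_monotone_copy(self):
        data, truth = gen_se_cohort(n_ses=6, n_genes=30, rho_target=1.0, seed=2)
        for se_id, gene in truth.se_targets.items():
            sig = data["signal"].loc[se_id]
            expr = data["expression"].loc[gene]
            assert (sig.rank() == expr.rank()).all()

    def test_realised_spearman_near_target(self):
        data, truth = gen_se_cohort(n_ses=30, n_genes=300, samples_per_subtype=10,
                                    rho_target=0.9, seed=3)
        rhos = [
            stats.spearmanr(data["signal"].loc[se], data["expression"].loc[g]).statistic
            for se, g in truth.se_targets.items()
        ]
        assert 0.8 <= np.median(rhos) <= 0.97

    def test_planted_logfc_realised(self):
        data, truth = gen_se_cohort(n_ses=12, n_genes=60, samples_per_subtype=10,
                                    effect_logfc=2.0, seed=4)
        labels = pd.Series(data["sample_subtypes"])
        log_sig = np.log2(data["signal"])
        lfcs = []
        for se_id, st in truth.subtype_se.items():
            inside = log_sig.loc[se_id, labels[labels == st].index].mean()
            outside = log_sig.loc[se_id, labels[labels != st].index].mean()
            lfcs.append(inside - outside)
        assert np.mean(lfcs) == pytest.approx(2.0, abs=0.35)

    def test_targets_within_tad_and_range(self):
        data, truth = gen_se_cohort(n_ses=10, n_genes=100, seed=5)
        genes = data["genes"].set_index("gene_id")
        for se_row in data["ses"].itertuples():
            g = genes.loc[truth.se_targets[se_row.se_id]]
            assert g["tad_id"] == se_row.tad_id
            assert abs(g["tss"] - se_row.end) <= 500_000

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="tad_count"):
            gen_se_cohort(tad_count=0)
        with pytest.raises(ValueError, match="gene per SE"):
            gen_se_cohort(n_ses=10, n_genes=5)


class TestActivityMatrix:
    def test_determinism(self):
        a, _ = gen_activity_matrix(seed=6)
        b, _ = gen_activity_matrix(seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_effect_means_near_zero(self):
        mat, truth = gen_activity_matrix(mrs_per_subtype=5, samples_per_subtype=50,
                                         effect_sd=0.0, seed=7)
        labels = pd.Series({s: s.rsplit("_", 1)[0] for s in mat.columns})
        means = mat.T.groupby(labels).mean().T
        # each subtype mean of each MR within +-3/sqrt(n) of zero
        assert np.abs(means.to_numpy()).max() <= 3 / np.sqrt(50)

    def test_large_effect_argmax_matches_truth(self):
        mat, truth = gen_activity_matrix(mrs_per_subtype=5, samples_per_subtype=10,
                                         effect_sd=10.0, seed=8)
        labels = pd.Series({s: s.rsplit("_", 1)[0] for s in mat.columns})
        means = mat.T.groupby(labels).mean().T
        assert all(means.loc[m].idxmax() == st for m, st in truth.mr_subtype.items())


class TestSCExpression:
    def test_determinism(self):
        a, _ = gen_sc_expression(n_cells=40, n_genes=100, seed=10)
        b, _ = gen_sc_expression(n_cells=40, n_genes=100, seed=10)
        pd.testing.assert_frame_equal(a, b)

    def test_exact_positive_count(self):
        _, truth = gen_sc_expression(n_cells=200, n_genes=100, signature_size=10,
                                     positive_fraction=0.5, seed=11)
        assert len(truth.signature_positive_cells) == 100

    def test_zero_shift_indistinguishable(self):
        expr, truth = gen_sc_expression(n_cells=200, n_genes=500, signature_size=20,
                                        shift=0.0, seed=12)
        sig_mean = expr.loc[truth.signature_genes].mean(axis=0)
        pos = sig_mean.index.isin(truth.signature_positive_cells)
        p = stats.ttest_ind(sig_mean[pos], sig_mean[~pos]).pvalue
        assert p > 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="signature_size"):
            gen_sc_expression(n_genes=10, signature_size=11)
        with pytest.raises(ValueError, match="positive_fraction"):
            gen_sc_expression(positive_fraction=1.0)
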