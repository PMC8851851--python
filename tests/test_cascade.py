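import numpy as np
import pandas as pd
import pytest

from contactnorm import (
    CascadeConfig,
    ContactNormalizationCascade,
    classify_cadherin_dependence,
    classify_reversal,
    classify_src_effect,
    generate_dataset,
    run_cascade,
    PlantedGeneSpec,
)
from conftest import frame_from_groups, make_design


def single_gene_tpm(n_self, t_self, t_vs_n=None, t_vs_ko=None, gene="g"):
    t_vs_n = t_vs_n if t_vs_n is not None else t_self
    t_vs_ko = t_vs_ko if t_vs_ko is not None else t_vs_n
    return frame_from_groups({gene: {
        "N_self": n_self, "T_self": t_self, "T_vs_N": t_vs_n, "T_vs_KO": t_vs_ko,
    }})


class TestSrcEffect:
    def test_clear_induction_is_up(self, design3):
        tpm = single_gene_tpm([10, 10, 10], [40, 41, 39])
        out = classify_src_effect(tpm, design3)
        assert out.loc["g", "src_class"] == "up"
        assert out.loc["g", "src_fc"] == pytest.approx(41 / 11)
        assert out.loc["g", "src_p"] < 0.05

    def test_identical_groups_are_none(self, design3):
        tpm = single_gene_tpm([10, 11, 12], [10, 11, 12])
        out = classify_src_effect(tpm, design3)
        assert out.loc["g", "src_class"] == "none"
        assert out.loc["g", "src_fc"] == pytest.approx(1.0)

    def test_threefold_boundary_is_inclusive(self, design3):
        # means 10 and 32 with pseudocount 1: fold exactly (32+1)/(10+1) = 3
        tpm = single_gene_tpm([10, 10, 10], [31, 32, 33])
        out = classify_src_effect(tpm, design3)
        assert out.loc["g", "src_fc"] == pytest.approx(3.0)
        assert out.loc["g", "src_class"] == "up"

    def test_suppression_is_down(self, design3):
        tpm = single_gene_tpm([99, 100, 101], [24, 24, 24])
        out = classify_src_effect(tpm, design3)
        assert out.loc["g", "src_class"] == "down"


class TestReversal:
    def test_partial_suppression_of_src_up_gene(self, design3):
        tpm = single_gene_tpm([10, 10, 10], [100, 98, 102], [55, 54, 56])
        src = pd.Series(["up"], index=["g"])
        out = classify_reversal(tpm, design3, src_classes=src)
        assert out.loc["g", "reversal_change"] == pytest.approx((55 - 100) / 101)
        assert out.loc["g", "reversal_p"] < 0.08
        assert bool(out.loc["g", "reversed"]) is True

    def test_unchanged_coculture_not_reversed(self, design3):
        tpm = single_gene_tpm([10, 10, 10], [100, 98, 102], [100, 98, 102])
        out = classify_reversal(tpm, design3,
                                src_classes=pd.Series(["up"], index=["g"]))
        assert bool(out.loc["g", "reversed"]) is False
        assert out.loc["g", "reversal_change"] == pytest.approx(0.0)

    def test_same_direction_change_fails_inversely_requirement(self, design3):
        # Src-up gene that rises another 50% in coculture is not a reversal
        tpm = single_gene_tpm([10, 10, 10], [100, 98, 102], [150, 148, 152])
        out = classify_reversal(tpm, design3,
                                src_classes=pd.Series(["up"], index=["g"]))
        assert bool(out.loc["g", "reversed"]) is False

    def test_down_gene_reversal_requires_increase(self, design3):
        tpm = single_gene_tpm([100, 100, 100], [20, 21, 19], [33, 34, 32])
        out = classify_reversal(tpm, design3,
                                src_classes=pd.Series(["down"], index=["g"]))
        # (33 - 20) / 21 = 0.619 >= 0.40, opposite to the Src suppression
        assert bool(out.loc["g", "reversed"]) is True

    def test_rejects_non_affected_genes(self, design3):
        tpm = single_gene_tpm([10] * 3, [10] * 3)
        with pytest.raises(ValueError, match="Src-affected"):
            classify_reversal(tpm, design3,
                              src_classes=pd.Series(["none"], index=["g"]))

    def test_restoration_mode_counts_gap_closure(self, design3):
        # Src up 10 -> 100; coculture at 55 closes half the gap to baseline
        tpm = single_gene_tpm([10, 10, 10], [100, 98, 102], [55, 54, 56])
        config = CascadeConfig(reversal_mode="restoration", reversal_fraction=0.4)
        out = classify_reversal(tpm, design3, config,
                                src_classes=pd.Series(["up"], index=["g"]))
        assert out.loc["g", "reversal_change"] == pytest.approx((55 - 100) / (10 - 100))
        assert bool(out.loc["g", "reversed"]) is True


class TestCadherinDependence:
    def test_knockout_escape_is_dependent(self, design3):
        tpm = single_gene_tpm([10] * 3, [100, 98, 102], [50, 51, 49], [120, 118, 122])
        out = classify_cadherin_dependence(tpm, design3,
                                           src_classes=pd.Series(["up"], index=["g"]))
        assert out.loc["g", "cdh_fc"] == pytest.approx(121 / 51)
        assert out.loc["g", "cdh_class"] == "dependent"

    def test_identical_cocultures_are_independent(self, design3):
        tpm = single_gene_tpm([10] * 3, [100] * 3, [50, 51, 49], [50, 51, 49])
        out = classify_cadherin_dependence(tpm, design3,
                                           src_classes=pd.Series(["up"], index=["g"]))
        assert out.loc["g", "cdh_class"] == "independent"

    def test_direction_inconsistent_differential_is_independent(self, design3):
        # knockout coculture 2-fold LOWER than competent: not loss of normalization
        tpm = single_gene_tpm([10] * 3, [100] * 3, [50, 51, 49], [24, 25, 26])
        out = classify_cadherin_dependence(tpm, design3,
                                           src_classes=pd.Series(["up"], index=["g"]))
        assert out.loc["g", "cdh_fc"] < 0.55
        assert out.loc["g", "cdh_class"] == "independent"

    def test_rejects_without_src_direction(self, design3):
        tpm = single_gene_tpm([10] * 3, [100] * 3)
        with pytest.raises(ValueError, match="reversed genes"):
            classify_cadherin_dependence(tpm, design3, src_classes=pd.Series(dtype=object))


class TestRunCascade:
    def toy_dataset(self, dispersion=1e-4, seed=0):
        # the big unaffected gene is ballast: it keeps per-sample TPM
        # renormalization nearly constant while the small genes shift
        specs = [
            (PlantedGeneSpec("not_expressed", base_mean=0.05, dispersion=dispersion), 1),
            (PlantedGeneSpec("unaffected", base_mean=9.6e5, dispersion=dispersion), 1),
            (PlantedGeneSpec("src_up", base_mean=1000, dispersion=dispersion), 1),
            (PlantedGeneSpec("reversed_independent_up", base_mean=1000,
                             dispersion=dispersion), 1),
            (PlantedGeneSpec("reversed_dependent_up", base_mean=1000,
                             dispersion=dispersion), 1),
        ]
        return generate_dataset(specs, seed=seed)

    def test_each_toy_gene_lands_in_its_planted_layer(self):
        ds = self.toy_dataset()
        result = run_cascade(ds.to_expression_matrix(), ds.design)
        expected = ["not_expressed", "expressed_unaffected", "src_only",
                    "cn_cadherin_independent", "cn_cadherin_dependent"]
        assert list(result.per_gene["layer"]) == expected

    def test_zero_effect_dataset_is_all_unaffected(self, design3):
        rng = np.random.default_rng(2)
        base = rng.uniform(5, 500, size=30)
        tpm = pd.DataFrame(
            np.repeat(base[:, None], 12, axis=1) * rng.normal(1, 0.02, size=(30, 12)),
            index=[f"g{i}" for i in range(30)], columns=design3.sample_ids)
        result = run_cascade(tpm, design3)
        assert set(result.per_gene["layer"]) == {"expressed_unaffected"}

    def test_layers_partition_and_nest(self):
        from contactnorm import recovery_benchmark_mix
        ds = generate_dataset(recovery_benchmark_mix(dispersion=0.1), seed=4)
        result = run_cascade(ds.to_expression_matrix(), ds.design)
        per_gene, s = result.per_gene, result.summary
        assert per_gene["layer"].notna().all()
        assert s["detected"] == len(per_gene)
        src_affected = s["src_up"] + s["src_down"]
        reversed_total = s["reversed_up"] + s["reversed_down"]
        dependent_total = s["dependent_up"] + s["dependent_down"]
        assert dependent_total <= reversed_total <= src_affected <= s["expressed"] <= s["detected"]
        # stage fields are absent below the layer a gene reached
        not_expr = per_gene["layer"] == "not_expressed"
        assert per_gene.loc[not_expr, "src_fc"].isna().all()
        assert per_gene.loc[per_gene["src_class"] == "none", "reversal_p"].isna().all()
        reached_cdh = per_gene["cdh_class"].isin(["dependent", "independent"])
        assert (per_gene.loc[reached_cdh, "reversed"] == True).all()  # noqa: E712

    def test_threshold_monotonicity(self):
        from contactnorm import recovery_benchmark_mix
        ds = generate_dataset(recovery_benchmark_mix(dispersion=0.15), seed=9)
        matrix = ds.to_expression_matrix()

        def sets(config):
            pg = run_cascade(matrix, ds.design, config).per_gene
            affected = set(pg.index[pg["src_class"].isin(["up", "down"])])
            reversed_ = set(pg.index[pg["reversed"] == True])  # noqa: E712
            dependent = set(pg.index[pg["cdh_class"] == "dependent"])
            return affected, reversed_, dependent

        base = sets(CascadeConfig())
        # tightening a stage's fold (or alpha) never enlarges that stage's set
        cases = [
            (CascadeConfig(src_fold=5.0), 0),
            (CascadeConfig(src_alpha=0.01), 0),
            (CascadeConfig(reversal_fraction=0.6), 1),
            (CascadeConfig(reversal_alpha=0.02), 1),
            (CascadeConfig(cdh_fold=4.0), 2),
            (CascadeConfig(cdh_alpha=0.01), 2),
        ]
        for config, stage in cases:
            assert sets(config)[stage] <= base[stage]

    def test_degenerate_reversal_alpha_zero(self):
        from contactnorm import recovery_benchmark_mix
        ds = generate_dataset(recovery_benchmark_mix(), seed=3)
        result = run_cascade(ds.to_expression_matrix(), ds.design,
                             CascadeConfig(reversal_alpha=0.0))
        assert result.summary["reversed_up"] == 0
        assert result.summary["reversed_down"] == 0
        assert result.summary["dependent_up"] == 0

    def test_missing_group_rejected(self):
        from contactnorm import StudyDesign
        design = StudyDesign({"a": "N_self", "b": "N_self",
                              "c": "T_self", "d": "T_self"})
        tpm = pd.DataFrame(np.ones((3, 4)), index=list("xyz"),
                           columns=["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="T_vs_N"):
            run_cascade(tpm, design)


class TestEstimator:
    def test_fit_predict_returns_layers(self):
        ds = TestRunCascade().toy_dataset()
        tpm_df = None
        from contactnorm import tpm_normalize
        tpm_df = tpm_normalize(ds.to_expression_matrix()).values
        est = ContactNormalizationCascade(design=ds.design)
        labels = est.fit_predict(tpm_df)
        assert list(labels) == ["not_expressed", "expressed_unaffected", "src_only",
                                "cn_cadherin_independent", "cn_cadherin_dependent"]
        assert est.summary_["detected"] == 5
        assert est.classification_.shape[0] == 5

    def test_get_set_params_roundtrip(self):
        est = ContactNormalizationCascade(src_fold=4.0)
        params = est.get_params()
        assert params["src_fold"] == 4.0
        est.set_params(cdh_alpha=0.01)
        assert est._config().cdh_alpha == 0.01

    def test_requires_design(self):
        est = ContactNormalizationCascade()
        with pytest.raises(ValueError, match="StudyDesign"):
            est.fit(pd.DataFrame([[1.0]]))
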