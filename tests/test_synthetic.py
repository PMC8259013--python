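"""The generator's outputs honor their own ground truth."""

import filecmp

import numpy as np
import pandas as pd
import pytest

import epimarray as em
from epimarray.io import simulate_inputs
from epimarray.synthetic import CONTEXT_CLASSES, sample_sheet


class TestConfigValidation:
    def test_rejects_zero_mrna(self):
        with pytest.raises(ValueError, match="mRNA"):
            em.SimulationConfig(n_mrna=0)

    @pytest.mark.parametrize("kwargs", [
        {"n_spikein": 1},
        {"groups": ("A", "A")},
        {"noise_log2_sd": -0.1},
        {"base_methylation_alpha": 0.0},
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            em.SimulationConfig(**kwargs)

    def test_effect_must_target_known_group(self):
        cfg = em.SimulationConfig(planted_effects=[
            em.PlantedEffect("mRNA_00001", "M9-L", "methylation_shift", 2.0)])
        with pytest.raises(ValueError, match="unknown group"):
            cfg.resolved_effects()

    def test_effect_magnitude_nonzero(self):
        with pytest.raises(ValueError):
            em.PlantedEffect("t", "M1-L", "methylation_shift", 0.0)


class TestAnnotationLayout:
    def test_every_context_class_realized_once_at_six(self):
        cfg = em.SimulationConfig(n_mrna=20, n_lncrna=6, n_spikein=2, seed=7)
        ann, genes = em.generate_annotation(cfg)
        ctx = em.cis_lnc.classify_all(ann, genes)
        assert sorted(ctx["context_class"]) == sorted(CONTEXT_CLASSES)

    def test_classifier_roundtrips_intended_labels(self, small_dataset):
        ann, genes = small_dataset["annotation"], small_dataset["genes"]
        ctx = em.cis_lnc.classify_all(ann, genes)
        intended = ann.loc[ann["rna_class"] == "lncRNA", "context_class"]
        assert list(ctx["context_class"]) == list(intended)

    def test_gene_models_have_two_plus_exons_within_bounds(self, small_dataset):
        for g in small_dataset["genes"]:
            assert len(g.exons) >= 2
            assert all(g.start <= s < e <= g.end for s, e in g.exons)

    def test_low_lncrna_count_warns_not_errors(self, caplog):
        cfg = em.SimulationConfig(n_mrna=10, n_lncrna=3, n_spikein=2)
        with caplog.at_level("WARNING"):
            ann, _ = em.generate_annotation(cfg)
        assert (ann["rna_class"] == "lncRNA").sum() == 3
        assert any("context class" in r.message for r in caplog.records)

    def test_simulate_outputs_byte_identical(self, tmp_path):
        cfg = em.SimulationConfig(n_mrna=25, n_lncrna=6, n_spikein=3, seed=7)
        p1 = simulate_inputs(cfg, tmp_path / "a")
        p2 = simulate_inputs(cfg, tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key


class TestIntensityModel:
    def test_channel_conservation_without_noise(self, clean_dataset):
        """IP + SUP equals linear abundance when effects and noise are off."""
        arrays, truth, cfg = (clean_dataset["arrays"], clean_dataset["truth"],
                              clean_dataset["config"])
        sheet = arrays.samples
        tids = list(truth.methylation.index)
        total = arrays.ip.loc[tids] + arrays.sup.loc[tids]
        for _, row in sheet.iterrows():
            expected = np.exp2(truth.log2_abundance[row["group"]])
            np.testing.assert_allclose(total[row["sample_id"]], expected, rtol=1e-10)

    def test_ip_equals_sup_at_half_methylation(self):
        cfg = em.SimulationConfig(n_mrna=5, n_lncrna=0, n_spikein=2, seed=1,
                                  array_effect_sd=0.0, noise_log2_sd=0.0,
                                  base_methylation_alpha=1.0,
                                  base_methylation_beta=1.0, planted_effects=[])
        ann, _ = em.generate_annotation(cfg)
        arrays, truth = em.generate_intensities(cfg, ann)
        tids = list(truth.methylation.index)
        # force the symmetric case analytically: m = 0.5 => IP == SUP
        half = truth.methylation.iloc[:, 0].sub(0.5).abs() < 0.49
        ratio = (arrays.ip.loc[tids] / arrays.sup.loc[tids]).iloc[:, 0]
        m = truth.methylation.iloc[:, 0]
        np.testing.assert_allclose(ratio, m / (1 - m), rtol=1e-10)

    def test_methylation_shift_raises_group_mean(self):
        effects = [em.PlantedEffect("mRNA_00001", "M1-L", "methylation_shift", 2.0)]
        cfg = em.SimulationConfig(n_mrna=10, n_lncrna=0, n_spikein=2, seed=3,
                                  noise_log2_sd=0.0, planted_effects=effects)
        ann, _ = em.generate_annotation(cfg)
        arrays, truth = em.generate_intensities(cfg, ann)
        q = em.quantify(arrays)
        sheet = arrays.samples
        m = q.methylation.loc["mRNA_00001"]
        m1 = m[sheet.loc[sheet["group"] == "M1-L", "sample_id"]].mean()
        m0 = m[sheet.loc[sheet["group"] == "M0-L", "sample_id"]].mean()
        assert m1 > m0

    def test_ground_truth_labels_match_planted_signs(self):
        effects = [em.PlantedEffect("mRNA_00001", "M1-L", "methylation_shift", 2.0),
                   em.PlantedEffect("mRNA_00002", "M1-L", "methylation_shift", -2.0),
                   em.PlantedEffect("mRNA_00003", "M2-L", "expression_shift", 1.5)]
        cfg = em.SimulationConfig(n_mrna=5, n_lncrna=0, n_spikein=2, seed=1,
                                  planted_effects=effects)
        ann, _ = em.generate_annotation(cfg)
        _, truth = em.generate_intensities(cfg, ann)
        lab10 = truth.labels("M1-L", "M0-L")
        assert lab10.loc["mRNA_00001", "methylation"] == "hyper"
        assert lab10.loc["mRNA_00002", "methylation"] == "hypo"
        assert lab10.loc["mRNA_00003", "expression"] == "none"
        lab21 = truth.labels("M2-L", "M1-L")
        assert lab21.loc["mRNA_00001", "methylation"] == "hypo"
        assert lab21.loc["mRNA_00003", "expression"] == "up"

    def test_all_intensities_positive(self, small_dataset):
        assert (small_dataset["arrays"].ip.to_numpy() > 0).all()
        assert (small_dataset["arrays"].sup.to_numpy() > 0).all()

    def test_sample_sheet_layout(self, small_config):
        sheet = sample_sheet(small_config)
        assert len(sheet) == 9
        assert sheet["group"].nunique() == 3


class TestQpcrGenerator:
    def test_noise_free_ddct_recovers_designed_fold(self):
        design = em.QpcrDesign(sd_ct=0.0, expression={"T": {"M0-L": 1.0, "M1-L": 2.0,
                                                            "M2-L": 1.0}},
                               methylation={})
        table = em.generate_qpcr(design)
        cdna = table[table["tube"] == "cdna"]

        def cts(group, target):
            sub = cdna[(cdna["group"] == group) & (cdna["target"] == target)]
            return sub["ct"].to_numpy()

        res = em.ddct(cts("M1-L", "T"), cts("M1-L", "Gapdh"),
                      cts("M0-L", "T"), cts("M0-L", "Gapdh"))
        assert res.ddct == pytest.approx(-1.0, abs=1e-12)
        assert res.fold == pytest.approx(2.0, rel=1e-12)

    def test_noise_free_identical_groups_give_zero_ddct(self):
        design = em.QpcrDesign(sd_ct=0.0, expression={"T": {"M0-L": 1.0, "M1-L": 1.0,
                                                            "M2-L": 1.0}},
                               methylation={})
        table = em.generate_qpcr(design)
        cdna = table[table["tube"] == "cdna"]
        g = lambda grp, t: cdna[(cdna["group"] == grp) & (cdna["target"] == t)]["ct"].to_numpy()
        res = em.ddct(g("M1-L", "T"), g("M1-L", "Gapdh"), g("M0-L", "T"), g("M0-L", "Gapdh"))
        assert res.ddct == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_percent_input_recovers_fraction(self):
        design = em.QpcrDesign(sd_ct=0.0)
        table = em.generate_qpcr(design)
        res = em.qpcr.analyze_ct_table(table, "M1-L", "M0-L")
        merip = res[res["assay"] == "merip_percent_input"].set_index("target")
        assert merip.loc["TGT_A", "value"] == pytest.approx(60.0, rel=1e-10)
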