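"""Synthetic-cohort generator: determinism, label bookkeeping, assay round-trips."""

import numpy as np
import pandas as pd
import pytest

from mitovar import (
    CohortDesign,
    Disparity,
    DeficiencyModel,
    generate_cohort,
    generate_annotations,
    generate_qpcr,
    generate_pyroseq,
    study_design,
    unique_fibre_count,
    classify_by_polygons,
    fleiss_kappa,
)
from tests.conftest import clean_design


class TestGenerateCohort:
    def test_fixed_seed_reproducibility(self):
        a = generate_cohort(clean_design(seed=7))
        b = generate_cohort(clean_design(seed=7))
        pd.testing.assert_frame_equal(a.fibres, b.fibres)
        pd.testing.assert_frame_equal(a.controls, b.controls)
        pd.testing.assert_frame_equal(a.biopsies, b.biopsies)

    def test_different_seeds_differ(self):
        a = generate_cohort(clean_design(seed=7))
        b = generate_cohort(clean_design(seed=8))
        assert not np.allclose(a.fibres["vdac1"], b.fibres["vdac1"])

    def test_deterministic_deficiency_counts(self, clean_cohort):
        """Every section realises exactly round(p * n) deficient fibres."""
        fib = clean_cohort.fibres
        for section, sub in fib.groupby("section"):
            assert (sub["true_NDUFB8"] == -1).sum() == 30
            assert (sub["true_MT-CO1"] == -1).sum() == 10

    def test_every_fibre_has_labels_and_one_section(self, clean_cohort):
        fib = clean_cohort.fibres
        assert fib["true_NDUFB8"].isin([-1, 0, 1]).all()
        assert fib["fibre_id"].is_unique
        # each section belongs to exactly one biopsy
        assert (fib.groupby("section")["biopsy"].nunique() == 1).all()

    def test_null_model_residuals_centred_on_control_line(self):
        """With identity disparity and no batch effects, patient fibres sit
        on the true control line up to Monte Carlo error."""
        design = clean_design(
            deficiency=DeficiencyModel(mean_proportion={"NDUFB8": 0.0, "MT-CO1": 0.0},
                                       muscle_offset={}, spatial_drift_sd=0.0),
            fibres_per_section=400,
            seed=3,
        )
        cohort = generate_cohort(design)
        line = design.control["NDUFB8"]
        resid = cohort.fibres["NDUFB8"] - (line.intercept + line.slope * cohort.fibres["vdac1"])
        n = len(resid)
        assert abs(resid.mean()) < 3 * line.residual_sd / np.sqrt(n)

    def test_ground_truth_block_is_contiguous(self, clean_cohort):
        for _, sub in clean_cohort.fibres.groupby("section"):
            flags = sub["in_ground_truth_region"].to_numpy()
            assert flags.sum() == 5  # 5% of 100
            on = np.flatnonzero(flags)
            assert np.array_equal(on, np.arange(on[0], on[0] + on.size))

    def test_rejects_unidentifiable_design(self):
        with pytest.raises(ValueError, match="deficient_shift"):
            generate_cohort(clean_design(deficient_shift=0.0))

    def test_rejects_bad_l_split(self):
        with pytest.raises(ValueError, match="unknown biopsies"):
            CohortDesign(l_split_pairs=[("P1_QD_b1", "P9_QD_b9", 10.0)]).validate()
        with pytest.raises(ValueError, match="distance"):
            CohortDesign(
                biopsies_per_muscle=2,
                l_split_pairs=[("P1_QD_b1", "P1_QD_b2", -1.0)],
            ).validate()

    def test_l_split_positions_respect_recorded_distance(self):
        design = clean_design(l_split_pairs=[("P1_QD_b1", "P1_QD_b2", 14.4)])
        cohort = generate_cohort(design)
        pos = cohort.biopsies.set_index("biopsy")["position_mm"]
        assert pos["P1_QD_b2"] - pos["P1_QD_b1"] == pytest.approx(14.4)

    def test_study_design_structure(self):
        design = study_design(fibres_per_section=50)
        design.validate()
        total_biopsies = sum(
            design.biopsies_for(p, m) for p in design.patient_ids() for m in design.muscles
        )
        assert total_biopsies == 31
        assert len(design.l_split_pairs) == 4
        dists = [d for _, _, d in design.l_split_pairs]
        assert np.mean(dists) == pytest.approx(14.4, abs=0.1)

    def test_unique_fibre_arithmetic(self):
        assert unique_fibre_count(120_306, 3) == 40_102
        with pytest.raises(ValueError):
            unique_fibre_count(100, 3)


class TestGenerateAnnotations:
    def test_zero_jitter_polygons_reproduce_true_labels(self, clean_cohort):
        anns = generate_annotations(clean_cohort, n_investigators=1,
                                    boundary_jitter_sd=0.0, seed=0)
        labels = classify_by_polygons(clean_cohort.fibres, anns, "NDUFB8")
        assert np.array_equal(labels["label"].to_numpy(),
                              clean_cohort.fibres["true_NDUFB8"].to_numpy())

    def test_zero_jitter_unanimity_gives_fleiss_kappa_one(self, clean_cohort):
        anns = generate_annotations(clean_cohort, n_investigators=3,
                                    boundary_jitter_sd=0.0, seed=0)
        tables = [
            classify_by_polygons(
                clean_cohort.fibres,
                [a for a in anns if a.investigator == inv], "NDUFB8")
            for inv in ("I1", "I2", "I3")
        ]
        matrix = np.column_stack([t["label"].to_numpy() for t in tables])
        assert fleiss_kappa(matrix) == pytest.approx(1.0)

    def test_agreement_decreases_with_jitter(self, clean_cohort):
        """Average inter-investigator Fleiss' kappa falls as polygon
        boundaries are jittered harder."""
        kappas = []
        for jitter in (0.0, 60.0, 300.0):
            vals = []
            for seed in (1, 2, 3):
                anns = generate_annotations(clean_cohort, n_investigators=3,
                                            boundary_jitter_sd=jitter, seed=seed)
                tables = [
                    classify_by_polygons(
                        clean_cohort.fibres,
                        [a for a in anns if a.investigator == inv], "NDUFB8")
                    for inv in ("I1", "I2", "I3")
                ]
                matrix = np.column_stack([t["label"].to_numpy() for t in tables])
                vals.append(fleiss_kappa(matrix))
            kappas.append(np.mean(vals))
        assert kappas[0] == pytest.approx(1.0)
        assert kappas[0] > kappas[1] > kappas[2]


class TestGenerateQpcr:
    def test_noiseless_plate_inverts_exactly(self):
        plate = generate_qpcr(["b1"], {"b1": 1476.0}, cq_noise_sd=0.0, seed=0)
        slope, intercept = plate.true_curve["MT-ND1"]
        nd1 = 10 ** ((plate.biopsy_cq["b1"]["MT-ND1"][0] - intercept) / slope)
        b2m = 10 ** ((plate.biopsy_cq["b1"]["B2M"][0] - intercept) / slope)
        assert nd1 / (b2m / 2) == pytest.approx(1476.0, rel=1e-9)

    def test_standard_curve_line_evaluation(self):
        """Cq for 1,000 copies on a slope -3.3219 / intercept 38 curve."""
        plate = generate_qpcr(["b1"], {"b1": 1000.0}, cq_noise_sd=0.0, seed=0,
                              dilution_copies=(1e4, 1e3, 1e2))
        copies_1000_cq = plate.dilution_series["MT-ND1"][1][1][0]
        assert copies_1000_cq == pytest.approx(38 - 3.3219 * 3)  # = 28.0343

    def test_six_replicates_by_default(self):
        plate = generate_qpcr(["b1"], {"b1": 1000.0}, seed=0)
        assert all(len(r) == 6 for r in plate.biopsy_cq["b1"].values())
        assert all(len(reps) == 6 for _, reps in plate.dilution_series["B2M"])

    def test_rejects_invalid_curve(self):
        with pytest.raises(ValueError, match="slope"):
            generate_qpcr(["b1"], {"b1": 1000.0}, curve={"MT-ND1": (0.0, 38.0), "B2M": (-3.3, 38.0)})
        with pytest.raises(ValueError, match="mtDNAcn"):
            generate_qpcr(["b1"], {"b1": -5.0})


class TestGeneratePyroseq:
    @staticmethod
    def _biopsies():
        return pd.DataFrame({
            "patient": ["P2", "P2"], "muscle": ["QD", "TA"],
            "biopsy": ["P2_QD_b1", "P2_TA_b1"],
        })

    def test_zero_noise_triplicates_equal_truth(self):
        recs = generate_pyroseq(self._biopsies(), {"QD": 83.0, "TA": 85.0},
                                between_biopsy_sd=0.0, replicate_sd=0.0, seed=0)
        by_id = {r.biopsy: r for r in recs}
        assert by_id["P2_QD_b1"].replicates == [83.0] * 3
        assert by_id["P2_TA_b1"].replicates == [85.0] * 3

    def test_biopsy_means_straddle_muscle_means(self):
        """With QD/TA means of 83 and 85 percent, generated biopsy means stay
        near those values."""
        biopsies = pd.DataFrame({
            "patient": "P2", "muscle": np.repeat(["QD", "TA"], 6),
            "biopsy": [f"P2_{m}_b{i}" for m in ("QD", "TA") for i in range(6)],
        })
        recs = generate_pyroseq(biopsies, {"QD": 83.0, "TA": 85.0},
                                between_biopsy_sd=2.0, replicate_sd=0.5, seed=5)
        qd = [np.mean(r.replicates) for r in recs if "QD" in r.biopsy and not r.is_standard]
        ta = [np.mean(r.replicates) for r in recs if "TA" in r.biopsy and not r.is_standard]
        assert abs(np.mean(qd) - 83.0) < 3 * 2.0 / np.sqrt(len(qd))
        assert abs(np.mean(ta) - 85.0) < 3 * 2.0 / np.sqrt(len(ta))

    def test_standards_round_trip(self):
        recs = generate_pyroseq(self._biopsies(), {"QD": 50.0, "TA": 50.0},
                                between_biopsy_sd=1.0, replicate_sd=1.0, seed=2)
        standards = [r for r in recs if r.is_standard]
        assert [r.true_heteroplasmy for r in standards] == [0.0, 16.0, 52.0, 92.0]
        for r in standards:
            se = 1.0 / np.sqrt(3)
            # the 0% standard is clipped at zero, so only check one side there
            if r.true_heteroplasmy == 0.0:
                assert np.mean(r.replicates) <= 3 * se
            else:
                assert abs(np.mean(r.replicates) - r.true_heteroplasmy) < 3 * se

    def test_values_bounded(self):
        recs = generate_pyroseq(self._biopsies(), {"QD": 99.0, "TA": 1.0},
                                between_biopsy_sd=5.0, replicate_sd=5.0, seed=1)
        for r in recs:
            assert all(0.0 <= v <= 100.0 for v in r.replicates)
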