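import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from proteoflux import kinetics as kin
from proteoflux import ontology as onto
from proteoflux import proteostasis as ps
from proteoflux import synthdata as sd


def noise_free(config):
    return dataclasses.replace(
        config, fraction_new_noise_sd=0.0, lfq_noise_sd_log2=0.0,
        missing_rate=0.0, sample_effect_sd_log2=0.0,
    )


class TestGroundTruth:
    def test_count_forced_by_config(self):
        config = sd.SynthConfig(seed=7, n_proteins=500, n_ontologies=25,
                                proteins_per_ontology=20, peptides_per_protein=2)
        assert len(sd.generate_ground_truth(config)) == 500

    def test_determinism(self, small_config):
        a = sd.generate_ground_truth(small_config)
        b = sd.generate_ground_truth(small_config)
        assert a == b

    def test_degup_arithmetic(self):
        config = sd.SynthConfig(seed=1, n_proteins=25, n_ontologies=5,
                                proteins_per_ontology=5, effect_size_log2=0.5,
                                peptides_per_protein=2)
        truth = sd.generate_ground_truth(config)
        degup = [p for p in truth if p.regulation_class == ps.DEG_UP]
        assert degup
        for p in degup:
            assert p.params_experimental.kdeg == pytest.approx(
                p.params_control.kdeg * 2**0.5
            )
            assert p.params_experimental.steady_state == pytest.approx(
                p.params_control.steady_state * 2**-0.5
            )

    def test_class_sign_pattern_consistency(self, small_config):
        # the generated (Δlog2 steady state, Δlog2 kdeg) signs match the class
        expected_signs = {
            ps.SYN_UP: (1, 1), ps.SYN_DOWN: (-1, -1),
            ps.DEG_UP: (-1, 1), ps.DEG_DOWN: (1, -1), "Null": (0, 0),
        }
        for p in sd.generate_ground_truth(small_config):
            d_ab = np.log2(p.params_experimental.steady_state
                           / p.params_control.steady_state)
            d_tv = np.log2(p.params_experimental.kdeg / p.params_control.kdeg)
            assert (np.sign(round(d_ab, 12)), np.sign(round(d_tv, 12))) == \
                expected_signs[p.regulation_class]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            sd.SynthConfig(n_proteins=0)
        with pytest.raises(ValueError):
            sd.SynthConfig(n_proteins=10, n_ontologies=5, proteins_per_ontology=10)
        with pytest.raises(ValueError):
            sd.SynthConfig(timepoints=(1.0, 2.0))
        with pytest.raises(ValueError):
            sd.SynthConfig(missing_rate=0.5)


class TestTimeCourses:
    def test_noiseless_closed_form(self, small_config):
        config = dataclasses.replace(
            noise_free(small_config), n_proteins=4, n_ontologies=1,
            proteins_per_ontology=4, timepoints=(0.0, 0.25, 1.0, 4.0, 16.0, 32.0),
        )
        truth = sd.generate_ground_truth(config)
        courses = sd.simulate_time_courses(truth, config, "control")
        by_protein = {p.protein_id: p for p in truth}
        for course in courses:
            kdeg = by_protein[course.protein_id].params_control.kdeg
            for t, f in course.observations:
                assert f == pytest.approx(1 - np.exp(-kdeg * t), abs=1e-12)
                if t == 0:
                    assert f == 0.0

    def test_half_life_value(self):
        config = sd.SynthConfig(
            seed=2, n_proteins=1, n_ontologies=1, proteins_per_ontology=1,
            peptides_per_protein=1, fraction_new_noise_sd=0.0,
            timepoints=(0.0, 1.0), kdeg_range=(np.log(2) * 0.999999,
                                               np.log(2) * 1.000001),
        )
        truth = sd.generate_ground_truth(config)
        courses = sd.simulate_time_courses(truth, config, "control")
        assert courses[0].observations[1][1] == pytest.approx(0.5, abs=1e-5)

    def test_n_values_match_sequences(self, small_config):
        truth = sd.generate_ground_truth(small_config)
        courses = sd.simulate_time_courses(truth, small_config, "experimental")
        for course in courses[:50]:
            assert course.n_value == pytest.approx(
                kin.compute_n_value(course.peptide_sequence)
            )

    def test_unknown_genotype_rejected(self, small_config):
        truth = sd.generate_ground_truth(small_config)
        with pytest.raises(ValueError):
            sd.simulate_time_courses(truth, small_config, "mutant")


class TestLFQ:
    def test_no_missing_when_rate_zero(self, small_config):
        config = dataclasses.replace(small_config, missing_rate=0.0)
        truth = sd.generate_ground_truth(config)
        matrix = sd.simulate_lfq(truth, config)
        assert not matrix.values.isna().any().any()

    def test_noise_free_areas_equal_steady_state(self, small_config):
        config = noise_free(small_config)
        truth = sd.generate_ground_truth(config)
        matrix = sd.simulate_lfq(truth, config)
        for p in truth[:10]:
            row = matrix.values.loc[p.protein_id]
            ctrl = row[[s for s in matrix.sample_ids if s.startswith("control")]]
            assert np.allclose(ctrl, p.params_control.steady_state, rtol=1e-12)

    def test_synup_ratio_is_effect_size(self, small_config):
        config = dataclasses.replace(noise_free(small_config), effect_size_log2=1.0)
        truth = sd.generate_ground_truth(config)
        matrix = sd.simulate_lfq(truth, config)
        synup = next(p for p in truth if p.regulation_class == ps.SYN_UP)
        row = matrix.values.loc[synup.protein_id]
        ctrl = row[[s for s in matrix.sample_ids if s.startswith("control")]].mean()
        exp = row[[s for s in matrix.sample_ids if s.startswith("experimental")]].mean()
        assert exp / ctrl == pytest.approx(2.0)

    def test_conservation_under_labeling(self, small_config):
        # labeled + unlabeled pools sum to the steady state at all times
        truth = sd.generate_ground_truth(noise_free(small_config))
        for p in truth[:20]:
            for t in (0.0, 1.0, 4.0, 16.0):
                state = kin.concentration_trajectory(p.params_control, t)
                assert state.P + state.P_D == pytest.approx(
                    p.params_control.steady_state, rel=1e-12
                )


class TestEmit:
    def emit(self, tmp_path, config):
        truth = sd.generate_ground_truth(config)
        courses = sd.simulate_time_courses(truth, config, "control")
        courses += sd.simulate_time_courses(truth, config, "experimental")
        matrix = sd.simulate_lfq(truth, config)
        return truth, sd.emit_fixture_files(truth, courses, matrix, tmp_path, config)

    def test_output_files_exist(self, tmp_path, small_config):
        _, paths = self.emit(tmp_path / "out", small_config)
        for name in ("areas", "time_courses", "ontology", "ground_truth"):
            assert paths[name].exists()

    def test_ontology_round_trip(self, tmp_path, small_config):
        truth, paths = self.emit(tmp_path / "out", small_config)
        records = onto.parse_stringdb_table(paths["ontology"])
        emitted = pd.read_csv(paths["ontology"], sep="\t")
        assert len(records) == len(emitted)
        by_id = {r.term_id: r for r in records}
        for _, row in emitted.iterrows():
            rec = by_id[row["term ID"]]
            labels = tuple(row["matching proteins in your network (labels)"].split(","))
            assert rec.matching_labels == labels
            assert rec.observed_gene_count == row["observed gene count"]
            assert rec.observed_gene_count == len(labels)

    def test_byte_identical_across_runs(self, tmp_path, small_config):
        _, paths1 = self.emit(tmp_path / "a", small_config)
        _, paths2 = self.emit(tmp_path / "b", small_config)
        for name in paths1:
            assert paths1[name].read_bytes() == paths2[name].read_bytes()


class TestClassSeparation:
    def test_signs_recover_classes_without_noise(self, small_config):
        config = noise_free(small_config)
        truth = sd.generate_ground_truth(config)
        courses_c = sd.simulate_time_courses(truth, config, "control")
        courses_e = sd.simulate_time_courses(truth, config, "experimental")
        matrix = sd.simulate_lfq(truth, config)

        k_ctrl = {c.protein_id: kin.fit_turnover([c]).k_turnover for c in courses_c}
        k_exp = {c.protein_id: kin.fit_turnover([c]).k_turnover for c in courses_e}
        terms: dict[str, list[str]] = {}
        for p in truth:
            for term in p.ontology_ids:
                terms.setdefault(term, []).append(p.protein_id)
        truth_by_id = {p.protein_id: p for p in truth}
        expected_signs = {
            ps.SYN_UP: (1, 1), ps.SYN_DOWN: (-1, -1),
            ps.DEG_UP: (-1, 1), ps.DEG_DOWN: (1, -1),
        }
        exp_cols = [s for s in matrix.sample_ids if s.startswith("experimental")]
        ctrl_cols = [s for s in matrix.sample_ids if s.startswith("control")]
        for term, members in terms.items():
            cls = truth_by_id[members[0]].regulation_class
            if cls == "Null":
                continue
            d_ab = np.mean([
                np.log2(matrix.values.loc[m, exp_cols].mean()
                        / matrix.values.loc[m, ctrl_cols].mean())
                for m in members
            ])
            d_tv = np.mean([
                np.log2(k_exp[m] / k_ctrl[m]) for m in members
            ])
            assert (np.sign(d_ab), np.sign(d_tv)) == expected_signs[cls], term
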