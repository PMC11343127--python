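import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteoflux import abundance as ab
from proteoflux.abundance import AbundanceMatrix


def make_matrix(values, genotype_of=None, **kwargs):
    df = pd.DataFrame(values)
    if genotype_of is None:
        genotype_of = {c: ("control" if str(c).startswith("c") else "experimental")
                       for c in df.columns}
    return AbundanceMatrix(values=df, genotype_of=genotype_of, **kwargs)


class TestMissingnessFilter:
    def base(self, p1_row):
        values = {
            "c1": [1.0, p1_row[0]], "c2": [1.0, p1_row[1]],
            "c3": [1.0, p1_row[2]], "c4": [1.0, p1_row[3]],
            "e1": [1.0, p1_row[4]], "e2": [1.0, p1_row[5]],
            "e3": [1.0, p1_row[6]], "e4": [1.0, p1_row[7]],
        }
        df = pd.DataFrame(values, index=["P0", "P1"])
        return make_matrix(df)

    def test_two_missing_in_one_genotype_dropped(self):
        out = ab.filter_missingness(
            self.base([np.nan, np.nan, 1, 1, 1, 1, 1, 1])
        )
        assert list(out.values.index) == ["P0"]

    def test_fully_observed_retained(self):
        out = ab.filter_missingness(self.base([1] * 8))
        assert list(out.values.index) == ["P0", "P1"]

    def test_one_missing_per_genotype_retained(self):
        out = ab.filter_missingness(
            self.base([np.nan, 1, 1, 1, np.nan, 1, 1, 1])
        )
        assert "P1" in out.values.index

    def test_group_representative_flag(self):
        matrix = self.base([1] * 8)
        matrix.group_representative = {"P0": True, "P1": False}
        out = ab.filter_missingness(matrix)
        assert list(out.values.index) == ["P0"]


class TestLog2AndCenter:
    def test_log2_then_column_centering(self):
        matrix = make_matrix(
            {"c1": [1024.0, 4096.0], "e1": [2.0, 8.0]},
            genotype_of={"c1": "control", "e1": "experimental"},
        )
        out = ab.log2_and_center(matrix)
        np.testing.assert_allclose(out.values["c1"], [-1.0, 1.0])
        assert np.log2(1024.0) == 10.0

    def test_column_means_zero_and_idempotent(self, simple_matrix):
        out = ab.log2_and_center(simple_matrix)
        assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        # centering an already-centered matrix changes nothing
        again = out.values - out.values.mean(axis=0)
        pd.testing.assert_frame_equal(again, out.values)

    def test_nonpositive_area_rejected(self):
        matrix = make_matrix({"c1": [1.0, -2.0], "e1": [1.0, 2.0]},
                             genotype_of={"c1": "control", "e1": "experimental"})
        with pytest.raises(ValueError, match="c1"):
            ab.log2_and_center(matrix)


class TestSlopeNormalize:
    def test_half_slope_sample_rescaled(self):
        # reference profile is the row mean; the narrow sample has slope 0.5
        df = pd.DataFrame(
            {"s1": [-3.0, 0.0, 3.0], "s2": [-3.0, 0.0, 3.0], "s3": [-1.0, 0.0, 1.0]},
            index=["P0", "P1", "P2"],
        )
        # row means: [-7/3, 0, 7/3]; slope of s3 on reference = (1)/(7/3)
        matrix = AbundanceMatrix(values=df, genotype_of={s: "g" for s in df})
        out, slopes = ab.slope_normalize(matrix)
        assert slopes["s3"] == pytest.approx(3 / 7)
        np.testing.assert_allclose(out.values["s3"], [-7 / 3, 0.0, 7 / 3])

    def test_identical_samples_are_untouched(self):
        df = pd.DataFrame({"s1": [-2.0, 0.0, 2.0], "s2": [-2.0, 0.0, 2.0]})
        matrix = AbundanceMatrix(values=df, genotype_of={"s1": "a", "s2": "b"})
        out, slopes = ab.slope_normalize(matrix)
        assert np.allclose(slopes, 1.0)
        pd.testing.assert_frame_equal(out.values, df)

    def test_constant_sample_is_degenerate(self):
        df = pd.DataFrame({"s1": [-2.0, 0.0, 2.0], "s2": [0.0, 0.0, 0.0]})
        matrix = AbundanceMatrix(values=df, genotype_of={"s1": "a", "s2": "b"})
        with pytest.raises(ValueError, match="s2"):
            ab.slope_normalize(matrix)

    def test_injected_sample_effects_removed(self):
        # per-sample multiplicative factors vanish after center + slope-normalize
        rng = np.random.default_rng(3)
        profile = rng.uniform(15, 25, size=(30, 1))
        clean_log2 = np.repeat(profile, 6, axis=1)
        offsets = rng.normal(0, 0.5, size=6)
        areas = 2.0 ** (clean_log2 + offsets)
        samples = [f"s{i}" for i in range(6)]
        genotype_of = {s: ("control" if i < 3 else "experimental")
                       for i, s in enumerate(samples)}
        matrix = AbundanceMatrix(
            values=pd.DataFrame(areas, columns=samples), genotype_of=genotype_of
        )
        out, _ = ab.slope_normalize(ab.log2_and_center(matrix))
        expected = clean_log2 - clean_log2.mean(axis=0)
        assert np.abs(out.values.to_numpy() - expected).max() < 1e-6


class TestImputeKNN:
    def test_mean_of_two_nearest_neighbors(self):
        df = pd.DataFrame(
            {"s1": [1.0, 2.0, 1.5], "s2": [1.0, 2.0, 1.5], "s3": [1.0, 2.0, np.nan]},
            index=["P1", "P2", "P3"],
        )
        matrix = AbundanceMatrix(values=df, genotype_of={s: "g" for s in df})
        out = ab.impute_knn(matrix, k=2)
        assert out.values.loc["P3", "s3"] == pytest.approx(1.5)

    def test_no_missing_is_identity(self, simple_matrix):
        out = ab.impute_knn(simple_matrix)
        assert out is simple_matrix

    def test_imputed_values_bounded_by_donors(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(10, 20, size=(40, 8))
        mask = rng.random(values.shape) < 0.1
        masked = np.where(mask, np.nan, values)
        samples = [f"s{i}" for i in range(8)]
        matrix = AbundanceMatrix(
            values=pd.DataFrame(masked, columns=samples),
            genotype_of={s: "g" for s in samples},
        )
        out = ab.impute_knn(matrix, k=2)
        filled = out.values.to_numpy()
        assert not np.isnan(filled).any()
        for i, j in zip(*np.nonzero(mask)):
            col = masked[:, j]
            donors = col[~np.isnan(col)]
            assert donors.min() - 1e-9 <= filled[i, j] <= donors.max() + 1e-9


class TestVarianceGatedTest:
    def test_pooled_branch_closed_form(self):
        p, f_p, used = ab.variance_gated_test([1, 2, 3], [2, 3, 4])
        assert f_p == pytest.approx(1.0)
        assert used == "homoscedastic"
        assert p == pytest.approx(0.2878, abs=2e-4)

    def test_identical_groups(self):
        p, _, _ = ab.variance_gated_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_unequal_variances_take_welch_branch(self):
        p, f_p, used = ab.variance_gated_test([0.0, 0.1, -0.1], [-5.0, 0.0, 5.0])
        assert f_p < 0.05
        assert used == "heteroscedastic"

    def test_too_few_replicates(self):
        with pytest.raises(ValueError, match="3 measurements"):
            ab.variance_gated_test([1, 2], [1, 2, 3])

    def test_null_calibration(self):
        # false-positive rate at alpha=0.05 over seeded null simulations
        rng = np.random.default_rng(2024)
        hits = 0
        n = 2000
        for _ in range(n):
            p, _, _ = ab.variance_gated_test(rng.normal(size=4), rng.normal(size=4))
            hits += p < 0.05
        assert hits / n == pytest.approx(0.05, abs=0.015)


class TestProteinFoldChanges:
    def test_uniform_shift(self, simple_matrix):
        processed = ab.impute_knn(ab.log2_and_center(simple_matrix))
        fcs = {f.protein_id: f for f in ab.protein_fold_changes(
            processed, "experimental", "control")}
        # P2 doubled in experimental samples; per-sample centering reabsorbs
        # 1/10 of the shift into each column mean, leaving 0.9
        assert fcs["P2"].fc_log2 == pytest.approx(0.9, abs=1e-9)

    def test_equal_groups_zero(self):
        df = pd.DataFrame({c: [5.0, 7.0] for c in ["c1", "c2", "c3", "e1", "e2", "e3"]})
        matrix = make_matrix(df)
        fcs = ab.protein_fold_changes(matrix, "experimental", "control")
        assert all(f.fc_log2 == 0.0 for f in fcs)

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            rng.normal(size=(12, 8)),
            columns=[f"c{i}" for i in range(4)] + [f"e{i}" for i in range(4)],
        )
        matrix = make_matrix(df)
        ab_fc = ab.protein_fold_changes(matrix, "experimental", "control")
        ba_fc = ab.protein_fold_changes(matrix, "control", "experimental")
        for f1, f2 in zip(ab_fc, ba_fc):
            assert f1.fc_log2 == pytest.approx(-f2.fc_log2)
            assert f1.p_value == pytest.approx(f2.p_value)


class TestAveraging:
    def fc(self, pid, value):
        return ab.ProteinFC(protein_id=pid, fc_log2=value, p_value=0.5)

    def test_single_dataset_identity(self):
        out = ab.average_fc_across_datasets([[self.fc("P1", 0.2)]])
        assert out[0].fc_log2 == 0.2 and out[0].n_datasets == 1

    def test_mean_and_bookkeeping(self):
        out = ab.average_fc_across_datasets(
            [[self.fc("P1", 0.2)], [self.fc("P1", 0.4)], [self.fc("P2", 1.0)]]
        )
        by_id = {f.protein_id: f for f in out}
        assert by_id["P1"].fc_log2 == pytest.approx(0.3)
        assert by_id["P1"].n_datasets == 2
        assert by_id["P2"].n_datasets == 1
        assert set(by_id) == {"P1", "P2"}


class TestRangeScale:
    def test_example(self):
        scaled, summary = ab.range_scale([1.0, 2.0, 3.0, 6.0])
        np.testing.assert_allclose(scaled, [-0.4, -0.2, 0.0, 0.6])
        assert summary.min == 1.0 and summary.max == 6.0

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=40, unique=True))
    @settings(max_examples=50, derandomize=True)
    def test_unit_spread_zero_mean(self, values):
        scaled, _ = ab.range_scale(values)
        assert np.ptp(scaled) == pytest.approx(1.0, rel=1e-9)
        assert np.mean(scaled) == pytest.approx(0.0, abs=1e-9)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            ab.range_scale([2.0, 2.0])
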