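"""RPM normalization, aggregate ratios, depth factors, profile summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from trescreen import simulate
from trescreen.quantify import (
    aggregate_ratio,
    barcode_fold_changes,
    profile_summaries,
    rpm,
    upper_quartile_factors,
)


class TestRpm:
    def test_column_values(self):
        m = pd.DataFrame({"s1": [1, 1, 2]})
        assert list(rpm(m)["s1"]) == [250000.0, 250000.0, 500000.0]

    def test_column_sums_are_one_million(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.integers(0, 100, size=(50, 4)))
        assert np.allclose(rpm(m).sum(axis=0), 1e6)

    def test_scale_invariance_per_column(self):
        m = pd.DataFrame({"a": [3, 5, 9], "b": [1, 2, 3]})
        doubled = m.copy()
        doubled["a"] *= 2
        pd.testing.assert_frame_equal(rpm(m), rpm(doubled))

    def test_zero_total_sample_raises_with_name(self):
        m = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            rpm(m)


class TestAggregateRatio:
    B2P = {"b1": "P", "b2": "P", "b3": "Q"}

    def test_identity_when_rna_equals_dna(self):
        m = pd.DataFrame({"s": [10.0, 30.0, 5.0]}, index=["b1", "b2", "b3"])
        r = aggregate_ratio(m, m.rename(columns={"s": "d"}), self.B2P)
        assert np.allclose(r["s"], 1.0)

    def test_hand_computed_ratio(self):
        rna = pd.DataFrame({"s": [10.0, 30.0]}, index=["b1", "b2"])
        dna = pd.DataFrame({"d": [20.0, 20.0]}, index=["b1", "b2"])
        r = aggregate_ratio(rna, dna, self.B2P)
        assert r.loc["P", "s"] == pytest.approx(1.0)

    def test_zero_dna_promoter_flagged_nan(self):
        rna = pd.DataFrame({"s": [10.0, 4.0]}, index=["b1", "b3"])
        dna = pd.DataFrame({"d": [20.0, 0.0]}, index=["b1", "b3"])
        r = aggregate_ratio(rna, dna, self.B2P)
        assert np.isnan(r.loc["Q", "s"]) and r.loc["P", "s"] == pytest.approx(0.5)

    def test_invariant_to_scaling_raw_counts_of_a_sample(self):
        rng = np.random.default_rng(2)
        raw = pd.DataFrame(
            rng.integers(1, 200, size=(6, 3)).astype(float),
            index=list(self.B2P) * 2,
            columns=["rna1", "rna2", "dna"],
        )
        raw.index = [f"b{i}" for i in range(6)]
        b2p = {f"b{i}": "P" if i < 3 else "Q" for i in range(6)}
        r1 = aggregate_ratio(rpm(raw[["rna1", "rna2"]]), rpm(raw[["dna"]]), b2p)
        scaled = raw.copy()
        scaled["rna1"] *= 17.0
        r2 = aggregate_ratio(rpm(scaled[["rna1", "rna2"]]), rpm(scaled[["dna"]]), b2p)
        pd.testing.assert_frame_equal(r1, r2)

    def test_increasing_one_rna_count_raises_only_that_promoter(self):
        raw = pd.DataFrame(
            {"rna": [5.0, 7.0, 11.0], "dna": [4.0, 4.0, 4.0]},
            index=["b1", "b2", "b3"],
        )
        before = aggregate_ratio(rpm(raw[["rna"]]), rpm(raw[["dna"]]), self.B2P)
        bumped = raw.copy()
        bumped.loc["b1", "rna"] += 5
        after = aggregate_ratio(rpm(bumped[["rna"]]), rpm(bumped[["dna"]]), self.B2P)
        assert after.loc["P", "rna"] > before.loc["P", "rna"]
        # note: RPM renormalization lowers the other promoter, never raises it
        assert after.loc["Q", "rna"] <= before.loc["Q", "rna"]

    def test_rate_recovery_on_simulated_screen(self):
        cfg = simulate.SimulationConfig(
            n_barcodes_per_promoter=20, dna_depth=100, rna_depth=100,
            sample_depth_sigma=0.1,
        )
        truth, cm = simulate.simulate_counts(cfg, n_promoters=200, seed=4)
        norm = rpm(cm.values)
        rna = cm.samples("RNA", condition="ctrl")
        dna = cm.samples("DNA")
        rates = aggregate_ratio(norm[rna], norm[dna], truth.barcode_to_promoter)
        est = rates.mean(axis=1).reindex(truth.baseline_rate.index)
        rho = spearmanr(est, truth.baseline_rate).statistic
        assert rho >= 0.95


class TestFoldChanges:
    def test_identical_arms_give_unity(self):
        m = pd.DataFrame({"a": [5.0, 8.0], "b": [5.0, 8.0]})
        fc = barcode_fold_changes(m, m)
        assert np.allclose(fc, 1.0)

    def test_median_arithmetic(self):
        t = pd.DataFrame({"t1": [2.0], "t2": [4.0], "t3": [6.0]})
        c = pd.DataFrame({"c1": [1.0], "c2": [2.0], "c3": [3.0]})
        assert barcode_fold_changes(t, c).iloc[0] == pytest.approx(2.0)

    def test_zero_control_median_undefined(self):
        t = pd.DataFrame({"t": [2.0]})
        c = pd.DataFrame({"c": [0.0]})
        assert np.isnan(barcode_fold_changes(t, c).iloc[0])


class TestUpperQuartile:
    def test_reference_factor_is_one(self):
        m = pd.DataFrame({"ref": [1, 2, 3, 4], "s": [2, 4, 6, 8]})
        f = upper_quartile_factors(m, reference="ref")
        assert f["ref"] == 1.0 and f["s"] == pytest.approx(2.0)

    def test_interpolated_quartile_convention(self):
        # zeros of barcodes expressed in some sample stay in the quantile;
        # expected values recomputed independently with numpy's percentile
        m = pd.DataFrame({"ref": list(range(1, 51)) + [0] * 50,
                          "s": list(range(1, 101))})
        f = upper_quartile_factors(m, reference="ref")
        expect = np.percentile(m["s"], 75) / np.percentile(m["ref"], 75)
        assert f["s"] == pytest.approx(expect, rel=1e-12)
        assert np.percentile(m["s"], 75) == pytest.approx(75.25)

    def test_nonzero_only_truncated_convention(self):
        m = pd.DataFrame({"ref": list(range(1, 51)) + [0] * 50,
                          "s": list(range(1, 101))})
        f = upper_quartile_factors(m, reference="ref", nonzero_only=True)
        assert f["s"] == pytest.approx(75.25 / 37.75, rel=1e-12)

    def test_all_zero_rows_do_not_dilute_the_quantile(self):
        m = pd.DataFrame({"ref": [4, 8, 12, 16], "s": [8, 16, 24, 32]})
        padded = pd.concat(
            [m, pd.DataFrame({"ref": [0] * 20, "s": [0] * 20})],
            ignore_index=True,
        )
        pd.testing.assert_series_equal(
            upper_quartile_factors(m, reference="ref"),
            upper_quartile_factors(padded, reference="ref"),
        )

    def test_all_zero_sample_raises(self):
        m = pd.DataFrame({"ref": [1, 2], "dead": [0, 0]})
        with pytest.raises(ValueError, match="dead"):
            upper_quartile_factors(m, reference="ref")


class TestProfileSummaries:
    def test_identical_columns_merge_first(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        m = pd.DataFrame({"a": base, "b": base, "c": rng.normal(size=8) + 5})
        out = profile_summaries(m)
        order = out["col_order"]
        assert abs(order.index("a") - order.index("b")) == 1

    def test_rank_one_matrix_has_null_second_singular_value(self):
        u = np.arange(1, 7, dtype=float)
        m = pd.DataFrame(np.outer(u, [1.0, 2.0, 3.0]))
        # column-standardization makes all columns identical -> rank 1
        out = profile_summaries(m)
        assert out["singular_values"][1] == pytest.approx(0.0, abs=1e-8)

    def test_block_structure_separates_in_dendrogram(self):
        m = pd.DataFrame(
            [[10.0, 10.5, 0.0, 0.2], [10.2, 9.9, 0.1, 0.0],
             [0.0, 0.3, 9.8, 10.1], [0.2, 0.0, 10.0, 10.2]],
            index=list("wxyz"),
        )
        out = profile_summaries(m)
        order = out["row_order"]
        assert {order.index("w"), order.index("x")} in ({0, 1}, {2, 3})

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame({"a": rng.normal(size=5), "b": rng.normal(size=5),
                          "const": np.ones(5)})
        with pytest.warns(UserWarning, match="const"):
            out = profile_summaries(m)
        assert "const" not in out["col_coords"].index

    def test_nan_rows_dropped(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(5, 3)))
        m.iloc[0, 0] = np.nan
        out = profile_summaries(m)
        assert 0 not in out["row_coords"].index
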