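"""Regulation-calling unit and property tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosreg import datasets, silac, simulate


def make_sites(rows):
    df = pd.DataFrame(
        rows,
        columns=["gene", "position", "residue", "localization_prob", "ratio_rep1", "ratio_rep2"],
    )
    df["protein"] = df["gene"]
    df["sequence_window"] = "X" * 13
    return df


class TestClass1Filter:
    def test_boundary_and_residue_rules(self):
        df = make_sites(
            [
                ("A", 1, "Y", 0.75, 1.0, 1.0),  # boundary inclusive
                ("B", 2, "S", 0.74, 1.0, 1.0),  # below cutoff
                ("C", 3, "H", 0.99, 1.0, 1.0),  # non-STY
                ("D", 4, "T", 1.00, 1.0, 1.0),
            ]
        )
        kept = silac.filter_class1(df)
        assert list(kept["gene"]) == ["A", "D"]

    def test_order_preserved(self):
        rec, _ = simulate.gen_silac_dataset(simulate.SilacSimConfig(n_sites=500, seed=0))
        kept = silac.filter_class1(rec)
        assert list(kept.index) == sorted(kept.index)


class TestHarmonize:
    def test_reciprocal_fixed_point_passthrough(self):
        df = pd.DataFrame({"ratio_rep1": [1.0, 1.0, 1.0], "ratio_rep2_raw": [2.0, 1.0, 0.679]})
        swapped = silac.harmonize_label_swap(df, rep2_swapped=True)
        np.testing.assert_allclose(swapped["ratio_rep2"], [0.5, 1.0, 1.0 / 0.679])
        plain = silac.harmonize_label_swap(df, rep2_swapped=False)
        np.testing.assert_allclose(plain["ratio_rep2"], [2.0, 1.0, 0.679])

    def test_idempotent(self):
        df = pd.DataFrame({"ratio_rep1": [1.0], "ratio_rep2_raw": [2.0]})
        once = silac.harmonize_label_swap(df, rep2_swapped=True)
        twice = silac.harmonize_label_swap(once, rep2_swapped=True)
        pd.testing.assert_frame_equal(once, twice)

    def test_nonpositive_raw_ratio_rejected(self):
        df = pd.DataFrame({"ratio_rep1": [1.0], "ratio_rep2_raw": [0.0]})
        with pytest.raises(ValueError):
            silac.harmonize_label_swap(df)


class TestGaussianNull:
    def test_recovers_generator_sigma_pooled(self):
        cfg = simulate.SilacSimConfig(n_sites=20000, frac_regulated=0.0, seed=13)
        rec, _ = simulate.gen_silac_dataset(cfg)
        h = silac.harmonize_label_swap(rec)
        null = silac.fit_gaussian_null(h, mode="pooled_single_ratios")
        assert abs(null.sigma_log2 - 0.223) < 0.01
        assert abs(null.mu_log2) < 0.01

    def test_deterministic(self):
        rec, _ = simulate.gen_silac_dataset(simulate.SilacSimConfig(n_sites=2000, seed=1))
        h = silac.harmonize_label_swap(rec)
        a = silac.fit_gaussian_null(h)
        b = silac.fit_gaussian_null(h)
        assert (a.mu_log2, a.sigma_log2) == (b.mu_log2, b.sigma_log2)

    def test_degenerate_and_small_inputs_rejected(self):
        const = pd.DataFrame({"ratio_rep1": [1.0] * 200, "ratio_rep2": [1.0] * 200})
        with pytest.raises(ValueError, match="degenerate"):
            silac.fit_gaussian_null(const)
        small = pd.DataFrame({"ratio_rep1": [1.0, 2.0], "ratio_rep2": [1.0, 2.0]})
        with pytest.raises(ValueError, match="100"):
            silac.fit_gaussian_null(small)

    def test_ratio_of_ratios_mode_measures_replicate_disagreement(self):
        cfg = simulate.SilacSimConfig(
            n_sites=20000, frac_regulated=0.0, replicate_noise_log2=0.1, seed=3
        )
        rec, _ = simulate.gen_silac_dataset(cfg)
        h = silac.harmonize_label_swap(rec)
        null = silac.fit_gaussian_null(h, mode="ratio_of_ratios")
        assert abs(null.sigma_log2 - 0.1 * np.sqrt(2)) < 0.01


class TestThresholds:
    def test_printed_thresholds_from_sigma(self):
        null = silac.GaussianNull(0.0, 0.2233, "pooled_single_ratios", 50, 0.0)
        t = silac.derive_thresholds(null, k=2.5)
        assert round(t.up_thr, 3) == 1.472
        assert round(t.down_thr, 3) == 0.679

    def test_zero_k_collapses_to_unity(self):
        null = silac.GaussianNull(0.0, 0.5, "pooled_single_ratios", 10, 0.0)
        t = silac.derive_thresholds(null, k=0.0)
        assert t.up_thr == t.down_thr == 1.0

    def test_product_identity_and_symmetry(self):
        null = silac.GaussianNull(0.1, 0.2, "pooled_single_ratios", 10, 0.0)
        t = silac.derive_thresholds(null, k=2.5)
        assert t.up_thr * t.down_thr == pytest.approx(2.0**0.2)
        centered = silac.derive_thresholds(
            silac.GaussianNull(0.0, 0.31, "pooled_single_ratios", 10, 0.0), k=2.5
        )
        assert centered.up_thr * centered.down_thr == pytest.approx(1.0)

    def test_negative_k_rejected(self):
        null = silac.GaussianNull(0.0, 0.2, "pooled_single_ratios", 10, 0.0)
        with pytest.raises(ValueError):
            silac.derive_thresholds(null, k=-1.0)


TMD8 = silac.ThresholdSet(k=2.5, up_thr=1.472, down_thr=0.679)
U2932 = silac.ThresholdSet(k=2.5, up_thr=1.506, down_thr=0.664)


class TestCallRegulation:
    @pytest.mark.parametrize(
        "ratios,thresholds,expected",
        [
            ((0.34, 0.47), TMD8, "down"),  # ERK2 activation-loop site
            ((1.16, 0.87), U2932, "unchanged"),  # RSK1 C-terminal site
            ((0.5, 1.6), TMD8, "unchanged"),  # discordant directions
            ((1.5, 1.5), TMD8, "up"),
            ((0.679, 0.5), TMD8, "unchanged"),  # boundary is strict
            ((np.nan, 0.3), TMD8, "unchanged"),  # missing replicate
        ],
    )
    def test_direction_rules(self, ratios, thresholds, expected):
        df = make_sites([("G", 1, "S", 1.0, ratios[0], ratios[1])])
        calls = silac.call_regulation(df, thresholds)
        assert calls["direction"].iloc[0] == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        r1=st.floats(0.01, 100.0),
        r2=st.floats(0.01, 100.0),
        sigma=st.floats(0.05, 0.5),
        k=st.floats(0.5, 4.0),
    )
    def test_matches_brute_force_oracle(self, r1, r2, sigma, k):
        thresholds = silac.derive_thresholds(
            silac.GaussianNull(0.0, sigma, "pooled_single_ratios", 10, 0.0), k=k
        )
        df = make_sites([("G", 1, "S", 1.0, r1, r2)])
        got = silac.call_regulation(df, thresholds)["direction"].iloc[0]
        if r1 < thresholds.down_thr and r2 < thresholds.down_thr:
            expected = "down"
        elif r1 > thresholds.up_thr and r2 > thresholds.up_thr:
            expected = "up"
        else:
            expected = "unchanged"
        assert got == expected

    def test_monotone_in_k(self):
        rec, _ = simulate.gen_silac_dataset(
            simulate.SilacSimConfig(n_sites=5000, frac_regulated=0.05, effect_log2=0.9, seed=21)
        )
        h = silac.harmonize_label_swap(rec)
        null = silac.fit_gaussian_null(h)
        counts = []
        for k in (1.0, 1.5, 2.0, 2.5, 3.0, 4.0):
            calls = silac.call_regulation(h, silac.derive_thresholds(null, k=k))
            counts.append(int((calls["direction"] != "unchanged").sum()))
        assert counts == sorted(counts, reverse=True)

    def test_type_i_control_on_pure_null(self):
        rec, _ = simulate.gen_silac_dataset(
            simulate.SilacSimConfig(n_sites=20000, frac_regulated=0.0, seed=17)
        )
        h = silac.harmonize_label_swap(rec)
        thresholds = silac.derive_thresholds(silac.fit_gaussian_null(h), k=2.5)
        calls = silac.call_regulation(h, thresholds)
        assert (calls["direction"] != "unchanged").mean() < 0.01


class TestSummaryAndOverlap:
    def test_shared_sites_table_counts(self):
        tab = datasets.shared_downregulated_sites()
        df = tab.rename(columns={"tmd8_rep1": "ratio_rep1", "tmd8_rep2": "ratio_rep2"})
        calls = silac.call_regulation(df, TMD8)
        summary = silac.summarize_regulation(calls, n_quantified=9497)
        assert summary.n_down_sites == 5
        assert summary.n_down_proteins == 5
        assert summary.pct_down == 0.1

    def test_empty_calls_and_zero_quantified(self):
        calls = silac.call_regulation(make_sites([]), TMD8)
        summary = silac.summarize_regulation(calls, n_quantified=10)
        assert summary.n_down_sites == summary.n_up_sites == 0
        with pytest.raises(ValueError):
            silac.summarize_regulation(calls, n_quantified=0)

    def test_counts_match_generator_truth_at_large_effect(self):
        cfg = simulate.SilacSimConfig(
            n_sites=5000, frac_regulated=0.05, effect_log2=1.6, seed=23
        )
        rec, truth = simulate.gen_silac_dataset(cfg)
        h = silac.harmonize_label_swap(rec)
        calls = silac.call_regulation(h, silac.derive_thresholds(silac.fit_gaussian_null(h)))
        expected = np.where(truth.label == "null", "unchanged", truth.label)
        assert (calls["direction"].to_numpy() == expected).mean() > 0.99

    def test_residue_composition_exact(self):
        rows = [("G", i, "S", 1.0, 1.0, 1.0) for i in range(846)]
        rows += [("G", i, "T", 1.0, 1.0, 1.0) for i in range(144)]
        rows += [("G", i, "Y", 1.0, 1.0, 1.0) for i in range(10)]
        assert silac.residue_composition(make_sites(rows)) == (84.6, 14.4, 1.0)
        assert silac.residue_composition(make_sites(rows[:5])) == (100.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            silac.residue_composition(make_sites([]))

    def test_overlap_identical_and_disjoint(self):
        df = make_sites([("A", 1, "S", 1.0, 0.3, 0.3), ("B", 2, "S", 1.0, 2.0, 2.0)])
        calls = silac.call_regulation(df, TMD8)
        assert silac.overlap_regulated(calls, calls, "down") == [("A", 1, "S")]
        other = silac.call_regulation(
            make_sites([("C", 3, "S", 1.0, 0.3, 0.3)]), TMD8
        )
        assert silac.overlap_regulated(calls, other, "down") == []
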