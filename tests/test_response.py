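"""Standard response and pivotal-constrained regression."""

import numpy as np
import pandas as pd
import pytest

from aseries.response import (
    DegenerateDesignError,
    compute_standard_response,
    extract_features,
    feature_points,
    fit_pivotal,
)

from conftest import make_response_table


def grid_search_slope(x, y, lo=-5.0, hi=5.0, step=1e-4):
    """Dense grid minimizer of sum((y - k(x-5) - 5)^2) over k."""
    ks = np.arange(lo, hi + step, step)
    x = np.asarray(x, float)[:, None]
    y = np.asarray(y, float)[:, None]
    sse = ((y - (ks * (x - 5.0) + 5.0)) ** 2).sum(axis=0)
    return ks[np.argmin(sse)]


class TestStandardResponse:
    def test_pivotal_sentence_unanimous_present(self):
        # every ND participant scores sentence No. 5 as 5 -> mean 5.0, SD 0
        rng = np.random.default_rng(3)
        scores = rng.integers(1, 10, size=(6, 11))
        scores[:, 4] = 5  # sentence id 5 is column index 4
        table = make_response_table(scores)
        std = compute_standard_response(table)
        assert std.table.at[5, "mean"] == 5.0
        assert std.table.at[5, "sd"] == 0.0

    def test_means_and_sds_match_direct_summation(self):
        rng = np.random.default_rng(11)
        scores = rng.integers(1, 10, size=(6, 11))
        std = compute_standard_response(make_response_table(scores))
        for j, sid in enumerate(range(1, 12)):
            col = scores[:, j].astype(float)
            assert std.table.at[sid, "mean"] == pytest.approx(col.sum() / 6)
            manual_sd = np.sqrt(((col - col.mean()) ** 2).sum() / 5)
            assert std.table.at[sid, "sd"] == pytest.approx(manual_sd)

    def test_order_is_permutation_sorted_by_mean(self):
        rng = np.random.default_rng(5)
        std = compute_standard_response(
            make_response_table(rng.integers(1, 10, size=(4, 11)))
        )
        assert sorted(std.order) == list(range(1, 12))
        means = [std.table.at[i, "mean"] for i in std.order]
        assert means == sorted(means)

    def test_single_participant_sd_zero_with_flag(self):
        std = compute_standard_response(make_response_table([[5] * 11]))
        assert (std.table["sd"] == 0.0).all()
        assert std.table["single_observation"].all()

    def test_missing_sentence_for_nd_raises(self):
        table = make_response_table([[5] * 11])
        table.scores = table.scores[table.scores["sentence_id"] != 7]
        with pytest.raises(ValueError, match="sentence 7"):
            compute_standard_response(table)


class TestPivotalFit:
    def test_standard_response_self_fit(self, standard_scores):
        fit = fit_pivotal(standard_scores, standard_scores)
        assert fit.slope == 1.0
        assert fit.dc == 1.0

    def test_exact_line_through_pivot(self, standard_scores):
        y = 2.0 * (standard_scores - 5.0) + 5.0
        fit = fit_pivotal(standard_scores, y)
        assert fit.slope == pytest.approx(2.0)
        assert fit.dc == pytest.approx(1.0)

    def test_worked_example_against_grid_search(self):
        x = np.array([3, 4, 5, 6, 7], float)
        y = np.array([4, 4, 5, 6, 8], float)
        fit = fit_pivotal(x, y)
        assert fit.slope == pytest.approx(1.0)  # 10/10 by hand
        assert fit.slope == pytest.approx(grid_search_slope(x, y), abs=1e-4)
        resid = y - (fit.slope * (x - 5) + 5)
        expected_dc = 1 - (resid @ resid) / ((y - y.mean()) ** 2).sum()
        assert fit.dc_raw == pytest.approx(expected_dc)

    def test_random_fits_match_grid_search(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.uniform(1, 9, size=11)
            y = rng.uniform(1, 9, size=11)
            fit = fit_pivotal(x, y)
            assert fit.slope == pytest.approx(grid_search_slope(x, y), abs=1e-4)

    def test_all_x_at_pivot_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_pivotal([5, 5, 5], [1, 2, 3])

    def test_constant_y_has_undefined_dc(self):
        fit = fit_pivotal([3, 4, 6, 7], [5, 5, 5, 5])
        assert not fit.dc_defined
        assert np.isnan(fit.dc)
        assert fit.slope == pytest.approx(0.0)

    def test_negative_dc_clamped_raw_retained(self):
        # a line through the pivot can explain less than the mean does:
        # symmetric y forces slope 0, fitted value 5, far below mean 7.67
        x = np.array([4.0, 5.0, 6.0])
        y = np.array([9.0, 5.0, 9.0])
        fit = fit_pivotal(x, y)
        assert fit.dc_raw < 0
        assert fit.dc == 0.0

    def test_invariant_to_pair_ordering(self, standard_scores):
        rng = np.random.default_rng(21)
        y = rng.uniform(1, 9, size=11)
        base = fit_pivotal(standard_scores, y)
        perm = rng.permutation(11)
        shuffled = fit_pivotal(standard_scores[perm], y[perm])
        assert shuffled.slope == pytest.approx(base.slope)
        assert shuffled.dc == pytest.approx(base.dc)

    def test_dc_one_iff_zero_residuals(self, standard_scores):
        noisy = 1.2 * (standard_scores - 5) + 5 + 0.05
        assert fit_pivotal(standard_scores, noisy).dc < 1.0
        exact = 0.7 * (standard_scores - 5) + 5
        assert fit_pivotal(standard_scores, exact).dc == pytest.approx(1.0)


class TestExtractFeatures:
    def test_standard_scorers_all_at_one_one(self, standard):
        # integer scores exactly at the nine-point standard for sentences
        # whose standard score is integral would differ; use a synthetic
        # standard at integer scores instead
        scores = np.tile(np.arange(1, 12), (3, 1))
        table = make_response_table(scores, groups=["ND"] * 3)
        std = compute_standard_response(table)
        feats = extract_features(table, std)
        assert np.allclose(feats["slope"], 1.0)
        assert np.allclose(feats["dc"], 1.0)

    def test_flat_responder_excluded(self, standard):
        table = make_response_table(
            [np.arange(1, 12), [5] * 11], groups=["ND", "AD"]
        )
        std = compute_standard_response(table)
        feats = extract_features(table, std)
        flat = feats.set_index("participant_id").loc["S01"]
        assert flat["excluded_reason"] == "constant_response"
        assert flat["slope"] == pytest.approx(0.0)
        assert list(feature_points(feats)["participant_id"]) == ["S00"]

    def test_matches_per_participant_fits(self, standard):
        from aseries.synthetic import CohortSpec, gen_responses

        table, _ = gen_responses(CohortSpec(n_linear=5, n_coarse=5, n_flat=5), seed=4)
        feats = extract_features(table, standard)
        for _, row in feats.iterrows():
            if row["excluded_reason"]:
                continue
            scores = table.scores_of(row["participant_id"])
            fit = fit_pivotal(standard.x_for(scores.index), scores.to_numpy(float))
            assert row["slope"] == pytest.approx(fit.slope)
            assert row["dc"] == pytest.approx(fit.dc)

    def test_empty_table_raises(self):
        table = make_response_table([[5] * 11])
        table.scores = table.scores.iloc[0:0]
        with pytest.raises(ValueError, match="empty"):
            extract_features(table, None)
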