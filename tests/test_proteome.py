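"""Normalization, filtering, imputation, differential abundance,
restoration sets, enrichment, and PCA."""

import numpy as np
import pandas as pd
import pytest

from myofiber import (
    AbundanceMatrix,
    bh_adjust,
    differential_abundance,
    filter_by_missingness,
    hypergeometric_enrichment,
    log2_transform,
    mixed_impute,
    normalize_total_abundance,
    pca_scores,
    restoration_sets,
)
from myofiber.exceptions import InvalidInputError
from oracles import bh_stepup, hypergeom_upper_tail


def make_matrix(values, groups, scale="log2"):
    values = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"p{i}" for i in range(len(values))],
        columns=list(groups.keys()) if isinstance(groups, dict) else None,
    )
    if isinstance(groups, dict):
        gser = pd.Series(groups)
    else:
        values.columns = [f"s{i}" for i in range(values.shape[1])]
        gser = pd.Series(groups, index=values.columns)
    return AbundanceMatrix(values=values, groups=gser, scale=scale)


class TestNormalization:
    def test_equal_total_columns_unchanged(self):
        m = make_matrix([[1, 2], [3, 2]], ["a", "b"], scale="raw")
        out = normalize_total_abundance(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_column_totals_equalized(self):
        m = make_matrix([[40, 120], [60, 80]], ["a", "b"], scale="raw")
        out = normalize_total_abundance(m)
        totals = out.values.sum(axis=0)
        assert totals.nunique() == 1
        assert totals.iloc[0] == pytest.approx(200.0)  # max-column reference
        # within-column ratios preserved
        assert out.values.iloc[0, 0] / out.values.iloc[1, 0] == pytest.approx(40 / 60)

    def test_random_matrix_totals_match_reference_oracle(self, rng):
        vals = rng.lognormal(3, 1, size=(50, 6))
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3, scale="raw")
        out = normalize_total_abundance(m)
        # independent summation oracle
        ref = max(float(np.sum(vals[:, j])) for j in range(6))
        for j in range(6):
            assert float(np.sum(out.values.to_numpy()[:, j])) == pytest.approx(
                ref, abs=1e-9 * ref
            )

    def test_zero_total_column_rejected(self):
        m = make_matrix([[0, 2], [0, 2]], ["a", "b"], scale="raw")
        with pytest.raises(InvalidInputError):
            normalize_total_abundance(m)

    def test_log2_scale_rejected(self):
        m = make_matrix([[1, 2]], ["a", "b"], scale="log2")
        with pytest.raises(InvalidInputError):
            normalize_total_abundance(m)


class TestMissingnessFilter:
    def _matrix_with_missing(self, miss_per_group):
        """10 samples in two groups of 5; one protein with the requested
        number of missing values per group plus a complete protein."""
        vals = np.full((2, 10), 25.0)
        for g, n_miss in enumerate(miss_per_group):
            vals[0, g * 5 : g * 5 + n_miss] = np.nan
        return make_matrix(vals, ["a"] * 5 + ["b"] * 5)

    def test_protein_over_half_missing_in_one_group_dropped(self):
        m = self._matrix_with_missing([3, 0])  # 60% missing in group a
        kept, dropped = filter_by_missingness(m)
        assert dropped == ["p0"]
        assert list(kept.values.index) == ["p1"]

    def test_complete_protein_retained(self):
        m = self._matrix_with_missing([0, 0])
        kept, dropped = filter_by_missingness(m)
        assert dropped == []

    def test_under_half_missing_retained(self):
        m = self._matrix_with_missing([0, 2])  # worst group 40% missing
        kept, dropped = filter_by_missingness(m)
        assert dropped == []

    def test_boundary_is_strict(self):
        vals = np.full((1, 4), 25.0)
        vals[0, :2] = np.nan  # exactly 50% missing in a 4-sample group
        m = make_matrix(vals, ["a"] * 4)
        kept, dropped = filter_by_missingness(m)
        assert dropped == []


class TestMixedImpute:
    def test_complete_matrix_unchanged_any_seed(self, small_matrix):
        for seed in (0, 1, 99):
            out, report = mixed_impute(small_matrix, seed=seed)
            pd.testing.assert_frame_equal(out.values, small_matrix.values)
            assert not report.imputed_mask.any().any()

    def test_routing_by_sixty_percent_valid_rule(self):
        # group of 5 samples: 3 valid (60%) -> KNN; 2 valid (40%) -> MinProb
        rng = np.random.default_rng(3)
        vals = rng.normal(25, 2, size=(30, 5))
        vals[0, :2] = np.nan  # 60% valid -> knn
        vals[1, :3] = np.nan  # 40% valid -> minprob
        m = make_matrix(vals, ["a"] * 5)
        out, report = mixed_impute(m, seed=0)
        assert report.routes.loc["p0", "a"] == "knn"
        assert report.routes.loc["p1", "a"] == "minprob"
        assert not out.values.isna().any().any()

    def test_observed_values_never_modified(self, rng):
        vals = rng.normal(25, 2, size=(40, 8))
        mask = rng.random(vals.shape) < 0.2
        vals[mask] = np.nan
        m = make_matrix(vals, ["a"] * 4 + ["b"] * 4)
        out, report = mixed_impute(m, seed=5)
        observed = ~np.isnan(vals)
        np.testing.assert_array_equal(
            out.values.to_numpy()[observed], vals[observed]
        )
        np.testing.assert_array_equal(
            report.imputed_mask.to_numpy(), ~observed
        )

    def test_minprob_moment_recovery(self):
        """MinProb draws recover mean - 1.8*sd and 0.3*sd within Monte-Carlo
        tolerance on a sample with known observed moments."""
        rng = np.random.default_rng(12)
        n = 10000
        observed = rng.normal(25.0, 2.0, size=(n, 1))
        vals = np.hstack([observed, np.full((n, 1), np.nan)])
        # second sample fully missing except anchor rows defining its moments
        vals[:200, 1] = rng.normal(25.0, 2.0, 200)
        m = make_matrix(vals, ["a", "a"])
        out, _ = mixed_impute(m, knn_valid_frac=1.1, seed=7)  # force MinProb
        col = m.values.columns[1]
        obs = m.values[col].dropna()
        drawn = out.values.loc[m.values[col].isna(), col]
        mu, sd = obs.mean(), obs.std(ddof=1)
        se_mean = 0.3 * sd / np.sqrt(len(drawn))
        assert drawn.mean() == pytest.approx(mu - 1.8 * sd, abs=4 * se_mean)
        assert drawn.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.05)

    def test_same_seed_reproduces_imputation(self, rng):
        vals = rng.normal(25, 2, size=(30, 6))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3)
        out1, _ = mixed_impute(m, seed=11)
        out2, _ = mixed_impute(m, seed=11)
        pd.testing.assert_frame_equal(out1.values, out2.values)

    def test_oversized_k_falls_back_with_warning(self, caplog):
        vals = np.array([[25.0, np.nan, 24.0], [24.0, 23.0, 22.0]])
        m = make_matrix(vals, ["a"] * 3)
        with caplog.at_level("WARNING"):
            out, _ = mixed_impute(m, k=10, seed=0)
        assert "neighbour pool" in caplog.text
        assert not out.values.isna().any().any()


class TestBHAdjust:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_matches_literal_step_up_oracle(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            bh_adjust([0.5, 1.5])


class TestDifferentialAbundance:
    def test_identical_groups_nothing_significant(self):
        vals = np.tile(np.random.default_rng(0).normal(25, 2, 20)[:, None], (1, 8))
        m = make_matrix(vals, ["a"] * 4 + ["b"] * 4)
        res = differential_abundance(m, "a", "b")
        np.testing.assert_allclose(res["log2fc"], 0.0)
        assert not res["significant"].any()

    def test_fold_change_gate_blocks_small_shifts(self, rng):
        # strong consistency but sub-threshold shift: q small, |FC| < 1
        base = rng.normal(25, 2, 50)
        vals = np.tile(base[:, None], (1, 12)) + rng.normal(0, 0.01, (50, 12))
        vals[0, :6] += 0.9  # 0.9 log2 units, highly significant
        m = make_matrix(vals, ["a"] * 6 + ["b"] * 6)
        res = differential_abundance(m, "a", "b", fc=2.0)
        assert res.loc["p0", "q"] < 0.001
        assert not res.loc["p0", "significant"]

    def test_fc_one_reduces_to_pure_fdr_gate(self, rng):
        base = rng.normal(25, 2, 50)
        vals = np.tile(base[:, None], (1, 12)) + rng.normal(0, 0.01, (50, 12))
        vals[0, :6] += 0.9
        m = make_matrix(vals, ["a"] * 6 + ["b"] * 6)
        res = differential_abundance(m, "a", "b", fc=1.0)
        assert res.loc["p0", "significant"]
        assert (res["significant"] == (res["q"] <= 0.05)).all()

    def test_direction_follows_sign_convention(self, rng):
        vals = np.tile(rng.normal(25, 2, 10)[:, None], (1, 8))
        vals += rng.normal(0, 0.05, vals.shape)
        vals[0, :4] += 3  # up in case
        vals[1, :4] -= 3  # down in case
        m = make_matrix(vals, ["case"] * 4 + ["ctrl"] * 4)
        res = differential_abundance(m, "case", "ctrl")
        assert res.loc["p0", "direction"] == "up"
        assert res.loc["p1", "direction"] == "down"

    def test_missing_values_rejected(self):
        vals = np.full((3, 4), 25.0)
        vals[0, 0] = np.nan
        m = make_matrix(vals, ["a"] * 2 + ["b"] * 2)
        with pytest.raises(InvalidInputError):
            differential_abundance(m, "a", "b")

    def test_undersized_group_rejected(self):
        m = make_matrix(np.full((3, 3), 25.0), ["a", "b", "b"])
        with pytest.raises(InvalidInputError):
            differential_abundance(m, "a", "b")


def _diff_table(sig_down=(), sig_up=(), universe=None):
    universe = list(universe or [])
    sig = set(sig_down) | set(sig_up)
    return pd.DataFrame(
        {
            "significant": [p in sig for p in universe],
            "direction": ["down" if p in set(sig_down) else "up" for p in universe],
            "log2fc": 0.0,
        },
        index=universe,
    )


class TestRestorationSets:
    universe = [f"p{i}" for i in range(1, 16)]

    def test_identical_hits_all_maintained(self):
        d = _diff_table(sig_down=["p1", "p2"], universe=self.universe)
        sets = restoration_sets(d, d.copy())
        assert sets.maintained == {"p1", "p2"}
        assert not sets.restored and not sets.emergent and not sets.discordant

    def test_set_arithmetic_example(self):
        untreated = _diff_table(sig_down=[f"p{i}" for i in range(1, 11)], universe=self.universe)
        treated = _diff_table(sig_down=[f"p{i}" for i in range(6, 13)], universe=self.universe)
        sets = restoration_sets(untreated, treated)
        assert sets.maintained == {f"p{i}" for i in range(6, 11)}
        assert sets.restored == {f"p{i}" for i in range(1, 6)}
        assert sets.emergent == {"p11", "p12"}

    def test_opposite_direction_is_discordant(self):
        untreated = _diff_table(sig_down=["p1"], universe=self.universe)
        treated = _diff_table(sig_up=["p1"], universe=self.universe)
        sets = restoration_sets(untreated, treated)
        assert sets.discordant == {"p1"}
        assert not sets.maintained

    def test_direction_filter_restricts_hit_sets(self):
        untreated = _diff_table(sig_down=["p1"], sig_up=["p2"], universe=self.universe)
        treated = _diff_table(sig_down=["p1"], sig_up=["p3"], universe=self.universe)
        sets = restoration_sets(untreated, treated, direction="down")
        assert sets.maintained == {"p1"}
        assert sets.restored == set()
        assert sets.emergent == set()  # p3 is up, filtered out

    def test_partition_invariants_on_random_pairs(self, rng):
        for _ in range(100):
            down_u = rng.choice(self.universe, rng.integers(0, 8), replace=False)
            up_u = [p for p in rng.choice(self.universe, rng.integers(0, 8), replace=False) if p not in down_u]
            down_t = rng.choice(self.universe, rng.integers(0, 8), replace=False)
            up_t = [p for p in rng.choice(self.universe, rng.integers(0, 8), replace=False) if p not in down_t]
            u = _diff_table(sig_down=down_u, sig_up=up_u, universe=self.universe)
            t = _diff_table(sig_down=down_t, sig_up=up_t, universe=self.universe)
            sets = restoration_sets(u, t)
            groups = [sets.maintained, sets.restored, sets.emergent, sets.discordant]
            for i in range(4):
                for j in range(i + 1, 4):
                    assert not (groups[i] & groups[j])
            sig_u = set(u.index[u["significant"]])
            assert sets.maintained | sets.restored | sets.discordant == sig_u

    def test_disjoint_universes_rejected(self):
        u = _diff_table(universe=["p1"])
        t = _diff_table(universe=["p2"])
        with pytest.raises(InvalidInputError):
            restoration_sets(u, t)


class TestEnrichment:
    def test_exact_tail_probability(self):
        background = [f"g{i}" for i in range(20)]
        hits = background[:10]
        annotation = {"term": background[6:11]}  # 5 members, overlap 4
        res = hypergeometric_enrichment(hits, annotation, background, min_targets=1)
        expected = float(hypergeom_upper_tail(20, 5, 10, 4))
        assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(28028 / 184756)

    def test_min_targets_excludes_small_overlap(self):
        background = [f"g{i}" for i in range(40)]
        hits = background[:10]
        annotation = {
            "small": background[6:10],  # overlap 4 < 5
            "big": background[:20],  # overlap 10
        }
        res = hypergeometric_enrichment(hits, annotation, background, min_targets=5).set_index("term_id")
        assert not res.loc["small", "passed_min_size"]
        assert np.isnan(res.loc["small", "q"])
        assert res.loc["big", "passed_min_size"]

    def test_saturated_term_p_is_one(self):
        background = [f"g{i}" for i in range(15)]
        hits = background[:6]
        res = hypergeometric_enrichment(hits, {"all": background}, background)
        assert res.loc[0, "overlap"] == 6
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_p_decreases_as_overlap_grows(self):
        background = [f"g{i}" for i in range(100)]
        hits = background[:20]
        ps = []
        for overlap in (5, 10, 15):
            annotation = {"t": background[20 - overlap : 40 - overlap]}
            res = hypergeometric_enrichment(hits, annotation, background, min_targets=1)
            ps.append(res.loc[0, "p"])
        assert ps[0] > ps[1] > ps[2]

    def test_hits_outside_background_rejected(self):
        with pytest.raises(InvalidInputError):
            hypergeometric_enrichment(["x"], {"t": ["a"]}, ["a", "b"])


class TestPCA:
    def test_identical_samples_have_no_variance(self):
        vals = np.tile(np.random.default_rng(1).normal(25, 2, 30)[:, None], (1, 4))
        m = make_matrix(vals, ["a"] * 4)
        scores, evr = pca_scores(m)
        assert np.all(np.abs(scores.drop(columns="group").to_numpy()) < 1e-8)

    def test_rank_one_matrix_single_component(self, rng):
        direction = rng.normal(0, 1, 30)
        loadings = rng.normal(0, 2, 6)
        vals = 25 + np.outer(direction, loadings)
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3)
        _, evr = pca_scores(m)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_match_eigendecomposition_oracle(self, rng):
        vals = rng.normal(25, 2, size=(40, 6))
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3)
        scores, evr = pca_scores(m)
        x = vals.T - vals.T.mean(axis=0)
        cov = x.T @ x / (x.shape[0] - 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        oracle = x @ eigvecs[:, order]
        got = scores.drop(columns="group").to_numpy()
        for j in range(min(3, got.shape[1])):
            assert np.allclose(got[:, j], oracle[:, j], atol=1e-8) or np.allclose(
                got[:, j], -oracle[:, j], atol=1e-8
            )
        np.testing.assert_allclose(
            evr, (eigvals[order] / eigvals.sum())[: len(evr)], atol=1e-10
        )

    def test_single_sample_rejected(self):
        m = make_matrix(np.full((5, 1), 25.0), ["a"])
        with pytest.raises(InvalidInputError):
            pca_scores(m)
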