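"""Community transforms, distances, outliers, MRPP, ISA and overlays."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from dustshed import community as comm


# ---------------------------------------------------------------------------
# cover transform
# ---------------------------------------------------------------------------

class TestTransformCover:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (0.0, 0.0),  # zeros return to zero
            (0.1, np.log10(0.11) + 2),  # walkaround cover
            (3.2, np.log10(3.21) + 2),
        ],
    )
    def test_spot_values(self, x, expected):
        assert comm.transform_cover(x) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            comm.transform_cover(-0.5)

    @given(
        st.floats(min_value=0.0, max_value=1e4),
        st.floats(min_value=1e-9, max_value=1e4),
    )
    @settings(max_examples=100, derandomize=True)
    def test_strictly_monotone(self, x, delta):
        assert comm.transform_cover(x + delta) > comm.transform_cover(x)

    def test_elementwise_over_dataframe(self):
        df = pd.DataFrame({"a": [0.0, 1.0], "b": [0.1, 2.0]})
        out = comm.transform_cover(df)
        assert out.loc[0, "a"] == 0.0
        assert out.loc[1, "b"] == pytest.approx(np.log10(2.01) + 2)


# ---------------------------------------------------------------------------
# filtering and relativization
# ---------------------------------------------------------------------------

def _survey_like_matrix():
    """107 plots x 113 taxa with exactly 3 empty plots and 22 singletons.

    Engineered so plot deletion does not change taxon occurrence counts:
    the 3 empty plots contain nothing, every other taxon occurs >= 2 times.
    """
    rng = np.random.default_rng(42)
    m = np.zeros((107, 113))
    # 91 common taxa present in >= 2 of the first 104 plots
    for j in range(91):
        plots_j = rng.choice(104, size=rng.integers(2, 40), replace=False)
        m[plots_j, j] = rng.integers(1, 20, len(plots_j))
    # 22 singleton taxa, each in exactly one non-empty plot
    for j in range(91, 113):
        m[rng.integers(0, 104), j] = 0.1
    # rows 104-106 stay empty; make sure no earlier row is accidentally empty
    for i in range(104):
        if m[i].sum() == 0:
            m[i, 0] = 1.0
    return pd.DataFrame(
        m,
        index=[f"plot{i:03d}" for i in range(107)],
        columns=[f"sp{j:03d}" for j in range(113)],
    )


class TestFilterMatrix:
    def test_survey_counts(self):
        m = _survey_like_matrix()
        out = comm.filter_matrix(m, min_occurrences=1, drop_empty_plots=True)
        assert out.shape == (104, 91)  # 3 empty plots, 22 rare taxa removed

    def test_identity_when_nothing_to_drop(self):
        m = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], columns=["a", "b"])
        pd.testing.assert_frame_equal(
            comm.filter_matrix(m, min_occurrences=0, drop_empty_plots=True), m
        )

    def test_matches_brute_force_occurrence_count(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(
            rng.integers(0, 3, (10, 8)).astype(float),
            columns=[f"s{j}" for j in range(8)],
        )
        m.iloc[0] = 0.0  # one empty plot
        out = comm.filter_matrix(m, min_occurrences=1, drop_empty_plots=True)
        kept_plots = m.index[m.sum(axis=1) > 0]
        for col in m.columns:
            occ = sum(m.loc[i, col] > 0 for i in kept_plots)
            assert (col in out.columns) == (occ > 1)

    def test_empty_after_filtering_raises(self):
        m = pd.DataFrame([[0.0], [0.0]], columns=["a"])
        with pytest.raises(ValueError):
            comm.filter_matrix(m)


class TestRelativize:
    def test_column_maxima_become_one(self):
        m = pd.DataFrame({"a": [2.0, 4.0], "b": [1.0, 0.5]})
        out = comm.relativize_by_max(m)
        assert list(out["a"]) == [0.5, 1.0]
        assert (out.max(axis=0) == 1.0).all()

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.uniform(0.1, 5, (20, 5)))
        once = comm.relativize_by_max(m)
        pd.testing.assert_frame_equal(comm.relativize_by_max(once), once)
        assert ((once.to_numpy() >= 0) & (once.to_numpy() <= 1)).all()

    def test_zero_column_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
        with pytest.raises(ValueError, match="b"):
            comm.relativize_by_max(m)


# ---------------------------------------------------------------------------
# distances and outliers
# ---------------------------------------------------------------------------

class TestDistanceMatrix:
    def test_disjoint_plots_sorenson_one(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        d = comm.distance_matrix(m, "sorenson")
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_identical_plots_zero(self):
        m = pd.DataFrame([[2.0, 1.0], [2.0, 1.0]], index=["a", "b"])
        for method in ("sorenson", "euclidean"):
            assert comm.distance_matrix(m, method).values[0, 1] == 0.0

    def test_hand_computed_sorenson(self):
        m = pd.DataFrame([[2.0, 1.0], [1.0, 1.0]], index=["a", "b"])
        # sum|a-b| / sum(a+b) = 1 / 5
        assert comm.distance_matrix(m, "sorenson").values[0, 1] == pytest.approx(0.2)

    def test_empty_plot_rejected_for_sorenson_but_not_euclidean(self):
        m = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["empty", "b"])
        with pytest.raises(ValueError, match="empty"):
            comm.distance_matrix(m, "sorenson")
        assert comm.distance_matrix(m, "euclidean").values[0, 1] > 0

    def test_bounds_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.uniform(0, 5, (12, 6)) * rng.integers(0, 2, (12, 6)))
        m += 0.01  # avoid empty plots
        d = comm.distance_matrix(m, "sorenson").values
        assert d.min() >= 0 and d.max() <= 1
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)


class TestOutliers:
    def test_identical_plots_no_outliers(self):
        m = pd.DataFrame(np.ones((5, 3)), index=list("abcde"))
        d = comm.distance_matrix(m, "euclidean")
        assert comm.detect_outliers(d) == []

    def test_far_plot_flagged(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 0.1, (10, 3)) + 5.0
        X = np.vstack([X, [50.0, 50.0, 50.0]])
        m = pd.DataFrame(X, index=[f"p{i}" for i in range(11)])
        d = comm.distance_matrix(m, "euclidean")
        assert comm.detect_outliers(d, 2.0) == ["p10"]

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.uniform(0, 5, (15, 4)), index=[f"p{i}" for i in range(15)])
        m.iloc[3] += 40.0
        d1 = comm.distance_matrix(m, "euclidean")
        perm = rng.permutation(15)
        d2 = comm.distance_matrix(m.iloc[perm], "euclidean")
        assert set(comm.detect_outliers(d1)) == set(comm.detect_outliers(d2))


# ---------------------------------------------------------------------------
# MRPP
# ---------------------------------------------------------------------------

def _mrpp_exhaustive_oracle(D, labels):
    """Brute-force enumeration over all distinct label assignments."""
    from itertools import permutations

    labels = list(labels)
    n = len(labels)

    def delta(lab):
        lab = np.asarray(lab)
        tot = 0.0
        for g in set(labels):
            idx = np.flatnonzero(lab == g)
            pairs = [(i, j) for i in idx for j in idx if i < j]
            tot += (len(idx) / n) * np.mean([D[i, j] for i, j in pairs])
        return tot

    seen = set()
    deltas = []
    for p in permutations(labels):
        if p in seen:
            continue
        seen.add(p)
        deltas.append(delta(p))
    deltas = np.array(deltas)
    d_obs = delta(labels)
    d_exp = deltas.mean()
    return 1.0 - d_obs / d_exp, np.mean(deltas <= d_obs + 1e-12)


def _toy_distance(points, ids):
    from scipy.spatial.distance import pdist, squareform

    return comm.DistanceMatrix(ids, squareform(pdist(np.asarray(points))), "euclidean")


class TestMrpp:
    def test_perfect_separation(self):
        pts = [[0, 0], [0, 0], [0, 0], [9, 9], [9, 9], [9, 9]]
        d = _toy_distance(pts, list("abcdef"))
        res = comm.mrpp(d, ["g1"] * 3 + ["g2"] * 3)
        assert res.delta_observed == 0.0
        assert res.A == pytest.approx(1.0, abs=1e-12)

    def test_null_data_A_near_zero(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(40, 3))
            d = _toy_distance(pts, [f"p{i}" for i in range(40)])
            res = comm.mrpp(d, ["a"] * 20 + ["b"] * 20, n_permutations=99, seed=seed)
            vals.append(res.A)
        assert np.mean(np.abs(vals)) < 0.05

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2, 1, (3, 2))])
        d = _toy_distance(pts, [f"p{i}" for i in range(6)])
        labels = ["a"] * 3 + ["b"] * 3
        res = comm.mrpp(d, labels, n_permutations=10_000, seed=0)
        A_ref, p_ref = _mrpp_exhaustive_oracle(d.values, labels)
        assert res.exhaustive  # 20 distinct splits -> complete enumeration
        assert res.A == pytest.approx(A_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=0.01)

    def test_group_of_one_rejected(self):
        d = _toy_distance([[0, 0], [1, 1], [2, 2]], list("abc"))
        with pytest.raises(ValueError):
            comm.mrpp(d, ["a", "a", "b"])

    def test_monte_carlo_close_to_exhaustive(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 1, (4, 2)), rng.normal(1.5, 1, (4, 2))])
        d = _toy_distance(pts, [f"p{i}" for i in range(8)])
        labels = ["a"] * 4 + ["b"] * 4
        exact = comm.mrpp(d, labels)  # 70 splits -> exhaustive
        mc = comm.mrpp(d, labels, n_permutations=5_000, seed=1)
        mc.exhaustive or pytest.skip  # both exhaustive at these sizes
        assert exact.A == pytest.approx(mc.A, abs=1e-12)


def test_mrpp_agrees_with_vegan(tmp_path):
    """Independent cross-check of the observed delta and A against R vegan."""
    import shutil, subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    rng = np.random.default_rng(8)
    X = rng.uniform(0, 5, (10, 4))
    labels = ["a"] * 5 + ["b"] * 5
    m = pd.DataFrame(X, index=[f"p{i}" for i in range(10)])
    d = comm.distance_matrix(m, "euclidean")
    res = comm.mrpp(d, labels)
    np.savetxt(tmp_path / "x.csv", X, delimiter=",")
    script = tmp_path / "mrpp.R"
    script.write_text(
        "suppressMessages(library(vegan))\n"
        f"x <- as.matrix(read.csv('{tmp_path}/x.csv', header=FALSE))\n"
        "g <- factor(rep(c('a','b'), each=5))\n"
        "set.seed(1)\n"
        "r <- mrpp(dist(x), g, permutations=9999, weight.type=1)\n"
        "cat(sprintf('%.12f', c(r$delta, r$E.delta, r$A)), sep='\\n')\n"
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    delta_r, edelta_r, A_r = (float(v) for v in out.stdout.split())
    assert res.delta_observed == pytest.approx(delta_r, abs=1e-8)
    assert res.A == pytest.approx(A_r, abs=0.01)  # E(delta) estimated differently


# ---------------------------------------------------------------------------
# indicator species analysis
# ---------------------------------------------------------------------------

class TestIsa:
    def test_perfect_indicator(self):
        m = pd.DataFrame(
            {"sp1": [2.0, 3.0, 2.5, 0.0, 0.0, 0.0], "sp2": [1.0] * 6},
            index=[f"p{i}" for i in range(6)],
        )
        res = comm.indicator_species_analysis(m, ["near"] * 3 + ["far"] * 3)
        assert res.table.loc["sp1", "indval"] == pytest.approx(1.0)
        assert res.table.loc["sp1", "group"] == "near"

    def test_symmetric_taxon_indval_half(self):
        m = pd.DataFrame({"sp": [2.0] * 6}, index=[f"p{i}" for i in range(6)])
        res = comm.indicator_species_analysis(m, ["a"] * 3 + ["b"] * 3)
        assert res.table.loc["sp", "indval"] == pytest.approx(0.5)

    def test_exhaustive_matches_monte_carlo_p(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(
            rng.uniform(0, 3, (6, 4)) * rng.integers(0, 2, (6, 4)),
            index=[f"p{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(4)],
        )
        labels = ["a"] * 3 + ["b"] * 3
        res = comm.indicator_species_analysis(m, labels, n_permutations=10_000)
        assert res.exhaustive
        # brute-force oracle over all 20 assignments
        from itertools import permutations

        X = m.to_numpy()
        for j, taxon in enumerate(m.columns):
            obs = res.table.loc[taxon, "indval"]
            stats = []
            for p in set(permutations([0] * 3 + [1] * 3)):
                lab = np.array(p)
                stats.append(
                    comm._indval_matrix(X, lab, 2).max(axis=1)[j]
                )
            p_ref = np.mean(np.array(stats) >= obs - 1e-12)
            assert res.table.loc[taxon, "p"] == pytest.approx(p_ref, abs=0.01)

    def test_empty_group_rejected(self):
        m = pd.DataFrame({"s": [1.0, 2.0]})
        with pytest.raises(ValueError):
            comm.indicator_species_analysis(m, ["a", "a"])


# ---------------------------------------------------------------------------
# score rotation and overlays
# ---------------------------------------------------------------------------

class TestRotateScores:
    def _scores(self, seed=0, n=30, k=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(0, [2.0, 1.0, 0.5][:k], (n, k)),
            columns=[f"axis{i + 1}" for i in range(k)],
        )

    def test_target_equal_axis1_identity_correlation(self):
        s = self._scores()
        rot = comm.rotate_scores(s, s["axis1"].to_numpy())
        r = np.corrcoef(rot["axis1"], s["axis1"])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_correlation_not_decreased(self):
        s = self._scores(seed=1, k=2)
        target = (s["axis1"] + s["axis2"]).to_numpy()  # 45-degree target
        pre = abs(np.corrcoef(s["axis1"], target)[0, 1])
        rot = comm.rotate_scores(s, target)
        post = abs(np.corrcoef(rot["axis1"], target)[0, 1])
        assert post >= pre - 1e-12

    def test_distances_preserved(self):
        from scipy.spatial.distance import pdist

        s = self._scores(seed=2)
        rot = comm.rotate_scores(s, np.arange(len(s), dtype=float))
        assert np.allclose(pdist(s.to_numpy()), pdist(rot.to_numpy()), atol=1e-10)

    def test_constant_target_rejected(self):
        s = self._scores()
        with pytest.raises(ValueError):
            comm.rotate_scores(s, np.ones(len(s)))


class TestAxisCorrelations:
    def test_monotone_transform_gives_r_one(self):
        s = pd.DataFrame({"axis1": np.arange(10.0), "axis2": np.zeros(10)})
        cov = pd.DataFrame({"v": np.exp(np.arange(10.0))}, index=s.index)
        out = comm.axis_correlations(s, cov)
        assert out.loc["v", "axis1"] == pytest.approx(1.0)

    def test_matches_manual_rank_correlation(self):
        rng = np.random.default_rng(10)
        s = pd.DataFrame({"axis1": rng.normal(size=50)})
        cov = pd.DataFrame({"v": rng.normal(size=50)}, index=s.index)
        out = comm.axis_correlations(s, cov)
        manual = np.corrcoef(rankdata(cov["v"]), rankdata(s["axis1"]))[0, 1]
        assert out.loc["v", "axis1"] == pytest.approx(manual, abs=1e-12)

    def test_too_few_pairs_flagged_nan(self):
        s = pd.DataFrame({"axis1": [1.0, 2.0, 3.0, 4.0]})
        cov = pd.DataFrame({"v": [1.0, 2.0, np.nan, np.nan]}, index=s.index)
        out = comm.axis_correlations(s, cov)
        assert np.isnan(out.loc["v", "axis1"])


# ---------------------------------------------------------------------------
# distance-class summaries
# ---------------------------------------------------------------------------

class TestSummarizeByClass:
    def _table(self):
        return pd.DataFrame(
            {
                "plot_id": [f"p{i}" for i in range(6)],
                "dist_road": [20, 20, 20, 1500, 1500, 1500],
                "v": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )

    def test_hand_computed_means_se_and_F(self):
        summary, anova = comm.summarize_by_class(
            self._table(), "v", (0, 50, 2000)
        )
        assert list(summary["mean"]) == [2.0, 5.0]
        assert summary["se"].iloc[0] == pytest.approx(0.5774, abs=1e-4)
        assert anova["F"] == pytest.approx(13.5)
        assert (anova["df_between"], anova["df_within"]) == (1, 4)

    def test_single_class_no_anova(self):
        t = self._table()
        t["dist_road"] = 20
        summary, anova = comm.summarize_by_class(t, "v", (0, 50, 2000))
        assert anova is None and len(summary) == 1
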