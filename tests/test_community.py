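"""Distance statistics, decay classes, perMANOVA, MRT, PCA and regressions."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from nifhnet.community import (
    TABLE1_TERMS,
    best_split,
    bray_curtis,
    kmeans_decay_classes,
    mrt,
    pca_group_means,
    permanova,
    polynomial_fit,
    richness_models,
)
from nifhnet.synthetic import StudyDesign, generate_logs, generate_occurrences


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == 0

    def test_disjoint_supports_one(self):
        m = pd.DataFrame([[2, 0], [0, 5]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == 1

    def test_hand_computed_value(self):
        # |2-1| + |0-1| over (2+1) + (0+1) = 2/4
        m = pd.DataFrame([[2, 0], [1, 1]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == pytest.approx(0.5)

    def test_all_zero_row_named_in_error(self):
        m = pd.DataFrame([[1, 1], [0, 0]], index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(m)

    def test_range_and_symmetry(self, rng):
        m = pd.DataFrame(rng.poisson(2, size=(10, 6)) + 1)
        d = bray_curtis(m).to_numpy()
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


def _brute_force_1d_kmeans(values, k):
    """Minimum within-cluster SS over all ordered partitions (oracle)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        ss = sum(
            ((x[i:j] - x[i:j].mean()) ** 2).sum()
            for i, j in zip(bounds, bounds[1:])
        )
        best = min(best, ss)
    return best


class TestDecayClasses:
    def test_separated_pairs_cluster_together(self):
        values = pd.Series(
            [90, 91, 70, 71, 50, 51, 30, 31],
            index=[f"L{i}" for i in range(8)],
        )
        res = kmeans_decay_classes(values, k=4)
        labels = res.classes
        assert labels.iloc[0] == labels.iloc[1] == 1  # most intact = class 1
        assert labels.iloc[6] == labels.iloc[7] == 4
        assert labels.nunique() == 4

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_decay_classes(pd.Series([50.0] * 10), k=4)

    def test_classes_are_contiguous_intervals(self, rng):
        values = pd.Series(rng.uniform(10, 95, size=40))
        res = kmeans_decay_classes(values, k=4)
        df = pd.DataFrame({"mass": values, "cls": res.classes}).sort_values("mass")
        # walking up in mass, the class label only ever decreases (4 -> 1)
        assert (df["cls"].diff().dropna() <= 0).all()

    def test_matches_exhaustive_partition_search(self, rng):
        for _ in range(20):
            values = rng.uniform(0, 100, size=int(rng.integers(6, 13)))
            res = kmeans_decay_classes(pd.Series(values), k=4)
            oracle = _brute_force_1d_kmeans(values, 4)
            assert res.within_ss == pytest.approx(oracle, abs=1e-9)


@pytest.fixture(scope="module")
def community_data():
    logs = generate_logs(StudyDesign(seed=3))
    fungal, motus, _ = generate_occurrences(logs, seed=5)
    decay = kmeans_decay_classes(logs["remaining_mass"], k=4)
    meta = logs.assign(decay_class=decay.classes)
    return meta, fungal, motus


class TestPermanova:
    def test_table1_structure_df_bookkeeping(self, community_data):
        meta, _, motus = community_data
        res = permanova(bray_curtis(motus), meta, n_permutations=19, seed=1)
        t = res.table
        assert res.total_df == 44 and res.residual_df == 33
        assert list(t.loc[list(TABLE1_TERMS), "Df"]) == [1, 1, 2, 1, 2, 2, 2]
        assert int(t["Df"][:-1].sum()) == res.total_df

    def test_ss_additivity_and_r2(self, community_data):
        meta, _, motus = community_data
        res = permanova(bray_curtis(motus), meta, n_permutations=19, seed=1)
        t = res.table
        terms = list(TABLE1_TERMS)
        assert t.loc[terms, "SS"].sum() + t.loc["Residual", "SS"] == pytest.approx(
            t.loc["Total", "SS"]
        )
        assert t.loc[terms, "R2"].sum() + t.loc["Residual", "R2"] == pytest.approx(1.0)

    def test_matches_skbio_single_factor(self, community_data):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        meta, _, motus = community_data
        d = bray_curtis(motus)
        dm = DistanceMatrix(d.values, ids=list(d.index))
        sk = skbio_permanova(dm, grouping=meta["species"].values, permutations=9)
        mine = permanova(d, meta, terms=("species",), n_permutations=9, seed=1)
        assert mine.table.loc["species", "F"] == pytest.approx(sk["test statistic"])

    def test_matches_vegan_adonis2_sequential_ss(self, community_data, tmp_path):
        """Independent oracle: vegan's adonis2 with terms added sequentially."""
        meta, _, motus = community_data
        motus.to_csv(tmp_path / "mot.tsv", sep="\t")
        meta.to_csv(tmp_path / "meta.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            mot <- read.delim("mot.tsv", row.names = 1)
            meta <- read.delim("meta.tsv", row.names = 1)
            meta$decay_class <- as.numeric(meta$decay_class)
            d <- vegdist(mot, method = "bray")
            fit <- adonis2(d ~ species + decay_class + management
                           + species:decay_class, data = meta,
                           by = "terms", permutations = 9)
            write.csv(data.frame(SS = fit$SumOfSqs, F = fit$F), "vegan.csv")
            """
        )
        (tmp_path / "check.R").write_text(script)
        subprocess.run(
            ["Rscript", "check.R"], cwd=tmp_path, check=True, capture_output=True
        )
        vegan = pd.read_csv(tmp_path / "vegan.csv")
        mine = permanova(
            bray_curtis(motus), meta,
            terms=("species", "decay_class", "management", "species:decay_class"),
            n_permutations=9, seed=1,
        ).table
        np.testing.assert_allclose(
            mine["SS"].to_numpy()[:5], vegan["SS"].to_numpy()[:5], rtol=1e-6
        )
        np.testing.assert_allclose(
            mine["F"].to_numpy()[:4], vegan["F"].to_numpy()[:4], rtol=1e-6
        )

    def test_strong_separation_reaches_p_floor(self):
        rng = np.random.default_rng(0)
        groups = ["a"] * 10 + ["b"] * 10
        data = pd.DataFrame(
            np.vstack(
                [rng.poisson(5, (10, 6)), rng.poisson(5, (10, 6)) + 40]
            ),
            index=[f"s{i}" for i in range(20)],
        )
        meta = pd.DataFrame({"species": groups}, index=data.index)
        res = permanova(bray_curtis(data), meta, terms=("species",),
                        n_permutations=999, seed=2)
        assert res.table.loc["species", "p"] == pytest.approx(0.001)

    def test_aliased_term_rejected(self, community_data):
        meta, _, motus = community_data
        meta = meta.assign(species_copy=meta["species"])
        with pytest.raises(ValueError, match="aliased"):
            permanova(bray_curtis(motus), meta,
                      terms=("species", "species_copy"), n_permutations=9)

    def test_asymmetric_distance_rejected(self, community_data):
        meta, _, motus = community_data
        d = bray_curtis(motus).to_numpy().copy()
        d[0, 1] += 0.1
        with pytest.raises(ValueError, match="symmetric"):
            permanova(d, meta, n_permutations=9)


def _brute_force_best_split_ss(response, predictors, ordered):
    """Minimum child-SS sum over every realizable sample bipartition (oracle)."""
    y = np.asarray(response, dtype=float)

    def ss(rows):
        if len(rows) == 0:
            return 0.0
        sub = y[rows]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    best = np.inf
    n = len(response)
    for var in predictors.columns:
        col = predictors[var].to_numpy()
        levels = sorted(pd.unique(col))
        if var in ordered:
            partitions = [set(levels[: i + 1]) for i in range(len(levels) - 1)]
        else:
            partitions = []
            for r in range(1, len(levels)):
                partitions += [set(c) for c in itertools.combinations(levels, r)]
        for left in partitions:
            mask = np.isin(col, list(left))
            if mask.all() or not mask.any():
                continue
            best = min(best, ss(np.flatnonzero(mask)) + ss(np.flatnonzero(~mask)))
    return best


class TestMrt:
    def test_species_determined_composition_splits_on_species(self):
        rng = np.random.default_rng(1)
        n = 30
        species = ["Fagus", "Picea"] * (n // 2)
        base = np.where(np.array(species) == "Fagus", 20, 0)[:, None]
        response = pd.DataFrame(base + rng.poisson(1.0, size=(n, 5)))
        predictors = pd.DataFrame(
            {"species": species, "decay_class": rng.integers(1, 5, n)}
        )
        tree = mrt(response, predictors)
        assert tree.split_var == "species"

    def test_single_sample_is_leaf(self):
        tree = mrt(pd.DataFrame([[1.0, 2.0]]), pd.DataFrame({"species": ["Fagus"]}))
        assert tree.is_leaf and tree.leaf_id == 1

    def test_node_ss_never_increases_down_a_path(self, community_data):
        meta, _, motus = community_data
        tree = mrt(motus, meta[["species", "management", "decay_class"]])

        def walk(node):
            if node.is_leaf:
                return
            assert node.left.ss + node.right.ss <= node.ss + 1e-9
            assert node.left.ss <= node.ss + 1e-9
            walk(node.left)
            walk(node.right)

        walk(tree)

    def test_leaves_partition_samples(self, community_data):
        meta, _, motus = community_data
        tree = mrt(motus, meta[["species", "management", "decay_class"]])
        leaf_samples = [s for leaf in tree.leaves() for s in leaf.samples]
        assert sorted(leaf_samples) == sorted(motus.index)

    def test_best_split_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 11))
            response = pd.DataFrame(rng.normal(size=(n, 3)))
            predictors = pd.DataFrame(
                {
                    "cat": rng.choice(list("abcd"), size=n),
                    "ord": rng.integers(1, 5, size=n),
                }
            )
            found = best_split(response, predictors, ordered={"ord"})
            oracle = _brute_force_best_split_ss(response, predictors, {"ord"})
            if found is None:
                assert not np.isfinite(oracle)
            else:
                assert found[3] == pytest.approx(oracle, abs=1e-9)


class TestPcaGroupMeans:
    def test_two_groups_single_axis(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        m.iloc[5:] += 5
        groups = pd.Series([1] * 5 + [2] * 5, index=m.index)
        res = pca_group_means(m, groups)
        assert res["explained_variance"][0] == pytest.approx(1.0)
        assert res["group_scores"].shape == (2, 1)

    def test_eigenvalues_match_closed_form(self):
        # 3 groups in 2-D placed so the group-mean covariance is known
        means = pd.DataFrame(
            [[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]], index=["a", "b", "c"]
        )
        groups = pd.Series(["a", "b", "c"], index=means.index)
        res = pca_group_means(means, groups)
        # covariance of {0,2,4} along x is 4; zero along y
        assert res["eigenvalues"][0] == pytest.approx(4.0)
        assert res["explained_variance"][0] == pytest.approx(1.0)

    def test_single_group_rejected(self):
        m = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="two groups"):
            pca_group_means(m, pd.Series([1, 1, 1], index=m.index))

    def test_correlation_flag_thresholded(self, community_data):
        meta, _, motus = community_data
        groups = pd.Series(meta["species"].values, index=motus.index)
        res = pca_group_means(motus, groups, correlation_threshold=0.8)
        corr = res["intersect_correlations"]
        assert res["significant_axes"] == [
            i + 1 for i, c in enumerate(corr) if c > 0.8
        ]


class TestRichnessModels:
    def _table(self, n=45, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "sporocarp_richness": rng.poisson(8, n) + 1.0,
                "nifh_richness": rng.poisson(8, n) + 1.0,
                "species": rng.choice(["Fagus", "Picea"], n),
                "n_per_density": rng.lognormal(-7, 0.3, n),
                "c_per_density": rng.lognormal(-1.4, 0.1, n),
                "decay_class": rng.integers(1, 5, n),
            }
        )

    def test_residual_df_with_five_predictors(self):
        res = richness_models(self._table())
        assert res["residual_df"] == 39
        assert res["anova"].loc["Residual", "Df"] == 39
        assert (res["anova"]["Df"][:-1] == 1).all()

    def test_nonpositive_log_input_rejected(self):
        t = self._table()
        t.loc[t.index[0], "n_per_density"] = 0.0
        with pytest.raises(ValueError, match="log-transformed"):
            richness_models(t)

    def test_backward_selection_recovers_true_predictor(self):
        t = self._table(seed=3)
        t["sporocarp_richness"] = 2.0 * t["nifh_richness"] + np.random.default_rng(
            4
        ).normal(0, 0.5, len(t))
        res = richness_models(t)
        assert "nifh_richness" in res["selected_predictors"]
        assert res["selected_model"].rsquared > 0.9

    def test_exact_linear_response_r2_one(self):
        x = np.arange(20, dtype=float)
        fit = polynomial_fit(x, 3 * x + 1, degree=1)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["coefficients"][0] == pytest.approx(3.0)

    def test_hump_gives_negative_quadratic(self):
        x = np.linspace(0, 10, 30)
        y = -((x - 5) ** 2) + 25
        fit = polynomial_fit(x, y, degree=2)
        assert fit["coefficients"][0] < 0
        assert fit["r_squared"] == pytest.approx(1.0)
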