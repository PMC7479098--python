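"""Compositional layer: closed forms, clustering, inference, networks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metataxa.compositional_stats import (
    aitchison_distance,
    build_network,
    clr,
    dirichlet_mc_da,
    ordinate,
    permanova,
    permanova_table,
    proportionality_rho,
    replace_zeros,
    ward_cluster,
)


def _df(rows, index=None, columns=None):
    return pd.DataFrame(np.asarray(rows, dtype=float), index=index, columns=columns)


class TestReplaceZeros:
    def test_no_zeros_leaves_proportions_unchanged(self):
        out = replace_zeros(_df([[2, 2], [1, 3]]))
        assert np.allclose(out.to_numpy(), [[0.5, 0.5], [0.25, 0.75]])

    def test_stated_formula_on_single_zero(self):
        out = replace_zeros(_df([[0, 10], [5, 5]]))
        assert out.iloc[0].tolist() == pytest.approx([0.065, 0.935], abs=1e-12)

    def test_rows_sum_to_one_on_random_sparse_matrices(self, rng):
        for _ in range(30):
            X = rng.integers(0, 5, size=(6, 8))
            X[:, 0] += 1
            X[0] += 1
            out = replace_zeros(pd.DataFrame(X))
            assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)
            assert (out.to_numpy() > 0).all()

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            replace_zeros(_df([[0, 0], [1, 2]]))


class TestClr:
    def test_constant_row_maps_to_zero(self):
        out = clr(_df([[1, 1, 1, 1]]))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_two_part_closed_form(self):
        out = clr(_df([[1, 10]]))
        v = np.log(np.sqrt(10))
        assert out.iloc[0].tolist() == pytest.approx([-v, v], abs=1e-9)

    def test_scale_invariance(self, rng):
        X = rng.uniform(0.1, 5, size=(4, 6))
        assert np.allclose(clr(pd.DataFrame(X)).to_numpy(),
                           clr(pd.DataFrame(7.3 * X)).to_numpy(), atol=1e-9)

    def test_rows_sum_to_zero(self, rng):
        X = rng.uniform(0.1, 5, size=(5, 7))
        assert np.allclose(clr(pd.DataFrame(X)).sum(axis=1), 0.0, atol=1e-9)

    def test_agrees_with_skbio(self, rng):
        from skbio.stats.composition import clr as skbio_clr

        x = rng.uniform(0.1, 5, size=(3, 6))
        assert np.allclose(clr(pd.DataFrame(x)).to_numpy(), skbio_clr(x), atol=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            clr(_df([[0.0, 1.0]]))


class TestAitchison:
    def test_identical_rows_zero_distance(self):
        D = aitchison_distance(clr(_df([[1, 2], [1, 2]])))
        assert D.iloc[0, 1] == 0.0

    def test_swapped_two_part_closed_form(self):
        D = aitchison_distance(clr(_df([[1, 10], [10, 1]])))
        assert D.iloc[0, 1] == pytest.approx(2 * np.sqrt(2) * np.log(np.sqrt(10)), abs=1e-9)

    def test_invariance_to_sample_scaling(self, rng):
        X = rng.uniform(0.5, 5, size=(4, 6))
        scale = rng.uniform(0.1, 10, size=(4, 1))
        d1 = aitchison_distance(clr(pd.DataFrame(X)))
        d2 = aitchison_distance(clr(pd.DataFrame(X * scale)))
        assert np.allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-9)


class TestWard:
    def test_two_tight_groups_perfectly_split(self, rng):
        A = rng.normal(0, 0.1, size=(10, 3))
        B = rng.normal(5, 0.1, size=(10, 3))
        X = pd.DataFrame(np.vstack([A, B]))
        D = aitchison_distance(X)  # plain Euclidean on rows
        res = ward_cluster(D, k=2)
        labels = res.labels.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]
        assert res.mean_silhouette > 0.9

    def test_one_dimensional_pairs_silhouette(self):
        X = pd.DataFrame([[0.0], [0.1], [10.0], [10.1]])
        D = aitchison_distance(X)
        res = ward_cluster(D, k=2)
        assert sorted(res.labels.to_numpy()[:2]) != sorted(res.labels.to_numpy()[1:3])
        assert res.mean_silhouette == pytest.approx(0.98999, abs=1e-4)

    def test_degenerate_k_equals_n(self):
        X = pd.DataFrame([[0.0], [1.0], [2.0]])
        res = ward_cluster(aitchison_distance(X), k=3)
        assert sorted(res.labels) == [1, 2, 3]
        assert res.mean_silhouette == 0.0

    def test_k_larger_than_n_rejected(self):
        X = pd.DataFrame([[0.0], [1.0]])
        with pytest.raises(ValueError):
            ward_cluster(aitchison_distance(X), k=3)

    def test_heights_match_r_hclust_ward_d2(self, rng):
        import subprocess

        X = rng.normal(size=(8, 3))
        D = aitchison_distance(pd.DataFrame(X))
        res = ward_cluster(D, k=2)
        flat = ",".join(f"{v:.12f}" for v in D.to_numpy().flatten())
        rscript = (
            f"d <- matrix(c({flat}), nrow=8, byrow=TRUE);"
            "h <- hclust(as.dist(d), method='ward.D2');"
            "cat(sprintf('%.10f', sort(h$height)), sep='\\n')"
        )
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True)
        r_heights = np.array([float(x) for x in out.stdout.split()])
        assert np.allclose(np.sort(res.linkage[:, 2]), r_heights, atol=1e-8)


class TestOrdination:
    def test_collinear_points_single_axis(self):
        X = pd.DataFrame([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        res = ordinate(dist=aitchison_distance(X))
        assert res.proportion_explained.iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_pcoa_roundtrips_euclidean_distances(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 4)))
        D = aitchison_distance(X)
        res = ordinate(dist=D, n_axes=6)
        D2 = aitchison_distance(res.coords)
        assert np.allclose(D.to_numpy(), D2.to_numpy(), atol=1e-9)

    def test_pcoa_matches_pca_up_to_sign_on_clr(self, rng):
        X = clr(pd.DataFrame(rng.uniform(0.5, 4, size=(7, 5))))
        pcoa = ordinate(dist=aitchison_distance(X), n_axes=2)
        pca = ordinate(clr_matrix=X, n_axes=2)
        for ax in range(2):
            a = pcoa.coords.iloc[:, ax].to_numpy()
            b = pca.coords.iloc[:, ax].to_numpy()
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_non_euclidean_warns(self):
        ids = list("abc")
        D = pd.DataFrame([[0, 1, 10], [1, 0, 1], [10, 1, 0]], index=ids, columns=ids,
                         dtype=float)
        with pytest.warns(UserWarning):
            ordinate(dist=D)


class TestPermanova:
    def test_separated_groups_reach_minimal_p(self, rng):
        A = rng.normal(0, 0.2, size=(8, 4))
        B = rng.normal(10, 0.2, size=(8, 4))
        X = pd.DataFrame(np.vstack([A, B]), index=[f"s{i}" for i in range(16)])
        fac = pd.Series(["a"] * 8 + ["b"] * 8, index=X.index)
        res = permanova(aitchison_distance(X), fac, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.r2 > 0.9

    def test_agrees_with_skbio_permanova(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        X = pd.DataFrame(rng.normal(size=(12, 4)), index=[f"s{i}" for i in range(12)])
        fac = pd.Series(["a"] * 6 + ["b"] * 6, index=X.index)
        D = aitchison_distance(X)
        ours = permanova(D, fac, n_perm=99, seed=0)
        ref = skbio_permanova(DistanceMatrix(D.to_numpy(), ids=list(D.index)),
                              fac.to_numpy(), permutations=99)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_constant_factor_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError):
            permanova(aitchison_distance(X), pd.Series("a", index=X.index))

    def test_table_adjusts_with_bh(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)), index=[f"s{i}" for i in range(10)])
        md = pd.DataFrame(
            {"f1": ["a"] * 5 + ["b"] * 5, "f2": (["x", "y"] * 5)}, index=X.index
        )
        out = permanova_table(aitchison_distance(X), md, ["f1", "f2"], n_perm=99, seed=2)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestDirichletDA:
    def _counts(self, rng, shift=1.0):
        base = rng.integers(50, 200, size=20)
        X = rng.poisson(base, size=(20, 20))
        X[10:, 0] = rng.poisson(base[0] * shift, size=10)
        idx = [f"s{i}" for i in range(20)]
        return pd.DataFrame(X, index=idx), pd.Series(["a"] * 10 + ["b"] * 10, index=idx)

    def test_label_permutation_of_identical_groups_not_flagged(self, rng):
        flagged = 0
        for rep in range(10):
            counts, groups = self._counts(rng, shift=1.0)
            res = dirichlet_mc_da(counts, groups, n_mc=128, seed=rep)
            flagged += int(((res.table["t_q"] < 0.05) & (res.table["w_q"] < 0.05)).any())
        assert flagged <= 1  # no FDR hits in >= 9/10 null datasets

    def test_planted_eightfold_shift_flagged_with_large_effect(self, rng):
        counts, groups = self._counts(rng, shift=8.0)
        res = dirichlet_mc_da(counts, groups, seed=5)
        row = res.table.iloc[0]
        assert row["significant"] and abs(row["effect"]) >= 1.0

    def test_effect_sign_flips_with_group_swap(self, rng):
        counts, groups = self._counts(rng, shift=4.0)
        res1 = dirichlet_mc_da(counts, groups, n_mc=64, seed=3)
        swapped = groups.map({"a": "b", "b": "a"})
        res2 = dirichlet_mc_da(counts, swapped, n_mc=64, seed=3)
        assert np.sign(res1.table["effect"].iloc[0]) == -np.sign(res2.table["effect"].iloc[0])

    def test_adjusted_never_below_raw(self, rng):
        counts, groups = self._counts(rng)
        res = dirichlet_mc_da(counts, groups, n_mc=32, seed=9)
        assert (res.table["t_q"] >= res.table["t_p"] - 1e-12).all()

    def test_small_group_rejected(self, rng):
        counts, groups = self._counts(rng)
        bad = groups.copy()
        bad.iloc[:] = "a"
        bad.iloc[0] = "b"
        with pytest.raises(ValueError):
            dirichlet_mc_da(counts, bad, seed=1)


class TestProportionality:
    def test_perfectly_proportional_pair(self, rng):
        x = rng.normal(size=10)
        M = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=10)})
        rho = proportionality_rho(M)
        assert rho.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_antiproportional_pair(self, rng):
        x = rng.normal(size=10)
        M = pd.DataFrame({"a": x, "b": -x})
        rho = proportionality_rho(M)
        assert rho.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_columns_center_near_zero(self, rng):
        M = pd.DataFrame(rng.normal(size=(1000, 12)))
        rho = proportionality_rho(M)
        off = rho.to_numpy()[np.triu_indices(12, 1)]
        assert abs(off.mean()) < 0.05

    def test_zero_variance_reported_missing(self, rng):
        M = pd.DataFrame({"a": np.ones(5), "b": rng.normal(size=5)})
        rho = proportionality_rho(M)
        assert np.isnan(rho.loc["a", "b"]) and np.isnan(rho.loc["a", "a"])


class TestNetwork:
    def _rho(self, values, ids):
        return pd.DataFrame(values, index=ids, columns=ids, dtype=float)

    def test_unit_cutoff_gives_empty_network(self, rng):
        M = pd.DataFrame(rng.normal(size=(8, 5)))
        rho = proportionality_rho(M)
        net = build_network(rho, pd.Series(1.0, index=rho.index), cutoff=1.0)
        assert net.graph.number_of_edges() == 0

    def test_two_triangles_give_q_half(self):
        ids = list("abcdef")
        R = np.eye(6)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            R[i, j] = R[j, i] = 0.9
        net = build_network(self._rho(R, ids), pd.Series(1.0, index=ids), cutoff=0.3)
        assert len(net.modules) == 2
        assert net.modularity_q == pytest.approx(0.5, abs=1e-6)

    def test_planted_blocks_recovered(self, rng):
        # two co-varying guilds: within-block rho ~ +0.8, across ~ 0
        n = 400
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        cols = {}
        for i in range(5):
            cols[f"x{i}"] = 2.0 * f1 + rng.normal(scale=1.0, size=n)
        for i in range(5):
            cols[f"y{i}"] = 2.0 * f2 + rng.normal(scale=1.0, size=n)
        rho = proportionality_rho(pd.DataFrame(cols))
        net = build_network(rho, pd.Series(1.0, index=rho.index), cutoff=0.3)
        blocks = {frozenset(m) for m in net.modules}
        assert blocks == {
            frozenset(f"x{i}" for i in range(5)),
            frozenset(f"y{i}" for i in range(5)),
        }


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.floats(min_value=0.1, max_value=100), min_size=3, max_size=3),
        min_size=2, max_size=6,
    )
)
def test_clr_rows_always_centered(rows):
    out = clr(pd.DataFrame(rows))
    assert np.allclose(out.sum(axis=1), 0.0, atol=1e-8)
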