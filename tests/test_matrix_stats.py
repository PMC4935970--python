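import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from thermodiv.matrix_stats import (
    bioenv,
    bray_curtis,
    env_distance,
    mantel,
    partial_mantel,
    pearson_test,
    read_distance_matrix,
    write_distance_matrix,
)
from thermodiv.tables_io import OtuTable


def dm(data, ids=None):
    data = np.asarray(data, dtype=float)
    return DistanceMatrix(data, ids=ids or [f"u{i}" for i in range(data.shape[0])])


def dm_from_points(points, ids=None):
    return dm(squareform(pdist(np.asarray(points, dtype=float))), ids)


def sym_from_upper(vec, n, ids=None):
    m = np.zeros((n, n))
    m[np.triu_indices(n, k=1)] = vec
    return dm(m + m.T, ids)


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = OtuTable(pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3]}))
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.0)

    def test_disjoint_columns_one(self):
        t = OtuTable(pd.DataFrame({"a": [3, 0], "b": [0, 5]}))
        assert bray_curtis(t)["a", "b"] == pytest.approx(1.0)

    def test_direct_formula(self):
        t = OtuTable(pd.DataFrame({"a": [1, 1, 0], "b": [0, 1, 1]}))
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.5)

    def test_all_zero_sample_named(self):
        t = OtuTable(pd.DataFrame({"a": [1, 0], "bad": [0, 0]}))
        with pytest.raises(ValueError, match="bad"):
            bray_curtis(t)


class TestEnvDistance:
    def test_single_variable_two_units(self):
        df = pd.DataFrame({"v": [1.0, 5.0]}, index=["a", "b"])
        d = env_distance(df, ["v"])
        z = (np.array([1, 5]) - 3.0) / 2.0
        assert d["a", "b"] == pytest.approx(abs(z[0] - z[1]))

    def test_duplicate_rows_distance_zero(self):
        df = pd.DataFrame({"v": [2.0, 2.0, 7.0], "w": [1.0, 1.0, 0.0]}, index=list("abc"))
        assert env_distance(df, ["v", "w"])["a", "b"] == pytest.approx(0.0)

    def test_hand_computed_three_units(self):
        df = pd.DataFrame({"v": [0.0, 1.0, 2.0], "w": [10.0, 10.0, 16.0]}, index=list("abc"))
        # z_v = (-1.2247, 0, 1.2247); z_w = (-0.7071, -0.7071, 1.4142)
        zv = (df.v - 1.0) / np.sqrt(2 / 3)
        zw = (df.w - 12.0) / np.sqrt(8.0)
        expected = np.hypot(zv["a"] - zv["b"], zw["a"] - zw["b"])
        assert env_distance(df, ["v", "w"])["a", "b"] == pytest.approx(expected)

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"v": [3.0, 3.0, 3.0]}, index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            env_distance(df, ["v"])


class TestDistanceMatrixIO:
    def test_round_trip(self, tmp_path):
        d = dm_from_points(np.random.default_rng(0).random((5, 2)))
        p = tmp_path / "d.tsv"
        write_distance_matrix(d, p)
        back = read_distance_matrix(p)
        assert list(back.ids) == list(d.ids)
        np.testing.assert_allclose(back.data, d.data, atol=1e-12)


class TestMantel:
    def test_scaled_copy_r_one(self):
        rng = np.random.default_rng(1)
        d1 = dm_from_points(rng.random((6, 2)))
        d2 = dm(2.0 * d1.data, list(d1.ids))
        res = mantel(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_self_mantel_minimal_p(self):
        d1 = dm_from_points(np.random.default_rng(2).random((8, 2)))
        res = mantel(d1, d1, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        d1 = dm_from_points(rng.random((4, 2)))
        d2 = dm_from_points(rng.random((4, 2)), list(d1.ids))
        res = mantel(d1, d2, exact=True)
        # independent enumeration of all 4! joint relabellings of d1
        iu = np.triu_indices(4, k=1)
        v2 = d2.data[iu]
        r_obs = np.corrcoef(d1.data[iu], v2)[0, 1]
        rs = []
        for perm in itertools.permutations(range(4)):
            p = np.asarray(perm)
            rs.append(np.corrcoef(d1.data[np.ix_(p, p)][iu], v2)[0, 1])
        expected_p = np.mean([r >= r_obs - 1e-12 for r in rs])
        assert res.p == pytest.approx(expected_p)
        assert res.n_perm == 24

    def test_agrees_with_skbio_r(self):
        rng = np.random.default_rng(4)
        d1 = dm_from_points(rng.random((10, 3)))
        d2 = dm_from_points(rng.random((10, 3)), list(d1.ids))
        ours = mantel(d1, d2, n_perm=999, seed=5)
        theirs_r, _, _ = skbio_mantel(d1, d2, permutations=0, alternative="greater")
        assert ours.r == pytest.approx(theirs_r, abs=1e-12)

    def test_label_mismatch_rejected(self):
        d1 = dm_from_points(np.random.default_rng(0).random((4, 2)), list("abcd"))
        d2 = dm_from_points(np.random.default_rng(1).random((4, 2)), list("abce"))
        with pytest.raises(ValueError):
            mantel(d1, d2, n_perm=9, seed=0)


class TestPartialMantel:
    def _orthogonal_control(self, d1, d2, seed=0):
        n = d1.shape[0]
        iu = np.triu_indices(n, k=1)
        v1, v2 = d1.data[iu], d2.data[iu]
        rng = np.random.default_rng(seed)
        c = rng.random(iu[0].size)
        design = np.column_stack([np.ones_like(v1), v1, v2])
        c -= design @ np.linalg.lstsq(design, c, rcond=None)[0]
        return sym_from_upper(c - c.min() + 1.0, n, list(d1.ids))

    def test_orthogonal_control_is_noop(self):
        rng = np.random.default_rng(6)
        d1 = dm_from_points(rng.random((7, 2)))
        d2 = dm_from_points(rng.random((7, 2)), list(d1.ids))
        ctrl = self._orthogonal_control(d1, d2)
        simple = mantel(d1, d2, n_perm=9, seed=0)
        partial = partial_mantel(d1, d2, [ctrl], n_perm=9, seed=0)
        assert partial.r == pytest.approx(simple.r, abs=1e-10)

    def test_control_equal_to_d2_kills_correlation(self):
        rng = np.random.default_rng(7)
        d1 = dm_from_points(rng.random((7, 2)))
        d2 = dm_from_points(rng.random((7, 2)), list(d1.ids))
        res = partial_mantel(d1, d2, [d2], n_perm=9, seed=0)
        assert abs(res.r) < 1e-8

    def test_matches_closed_form_partial_correlation(self):
        rng = np.random.default_rng(8)
        d1 = dm_from_points(rng.random((5, 2)))
        d2 = dm_from_points(rng.random((5, 2)), list(d1.ids))
        dc = dm_from_points(rng.random((5, 2)), list(d1.ids))
        iu = np.triu_indices(5, k=1)
        rxy = np.corrcoef(d1.data[iu], d2.data[iu])[0, 1]
        rxz = np.corrcoef(d1.data[iu], dc.data[iu])[0, 1]
        ryz = np.corrcoef(d2.data[iu], dc.data[iu])[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        res = partial_mantel(d1, d2, [dc], n_perm=9, seed=0)
        assert res.r == pytest.approx(expected, abs=1e-10)

    def test_empty_controls_rejected(self):
        d1 = dm_from_points(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(ValueError):
            partial_mantel(d1, d1, [], n_perm=9, seed=0)

    def test_collinear_controls_rejected(self):
        rng = np.random.default_rng(9)
        d1 = dm_from_points(rng.random((6, 2)))
        d2 = dm_from_points(rng.random((6, 2)), list(d1.ids))
        dc = dm_from_points(rng.random((6, 2)), list(d1.ids))
        dc2 = dm(2.0 * dc.data, list(d1.ids))
        with pytest.raises(ValueError, match="collinear"):
            partial_mantel(d1, d2, [dc, dc2], n_perm=9, seed=0)


def _bioenv_oracle(community, df, variables):
    """Independent brute-force BioENV (plain loops, scipy spearman)."""
    iu = np.triu_indices(len(community.ids), k=1)
    comm = community.data[iu]
    best = (-np.inf, None)
    for k in range(1, len(variables) + 1):
        for combo in itertools.combinations(sorted(variables), k):
            z = df[list(combo)].astype(float)
            z = (z - z.mean()) / z.std(ddof=0)
            ed = squareform(pdist(z.to_numpy()))[iu]
            rho = scipy.stats.spearmanr(comm, ed).statistic
            if rho > best[0]:
                best = (rho, combo)
    return best


class TestBioEnv:
    def test_perfect_single_variable(self):
        df = pd.DataFrame(
            {"good": [0.0, 1.0, 3.0, 6.0], "noise": [5.0, -1.0, 2.0, 2.5]},
            index=list("abcd"),
        )
        community = env_distance(df, ["good"])
        res = bioenv(community, df, ["good", "noise"])
        assert res.best_subset == ("good",)
        assert res.best_rho == pytest.approx(1.0)

    def test_subset_count(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.random((5, 3)), columns=list("xyz"), index=list("abcde"))
        community = dm_from_points(rng.random((5, 2)), list("abcde"))
        res = bioenv(community, df, ["x", "y", "z"])
        assert len(res.ranking) == 7

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(20 + seed)
        ids = list("abcdef")
        df = pd.DataFrame(rng.random((6, 4)), columns=list("pqrs"), index=ids)
        community = dm_from_points(rng.random((6, 2)), ids)
        res = bioenv(community, df, ["p", "q", "r", "s"])
        rho, combo = _bioenv_oracle(community, df, ["p", "q", "r", "s"])
        assert res.best_rho == pytest.approx(rho, abs=1e-12)
        assert res.best_subset == combo

    def test_invariant_to_variable_ordering(self):
        rng = np.random.default_rng(11)
        ids = list("abcdef")
        df = pd.DataFrame(rng.random((6, 3)), columns=list("xyz"), index=ids)
        community = dm_from_points(rng.random((6, 2)), ids)
        a = bioenv(community, df, ["x", "y", "z"])
        b = bioenv(community, df, ["z", "x", "y"])
        assert a.best_subset == b.best_subset
        assert a.best_rho == pytest.approx(b.best_rho)

    def test_too_many_variables_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).random((4, 16)), index=list("abcd"))
        df.columns = [f"v{i}" for i in range(16)]
        community = dm_from_points(np.random.default_rng(1).random((4, 2)), list("abcd"))
        with pytest.raises(ValueError, match="15"):
            bioenv(community, df, list(df.columns))


class TestPearson:
    def test_perfect_correlation_flagged_zero_p(self):
        x = np.arange(5.0)
        r, t, p = pearson_test(x, x)
        assert r == 1.0 and np.isinf(t) and p == 0.0

    def test_orthogonal_vectors_r_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0]) - 1 / 3
        y -= y.mean()
        r, t, p = pearson_test(x, y)
        assert abs(r) < 1e-12 and p == pytest.approx(1.0)

    def test_matches_scipy_on_hand_case(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0]
        r, t, p = pearson_test(x, y)
        ref = scipy.stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
        assert t == pytest.approx(r * np.sqrt(3 / (1 - r * r)), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
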