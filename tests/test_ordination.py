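"""Ordination: PCA eigen-oracle, MCOA identities and maximality,
PERMANOVA against exhaustive enumeration and an independent implementation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from seacycle import MCOA, Permanova, pca, permanova


def frame(arr, prefix="f"):
    """Features x samples frame with ISO-date columns."""
    arr = np.asarray(arr, dtype=float)
    cols = [
        d.strftime("%Y-%m-%d")
        for d in pd.date_range("2011-01-15", periods=arr.shape[1], freq="37D")
    ]
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=cols)


def zscored(rng, p, n):
    X = rng.normal(size=(p, n))
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
    return frame(X)


class TestPCA:
    def test_rank_one_matrix_pc1_explains_everything(self, rng):
        u = rng.normal(size=4)
        v = rng.normal(size=6)
        res = pca(frame(np.outer(u, v)))
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_eigenvalues_match_direct_covariance_eigensolve(self, rng):
        X = zscored(rng, 5, 8)
        res = pca(X, mode="samples")
        A = X.to_numpy().T
        Ac = A - A.mean(axis=0)
        cov = Ac.T @ Ac / A.shape[0]
        expect = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(res.eigenvalues, expect[: len(res.eigenvalues)],
                           atol=1e-10)

    def test_duplicating_samples_preserves_variance_fractions(self, rng):
        X = zscored(rng, 4, 6)
        doubled = pd.concat([X, X.set_axis([c + "x" for c in X.columns], axis=1)],
                            axis=1)
        f1 = pca(X).variance_fractions
        f2 = pca(doubled).variance_fractions
        assert np.allclose(f1, f2, atol=1e-10)

    def test_feature_mode_transposes(self, rng):
        X = zscored(rng, 5, 7)
        res = pca(X, mode="features")
        assert list(res.scores.index) == list(X.index)

    def test_consistent_sample_permutation_preserves_eigenvalues(self, rng):
        X = zscored(rng, 5, 9)
        perm = rng.permutation(X.shape[1])
        Xp = X.iloc[:, perm]
        assert np.allclose(pca(X).eigenvalues, pca(Xp).eigenvalues, atol=1e-10)


class TestMCOA:
    def test_single_table_reduces_to_pca(self, rng):
        X = zscored(rng, 6, 8)
        res_pca = pca(X, mode="samples")
        res = MCOA([X], table_scaling="none").fit(n_axes=5)
        assert np.allclose(res.eigenvalues, res_pca.eigenvalues[:5], atol=1e-8)
        # scores agree up to per-axis scale and sign
        for h in range(3):
            a = res.scores.iloc[:, h].to_numpy()
            b = res_pca.scores.iloc[:, h].to_numpy()
            a = a / np.linalg.norm(a)
            b = b / np.linalg.norm(b)
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_duplicated_table_doubles_pseudo_eigenvalues(self, rng):
        X = zscored(rng, 6, 8)
        one = MCOA([X], table_scaling="none").fit(n_axes=4)
        two = MCOA([X, X.copy()], table_scaling="none").fit(n_axes=4)
        assert np.allclose(two.eigenvalues, 2 * one.eigenvalues, atol=1e-8)
        for h in range(2):
            a = one.scores.iloc[:, h].to_numpy()
            b = two.scores.iloc[:, h].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_leading_axis_maximizes_criterion_monte_carlo(self, rng):
        tables = [zscored(rng, 3, 6), zscored(rng, 3, 6, )]
        res = MCOA(tables, table_scaling="none").fit(n_axes=2)
        lam1 = res.eigenvalues[0]
        best = max(
            res.criterion_value(rng.normal(size=6)) for _ in range(10_000)
        )
        assert best <= lam1 + 1e-10
        # and the attained maximum is reached by the leading synthetic axis
        v1 = res.scores.iloc[:, 0].to_numpy()
        assert res.criterion_value(v1) == pytest.approx(lam1, abs=1e-10)

    def test_scores_orthonormal_under_row_weights(self, rng):
        tables = {"a": zscored(rng, 5, 10), "b": zscored(rng, 4, 10)}
        res = MCOA(tables).fit(n_axes=3)
        V = res.scores.to_numpy()
        gram = V.T @ V / V.shape[0]
        assert np.allclose(gram, np.eye(3), atol=1e-8)

    def test_eigenvalues_non_increasing_and_nonnegative(self, rng):
        res = MCOA([zscored(rng, 5, 9), zscored(rng, 6, 9)]).fit(n_axes=6)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert (res.eigenvalues >= 0).all()

    def test_sample_order_mismatch_rejected(self, rng):
        X = zscored(rng, 4, 6)
        Y = X.iloc[:, ::-1]
        with pytest.raises(ValueError, match="sample ordering"):
            MCOA([X, Y])

    def test_zero_variance_table_rejected(self, rng):
        X = zscored(rng, 4, 6)
        Z = frame(np.ones((3, 6)))
        with pytest.raises(ValueError, match="zero total variance"):
            MCOA([X, Z]).fit()


def oracle_one_factor_permanova(D, labels):
    """Independent one-factor pseudo-F from the classical group-sum
    formula: SS_total = sum d^2 / n, SS_within = per-group sums."""
    n = len(labels)
    D2 = D**2
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += D2[np.ix_(idx, idx)][
            np.triu_indices(len(idx), 1)
        ].sum() / len(idx)
    ss_among = ss_total - ss_within
    a = len(np.unique(labels))
    F = (ss_among / (a - 1)) / (ss_within / (n - a))
    return ss_among, ss_within, F


class TestPermanova:
    def test_two_separated_groups_r2_near_one(self, rng):
        X = np.vstack([np.zeros((3, 2)), np.full((3, 2), 100.0)])
        D = squareform(pdist(X))
        factors = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3})
        res = Permanova(D, factors).fit(n_perm=99, seed=0)
        assert res.table.loc["group", "R2"] > 0.99
        assert res.table.loc["group", "p_value"] >= 1 / 100

    def test_matches_one_factor_oracle_and_skbio(self, rng):
        X = rng.normal(size=(12, 4))
        D = squareform(pdist(X))
        labels = np.array(list("aabbccaabbcc"))
        factors = pd.DataFrame({"g": labels})
        res = Permanova(D, factors).fit(n_perm=99, seed=1)
        ss_among, ss_within, F = oracle_one_factor_permanova(D, labels)
        assert res.table.loc["g", "SS"] == pytest.approx(ss_among, rel=1e-10)
        assert res.table.loc["Residual", "SS"] == pytest.approx(ss_within, rel=1e-10)
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(F, rel=1e-10)
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        sk = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(D), grouping=list(labels), permutations=0
        )
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(
            sk["test statistic"], rel=1e-8
        )

    def test_exhaustive_permutation_p_value(self, rng):
        # n=6, one 2-level factor: compare against full 6! enumeration
        X = rng.normal(size=(6, 3))
        D = squareform(pdist(X))
        labels = np.array(list("aaabbb"))
        factors = pd.DataFrame({"g": labels})
        _, _, F_obs = oracle_one_factor_permanova(D, labels)
        stats = []
        for perm in itertools.permutations(range(6)):
            _, _, F = oracle_one_factor_permanova(D, labels[list(perm)])
            stats.append(F)
        stats = np.asarray(stats)
        p_exact = (stats >= F_obs - 1e-12).mean()
        n_perm = 1999
        res = Permanova(D, factors).fit(n_perm=n_perm, seed=3)
        p_mc = res.table.loc["g", "p_value"]
        # Monte-Carlo p concentrates on the exhaustive value
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < max(4 * se, 0.02)

    def test_total_ss_identity_on_zscored_table(self, rng):
        p, n = 7, 20
        X = zscored(rng, p, n)
        dates = pd.to_datetime(X.columns)
        factors = pd.DataFrame({"month": dates.month})
        res = Permanova(X, factors).fit(n_perm=9, seed=0)
        assert res.table.loc["Total", "SS"] == pytest.approx(
            (n - 1) * p, rel=1e-6
        )

    def test_r2_sums_to_one_with_interaction(self, truth, tables):
        from seacycle import filter_rare, to_proportions, zscore

        z = zscore(filter_rare(to_proportions(tables["family"])))
        dates = z.dates
        factors = pd.DataFrame({"month": dates.month, "year": dates.year})
        res = Permanova(z, factors, interaction=True).fit(n_perm=29, seed=0)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)
        # seasonal factor dominates in a seasonally forced community
        assert res.table.loc["month", "R2"] > res.table.loc["year", "R2"]

    def test_interaction_dropped_when_cells_empty(self, rng):
        X = rng.normal(size=(8, 3))
        D = squareform(pdist(X))
        factors = pd.DataFrame(
            {"a": list("xxxxyyyy"), "b": list("uuvvuuvv")}
        )
        # remove one cell: samples where a=x & b=v
        keep = [i for i in range(8) if not (factors.a[i] == "x" and factors.b[i] == "v")]
        with pytest.warns(UserWarning, match="interaction dropped"):
            model = Permanova(D[np.ix_(keep, keep)], factors.iloc[keep],
                              interaction=True)
        assert [t for t, _ in model.terms] == ["a", "b"]

    def test_permutation_invariance_of_sample_order(self, rng):
        X = rng.normal(size=(10, 4))
        D = squareform(pdist(X))
        labels = np.array(list("aabbaabbab"))
        perm = rng.permutation(10)
        res1 = Permanova(D, pd.DataFrame({"g": labels})).fit(n_perm=49, seed=5)
        res2 = Permanova(
            D[np.ix_(perm, perm)], pd.DataFrame({"g": labels[perm]})
        ).fit(n_perm=49, seed=5)
        for col in ("SS", "R2", "pseudo_F"):
            assert res1.table.loc["g", col] == pytest.approx(
                res2.table.loc["g", col], rel=1e-9
            )

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            Permanova(D, pd.DataFrame({"g": ["a", "b"]}))
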