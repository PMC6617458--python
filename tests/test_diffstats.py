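import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom, poisson

from chitomics.diffstats import (
    DispersionEstimate,
    _equalize_library_sizes,
    _exact_nb_pvalue,
    bh_adjust,
    bray_curtis,
    cpm_filter,
    dispersion_homogeneity,
    estimate_dispersion_qcml,
    nb_exact_test,
    permanova,
    quasi_poisson_test,
    tmm_factors,
)

SAMPLES = [f"PS{i}" for i in range(1, 5)] + [f"Chitin{i}" for i in range(1, 5)]
GROUPS = {s: ("PS" if s.startswith("PS") else "Chitin") for s in SAMPLES}


def _df(rows, columns=None):
    return pd.DataFrame(rows, columns=columns or SAMPLES)


class TestCpmFilter:
    def test_paper_threshold_kept(self):
        counts = _df([[4, 4, 4, 4, 0, 0, 0, 0]])
        lib = pd.Series(1e6, index=SAMPLES)
        kept, n_removed = cpm_filter(counts, lib)
        assert len(kept) == 1 and n_removed == 0

    def test_three_samples_removed(self):
        counts = _df([[4, 4, 4, 0, 0, 0, 0, 0]])
        lib = pd.Series(1e6, index=SAMPLES)
        kept, n_removed = cpm_filter(counts, lib)
        assert kept.empty and n_removed == 1

    def test_random_tables_match_predicate_oracle(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.integers(0, 30, size=(200, 8)), columns=SAMPLES)
        lib = pd.Series(rng.integers(1_000_000, 3_000_000, 8).astype(float), index=SAMPLES)
        kept, _ = cpm_filter(counts, lib, min_cpm=4, min_samples=4)
        for fid in counts.index:
            n_ok = sum(
                counts.loc[fid, s] / lib[s] * 1e6 >= 4 for s in SAMPLES
            )
            assert (fid in kept.index) == (n_ok >= 4)

    def test_zero_library_size_rejected(self):
        counts = _df([[1] * 8])
        lib = pd.Series([0.0] + [100.0] * 7, index=SAMPLES)
        with pytest.raises(ValueError):
            cpm_filter(counts, lib)


def _tmm_oracle(counts, lib, trim_m=0.30, trim_a=0.05):
    """Step-by-step trimmed weighted mean, independent of the implementation."""
    y = counts.to_numpy(dtype=float)
    q75 = [np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])]
    ref = int(np.argmin([abs(q - np.mean(q75)) for q in q75]))
    factors = []
    for j in range(y.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        rows = [i for i in range(y.shape[0]) if y[i, j] > 0 and y[i, ref] > 0]
        m = [math.log2((y[i, j] / lib[j]) / (y[i, ref] / lib[ref])) for i in rows]
        a = [0.5 * math.log2((y[i, j] / lib[j]) * (y[i, ref] / lib[ref])) for i in rows]
        w = [
            (lib[j] - y[i, j]) / (lib[j] * y[i, j])
            + (lib[ref] - y[i, ref]) / (lib[ref] * y[i, ref])
            for i in rows
        ]
        if max(abs(v) for v in m) < 1e-10:
            factors.append(1.0)
            continue
        n = len(rows)
        rank_m = {i: r for r, i in enumerate(sorted(range(n), key=lambda i: m[i]))}
        rank_a = {i: r for r, i in enumerate(sorted(range(n), key=lambda i: a[i]))}
        lo_m = math.floor(n * trim_m)
        lo_a = math.floor(n * trim_a)
        keep = [
            i for i in range(n)
            if lo_m <= rank_m[i] <= n - lo_m - 1 and lo_a <= rank_a[i] <= n - lo_a - 1
        ]
        num = sum(w[i] * m[i] for i in keep)
        den = sum(w[i] for i in keep)
        factors.append(2 ** (num / den))
    g = math.exp(sum(math.log(f) for f in factors) / len(factors))
    return [f / g for f in factors]


class TestTmm:
    def test_identical_libraries(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_pure_depth_scaling(self):
        a = np.array([12, 40, 7, 100, 55, 18, 3, 9])
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_composition_shift_matches_hand_oracle(self):
        rng = np.random.default_rng(10)
        base = rng.integers(20, 400, size=30).astype(float)
        shifted = base.copy()
        shifted[:5] *= 6  # strong composition change in a few features
        counts = pd.DataFrame({"a": base, "b": shifted})
        lib = counts.sum(axis=0).to_numpy()
        expected = _tmm_oracle(counts, lib)
        assert np.allclose(tmm_factors(counts), expected, rtol=1e-10)

    def test_factors_have_geometric_mean_one(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.integers(0, 500, size=(100, 6)))
        f = tmm_factors(counts).to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_single_sample(self):
        counts = pd.DataFrame({"a": [1, 2, 3]})
        assert (tmm_factors(counts) == 1.0).all()


class TestQcmlDispersion:
    def test_poisson_data_gives_near_zero_phi(self):
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(rng.poisson(100, size=(300, 8)), columns=SAMPLES)
        est = estimate_dispersion_qcml(counts, GROUPS)
        assert est.common_phi <= 0.01

    def test_nb_phi_recovery_across_seeds(self):
        phi = 0.2
        r = 1 / phi
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            mu = 100
            counts = pd.DataFrame(
                rng.negative_binomial(r, r / (r + mu), size=(300, 8)), columns=SAMPLES
            )
            est = estimate_dispersion_qcml(counts, GROUPS)
            hits += 0.1 <= est.common_phi <= 0.4
        assert hits == 20

    def test_equal_library_sizes_adjustment_is_identity(self):
        rng = np.random.default_rng(13)
        y = rng.poisson(50, size=(50, 8)).astype(float)
        lib = np.full(8, 1000.0)
        idx = [np.arange(4), np.arange(4, 8)]
        pseudo, target = _equalize_library_sizes(y, lib, idx, phi=0.1)
        assert target == pytest.approx(1000.0)
        assert np.array_equal(pseudo, y)

    def test_tagwise_shrinks_toward_common(self):
        rng = np.random.default_rng(14)
        r = 1 / 0.15
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + 80), size=(100, 8)), columns=SAMPLES
        )
        est = estimate_dispersion_qcml(counts, GROUPS, tagwise=True, prior_df=10)
        assert est.tagwise_phi is not None and len(est.tagwise_phi) == 100
        spread = est.tagwise_phi.max() - est.tagwise_phi.min()
        loose = estimate_dispersion_qcml(counts, GROUPS, tagwise=True, prior_df=0.5)
        assert spread <= loose.tagwise_phi.max() - loose.tagwise_phi.min() + 1e-9

    def test_single_replicate_everywhere_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        with pytest.raises(ValueError):
            estimate_dispersion_qcml(counts, {"a": "g1", "b": "g2"})


def _exact_oracle(z1, z2, n1, n2, phi):
    """Direct-sum enumeration of all splits of the total, independent path."""
    total = z1 + z2
    if total == 0:
        return 1.0
    mu = total / (n1 + n2)

    def prob(a):
        if phi == 0:
            return poisson.pmf(a, n1 * mu) * poisson.pmf(total - a, n2 * mu)
        r1, r2 = n1 / phi, n2 / phi
        return nbinom.pmf(a, r1, r1 / (r1 + n1 * mu)) * nbinom.pmf(
            total - a, r2, r2 / (r2 + n2 * mu)
        )

    p_obs = prob(z1)
    num = sum(prob(a) for a in range(total + 1) if prob(a) <= p_obs * (1 + 1e-8))
    den = sum(prob(a) for a in range(total + 1))
    return min(num / den, 1.0)


class TestNbExactTest:
    def test_balanced_split_gives_p_one(self):
        for phi in (0.0, 0.1, 0.7):
            assert _exact_nb_pvalue(15, 15, 4, 4, phi) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_small_totals(self):
        for phi in (0.0, 0.1, 0.5):
            for total in (1, 5, 12, 30):
                for z1 in range(0, total + 1, max(1, total // 5)):
                    p = _exact_nb_pvalue(z1, total - z1, 4, 4, phi)
                    assert p == pytest.approx(
                        _exact_oracle(z1, total - z1, 4, 4, phi), abs=1e-9
                    )

    def test_dataframe_interface_and_log2fc_sign(self):
        counts = _df([[10, 12, 9, 11, 50, 48, 52, 55], [20, 21, 19, 22, 21, 20, 22, 19]])
        lib = pd.Series(100.0, index=SAMPLES)
        res = nb_exact_test(counts, GROUPS, DispersionEstimate(0.01), library_sizes=lib)
        assert res.loc[0, "log2_fold_change"] > 1  # Chitin higher
        assert res.loc[0, "p_value"] < 0.01
        assert res.loc[1, "p_value"] > 0.5


class TestQuasiPoisson:
    def test_identical_groups_give_p_one(self):
        counts = _df([[7, 7, 7, 7, 7, 7, 7, 7]])
        res = quasi_poisson_test(counts, GROUPS)
        assert res.loc[0, "log2_fold_change"] == pytest.approx(0.0)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_rate_ratio_matches_closed_form(self):
        rng = np.random.default_rng(15)
        y = rng.poisson([20, 25, 18, 22, 40, 44, 39, 41])
        exposure = np.array([1.0, 1.2, 0.9, 1.1, 1.0, 1.3, 0.8, 1.0])
        counts = _df([y])
        offsets = pd.Series(np.log(exposure), index=SAMPLES)
        res = quasi_poisson_test(counts, GROUPS, offsets=offsets)
        e1, e2 = exposure[:4].sum(), exposure[4:].sum()
        ratio = (y[4:].sum() / e2) / (y[:4].sum() / e1)
        assert 2 ** res.loc[0, "log2_fold_change"] == pytest.approx(ratio, rel=1e-8)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm
        from scipy.stats import t as t_dist

        rng = np.random.default_rng(16)
        y = rng.negative_binomial(10, 10 / (10 + 30.0), size=8)
        counts = _df([y])
        res = quasi_poisson_test(counts, GROUPS)
        X = np.column_stack([np.ones(8), np.r_[np.zeros(4), np.ones(4)]])
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
        assert res.loc[0, "log2_fold_change"] * math.log(2) == pytest.approx(
            fit.params[1], rel=1e-6
        )
        t = fit.params[1] / fit.bse[1]
        assert res.loc[0, "p_value"] == pytest.approx(
            2 * t_dist.sf(abs(t), 6), rel=1e-6
        )

    def test_all_zero_feature_is_uninformative(self):
        counts = _df([[0] * 8])
        res = quasi_poisson_test(counts, GROUPS)
        assert res.loc[0, "p_value"] == 1.0


class TestBhAdjust:
    def test_hand_arithmetic(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_equal_p(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=50)
        fdr = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        for rank0, i in enumerate(order):
            tail = [
                m * p[order[j]] / (j + 1) for j in range(rank0, m)
            ]
            assert fdr[i] == pytest.approx(min(1.0, min(tail)))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(18)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestBrayCurtis:
    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [5, 5, 0], "b": [10, 10, 0]})
        d = bray_curtis(counts)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_supports(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 7]})
        assert bray_curtis(counts).loc["a", "b"] == pytest.approx(1.0)

    def test_matches_scipy_on_random_pairs(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(19)
        counts = pd.DataFrame(rng.integers(0, 100, size=(20, 5)))
        rel = counts / counts.sum(axis=0)
        d = bray_curtis(counts)
        for i, j in itertools.combinations(range(5), 2):
            assert d.iloc[i, j] == pytest.approx(
                braycurtis(rel.iloc[:, i], rel.iloc[:, j])
            )
        assert np.allclose(d, d.T)
        assert (np.diag(d) == 0).all()


def _permanova_f_oracle(d, labels):
    """Pseudo-F via explicit pair loops (independent of the implementation)."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            d[i][j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_between = ss_total - ss_within
    if ss_within == 0:
        return math.inf
    return (ss_between / (len(groups) - 1)) / (ss_within / (n - len(groups)))


class TestPermanova:
    @staticmethod
    def _random_dist(rng, n):
        x = rng.normal(size=(n, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        return d

    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(20)
        d = self._random_dist(rng, 8)
        labels = ["PS"] * 4 + ["Chitin"] * 4
        res = permanova(d, labels)
        assert res.exhaustive and res.n_permutations == 70
        f_obs = _permanova_f_oracle(d, labels)
        assert res.pseudo_f == pytest.approx(f_obs, rel=1e-12)
        count = 0
        for combo in itertools.combinations(range(8), 4):
            lab = ["PS" if i in combo else "Chitin" for i in range(8)]
            if _permanova_f_oracle(d, lab) >= f_obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / 70)

    def test_separated_clusters_minimal_p(self):
        # within-group distance 0, between-group distance 1
        d = np.ones((8, 8)) - np.eye(8)
        d[:4, :4] = 0
        d[4:, 4:] = 0
        np.fill_diagonal(d, 0)
        res = permanova(d, ["PS"] * 4 + ["Chitin"] * 4)
        assert res.p_value == pytest.approx(1 / 35)

    def test_pseudo_f_matches_scikit_bio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(21)
        d = self._random_dist(rng, 10)
        labels = ["a"] * 5 + ["b"] * 5
        mine = permanova(d, labels, n_perm=99, exhaustive_limit=10, seed=0)
        theirs = sk_permanova(
            DistanceMatrix(d, ids=[str(i) for i in range(10)]), labels, permutations=9
        )
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_singleton_group_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "b"])

    def test_sampled_mode_reproducible_and_bounded(self):
        rng = np.random.default_rng(22)
        d = self._random_dist(rng, 12)
        labels = ["a"] * 6 + ["b"] * 6
        r1 = permanova(d, labels, n_perm=199, exhaustive_limit=10, seed=5)
        r2 = permanova(d, labels, n_perm=199, exhaustive_limit=10, seed=5)
        assert not r1.exhaustive
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 200


class TestDispersionHomogeneity:
    def test_equal_spread_groups_not_flagged(self):
        rng = np.random.default_rng(23)
        x = np.vstack([rng.normal(0, 1, size=(6, 2)), rng.normal(5, 1, size=(6, 2))])
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        res = dispersion_homogeneity(d, ["a"] * 6 + ["b"] * 6, seed=1)
        assert res.p_value > 0.05

    def test_unequal_spread_flagged(self):
        rng = np.random.default_rng(24)
        x = np.vstack(
            [rng.normal(0, 0.01, size=(6, 2)), rng.normal(0, 5.0, size=(6, 2))]
        )
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        res = dispersion_homogeneity(d, ["a"] * 6 + ["b"] * 6, seed=2)
        assert res.p_value < 0.05

    def test_degenerate_equal_distances(self):
        d = np.ones((6, 6)) - np.eye(6)
        res = dispersion_homogeneity(d, ["a"] * 3 + ["b"] * 3, seed=3)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)
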