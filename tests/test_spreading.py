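"""Spreading statistics: distances to epicentres, beta-values, FC metrics,
association models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tauspread as tsp
from tauspread.exceptions import InvalidConfigError, RankDeficientError


def _dist_matrix(d, labels):
    return tsp.DistanceMatrix(regions=tuple(labels), d=np.asarray(d, dtype=float))


def _episet(regions, sid="s0"):
    return tsp.EpicentreSet(subject_id=sid, regions=list(regions),
                            scores=[1.0] * len(regions))


class TestDistanceToEpicentres:
    def test_single_epicentre_returns_row(self):
        d = [[0, 1, 2], [1, 0, 3], [2, 3, 0]]
        out = tsp.distance_to_epicentres(_dist_matrix(d, "abc"), _episet(["a"]))
        assert list(out.index) == ["b", "c"]
        assert out["b"] == 1 and out["c"] == 2

    def test_mean_over_two_epicentres(self):
        d = [[0, 4, 1, 3], [4, 0, 5, 3], [1, 5, 0, 2], [3, 3, 2, 0]]
        out = tsp.distance_to_epicentres(_dist_matrix(d, "abcd"), _episet(["a", "b"]))
        assert out["c"] == pytest.approx((1 + 5) / 2)
        assert out["d"] == pytest.approx(3.0)

    def test_min_aggregation_option(self):
        d = [[0, 4, 1], [4, 0, 5], [1, 5, 0]]
        out = tsp.distance_to_epicentres(_dist_matrix(d, "abc"), _episet(["a", "b"]),
                                         aggregate="min")
        assert out["c"] == 1.0

    def test_190_non_epicentre_regions_at_200_parcels(self):
        rng = np.random.default_rng(0)
        n = 200
        d = rng.uniform(1, 5, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"r{i}" for i in range(n)]
        out = tsp.distance_to_epicentres(_dist_matrix(d, labels),
                                         _episet(labels[:10]))
        assert len(out) == 190

    def test_empty_epicentre_set_rejected(self):
        with pytest.raises(InvalidConfigError):
            tsp.distance_to_epicentres(_dist_matrix([[0, 1], [1, 0]], "ab"),
                                       _episet([]))


class TestSubjectBeta:
    def test_perfect_negative_relation(self, rng):
        dist = pd.Series(rng.uniform(1, 4, 30), index=[f"r{i}" for i in range(30)])
        out = tsp.subject_beta(-dist, dist)
        assert out.beta == pytest.approx(-1.0)

    def test_equals_pearson_oracle(self, rng):
        labels = [f"r{i}" for i in range(190)]
        dist = pd.Series(rng.uniform(1, 4, 190), index=labels)
        rate = pd.Series(rng.normal(0, 0.02, 190), index=labels)
        out = tsp.subject_beta(rate, dist)
        r, p = stats.pearsonr(dist.to_numpy(), rate.to_numpy())
        assert out.beta == pytest.approx(r, abs=1e-12)
        assert out.p_value == pytest.approx(p, abs=1e-12)
        assert out.n_regions_used == 190

    def test_null_beta_small_at_190_regions(self, rng):
        labels = [f"r{i}" for i in range(190)]
        betas = []
        for _ in range(50):
            dist = pd.Series(rng.uniform(1, 4, 190), index=labels)
            rate = pd.Series(rng.normal(0, 0.02, 190), index=labels)
            betas.append(tsp.subject_beta(rate, dist).beta)
        assert np.percentile(np.abs(betas), 95) < 0.15

    def test_affine_invariance(self, rng):
        labels = [f"r{i}" for i in range(40)]
        dist = pd.Series(rng.uniform(1, 4, 40), index=labels)
        rate = pd.Series(rng.normal(0.02, 0.01, 40), index=labels)
        b0 = tsp.subject_beta(rate, dist).beta
        b1 = tsp.subject_beta(rate * 3 + 1, dist * 0.5 - 2).beta
        assert b1 == pytest.approx(b0, abs=1e-12)

    def test_zero_variance_flagged(self):
        labels = [f"r{i}" for i in range(12)]
        dist = pd.Series(np.ones(12), index=labels)
        rate = pd.Series(np.arange(12, dtype=float), index=labels)
        out = tsp.subject_beta(rate, dist)
        assert out.undefined and np.isnan(out.beta)


class TestGroupBetaMap:
    def test_planted_deterministic_relation(self, rng):
        labels = [f"r{i}" for i in range(5)]
        subs = [f"s{i}" for i in range(30)]
        dist = pd.DataFrame(rng.uniform(1, 4, (30, 5)), index=subs, columns=labels)
        rates = -dist
        out = tsp.group_beta_map(rates, dist)
        assert np.allclose(out["beta"], -1.0, atol=1e-10)

    def test_irrelevant_covariates_leave_estimates(self, rng):
        labels = [f"r{i}" for i in range(8)]
        subs = [f"s{i}" for i in range(200)]
        dist = pd.DataFrame(rng.uniform(1, 4, (200, 8)), index=subs, columns=labels)
        rates = -0.5 * dist + pd.DataFrame(rng.normal(0, 1, (200, 8)),
                                           index=subs, columns=labels)
        cov = pd.DataFrame(rng.normal(0, 1, (200, 2)), index=subs,
                           columns=["age", "edu"])
        adj = tsp.group_beta_map(rates, dist, covariates=cov)
        unadj = tsp.group_beta_map(rates, dist)
        assert np.allclose(adj["beta"], unadj["beta"], atol=0.02)

    def test_shuffled_subjects_null(self, rng):
        labels = [f"r{i}" for i in range(20)]
        subs = [f"s{i}" for i in range(100)]
        dist = pd.DataFrame(rng.uniform(1, 4, (100, 20)), index=subs, columns=labels)
        rates = pd.DataFrame(rng.normal(0, 1, (100, 20)), index=subs, columns=labels)
        out = tsp.group_beta_map(rates, dist)
        assert abs(out["beta"].mean()) < 0.03


class TestFCToEpicentres:
    def test_constant_matrix(self):
        z = np.full((4, 4), 0.3)
        np.fill_diagonal(z, 0)
        fc = tsp.ConnectivityMatrix(regions=tuple("abcd"), z=z)
        out = tsp.fc_to_epicentres(fc, _episet(["a"]))
        assert out.scalar == pytest.approx(0.3)
        assert np.allclose(out.per_region, 0.3)

    def test_worked_mean(self):
        z = np.zeros((4, 4))
        z[1, 0] = z[0, 1] = 0.2
        z[2, 0] = z[0, 2] = 0.4
        z[3, 0] = z[0, 3] = 0.6
        fc = tsp.ConnectivityMatrix(regions=tuple("abcd"), z=z)
        out = tsp.fc_to_epicentres(fc, _episet(["a"]))
        assert out.scalar == pytest.approx(0.4)

    def test_scalar_is_mean_of_per_region(self, small_cohort):
        sid = small_cohort.cohort["subject_id"].iloc[0]
        e = _episet(small_cohort.truth.true_epicentres[sid], sid)
        out = tsp.fc_to_epicentres(small_cohort.fc[sid], e)
        assert out.scalar == pytest.approx(out.per_region.mean())
        assert len(out.per_region) == small_cohort.atlas.n_regions - len(e.regions)


class TestAssociationModel:
    def test_deterministic_standardized_slope(self, rng):
        x = pd.Series(rng.normal(0, 1, 50))
        table = tsp.association_model(2 * x, x)
        est = table.set_index("term")["estimate"]
        assert est["x"] == pytest.approx(1.0)

    def test_interaction_recovery(self, rng):
        n = 500
        x = rng.normal(0, 1, n)
        g = (rng.random(n) < 0.5).astype(float)
        y = 0.3 * x + 0.2 * g + 0.5 * x * g + rng.normal(0, 0.1, n)
        table = tsp.association_model(pd.Series(y), pd.Series(x),
                                      moderator=pd.Series(g))
        est = table.set_index("term")["estimate"]
        # y was standardized; rescale the interaction back to raw units
        scale = np.std(y)
        assert est["x:moderator"] * scale == pytest.approx(0.5, abs=0.05)

    def test_null_interaction_calibrated(self, rng):
        hits = 0
        for _ in range(200):
            n = 500
            x = rng.normal(0, 1, n)
            g = (rng.random(n) < 0.5).astype(float)
            y = 0.3 * x + rng.normal(0, 0.1, n)
            table = tsp.association_model(pd.Series(y), pd.Series(x),
                                          moderator=pd.Series(g))
            est = table.set_index("term")["estimate"]
            if abs(est["x:moderator"]) < 0.1:
                hits += 1
        assert hits >= 0.90 * 200

    def test_rank_deficient_design_reports_aliased(self, rng):
        x = pd.Series(rng.normal(0, 1, 40))
        cov = pd.DataFrame({"dup": x})
        with pytest.raises(RankDeficientError):
            tsp.association_model(x * 2, x, covariates=cov)

    def test_too_small_sample_rejected(self, rng):
        x = pd.Series(rng.normal(0, 1, 4))
        cov = pd.DataFrame({c: rng.normal(0, 1, 4) for c in "abc"})
        with pytest.raises(InvalidConfigError):
            tsp.association_model(x, x * 2, covariates=cov)
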