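"""Severity, HPDI, hierarchical slope models and related statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dendropy

from megadecline.bayes import MCMCConfig, hpdi
from megadecline.decline import (HierarchicalSlopeModel, SeverityModel,
                                 decline_severity, fit_phylo_slope_model,
                                 fit_severity_model, genus_subset, phylo_vcv,
                                 spearman_ne_time)
from megadecline.simulate import simulate_species
from megadecline.trajectories import NeTrajectory, SpeciesTraits
from tests.conftest import make_linear_cohort

FAST = MCMCConfig(warmup=500, draws=500, posterior_samples=500)


def _traj(seed, n=15):
    rng = np.random.default_rng(seed)
    b = np.concatenate([[0.0], np.sort(rng.uniform(1e3, 1e6, n))])
    return NeTrajectory(f"G{seed:02d}_sp", b, rng.uniform(100, 1e5, n))


class TestSeverity:
    def test_constant_trajectory_zero(self):
        tr = NeTrajectory("A_b", [0, 1e3, 1e4], [500.0, 500.0])
        assert decline_severity(tr).severity == 0.0

    def test_direct_ratio(self):
        tr = NeTrajectory("A_b", [0, 1e3, 1e4], [1000.0, 100.0])
        rec = decline_severity(tr)
        assert rec.severity == pytest.approx(0.9)
        assert rec.t_min_yr > rec.t_max_yr  # min is in the older window here

    @given(st.integers(0, 300))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_and_scale_invariance(self, seed):
        tr = _traj(seed)
        rec = decline_severity(tr)
        assert rec.ne_min == tr.ne.min()
        assert rec.ne_max == tr.ne.max()
        assert rec.severity == pytest.approx(1 - tr.ne.min() / tr.ne.max())
        scaled = decline_severity(tr.scaled(7.3))
        assert scaled.severity == pytest.approx(rec.severity, rel=1e-12)


class TestHPDI:
    def test_uniform_grid_width(self):
        draws = np.arange(1.0, 101.0)
        lo, hi = hpdi(draws, 0.95)
        assert hi - lo == 94.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            draws = rng.gamma(3.0, 1.0, size=500)
            lo, hi = hpdi(draws, 0.9)
            x = np.sort(draws)
            k = int(np.ceil(0.9 * len(x)))
            widths = [(x[i + k - 1] - x[i], x[i], x[i + k - 1])
                      for i in range(len(x) - k + 1)]
            w, blo, bhi = min(widths)
            assert (lo, hi) == (blo, bhi)

    def test_degenerate_all_equal(self):
        lo, hi = hpdi(np.full(200, 3.14), 0.95)
        assert lo == hi == 3.14

    def test_prob_domain(self):
        with pytest.raises(ValueError):
            hpdi(np.arange(100.0), 1.5)


class TestSlopeModel:
    def test_recovers_mass_effect_single_fit(self):
        trajs, traits, truth = make_linear_cohort(40, -0.1, 0.1, seed=7)
        res = HierarchicalSlopeModel(trajs, traits).fit(config=FAST, seed=1)
        lo, hi = res.beta_hpdi
        assert lo < -0.1 < hi
        # per-species slope medians track the generating slopes
        tab = res.species_table().set_index("species_id")
        gen = truth.set_index("species_id")["true_post_slope"]
        err = (tab["slope_median"] - gen.loc[tab.index]).abs()
        assert err.median() < 0.03

    def test_constant_mass_unidentifiable(self):
        trajs, traits, _ = make_linear_cohort(5, 0.0, 0.1, seed=2)
        flat = [SpeciesTraits(**{**t.__dict__, "mass_kg": 100.0}) for t in traits]
        with pytest.raises(ValueError, match="unidentifiable"):
            HierarchicalSlopeModel(trajs, flat)

    def test_needs_three_species(self):
        trajs, traits, _ = make_linear_cohort(4, 0.0, 0.1, seed=2)
        with pytest.raises(ValueError):
            HierarchicalSlopeModel(trajs[:2], traits[:2])


class TestSeverityRegression:
    def _records(self, n, seed, driver="t_min"):
        rng = np.random.default_rng(seed)
        traits, _ = simulate_species(n, seed=seed)
        recs = []
        from megadecline.decline import SeverityRecord

        t_min = rng.uniform(1e3, 4e4, n)
        t_max = rng.uniform(2e5, 1e6, n)
        z = (t_min - t_min.mean()) / t_min.std()
        eta = -1.5 * z + 1.0 if driver == "t_min" else np.full(n, 1.0)
        sev = 1.0 / (1.0 + np.exp(-eta))
        for i, t in enumerate(traits):
            recs.append(SeverityRecord(t.species_id, 1.0, 1.0 / (1 - sev[i]),
                                       sev[i], t_min[i], t_max[i]))
        return recs, traits

    def test_recovers_generating_driver(self):
        recs, traits = self._records(60, 1, driver="t_min")
        res = fit_severity_model(recs, traits, seed=0)
        assert res.importance.iloc[0]["predictor"] == "t_min_yr"
        lo, hi = res.coef_hpdi("t_min_yr")
        assert hi < 0  # generated with a negative t_min coefficient

    def test_noiseless_dominant_predictor_r2(self):
        recs, traits = self._records(40, 2, driver="t_min")
        res = fit_severity_model(recs, traits, seed=0)
        assert res.r_squared > 0.999

    def test_shuffled_predictors_mostly_null(self):
        # severities drawn independently of all predictors: per-coefficient
        # HPDI exclusion of zero stays at the alpha level
        rng = np.random.default_rng(0)
        excl = tot = 0
        for rep in range(30):
            recs, traits = self._records(40, 100 + rep, driver="t_min")
            sev = rng.permutation([r.severity for r in recs])
            shuffled = [r.__class__(r.species_id, r.ne_min, r.ne_max, s,
                                    r.t_min_yr, r.t_max_yr)
                        for r, s in zip(recs, sev)]
            res = fit_severity_model(shuffled, traits, seed=rep)
            for name in ("log10_mass", "t_min_yr", "t_max_yr"):
                lo, hi = res.coef_hpdi(name)
                tot += 1
                excl += (hi < 0 or lo > 0)
        assert excl / tot <= 0.10

    def test_winsorises_boundary_severity(self):
        from megadecline.decline import SeverityRecord

        traits, _ = simulate_species(4, seed=0)
        recs = [SeverityRecord(t.species_id, 0.0, 1.0, s, 1e4, 1e5)
                for t, s in zip(traits, [0.0, 0.5, 0.7, 0.9])]
        with pytest.warns(UserWarning, match="winsorised"):
            res = fit_severity_model(recs, traits, seed=0)
        assert np.isfinite(res.coef_draws).all()


class TestGenusSubset:
    def _traits(self, ids):
        return [SpeciesTraits(species_id=s, mass_kg=100, gen_time_yr=10,
                              mu=1e-8, realm="Palearctic") for s in ids]

    def test_one_per_genus_and_idempotent(self):
        traits = self._traits(["Loxodonta_africana", "Loxodonta_cyclotis",
                               "Bison_bison", "Elephas_maximus"])
        sub = genus_subset(traits)
        assert len(sub) == 3
        assert genus_subset(sub) == sub

    def test_all_distinct_genera_identity(self):
        traits = self._traits(["A_x", "B_y", "C_z"])
        assert sorted(t.species_id for t in genus_subset(traits)) == \
            ["A_x", "B_y", "C_z"]

    def test_window_count_breaks_ties(self):
        traits = self._traits(["Bos_taurus", "Bos_gaurus"])
        b = [0, 1e3, 1e4, 1e5]
        trajs = [NeTrajectory("Bos_taurus", b[:3], [1.0, 2.0]),
                 NeTrajectory("Bos_gaurus", b, [1.0, 2.0, 3.0])]
        sub = genus_subset(traits, trajs)
        assert sub[0].species_id == "Bos_gaurus"

    def test_count_matches_unique_genera(self):
        rng = np.random.default_rng(0)
        ids = [f"Genus{rng.integers(0, 12):02d}_sp{i}" for i in range(40)]
        traits = self._traits(ids)
        assert len(genus_subset(traits)) == len({i.split("_")[0] for i in ids})

    def test_unparseable_id_raises(self):
        with pytest.raises(ValueError, match="nogenus"):
            genus_subset(self._traits(["nogenus"]))


class TestPhylo:
    def _star_tree(self, ids, depth=1.0):
        nwk = "(" + ",".join(f"{i}:{depth}" for i in ids) + ");"
        return dendropy.Tree.get(data=nwk, schema="newick")

    def test_star_phylogeny_vcv_is_identity(self):
        ids = ["A_a", "B_b", "C_c"]
        C = phylo_vcv(self._star_tree(ids), ids)
        np.testing.assert_allclose(C, np.eye(3), atol=1e-12)

    def test_vcv_shared_branches(self):
        tree = dendropy.Tree.get(data="((A_a:1,B_b:1):1,C_c:2);",
                                 schema="newick")
        C = phylo_vcv(tree, ["A_a", "B_b", "C_c"])
        assert C[0, 1] == pytest.approx(0.5)   # half their depth is shared
        assert C[0, 2] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_lambda_zero_reduces_to_independent_fit(self):
        trajs, traits, _ = make_linear_cohort(8, -0.1, 0.1, seed=4)
        ids = [t.species_id for t in traits]
        tree = self._star_tree(ids)
        res_indep = HierarchicalSlopeModel(trajs, traits).fit(config=FAST, seed=3)
        res_lam0 = fit_phylo_slope_model(trajs, traits, tree, mcmc=FAST,
                                         seed=3, lam_fixed=0.0)
        np.testing.assert_allclose(res_lam0.beta_draws, res_indep.beta_draws)

    def test_star_tree_posterior_close_to_independent(self):
        trajs, traits, _ = make_linear_cohort(10, -0.1, 0.1, seed=9)
        ids = [t.species_id for t in traits]
        res_p = fit_phylo_slope_model(trajs, traits, self._star_tree(ids),
                                      mcmc=FAST, seed=5)
        res_i = HierarchicalSlopeModel(trajs, traits).fit(config=FAST, seed=5)
        lo_p, hi_p = res_p.beta_hpdi
        lo_i, hi_i = res_i.beta_hpdi
        # same data, zero shared branches: intervals overlap substantially
        assert max(lo_p, lo_i) < min(hi_p, hi_i)
        assert abs(np.median(res_p.beta_draws)
                   - np.median(res_i.beta_draws)) < 0.02

    def test_missing_species_excluded_with_warning(self):
        trajs, traits, _ = make_linear_cohort(6, -0.1, 0.1, seed=10)
        ids = [t.species_id for t in traits]
        tree = self._star_tree(ids[:-1])
        with pytest.warns(UserWarning, match="absent"):
            res = fit_phylo_slope_model(trajs, traits, tree, mcmc=FAST, seed=1)
        assert ids[-1] not in res.species_ids

    def test_zero_depth_tree_raises(self):
        ids = ["A_a", "B_b", "C_c"]
        tree = self._star_tree(ids, depth=0.0)
        with pytest.raises(ValueError, match="zero"):
            phylo_vcv(tree, ids)


class TestSpearman:
    def test_monotone_and_antimonotone(self):
        b = np.concatenate([[0.0], np.geomspace(1e3, 1e6, 10)])
        up = NeTrajectory("A_a", b, np.linspace(100, 1000, 10))
        rho, _ = spearman_ne_time([up])
        assert rho == pytest.approx(1.0)
        down = NeTrajectory("A_a", b, np.linspace(1000, 100, 10))
        rho, _ = spearman_ne_time([down])
        assert rho == pytest.approx(-1.0)

    def test_independent_data_small_rho(self):
        rng = np.random.default_rng(0)
        rhos = []
        b = np.concatenate([[0.0], np.geomspace(1e3, 1e6, 50)])
        for _ in range(50):
            tr = NeTrajectory("A_a", b, rng.uniform(1e3, 1e4, 50))
            rhos.append(spearman_ne_time([tr])[0])
        assert abs(np.mean(rhos)) < 0.05

    def test_too_few_points(self):
        tr = NeTrajectory("A_a", [0, 1, 2], [10.0, 20.0])
        with pytest.raises(ValueError):
            spearman_ne_time([tr])
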