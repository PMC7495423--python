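"""Niche GLMs, suitability hindcasting, spread automaton and refugia detection."""

import numpy as np
import pytest
import statsmodels.api as sm

from phylolegacy.grid import SiteGrid
from phylolegacy.io import CommunityMatrix
from phylolegacy.refugia import (NicheModel, _fit_with_access, derive_seed,
                                 deterministic_spread_many, detect_refugia,
                                 distance_to_refugia, fit_niche_glm,
                                 hindcast_suitability, kissmig_spread,
                                 lgm_candidates, mean_range_size,
                                 migration_budget)
from phylolegacy.synthetic import standard_scenario, generate_scenario

from conftest import make_stack


def grid(n=9, cell=50.0, mask=None):
    m = np.ones((n, n), bool) if mask is None else mask
    return SiteGrid(m.shape[1], m.shape[0], cell, m)


def bfs_budgeted(S, origin_yx, m):
    """Independent oracle: per-interval m-step reachability with extinction.

    Each interval t allows m expansion steps through cells habitable in
    that interval; occupancy outside the habitable set dies.
    """
    n_int, n_y, n_x = S.shape
    occ = {origin_yx}
    for t in range(n_int):
        for _ in range(m):
            nxt = set()
            for (y, x) in occ:
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < n_y and 0 <= xx < n_x and S[t, yy, xx]:
                            nxt.add((yy, xx))
            occ = nxt
            if not occ:
                return occ
    return occ


class TestNicheGlm:
    def test_prevalence_weights_balance_masses(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(10), np.zeros(30)]
        clim = rng.normal(size=(40, 2))
        model = fit_niche_glm(y, clim, ["t", "p"])
        w = model.weights
        assert w[y > 0].sum() == pytest.approx(w[y == 0].sum(), abs=1e-9)
        assert w.sum() == pytest.approx(40.0)

    def test_null_signal_low_d2(self):
        rng = np.random.default_rng(1)
        y = (rng.random(400) < 0.3).astype(float)
        clim = rng.normal(size=(400, 2))
        model = fit_niche_glm(y, clim, ["t", "p"])
        assert model.d2 < 0.05

    def test_coefficients_match_statsmodels_irls(self):
        """Independent oracle: statsmodels GLM with the same weights/terms."""
        rng = np.random.default_rng(2)
        n = 200
        t = rng.normal(10, 3, n)
        p = rng.normal(800, 100, n)
        eta = -1 + 0.8 * (t - 10) - 0.15 * (t - 10) ** 2 + 0.003 * (p - 800)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        clim = np.column_stack([t, p])
        model = fit_niche_glm(y, clim, ["t", "p"])
        assert model.converged and model.ridge_used == 0.0

        raw = np.column_stack([t, t**2, p, p**2])
        Z = (raw - model.col_means) / model.col_sds
        X = sm.add_constant(Z)
        ref = sm.GLM(y, X, family=sm.families.Binomial(),
                     var_weights=model.weights).fit()
        np.testing.assert_allclose(model.coef, ref.params, atol=1e-6)
        d2_ref = 1 - ref.deviance / ref.null_deviance
        assert model.d2 == pytest.approx(d2_ref, abs=1e-6)

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            fit_niche_glm(np.ones(10), np.zeros((10, 1)), ["t"])


class TestHindcast:
    def _zero_model(self):
        return NicheModel(variables=["t"], coef=np.zeros(3),
                          col_means=np.zeros(2), col_sds=np.ones(2),
                          d2=0.0, weights=np.ones(4))

    def test_zero_coefficients_give_half_and_no_candidates(self):
        g = grid(3)
        stack = make_stack(g, {"t": np.random.default_rng(0).normal(size=(3, 3, 3))})
        h = hindcast_suitability(self._zero_model(), stack)
        assert np.allclose(h[:, g.mask], 0.5)
        # strict > 0.5: a flat 0.5 map yields zero LGM candidate origins
        assert len(lgm_candidates(h, g)) == 0

    def test_constant_climate_constant_suitability(self):
        g = grid(3)
        stack = make_stack(g, {"t": np.full((4, 3, 3), 7.0)})
        rng = np.random.default_rng(3)
        model = NicheModel(variables=["t"], coef=rng.normal(size=3),
                           col_means=np.array([7.0, 49.0]),
                           col_sds=np.array([1.0, 1.0]), d2=0.5,
                           weights=np.ones(9))
        h = hindcast_suitability(model, stack)
        assert np.allclose(h[0][g.mask], h[-1][g.mask])

    def test_linear_predictor_arithmetic(self):
        model = NicheModel(variables=["t"], coef=np.array([0.5, 1.0, -2.0]),
                           col_means=np.array([10.0, 100.0]),
                           col_sds=np.array([2.0, 50.0]), d2=0.5,
                           weights=np.ones(1))
        val = np.array([[12.0]])
        # eta = 0.5 + 1*(12-10)/2 - 2*(144-100)/50
        eta = 0.5 + 1.0 - 2.0 * 44 / 50
        assert model.linear_predictor(val)[0] == pytest.approx(eta, abs=1e-12)
        assert model.suitability(val)[0] == pytest.approx(
            1 / (1 + np.exp(-eta)), abs=1e-12)


class TestSpread:
    def test_unconstrained_spread_is_chebyshev_ball(self):
        g = grid(9)
        suit = np.ones((3, 9, 9))  # 2 intervals
        origin = g.cell_id(4, 4)
        reached = kissmig_spread(suit, g, origin, m=1)
        iy, ix = np.mgrid[0:9, 0:9]
        ball = np.maximum(abs(iy - 4), abs(ix - 4)) <= 2
        assert np.array_equal(reached, ball)

    def test_zero_suitability_outside_origin(self):
        g = grid(5)
        suit = np.zeros((4, 5, 5))
        suit[:, 2, 2] = 1.0
        reached = kissmig_spread(suit, g, g.cell_id(2, 2), m=3)
        assert reached.sum() == 1 and reached[2, 2]

    def test_single_slice_keeps_persistent_origin_only(self):
        g = grid(5)
        suit = np.ones((1, 5, 5))
        reached = kissmig_spread(suit, g, g.cell_id(1, 3), m=2)
        assert reached.sum() == 1 and reached[3, 1]

    def test_matches_bfs_on_random_corridors(self):
        rng = np.random.default_rng(7)
        for rep in range(15):
            g = grid(8)
            n_int = int(rng.integers(2, 5))
            S = rng.random((n_int, 8, 8)) < 0.55
            oy, ox = 4, 4
            S[:, oy, ox] = True
            m = int(rng.integers(1, 4))
            suit = np.where(S, 0.9, 0.1)  # 0.81 > 0.5 > 0.01
            stack = np.concatenate([suit, suit[-1:]], axis=0)
            reached = kissmig_spread(stack, g, g.cell_id(ox, oy), m=m)
            exp = bfs_budgeted(S, (oy, ox), m)
            got = {(y, x) for y, x in zip(*np.nonzero(reached))}
            assert got == exp

    def test_monotone_in_m(self):
        rng = np.random.default_rng(8)
        g = grid(8)
        suit = np.where(rng.random((5, 8, 8)) < 0.6, 0.95, 0.0)
        suit[:, 4, 4] = 0.95
        prev = None
        for m in range(1, 6):
            r = kissmig_spread(suit, g, g.cell_id(4, 4), m=m)
            if prev is not None:
                assert not (prev & ~r).any()  # reached(m) subset reached(m+1)
            prev = r

    def test_stochastic_mode_reduces_to_ball_at_h1(self):
        g = grid(7)
        suit = np.ones((3, 7, 7))
        r = kissmig_spread(suit, g, g.cell_id(3, 3), m=1, mode="stochastic",
                           n_reps=5, seed=1)
        iy, ix = np.mgrid[0:7, 0:7]
        assert np.array_equal(r, np.maximum(abs(iy - 3), abs(ix - 3)) <= 2)

    def test_stochastic_seeded_reproducible(self):
        rng = np.random.default_rng(9)
        g = grid(7)
        suit = np.clip(rng.random((4, 7, 7)), 0.3, 1.0)
        a = kissmig_spread(suit, g, g.cell_id(3, 3), m=2, mode="stochastic",
                           n_reps=10, seed=42)
        b = kissmig_spread(suit, g, g.cell_id(3, 3), m=2, mode="stochastic",
                           n_reps=10, seed=42)
        assert np.array_equal(a, b)

    def test_m_out_of_range(self):
        g = grid(5)
        with pytest.raises(ValueError):
            kissmig_spread(np.ones((2, 5, 5)), g, 0, m=11)


class TestMigrationBudget:
    def test_step_structure_arithmetic(self):
        b = migration_budget()
        assert b["iterations_min"] == 21
        assert b["iterations_max"] == 210
        assert b["rate_min_m_per_yr"] == pytest.approx(18.6)
        assert b["rate_max_m_per_yr"] == pytest.approx(186.0)


class TestDetectRefugia:
    def test_constant_accessibility_inestimable(self):
        rng = np.random.default_rng(1)
        y = (rng.random(50) < 0.5).astype(float)
        base_Z = rng.normal(size=(50, 2))
        w = np.ones(50)
        assert _fit_with_access(base_Z, y, w, np.ones(50)) is None

    def test_adding_access_never_decreases_d2(self):
        rng = np.random.default_rng(2)
        n = 300
        clim = rng.normal(size=(n, 2))
        eta = 0.5 * clim[:, 0] - 0.3 * clim[:, 1] ** 2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        model = fit_niche_glm(y, clim, ["t", "p"])
        raw = model.raw_terms(clim)
        Z = (raw - model.col_means) / model.col_sds
        access = (rng.random(n) < 0.4).astype(float)
        res = _fit_with_access(Z, y, model.weights, access)
        assert res is not None
        d2a, _ = res
        assert d2a >= model.d2 - 1e-9

    def test_recovers_true_refugium_small_scenario(self):
        cfg = standard_scenario(seed=5, n_x=14, n_y=14, n_species=8)
        cfg.refugia_per_species = 1
        cfg.refugia_hotspots = 0
        scen = generate_scenario(cfg)
        com, stack = scen.community, scen.climate
        hits = found = 0
        for j, sp in enumerate(com.species_ids):
            res = detect_refugia(sp, com.presence[:, j].astype(float), stack)
            if res.found:
                found += 1
                hits += bool(np.isin(scen.true_refugia[sp], res.retained).any())
        assert found >= 6
        assert hits / found >= 0.6

    def test_d2_with_access_exceeds_initial(self):
        cfg = standard_scenario(seed=3, n_x=12, n_y=12, n_species=6)
        scen = generate_scenario(cfg)
        com, stack = scen.community, scen.climate
        for j, sp in enumerate(com.species_ids[:3]):
            res = detect_refugia(sp, com.presence[:, j].astype(float), stack)
            if res.found:
                assert (res.d2_access > res.d2_initial).all()


class TestDriverSurfaces:
    def _community(self, g, presence, species):
        ids = g.masked_ids[: presence.shape[0]]
        return CommunityMatrix(site_ids=ids, coords=g.coords[ids],
                               species_ids=species, presence=presence)

    def test_cell_that_is_its_species_refugium(self):
        g = grid(3)
        com = self._community(g, np.array([[1]] + [[0]] * 8, bool), ["s1"])
        d = distance_to_refugia({"s1": np.array([0])}, com, g)
        assert d[0] == 0.0

    def test_mean_of_two_species_distances(self):
        g = SiteGrid(9, 1, 50.0, np.ones((1, 9), bool))
        pres = np.zeros((9, 2), bool)
        pres[0] = True  # both species present at cell 0
        com = self._community(g, pres, ["s1", "s2"])
        # refugia 2 cells (100 km) and 6 cells (300 km) east of cell 0
        d = distance_to_refugia({"s1": np.array([2]), "s2": np.array([6])},
                                com, g)
        assert d[0] == pytest.approx(200.0)

    def test_species_without_refugia_excluded(self):
        g = grid(3)
        pres = np.ones((9, 2), bool)
        com = self._community(g, pres, ["s1", "s2"])
        d_all = distance_to_refugia({"s1": np.array([4]),
                                     "s2": np.array([0])}, com, g)
        d_one = distance_to_refugia({"s1": np.array([4])}, com, g)
        exp = np.linalg.norm(g.coords - g.coords[4], axis=1)
        np.testing.assert_allclose(d_one, exp)
        assert not np.allclose(d_all, d_one)

    def test_matches_bruteforce_random_scenario(self):
        rng = np.random.default_rng(11)
        g = grid(6)
        pres = rng.random((36, 5)) < 0.5
        pres[0] = True
        com = self._community(g, pres, [f"s{i}" for i in range(5)])
        refs = {f"s{i}": rng.choice(36, size=2, replace=False)
                for i in range(5)}
        d = distance_to_refugia(refs, com, g)
        for c in range(36):
            sp_here = [f"s{i}" for i in range(5) if pres[c, i]]
            if not sp_here:
                assert np.isnan(d[c])
                continue
            exp = np.mean([min(np.linalg.norm(g.coords[c] - g.coords[r])
                               for r in refs[s]) for s in sp_here])
            assert d[c] == pytest.approx(exp, abs=1e-9)

    def test_range_size_cosmopolitan(self):
        g = grid(4)
        pres = np.ones((16, 1), bool)
        com = self._community(g, pres, ["s1"])
        np.testing.assert_allclose(mean_range_size(com), 16.0)

    def test_range_size_mean_of_two(self):
        g = SiteGrid(30, 2, 50.0, np.ones((2, 30), bool))
        pres = np.zeros((60, 2), bool)
        pres[:10, 0] = True
        pres[:30, 1] = True
        com = self._community(g, pres, ["s1", "s2"])
        rs = mean_range_size(com)
        assert rs[0] == pytest.approx(20.0)  # mean of {10, 30}
        assert rs[15] == pytest.approx(30.0)
        assert np.isnan(rs[45])


class TestDeriveSeed:
    def test_stable_and_bounded(self):
        assert derive_seed(1, "a") == derive_seed(1, "a")
        assert derive_seed(1, "a") != derive_seed(1, "b")
        assert 0 <= derive_seed(123456789, "x", 9) < 2**31
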