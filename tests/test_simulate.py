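"""Synthetic landscape and community generator: determinism, planted
statistical structure, and calibration checks."""

import numpy as np
import pytest

from structura import simulate as sim
from structura.canopy import canopy_rugosity
from structura.diversity import diversity, mdi
from structura.grids import aggregate, compute_chm
from structura.pipeline import spearman
from structura.terrain import terrain_rugosity


def params(**kw):
    defaults = dict(seed=42, extent=64)
    defaults.update(kw)
    return sim.LandscapeParams(**defaults)


class TestTerrainGenerator:
    def test_zero_sigma_constant(self):
        dtm = sim.make_terrain(params(sigma_t=0.0))
        assert np.ptp(dtm.values) == 0.0
        assert terrain_rugosity(dtm.values.ravel() + np.array([0, 1e-12] * 2048)) < 1e-6

    def test_deterministic(self):
        a = sim.make_terrain(params())
        b = sim.make_terrain(params())
        np.testing.assert_array_equal(a.values, b.values)

    def test_seed_changes_field(self):
        a = sim.make_terrain(params(seed=1))
        b = sim.make_terrain(params(seed=2))
        assert not np.array_equal(a.values, b.values)

    def test_realized_sd_matches_target(self):
        sds = [sim.make_terrain(params(seed=s, sigma_t=7.5)).values.std() for s in range(20)]
        assert np.all(np.abs(np.array(sds) - 7.5) / 7.5 < 0.1)

    def test_invalid_extent_rejected(self):
        with pytest.raises(ValueError):
            sim.LandscapeParams(seed=1, extent=0)


class TestCanopyGenerator:
    def test_flat_canopy_degenerate(self):
        p = params(sigma_t=0.0, sigma_h=0.0, gap_frac=0.0, mu_h=18.0)
        dtm = sim.make_terrain(p)
        dsm = sim.make_canopy(dtm, p)
        chm = compute_chm(dsm, dtm)
        assert np.ptp(chm.values) == 0.0
        assert canopy_rugosity(aggregate(chm, 1.0)) == 0.0

    def test_gap_fraction_recovered(self):
        p = params(extent=100, gap_frac=0.3, mu_h=20.0, sigma_h=1.0)
        dtm = sim.make_terrain(p)
        chm = compute_chm(sim.make_canopy(dtm, p), dtm)
        dgf = np.mean(chm.values == 0)
        assert dgf == pytest.approx(0.3, abs=0.02)

    def test_cr_increases_with_sigma_h(self):
        crs = []
        for sh in (0.5, 1.0, 2.0, 4.0):
            vals = []
            for s in range(10):
                p = params(seed=s, sigma_h=sh, gap_frac=0.0, mu_h=20.0)
                dtm = sim.make_terrain(p)
                chm = compute_chm(sim.make_canopy(dtm, p), dtm)
                vals.append(canopy_rugosity(aggregate(chm, 1.0)))
            crs.append(np.mean(vals))
        assert all(a < b for a, b in zip(crs, crs[1:]))


class TestCommunityGenerator:
    def test_deterministic(self):
        cp = sim.CommunityParams(seed=3)
        c1 = sim.make_communities(np.array([1.0, 2.0, 3.0, 4.0]), cp)
        c2 = sim.make_communities(np.array([1.0, 2.0, 3.0, 4.0]), cp)
        assert c1.equals(c2)

    def test_geometric_shannon_monotone_in_evenness(self):
        hs = [sim.geometric_shannon(100, k) for k in (0.8, 0.9, 0.95, 0.99)]
        assert all(a < b for a, b in zip(hs, hs[1:]))

    def test_effect_orders_diversity(self):
        complexity = np.linspace(0, 5, 8)
        cp = sim.CommunityParams(seed=9, beta_c=2.0)
        counts = sim.make_communities(complexity, cp)
        d = diversity(counts)
        h = d[d["trophic_level"] == "plant"].set_index("site")["shannon"]
        assert spearman(complexity, h.to_numpy())[0] > 0.9

    def test_null_has_no_systematic_order(self):
        complexity = np.linspace(0, 5, 20)
        rhos = []
        for s in range(40):
            counts = sim.make_communities(complexity, sim.CommunityParams(seed=s, beta_c=0.0))
            d = diversity(counts)
            m = mdi(d, ["plant", "beetle", "bird"]).set_index("site")
            sites = [f"S{i + 1:02d}" for i in range(20)]
            rhos.append(spearman(complexity, m.loc[sites, "mdi"].to_numpy())[0])
        assert abs(np.mean(rhos)) < 0.1

    def test_group_shift_changes_composition_not_diversity(self):
        complexity = np.array([1.0, 2.0, 3.0, 4.0])
        groups = np.array(["x", "x", "y", "y"])
        cp0 = sim.CommunityParams(seed=5, group_shift=0.0)
        cp1 = sim.CommunityParams(seed=5, group_shift=0.4)
        c0 = sim.make_communities(complexity, cp0, groups=groups)
        c1 = sim.make_communities(complexity, cp1, groups=groups)
        d0 = diversity(c0).set_index(["site", "trophic_level"])["shannon"]
        d1 = diversity(c1).set_index(["site", "trophic_level"])["shannon"]
        np.testing.assert_allclose(d0.to_numpy(), d1.to_numpy())
        # but the taxon identities differ between groups under the shift
        tax_x = set(c1[(c1["site"] == "S01") & (c1["trophic_level"] == "plant")]["taxon"])
        tax_y = set(c1[(c1["site"] == "S03") & (c1["trophic_level"] == "plant")]["taxon"])
        overlap = len(tax_x & tax_y) / max(len(tax_x), 1)
        assert overlap < 0.9

    def test_depth_floor_enforced(self):
        with pytest.raises(ValueError):
            sim.CommunityParams(seed=1, depths={"plant": 10, "beetle": 600, "bird": 900})


class TestSimulateSites:
    def test_end_to_end_shapes_and_determinism(self):
        r1 = sim.simulate_sites(n_sites=6, seed=3, extent=48)
        r2 = sim.simulate_sites(n_sites=6, seed=3, extent=48)
        assert len(r1.sites) == 6
        assert set(r1.metrics.columns) >= {"cr", "tr", "q95", "ruc", "roc"}
        assert r1.counts.equals(r2.counts)
        np.testing.assert_array_equal(
            r1.landscapes["S01"][0].values, r2.landscapes["S01"][0].values
        )

    def test_planted_effect_visible(self):
        res = sim.simulate_sites(n_sites=20, seed=11, extent=48, beta_c=1.0)
        d = diversity(res.counts)
        m = mdi(d, ["plant", "beetle", "bird"]).set_index("site")
        rho, p = spearman(res.metrics["ruc"], m.loc[res.metrics["site"], "mdi"])
        assert rho > 0.8 and p < 0.001
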