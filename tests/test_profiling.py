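"""Band profiles, normalization, geometry series, space-time maps."""

import numpy as np
import pandas as pd
import pytest

from cupmap import mesh as mm
from cupmap import profiling as prof
from cupmap import synth


@pytest.fixture(scope="module")
def cap_domain(unit_icosphere4):
    mesh = unit_icosphere4
    th = np.arccos(np.clip(mesh.vertices[:, 2], -1, 1))
    domain = mm.VertexRegion(mesh, np.flatnonzero(th <= 1.0))
    return mesh, domain, th


class TestBandPartition:
    def test_every_domain_vertex_in_exactly_one_band(self, cap_domain):
        mesh, domain, _ = cap_domain
        bands = prof.band_partition(mesh, domain, depth=1.0)
        inside = bands.band[domain.indices]
        assert (inside >= 0).all() and (inside < prof.N_INSIDE_BANDS).all()

    def test_band_areas_match_zonal_closed_forms(self, cap_domain):
        # inside bands at 0.1 x depth spacing on a unit-sphere cap are
        # zones; zone area = 2 pi (cos(a) - cos(b)).  Depth is measured in
        # the same graph metric as the banding distance so the systematic
        # shortest-path stretch cancels.
        mesh = mm.icosphere(1.0, 5)
        th = np.arccos(np.clip(mesh.vertices[:, 2], -1, 1))
        domain = mm.VertexRegion(mesh, np.flatnonzero(th <= 1.0))
        bands = prof.band_partition(mesh, domain)
        va = mesh.vertex_areas()
        cap = 1.0
        cum_got = 0.0
        for k in range(prof.N_INSIDE_BANDS - 1):
            cum_got += va[bands.inside_indices(k)].sum()
            edge = cap - 0.1 * (k + 1) * cap
            cum_exp = 2 * np.pi * (np.cos(edge) - np.cos(cap))
            assert cum_got == pytest.approx(cum_exp, rel=0.05)

    def test_outside_bands_step_at_point_two_um(self, cap_domain):
        mesh, domain, th = cap_domain
        bands = prof.band_partition(mesh, domain, depth=1.0,
                                    max_outside=1.0)
        assert bands.n_outside == 5
        sel = bands.outside_indices(0)
        assert len(sel) and (th[sel] > 1.0 - 0.05).all()

    def test_shared_outside_vertices_claimed_by_nearer_domain(
            self, unit_icosphere4):
        mesh = unit_icosphere4
        th = np.arccos(np.clip(mesh.vertices[:, 2], -1, 1))
        d1 = mm.VertexRegion(mesh, np.flatnonzero(th < 0.5))
        d2 = mm.VertexRegion(mesh, np.flatnonzero(th > np.pi - 0.5))
        claims = prof.claim_masks(mesh, [d1, d2])
        north = th < np.pi / 2 - 0.1
        south = th > np.pi / 2 + 0.1
        assert claims[0][north & ~d1.mask()].all()
        assert not claims[0][south].any()
        b1 = prof.band_partition(mesh, d1, depth=0.5, claimed=claims[0])
        outside1 = np.concatenate([b1.outside_indices(k)
                                   for k in range(b1.n_outside)])
        # equidistant (equatorial) vertices go to the lower-index domain
        assert (th[outside1] <= np.pi / 2 + 1e-9).all()

    def test_zero_depth_single_band_warns(self, cap_domain):
        mesh, domain, _ = cap_domain
        with pytest.warns(UserWarning, match="single inside band"):
            bands = prof.band_partition(mesh, domain, depth=0.0)
        assert (bands.band[domain.indices] == 0).all()


class TestBandProfile:
    def test_constant_intensity_gives_constant_profile(self, cap_domain):
        mesh, domain, _ = cap_domain
        bands = prof.band_partition(mesh, domain, depth=1.0)
        p = prof.band_profile(bands, np.full(mesh.n_vertices, 3.5))
        assert np.allclose(p.inside_mean, 3.5)
        assert np.allclose(p.outside_mean[np.isfinite(p.outside_mean)], 3.5)

    def test_linear_field_reproduces_band_midpoints(self, cap_domain):
        # a field linear in the banding distance averages to the band
        # midpoints up to discretisation
        mesh, domain, th = cap_domain
        bands = prof.band_partition(mesh, domain, depth=1.0)
        d = 0.5 * (mm.geodesic_distance(mesh, mm.boundary_vertices(domain))
                   + mm.geodesic_distance(
                       mesh, mm.outside_boundary_vertices(domain)))
        p = prof.band_profile(bands, d)
        mid = (np.arange(10) + 0.5) * 0.1
        ok = np.isfinite(p.inside_mean)
        assert np.allclose(p.inside_mean[ok], mid[ok], atol=0.05)

    def test_masked_vertices_excluded(self, cap_domain):
        mesh, domain, _ = cap_domain
        bands = prof.band_partition(mesh, domain, depth=1.0)
        x = np.full(mesh.n_vertices, 2.0)
        poison = domain.indices[::2]
        x[poison] = 1e6
        mask = np.ones(mesh.n_vertices, bool)
        mask[poison] = False
        p = prof.band_profile(bands, x, mask=mask)
        assert np.allclose(p.inside_mean[np.isfinite(p.inside_mean)], 2.0)


class TestNormalization:
    def _profiles(self, values):
        return [prof.BandProfile(
            inside_centers=np.linspace(0.05, 0.95, 10),
            inside_mean=np.full(10, v),
            outside_centers=(np.arange(25) + 0.5) * 0.2,
            outside_mean=np.full(25, b)) for v, b in values]

    def test_constant_field_normalizes_to_one(self):
        ps, bg = prof.normalize_profile(self._profiles([(5.0, 5.0)] * 3))
        assert bg == 5.0
        assert np.allclose(ps[0].inside_mean, 1.0)

    def test_scale_invariance(self):
        p1, _ = prof.normalize_profile(self._profiles([(6.0, 2.0),
                                                       (8.0, 2.0)]))
        p2, _ = prof.normalize_profile(self._profiles([(12.0, 4.0),
                                                       (16.0, 4.0)]))
        assert np.allclose(p1[0].inside_mean, p2[0].inside_mean)

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            prof.normalize_profile(self._profiles([(5.0, 0.0)]))

    def test_programmed_gradient_recovered(self, projected_cup):
        # 3:1 base-to-lip PIP3 gradient painted by the generator: the
        # fold-normalised inside profile must rise toward the domain centre
        # with (fold-1) ratio ~ 3 within 10%
        mesh = projected_cup["mesh"]
        scene = projected_cup["scene"]
        lab = np.flatnonzero(mesh.scalars["label"] > 0)
        domain = mm.VertexRegion(mesh, lab)
        depth = mm.region_depth(domain)
        bands = prof.band_partition(mesh, domain, depth)
        p = prof.band_profile(bands, projected_cup["pip3"])
        normed, bg = prof.normalize_profile([p])
        inside = normed[0].inside_mean
        ratio = (inside[-1] - 1.0) / (inside[0] - 1.0)
        # the painted gradient evaluated at the band centres (0.05 and 0.95
        # of depth from the boundary): lip*(1 + (g-1)*f)
        g = scene.cups[0].pip3_gradient
        expected = (1 + (g - 1) * 0.95) / (1 + (g - 1) * 0.05)
        assert ratio == pytest.approx(expected, rel=0.10)


class TestAggregation:
    def test_identical_domains_zero_se(self):
        p = prof.BandProfile(np.linspace(0.05, 0.95, 10), np.full(10, 2.0),
                             (np.arange(5) + 0.5) * 0.2, np.full(5, 1.0))
        df = prof.aggregate_profiles([p, p, p])
        assert (df["se"].dropna() == 0).all()
        assert (df["n"] == 3).all()

    def test_single_domain_se_missing(self):
        p = prof.BandProfile(np.linspace(0.05, 0.95, 10), np.full(10, 2.0),
                             (np.arange(5) + 0.5) * 0.2, np.full(5, 1.0))
        df = prof.aggregate_profiles([p])
        assert df["se"].isna().all()

    def test_cohort_mean_within_two_se(self):
        rng = np.random.default_rng(0)
        ps = [prof.BandProfile(np.linspace(0.05, 0.95, 10),
                               2.0 + 0.2 * rng.standard_normal(10),
                               (np.arange(5) + 0.5) * 0.2,
                               np.ones(5)) for _ in range(40)]
        df = prof.aggregate_profiles(ps)
        ins = df[df["kind"] == "inside"]
        assert (np.abs(ins["mean"] - 2.0) <= 2.5 * ins["se"]).all()


class TestDomainGeometry:
    def test_cap_geometry_closed_forms(self, unit_icosphere4):
        mesh = unit_icosphere4
        th = np.arccos(np.clip(mesh.vertices[:, 2], -1, 1))
        rng = np.random.default_rng(11)
        for cap in rng.uniform(0.7, 1.2, 4):
            domain = mm.VertexRegion(mesh, np.flatnonzero(th <= cap))
            area, perim, depth = prof.domain_geometry(mesh, domain)
            assert area == pytest.approx(2 * np.pi * (1 - np.cos(cap)),
                                         rel=0.05)
            assert perim == pytest.approx(2 * np.pi * np.sin(cap), rel=0.05)
            assert depth == pytest.approx(cap, rel=0.05)

    def test_area_additive_over_split_halves(self, unit_icosphere4):
        mesh = unit_icosphere4
        th = np.arccos(np.clip(mesh.vertices[:, 2], -1, 1))
        full = mm.VertexRegion(mesh, np.flatnonzero(th <= 1.0))
        right = mm.VertexRegion(
            mesh, full.indices[mesh.vertices[full.indices, 0] >= 0])
        left = mm.VertexRegion(
            mesh, full.indices[mesh.vertices[full.indices, 0] < 0])
        assert mm.region_area(right) + mm.region_area(left) == \
            pytest.approx(mm.region_area(full), rel=1e-9)


class TestExpansionRate:
    def test_exact_linear_slope(self):
        t = np.arange(0, 28, 2.5)
        a = 1.2 + 0.42 * t
        assert prof.expansion_rate(t, a) == pytest.approx(0.42, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 30, 12))
        a = 2 + 0.3 * t + rng.normal(0, 0.3, 12)
        slope = prof.expansion_rate(t, a)
        X = np.column_stack([t, np.ones_like(t)])
        beta = np.linalg.solve(X.T @ X, X.T @ a)
        assert slope == pytest.approx(beta[0], rel=1e-9)

    def test_too_few_points_gives_nan(self):
        assert np.isnan(prof.expansion_rate([0, 40], [1, 2]))

    def test_cohort_recovery_from_generator(self):
        df = synth.make_domain_timeseries(
            n_domains=60, rate_mean=0.35, rate_sd=0.16,
            lifetime_range=(60.0, 130.0), stall_fraction=0.6, dt=2.5,
            seed=9)
        slopes = df.groupby("track").apply(
            lambda g: prof.expansion_rate(g["t"].to_numpy(),
                                          g["area"].to_numpy()),
            include_groups=False).dropna()
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert slopes.mean() == pytest.approx(0.35, abs=2 * se + 0.01)


class TestDoubleNormalize:
    def test_time_rescaled_copy_identical(self):
        t1 = np.linspace(0, 50, 21)
        base = {"track": 0, "t": t1, "area": 1 + 0.2 * t1,
                "perimeter": np.sqrt(1 + t1), "depth": 0.1 * t1}
        fast = {"track": 1, "t": t1 * 0.4, "area": base["area"],
                "perimeter": base["perimeter"], "depth": base["depth"]}
        df = pd.concat([pd.DataFrame(base), pd.DataFrame(fast)])
        per_track, _ = prof.double_normalize(df)
        a0 = per_track[per_track["track"] == 0]["area"].to_numpy()
        a1 = per_track[per_track["track"] == 1]["area"].to_numpy()
        assert np.allclose(a0, a1, rtol=1e-12)

    def test_programmed_stall_flattens_curve(self):
        df = synth.make_domain_timeseries(
            n_domains=40, rate_mean=0.35, rate_sd=0.16, stall_fraction=0.6,
            dt=2.5, seed=21)
        _, summary = prof.double_normalize(df, variables=("area",))
        late = summary[summary["s"] >= 0.65]
        slope = np.polyfit(late["s"], late["area_mean"], 1)[0]
        assert abs(slope) < 0.05

    def test_constant_tracks_normalize_to_quartile_ratio(self):
        t = np.linspace(0, 10, 5)
        df = pd.concat([
            pd.DataFrame({"track": i, "t": t, "area": np.full(5, v)})
            for i, v in enumerate([2.0, 4.0])])
        out, _ = prof.double_normalize(df, variables=("area",))
        q75 = np.percentile([2.0] * 20 + [4.0] * 20, 75)
        assert np.allclose(sorted(out["area"].unique()),
                           [2.0 / q75, 4.0 / q75])

    def test_short_tracks_excluded_with_warning(self):
        df = pd.DataFrame({"track": [0, 1, 1, 1], "t": [0.0, 0, 5, 10],
                           "area": [1.0, 1, 2, 3]})
        with pytest.warns(UserWarning, match="excluded"):
            per_track, _ = prof.double_normalize(df, variables=("area",))
        assert set(per_track["track"]) == {1}


class TestSpaceTimeMap:
    @staticmethod
    def _prof(values_inside, value_outside=1.0):
        return prof.BandProfile(np.linspace(0.05, 0.95, 10),
                                np.asarray(values_inside, dtype=float),
                                (np.arange(5) + 0.5) * 0.2,
                                np.full(5, value_outside))

    def test_constant_track_gives_uniform_map(self):
        plist = [(t, self._prof(np.ones(10))) for t in
                 np.arange(-80.0, 5.0, 2.5)]
        m = prof.spacetime_map({0: plist}, {0: 0.0}, window=60.0)
        assert m.n_tracks == 1
        assert np.allclose(m.grid, 1.0)

    def test_interpolation_matches_hand_computed(self):
        # irregular frame spacing, one band: grid values must equal the
        # brute-force linear interpolation
        times = np.array([-63.0, -61.0, -58.7, -45.0, -20.2, -1.0, 0.5])
        vals = np.array([0.2, 1.0, 3.0, 2.0, 5.0, 1.5, 0.7])
        plist = [(t, self._prof(np.full(10, v)))
                 for t, v in zip(times, vals)]
        m = prof.spacetime_map({0: plist}, {0: 0.0}, window=60.0)
        expected = np.interp(m.times, times, vals)
        assert np.allclose(m.grid[-1], expected)

    def test_incomplete_window_tracks_dropped(self):
        short = [(t, self._prof(np.ones(10))) for t in
                 np.arange(-30.0, 0.1, 2.5)]
        with pytest.warns(UserWarning, match="window"):
            m = prof.spacetime_map({0: short}, {0: 0.0}, window=60.0)
        assert m.n_tracks == 0

    def test_programmed_preclosure_signal_recovered(self):
        # an intensity burst 20 s before closure in the lip band must show
        # up at the -20 s column of the map
        rng = np.random.default_rng(2)
        tracks, closures = {}, {}
        for k in range(6):
            times = np.arange(-70.0, 2.0, 2.5) + rng.uniform(-1, 1)
            plist = []
            for t in times:
                inside = np.ones(10)
                inside[0] += 3.0 * np.exp(-(t + 20.0) ** 2 / (2 * 4.0 ** 2))
                plist.append((t, self._prof(inside)))
            tracks[k] = plist
            closures[k] = 0.0
        m = prof.spacetime_map(tracks, closures, window=60.0)
        lip_row = m.grid[5]          # first inside band, after 5 outside
        t_peak = m.times[np.argmax(lip_row)]
        assert abs(t_peak + 20.0) <= 2.5
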