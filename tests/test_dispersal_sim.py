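"""Dispersal protocol: spawning gate, release kernels, RK4 advection,
temperature-triggered mortality and settlement classification."""

import datetime

import numpy as np
import pytest

from seaconn.dispersal_sim import (COMPLETED, DispersalConfig, ParticleState,
                                   ReleaseSite, _advect_cohort, advect_particle,
                                   classify_arrival, draw_release_states,
                                   haversine_km, rk4_step, run_simulation,
                                   spawning_days)
from seaconn.field_model import METERS_PER_DEGREE
from seaconn.synthetic_data import solid_body_field

from conftest import make_constant_field

SITE = ReleaseSite("AAA", 18.0, 40.0)


def cfg(**kw):
    base = dict(particles_per_day=50, years=(2005,), seed=0)
    base.update(kw)
    return DispersalConfig(**base)


def particle(lon=18.0, lat=40.0, pld=1.0, depth=1.0):
    return ParticleState(lon=lon, lat=lat, depth=depth, birth_site="AAA",
                         birth_time=datetime.date(2005, 1, 1), pld=pld)


class TestSpawningGate:
    def test_cold_field_all_122_days(self, still_field_year):
        days = spawning_days(still_field_year, SITE, 2005, cfg())
        assert len(days) == 122
        assert days[0] == datetime.date(2005, 4, 1)
        assert days[-1] == datetime.date(2005, 7, 31)

    def test_warm_field_no_days(self, warm_field_year):
        assert spawning_days(warm_field_year, SITE, 2005, cfg()) == []

    def test_threshold_crossing_on_june_1(self, still_field_year):
        """Gate opens Apr 1 - May 31 (61 days) when 18 degC is crossed June 1."""
        f = still_field_year
        cross = (datetime.date(2005, 6, 1) - f.grid.time_origin).days
        f.temperature[cross:, :, :, :] = 19.0
        days = spawning_days(f, SITE, 2005, cfg())
        assert len(days) == 61
        assert days[-1] == datetime.date(2005, 5, 31)

    def test_site_outside_domain_rejected(self, still_field_year):
        from seaconn.field_model import OutOfDomainError
        with pytest.raises(OutOfDomainError):
            spawning_days(still_field_year, ReleaseSite("X", 30.0, 40.0),
                          2005, cfg())


class TestRelease:
    def test_cohort_size_is_particles_per_day(self, still_field):
        states = draw_release_states(still_field, SITE,
                                     datetime.date(2005, 1, 2), cfg(),
                                     np.random.default_rng(0))
        assert len(states) == 50
        assert all(s.survival_weight == 1.0 for s in states)
        assert all(0.5 <= s.depth <= 10.0 for s in states)

    def test_zero_sigma_collapses_to_site(self, still_field):
        states = draw_release_states(still_field, SITE,
                                     datetime.date(2005, 1, 2),
                                     cfg(release_sigma_km=0.0),
                                     np.random.default_rng(0))
        assert all(s.lon == SITE.lon and s.lat == SITE.lat for s in states)

    def test_pld_mean_matches_target(self, still_field):
        states = draw_release_states(
            still_field, SITE, datetime.date(2005, 1, 2),
            cfg(particles_per_day=100_000), np.random.default_rng(12))
        plds = np.array([s.pld for s in states])
        assert plds.mean() == pytest.approx(30.0, abs=0.05)
        assert plds.min() >= 1.0 and plds.max() <= 60.0

    def test_missing_rng_rejected(self, still_field):
        with pytest.raises(ValueError):
            draw_release_states(still_field, SITE, datetime.date(2005, 1, 2),
                                cfg(), None)


class TestRK4:
    def test_zero_field_no_motion(self, still_field):
        st = particle()
        out = rk4_step(still_field, st, 0.5, 360.0)
        assert (out.lon, out.lat) == (st.lon, st.lat)

    def test_uniform_current_one_day_displacement(self):
        """0.1 m/s eastward for 1 day of 6-min steps = 8.640 km."""
        f = make_constant_field(u=0.1)
        st = particle(lon=17.5, pld=1.0)
        out = advect_particle(f, st, cfg(dt_minutes=6.0))
        km = (out.lon - 17.5) * METERS_PER_DEGREE * np.cos(np.deg2rad(out.lat)) / 1e3
        assert km == pytest.approx(8.640, abs=1e-6)

    def test_solid_body_period_closure(self):
        omega = 2 * np.pi / 10
        f = solid_body_field(omega, (18.0, 40.0), radius_km=50, n_days=12,
                             time_origin=datetime.date(2005, 1, 1))
        r_km = 20.0
        lon0 = 18.0 + r_km * 1e3 / (METERS_PER_DEGREE * np.cos(np.deg2rad(40.0)))
        st = particle(lon=lon0, pld=10.0)
        out = advect_particle(f, st, cfg(dt_minutes=6.0))
        err_km = haversine_km(out.lon, out.lat, lon0, 40.0)
        assert out.status == COMPLETED
        assert err_km < 1e-3 * r_km

    def test_fourth_order_convergence(self):
        """Trajectory error scales as dt^4 on the rigid-rotation oracle.

        The error is measured against a fine-step (0.75 min) reference so
        the truncation term is isolated from the (dt-independent)
        spherical-metric floor of the analytic circle.
        """
        omega = 2 * np.pi / 0.5  # half-day period
        f = solid_body_field(omega, (18.0, 40.0), radius_km=40, n_days=3,
                             time_origin=datetime.date(2005, 1, 1))
        lon0 = 18.0 + 15e3 / (METERS_PER_DEGREE * np.cos(np.deg2rad(40.0)))

        def final(dt):
            out = advect_particle(f, particle(lon=lon0, pld=0.5),
                                  cfg(dt_minutes=dt))
            return out.lon, out.lat

        ref = final(0.75)
        dts = [24.0, 12.0, 6.0, 3.0]
        errs = [haversine_km(*final(dt), *ref) for dt in dts]
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert slope == pytest.approx(4.0, abs=0.3)

    def test_out_of_domain_marks_lost(self):
        f = make_constant_field(u=2.0, n_days=30)  # fast current exits domain
        st = particle(lon=18.95, pld=10.0)
        out = advect_particle(f, st, cfg(dt_minutes=30.0))
        assert out.status == "lost_domain"


class TestMortality:
    def test_cold_trajectory_keeps_full_weight(self, still_field):
        out = advect_particle(still_field, particle(pld=2.0), cfg(dt_minutes=30))
        assert out.survival_weight == pytest.approx(1.0)

    def test_one_warm_day_gives_5_percent(self):
        f = make_constant_field(temp=20.0)
        out = advect_particle(f, particle(pld=1.0), cfg(dt_minutes=6.0))
        assert out.survival_weight == pytest.approx(np.exp(-3.0), rel=1e-9)

    def test_half_warm_day(self):
        f = make_constant_field(temp=20.0)
        out = advect_particle(f, particle(pld=0.5), cfg(dt_minutes=6.0))
        assert out.survival_weight == pytest.approx(np.exp(-1.5), rel=1e-9)

    def test_weight_equals_exponential_of_time_above(self):
        """Step-wise decay accumulates to exp(-mu * time above threshold)."""
        f = make_constant_field(temp=16.0, n_days=10)
        f.temperature[3:5, :, :, :] = 21.0  # two warm days
        _, _, w, _, t_above = _advect_cohort(
            f, [18.0], [40.0], [1.0], [6.0], 0.0, cfg(dt_minutes=6.0))
        assert w[0] == pytest.approx(np.exp(-3.0 * t_above[0]), rel=1e-9)
        assert t_above[0] > 0

    def test_bernoulli_mode_matches_expectation(self):
        f = make_constant_field(temp=20.0)
        lon = [18.0] * 4000
        _, _, w, _, _ = _advect_cohort(
            f, lon, [40.0] * 4000, [1.0] * 4000, [1.0] * 4000, 0.0,
            cfg(dt_minutes=30.0, bernoulli_mortality=True),
            np.random.default_rng(0))
        assert w.mean() == pytest.approx(np.exp(-3.0), abs=0.02)


class TestArrival:
    sites = [ReleaseSite("BBB", 18.0, 40.0), ReleaseSite("AAA", 18.0, 40.0625)]

    def test_exact_site_position(self):
        st = particle(lon=18.0, lat=40.0)
        st.status = COMPLETED
        assert classify_arrival(st, self.sites, cfg()) == "BBB"

    def test_beyond_radius_is_none(self):
        lat = 40.0 + 5.001 / 111.0  # ~5.001 km north of BBB, ~1 km from AAA? no
        st = particle(lon=17.0, lat=39.0)  # far from both
        st.status = COMPLETED
        assert classify_arrival(st, self.sites, cfg()) is None

    def test_equidistant_tie_alphabetical(self):
        # midpoint between the two sites (~3 km from each)
        st = particle(lon=18.0, lat=40.03125)
        st.status = COMPLETED
        d_a = haversine_km(st.lon, st.lat, 18.0, 40.0625)
        d_b = haversine_km(st.lon, st.lat, 18.0, 40.0)
        assert d_a == pytest.approx(d_b, abs=1e-6)
        assert classify_arrival(st, self.sites, cfg()) == "AAA"


class TestRunSimulation:
    def quick_cfg(self, **kw):
        base = dict(particles_per_day=20, spawn_start=(4, 1), spawn_end=(4, 5),
                    pld_mean=4, pld_sd=1, pld_bounds=(1, 8), dt_minutes=30.0,
                    years=(2005,), seed=3)
        base.update(kw)
        return DispersalConfig(**base)

    def test_closed_system_full_retention(self, still_field_year):
        flux = run_simulation(still_field_year, [SITE], self.quick_cfg())
        rel = flux.releases.iloc[0]
        arrived = flux.records[flux.records["destination"] == "AAA"]
        assert rel["released_actual"] == 20 * 5
        assert arrived["weight"].sum() == pytest.approx(rel["released_actual"])

    def test_deterministic_given_seed(self, still_field_year):
        a = run_simulation(still_field_year, [SITE], self.quick_cfg())
        b = run_simulation(still_field_year, [SITE], self.quick_cfg())
        assert a.records.equals(b.records)
        assert a.releases.equals(b.releases)

    def test_empty_site_list_rejected(self, still_field_year):
        with pytest.raises(ValueError):
            run_simulation(still_field_year, [], self.quick_cfg())

    def test_mass_bound(self):
        """Summed arrival weights never exceed the released count."""
        omega = 2 * np.pi / 6
        f = solid_body_field(omega, (18.0, 40.0), radius_km=60, n_days=180,
                             time_origin=datetime.date(2005, 1, 1))
        sites = [SITE, ReleaseSite("BBB", 18.2, 40.1)]
        flux = run_simulation(f, sites, self.quick_cfg())
        for _, rel in flux.releases.iterrows():
            w = flux.records[
                (flux.records["origin"] == rel["origin"])
                & (flux.records["year"] == rel["year"])
                & (flux.records["destination"] != "-")]["weight"].sum()
            assert w <= rel["released_actual"] + 1e-9

    def test_raising_threshold_never_decreases_connectivity(self):
        f = make_constant_field(temp=16.0, n_days=365)
        warm_start = (datetime.date(2005, 5, 1) - f.grid.time_origin).days
        f.temperature[warm_start:warm_start + 30, :, :, :] = 19.0
        base = self.quick_cfg(spawn_end=(5, 10))
        hot = run_simulation(f, [SITE], base)
        f2 = make_constant_field(temp=16.0, n_days=365)
        f2.temperature[warm_start:warm_start + 30, :, :, :] = 19.0
        no_kill = run_simulation(
            f2, [SITE], self.quick_cfg(spawn_end=(5, 10), mortality_temp=1e9))
        w_hot = hot.records[hot.records["destination"] == "AAA"]["weight"].sum()
        w_cool = no_kill.records[
            no_kill.records["destination"] == "AAA"]["weight"].sum()
        assert w_cool >= w_hot - 1e-12
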