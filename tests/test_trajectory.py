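import json

import numpy as np
import pytest

import aeroloft as al


@pytest.fixture(scope="module")
def organelle():
    return al.preset("bacterial_organelle")


@pytest.fixture(scope="module")
def virus():
    return al.preset("h1n1_virus")


@pytest.fixture(scope="module")
def dust():
    return al.preset("standard_dust")


class TestIntegrateQuasiSteady:
    def test_constant_seven_m_s_equivalent_climb(self, organelle, profile):
        """A wind set 7 m/s above threshold under frozen density and constant
        gravity yields exactly 7 m/s quasi-steady ascent: 8.4 km in 20 min."""
        gravity = al.GravityModel(mode="constant")
        rho = 5.604e-7
        w = al.threshold_velocity(organelle, rho, gravity.g0) + 7.0
        episodes = [al.WindEpisode(w=w, duration=1200.0, rho_override=rho)]
        traj = al.integrate(
            organelle, episodes, profile, gravity, z0=100e3, mode="quasi_steady"
        )
        assert traj.climb == pytest.approx(8400.0, rel=1e-9)
        assert traj.stop_reason == "completed"

    def test_sub_threshold_wind_descends_monotonically(self, organelle, profile, gravity):
        episodes = [al.WindEpisode(w=5.0, duration=300.0)]
        traj = al.integrate(
            organelle, episodes, profile, gravity, z0=100e3, mode="quasi_steady"
        )
        assert np.all(np.diff(traj.altitudes) < 0)

    def test_row_velocities_are_steady_states(self, organelle, profile, gravity):
        episodes = [al.WindEpisode(w=50.0, duration=120.0)]
        traj = al.integrate(
            organelle, episodes, profile, gravity, z0=100e3, mode="quasi_steady"
        )
        for z, v, w, rho in zip(
            traj.altitudes, traj.velocities, traj.winds, traj.densities
        ):
            expected = al.steady_state_velocity(
                organelle, rho, al.gravity_at(gravity, z), w
            )
            assert v == pytest.approx(expected, rel=1e-9)


class TestIntegrateFullOde:
    def test_virus_arc_hour_climb(self, virus, profile, gravity):
        """Virus-sized disc at a frozen 9e-8 kg/m3 in a 50 m/s updraft climbs
        about 9 km in an hour."""
        episodes = [al.WindEpisode(w=50.0, duration=3600.0, rho_override=9e-8)]
        traj = al.integrate(
            virus, episodes, profile, gravity, z0=110e3, mode="full_ode"
        )
        assert traj.climb == pytest.approx(9000.0, rel=0.05)
        assert traj.stop_reason == "completed"

    def test_modes_agree_for_slow_forcing(self, organelle, profile, gravity):
        """Episodes lasting >> 100 relaxation times: the transient is
        negligible and both modes give the same final altitude to 1%."""
        episodes = [al.WindEpisode(w=50.0, duration=1200.0)]
        kwargs = dict(profile=profile, gravity=gravity, z0=100e3, dt=1.0)
        quasi = al.integrate(organelle, episodes, mode="quasi_steady", **kwargs)
        full = al.integrate(organelle, episodes, mode="full_ode", **kwargs)
        tau = al.relaxation_time(
            organelle, al.density_at(profile, 100e3), al.gravity_at(gravity, 100e3)
        )
        assert 1200.0 > 100 * tau
        assert full.climb == pytest.approx(quasi.climb, rel=0.01)

    @pytest.mark.parametrize("mode", ["quasi_steady", "full_ode"])
    def test_step_refinement_converged(self, virus, profile, gravity, mode):
        episodes = [al.WindEpisode(w=50.0, duration=1800.0, rho_override=9e-8)]
        kwargs = dict(profile=profile, gravity=gravity, z0=110e3)
        coarse = al.integrate(virus, episodes, dt=1.0, mode=mode, **kwargs)
        fine = al.integrate(virus, episodes, dt=0.5, mode=mode, **kwargs)
        assert abs(fine.altitudes[-1] - coarse.altitudes[-1]) < 1e-3 * abs(
            coarse.climb
        )


class TestBoundaryHandling:
    def test_descent_truncates_at_table_floor(self, organelle, profile, gravity):
        # sea-level terminal fall speed is ~2.5 cm/s, so start near the floor
        episodes = [al.WindEpisode(w=0.0, duration=3600.0)]
        traj = al.integrate(
            organelle, episodes, profile, gravity, z0=50.0, mode="quasi_steady"
        )
        lo, hi = profile.span
        assert traj.stop_reason == "below_table"
        assert traj.altitudes[-1] == pytest.approx(lo)
        assert np.all((traj.altitudes >= lo) & (traj.altitudes <= hi))

    def test_strong_updraft_truncates_at_table_top(self, dust, profile, gravity):
        episodes = [al.WindEpisode(w=400.0, duration=4e4)]
        traj = al.integrate(
            dust, episodes, profile, gravity, z0=150e3, dt=5.0, mode="quasi_steady"
        )
        assert traj.stop_reason == "above_table"
        assert traj.altitudes[-1] == profile.span[1]

    def test_bad_start_altitude_rejected(self, organelle, profile, gravity):
        with pytest.raises(ValueError, match="span"):
            al.integrate(
                organelle,
                [al.WindEpisode(w=10.0, duration=1.0)],
                profile,
                gravity,
                z0=300e3,
            )


class TestCeiling:
    def test_matches_brute_force_scan(self, virus, profile, gravity):
        result = al.ceiling_altitude(virus, 50.0, profile, gravity)
        assert result.status == "converged"
        # independent oracle: scan the column at 100 m steps for the first
        # altitude where the threshold velocity reaches the wind speed
        scan = None
        for z in np.arange(70e3, 200e3, 100.0):
            w_th = al.threshold_velocity(
                virus, al.density_at(profile, z), al.gravity_at(gravity, z)
            )
            if w_th >= 50.0:
                scan = z
                break
        assert scan is not None
        assert abs(result.altitude - scan) <= 100.0

    def test_virus_ceiling_in_lower_thermosphere(self, virus, profile, gravity):
        result = al.ceiling_altitude(virus, 50.0, profile, gravity)
        assert 105e3 < result.altitude < 125e3

    def test_stronger_wind_raises_ceiling(self, virus, profile, gravity):
        c50 = al.ceiling_altitude(virus, 50.0, profile, gravity)
        c60 = al.ceiling_altitude(virus, 60.0, profile, gravity)
        assert c60.altitude > c50.altitude

    def test_weak_wind_reports_no_ascent(self, organelle, profile, gravity):
        result = al.ceiling_altitude(organelle, 1.0, profile, gravity)
        assert result.status == "no_ascent"
        assert result.altitude is None

    def test_extreme_wind_reports_table_top(self, dust, profile, gravity):
        result = al.ceiling_altitude(dust, 500.0, profile, gravity)
        assert result.status == "above_table"
        assert result.altitude == profile.span[1]

    def test_particle_released_at_ceiling_hovers(self, virus, profile, gravity):
        result = al.ceiling_altitude(virus, 50.0, profile, gravity)
        episodes = [al.WindEpisode(w=50.0, duration=100.0)]
        traj = al.integrate(
            virus, episodes, profile, gravity, z0=result.altitude,
            mode="quasi_steady",
        )
        assert abs(traj.climb) < 1.0


class TestHorizontalExcursion:
    def test_twenty_minute_drift_within_correlation(self):
        result = al.horizontal_excursion(200.0, 1200.0)
        assert result.distance == pytest.approx(240e3)
        assert result.within_correlation

    def test_boundary_counts_as_within(self):
        result = al.horizontal_excursion(250.0, 1200.0)
        assert result.distance == pytest.approx(300e3)
        assert result.within_correlation

    def test_beyond_correlation_flagged(self):
        assert not al.horizontal_excursion(300.0, 1200.0).within_correlation

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            al.horizontal_excursion(200.0, 0.0)

    def test_calm_air_goes_nowhere(self):
        assert al.horizontal_excursion(0.0, 1200.0).distance == 0.0


class TestMeanAscentClimb:
    def test_average_speed_estimate(self):
        assert al.mean_ascent_climb(7.0, 1200.0) == pytest.approx(8400.0)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            al.mean_ascent_climb(7.0, 0.0)


class TestTrajectoryIo:
    def test_csv_and_sidecar_round_trip(self, organelle, profile, gravity, tmp_path):
        import pandas as pd

        episodes = [al.WindEpisode(w=50.0, duration=60.0)]
        traj = al.integrate(
            organelle, episodes, profile, gravity, z0=100e3, mode="quasi_steady"
        )
        csv_path = tmp_path / "traj.csv"
        meta_path = tmp_path / "traj.json"
        traj.to_csv(str(csv_path), sidecar=str(meta_path))
        df = pd.read_csv(csv_path)
        assert list(df.columns) == ["t_s", "z_m", "v_m_s", "w_m_s", "rho_kg_m3"]
        assert df["z_m"].to_numpy() == pytest.approx(traj.altitudes, rel=1e-9)
        meta = json.loads(meta_path.read_text())
        assert meta["mode"] == "quasi_steady"
        assert meta["particle"] == "bacterial_organelle"
        assert meta["stop_reason"] == "completed"
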