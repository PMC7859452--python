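"""Lamm forward models and the regularized species-distribution inversion."""

import numpy as np
import pytest

import scrdimer as sd
from scrdimer.auc import SpeciesDistribution, integrate_peaks, lsg_distribution
from scrdimer.hydro import diffusion_from_s_ff0
from scrdimer.sedimentation import (
    boundary_midpoints,
    default_run_geometry,
    faxen_boundary,
    lamm_fd,
    simulate_sv_run,
)

FF0 = 1.4


@pytest.fixture(scope="module")
def geometry():
    return default_run_geometry()


def _fit_s_from_midpoints(run):
    """Slope of ln r_mid vs w^2 t recovers s (in Svedberg)."""
    plateau = None
    # theoretical plateau: single species at unit load
    s_guess = None
    mids = boundary_midpoints(run)
    ok = np.isfinite(mids)
    slope = np.polyfit(run.omega2 * run.times[ok], np.log(mids[ok]), 1)[0]
    return slope / 1e-13


class TestForwardModels:
    @pytest.mark.parametrize("method", ["fd", "faxen"])
    def test_midpoint_exponential_law(self, geometry, method):
        """Boundary midpoint advances as r_m * exp(s w^2 t) to 1%."""
        s_true = 2.6
        d = diffusion_from_s_ff0(s_true, FF0)
        run = simulate_sv_run([(s_true, d, 1.0)], geometry, noise_level=0.0, method=method)
        assert _fit_s_from_midpoints(run) == pytest.approx(s_true, rel=0.01)

    def test_zero_time_gives_uniform_plateau(self, geometry):
        geo = sd.SedimentationRun(
            radii=geometry.radii, times=np.array([0.0, 600.0]),
            rotor_speed=geometry.rotor_speed,
            meniscus=geometry.meniscus, base=geometry.base,
        )
        run = simulate_sv_run([(2.6, 5e-7, 1.0)], geo, noise_level=0.0, method="faxen")
        np.testing.assert_allclose(run.signals[0], 1.0)

    def test_fd_matches_faxen_in_the_interior(self, geometry):
        """The two forward models agree away from meniscus and base."""
        s, d = 2.6, diffusion_from_s_ff0(2.6, FF0)
        fd = simulate_sv_run([(s, d, 1.0)], geometry, noise_level=0.0, method="fd")
        fx = simulate_sv_run([(s, d, 1.0)], geometry, noise_level=0.0, method="faxen")
        keep = (geometry.radii > 6.1) & (geometry.radii < 7.0)
        assert np.abs(fd.signals[:, keep] - fx.signals[:, keep]).max() < 0.04

    def test_fd_conserves_mass(self, geometry):
        run = simulate_sv_run([(2.6, 5e-7, 1.0)], geometry, noise_level=0.0, method="fd")
        r = geometry.radii
        m0 = np.trapezoid(np.ones_like(r) * r, r)
        m_end = np.trapezoid(run.signals[-1] * r, r)
        assert m_end == pytest.approx(m0, rel=1e-3)

    def test_fractions_must_sum_to_one(self, geometry):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_sv_run([(2.6, 5e-7, 0.5)], geometry)

    def test_unphysical_species_rejected(self, geometry):
        with pytest.raises(ValueError):
            simulate_sv_run([(-1.0, 5e-7, 1.0)], geometry)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError, match="meniscus"):
            sd.SedimentationRun(
                radii=np.linspace(6, 7.2, 50), times=np.array([0.0]),
                meniscus=7.5, base=7.2,
            )

    def test_deterministic_under_seed(self, geometry):
        a = simulate_sv_run([(2.6, 5e-7, 1.0)], geometry, noise_level=0.005, seed=9)
        b = simulate_sv_run([(2.6, 5e-7, 1.0)], geometry, noise_level=0.005, seed=9)
        np.testing.assert_array_equal(a.signals, b.signals)


class TestInversion:
    def test_single_species_recovery(self, geometry):
        d = diffusion_from_s_ff0(2.5, FF0)
        run = simulate_sv_run([(2.5, d, 1.0)], geometry, noise_level=0.005, seed=0)
        dist = lsg_distribution(run, s_grid=np.linspace(1.0, 6.0, 51), ff0=FF0)
        main = max(dist.peaks, key=lambda p: p.fraction)
        assert main.s_center == pytest.approx(2.5, rel=0.02)
        assert main.fraction == pytest.approx(1.0, abs=0.02)

    def test_two_species_60_40(self, geometry):
        """The observed 2.6 S / 3.6 S 60:40 scenario is resolved."""
        species = [
            (2.6, diffusion_from_s_ff0(2.6, FF0), 0.6),
            (3.6, diffusion_from_s_ff0(3.6, FF0), 0.4),
        ]
        run = simulate_sv_run(species, geometry, noise_level=0.005, seed=1)
        dist = lsg_distribution(run, s_grid=np.linspace(1.0, 6.0, 51), ff0=FF0)
        peaks = sorted(dist.peaks, key=lambda p: -p.fraction)[:2]
        peaks = sorted(peaks, key=lambda p: p.s_center)
        assert peaks[0].s_center == pytest.approx(2.6, abs=0.1)
        assert peaks[1].s_center == pytest.approx(3.6, abs=0.1)
        assert peaks[0].fraction == pytest.approx(0.6, abs=0.05)
        assert peaks[1].fraction == pytest.approx(0.4, abs=0.05)

    def test_all_zero_signal_rejected(self, geometry):
        run = sd.SedimentationRun(
            radii=geometry.radii, times=geometry.times,
            signals=np.zeros((geometry.times.size, geometry.radii.size)),
            meniscus=geometry.meniscus, base=geometry.base,
            rotor_speed=geometry.rotor_speed,
        )
        with pytest.raises(ValueError, match="signal"):
            lsg_distribution(run)

    def test_too_few_scans_rejected(self, geometry):
        geo = sd.SedimentationRun(
            radii=geometry.radii, times=geometry.times[:5],
            signals=np.ones((5, geometry.radii.size)),
            meniscus=geometry.meniscus, base=geometry.base,
            rotor_speed=geometry.rotor_speed,
        )
        with pytest.raises(ValueError, match="scans"):
            lsg_distribution(geo)

    def test_smoothing_never_adds_peaks(self, geometry):
        """Peak count is non-increasing in the regularization weight."""
        species = [
            (2.6, diffusion_from_s_ff0(2.6, FF0), 0.6),
            (3.6, diffusion_from_s_ff0(3.6, FF0), 0.4),
        ]
        run = simulate_sv_run(species, geometry, noise_level=0.005, seed=4)
        counts = []
        for alpha in (0.001, 0.01, 0.1, 1.0):
            dist = lsg_distribution(
                run, s_grid=np.linspace(1.0, 6.0, 51), alpha=alpha, ff0=FF0
            )
            counts.append(len(dist.peaks))
        assert counts == sorted(counts, reverse=True)


class TestPeakIntegration:
    def _make_dist(self, weights, s=None):
        s = np.linspace(1.0, 6.0, len(weights)) if s is None else s
        return SpeciesDistribution(
            s_grid=s, weights=np.asarray(weights, float), alpha=0.0
        )

    def test_unimodal_single_fraction(self):
        s = np.linspace(1.0, 6.0, 101)
        w = np.exp(-0.5 * ((s - 3.0) / 0.3) ** 2)
        peaks = integrate_peaks(self._make_dist(w, s))
        assert len(peaks) == 1
        assert peaks[0].fraction == pytest.approx(1.0)

    def test_bimodal_known_areas(self):
        """Two Gaussians with 0.8/0.2 areas integrate to 0.80/0.20."""
        s = np.linspace(1.0, 6.0, 501)
        w = 0.8 * np.exp(-0.5 * ((s - 2.5) / 0.15) ** 2) + 0.2 * np.exp(
            -0.5 * ((s - 4.5) / 0.15) ** 2
        )
        peaks = integrate_peaks(self._make_dist(w, s))
        assert len(peaks) == 2
        assert peaks[0].fraction == pytest.approx(0.8, abs=0.01)
        assert peaks[1].fraction == pytest.approx(0.2, abs=0.01)

    def test_fractions_sum_to_one(self):
        s = np.linspace(1.0, 6.0, 301)
        w = np.exp(-0.5 * ((s - 2.0) / 0.2) ** 2) + 0.7 * np.exp(
            -0.5 * ((s - 4.0) / 0.4) ** 2
        )
        peaks = integrate_peaks(self._make_dist(w, s))
        assert sum(p.fraction for p in peaks) == pytest.approx(1.0, abs=1e-9)

    def test_explicit_boundary_outside_grid_rejected(self):
        s = np.linspace(1.0, 6.0, 101)
        w = np.exp(-0.5 * ((s - 3.0) / 0.3) ** 2)
        with pytest.raises(ValueError, match="outside"):
            integrate_peaks(self._make_dist(w, s), boundaries=[9.0])
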