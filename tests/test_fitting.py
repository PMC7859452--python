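"""Debye forward model and R-factor ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import scrdimer as sd
from conftest import sphere_intensity


@pytest.fixture(scope="module")
def q_grid():
    return np.linspace(0.02, 3.0, 220)


class TestDebye:
    def test_forward_intensity_is_total_volume_squared(self, q_grid):
        n, vol = 7, 2.5
        centers = [[2.0 * k, 0.0, 0.0] for k in range(n)]
        m = sd.BeadModel(centers=centers, radii=[0.9] * n, volumes=[vol] * n)
        q = np.linspace(1e-4, 0.01, 20)
        c = sd.debye_intensity(m, q)
        assert c.intensity[0] == pytest.approx((n * vol) ** 2, rel=1e-6)

    def test_single_bead_equals_sphere_form_factor(self, q_grid):
        r = 2.0
        v = 4.0 / 3.0 * math.pi * r**3
        m = sd.BeadModel(centers=[[0, 0, 0]], radii=[r], volumes=[v])
        c = sd.debye_intensity(m, q_grid)
        expected = v**2 * sphere_intensity(q_grid, r)
        np.testing.assert_allclose(c.intensity, expected, rtol=1e-10)

    def test_low_q_rg_matches_parallel_axis(self):
        """Two touching unit beads: curve R_G = sqrt(0.6 + 1) nm."""
        m = sd.BeadModel(
            centers=[[0, 0, 0], [2, 0, 0]],
            radii=[1.0, 1.0],
            volumes=[4 * math.pi / 3] * 2,
        )
        q = np.linspace(0.005, 0.3, 80)
        fit = sd.guinier_fit(sd.debye_intensity(m, q), max_qrg=0.5)
        assert fit.rg == pytest.approx(math.sqrt(1.6), rel=1e-3)

    def test_dimer_vs_monomer_forward_ratio_is_four(self, two_domain_model, q_grid):
        dimer = sd.build_dimer_model(two_domain_model, "side_by_side_parallel")
        q = np.linspace(1e-4, 0.01, 5)
        i_m = sd.debye_intensity(two_domain_model, q).intensity[0]
        i_d = sd.debye_intensity(dimer, q).intensity[0]
        assert i_d / i_m == pytest.approx(4.0, rel=1e-6)


class TestRFactor:
    def test_identity_curve_scores_zero(self, sphere_curve):
        r, scale = sd.r_factor(sphere_curve, sphere_curve, fit_scale=False)
        assert r == pytest.approx(0.0, abs=1e-10)
        assert scale == 1.0

    def test_doubled_model_unscaled_scores_100(self, sphere_curve):
        model = sd.ScatteringCurve(sphere_curve.q, 2.0 * sphere_curve.intensity)
        r, _ = sd.r_factor(sphere_curve, model, fit_scale=False)
        assert r == pytest.approx(100.0, rel=1e-9)

    def test_scale_fit_removes_proportional_difference(self, sphere_curve):
        model = sd.ScatteringCurve(sphere_curve.q, 2.0 * sphere_curve.intensity)
        r, scale = sd.r_factor(sphere_curve, model, fit_scale=True)
        assert r == pytest.approx(0.0, abs=1e-6)
        assert scale == pytest.approx(0.5, rel=1e-6)

    def test_scale_matches_weighted_median_oracle(self, sphere_curve):
        """The L1-optimal scale is the volume-weighted median of ratios."""
        rng = np.random.default_rng(3)
        noisy = sphere_curve.intensity * (1.0 + 0.05 * rng.normal(size=len(sphere_curve)))
        exp = sd.ScatteringCurve(sphere_curve.q, noisy)
        _, scale = sd.r_factor(exp, sphere_curve, fit_scale=True)
        # brute-force L1 minimization over a fine grid
        grid = np.linspace(0.8, 1.2, 20001)
        obj = [np.abs(noisy - c * sphere_curve.intensity).sum() for c in grid]
        assert scale == pytest.approx(grid[int(np.argmin(obj))], abs=2e-4)

    @given(factor=st.floats(0.01, 100.0))
    def test_invariant_to_common_rescaling(self, sphere_curve, factor):
        a = sd.ScatteringCurve(sphere_curve.q, factor * sphere_curve.intensity)
        b = sd.ScatteringCurve(
            sphere_curve.q, factor * 1.7 * sphere_curve.intensity
        )
        r_scaled, _ = sd.r_factor(a, b, fit_scale=False)
        r_ref, _ = sd.r_factor(
            sphere_curve,
            sd.ScatteringCurve(sphere_curve.q, 1.7 * sphere_curve.intensity),
            fit_scale=False,
        )
        assert r_scaled == pytest.approx(r_ref, rel=1e-9)

    def test_all_zero_experimental_rejected(self, sphere_curve):
        zero = sd.ScatteringCurve(sphere_curve.q, np.zeros(len(sphere_curve)))
        with pytest.raises(ValueError):
            sd.r_factor(zero, sphere_curve)


class TestRankModels:
    @pytest.fixture()
    def library(self):
        specs = [
            sd.FragmentSpec("m1", (17,), 7000.0),
            sd.FragmentSpec("m2", (17, 18), 14700.0),
            sd.FragmentSpec("m3", (16, 17, 18), 22000.0),
        ]
        return [sd.build_fragment_model(s) for s in specs]

    def test_true_model_ranks_first(self, library, q_grid):
        target = sd.debye_intensity(library[1], q_grid)
        ranked = sd.rank_models(library, target, rg_tolerance=5.0)
        assert ranked[0].model_id == "m2"
        assert ranked[0].r_factor == pytest.approx(0.0, abs=1e-6)

    def test_ranking_invariant_to_library_order(self, library, q_grid):
        target = sd.debye_intensity(library[1], q_grid)
        fwd = sd.rank_models(library, target, rg_tolerance=5.0)
        rev = sd.rank_models(library[::-1], target, rg_tolerance=5.0)
        assert [r.model_id for r in fwd] == [r.model_id for r in rev]

    def test_top_n_larger_than_library_returns_all(self, library, q_grid):
        target = sd.debye_intensity(library[0], q_grid)
        ranked = sd.rank_models(library, target, rg_tolerance=10.0, top_n=50)
        assert len(ranked) == len(library)

    def test_no_model_passing_filter_is_reported(self, library, q_grid):
        target = sd.debye_intensity(library[0], q_grid)
        with pytest.raises(ValueError, match="filter"):
            sd.rank_models(library, target, rg_tolerance=1e-6, exp_rg=50.0)

    def test_monomer_r_factor_grows_with_dimer_content(self, two_domain_model):
        """Fitting a monomer model to increasingly dimeric mixtures must
        degrade monotonically — the signature used to flag dimerization."""
        dimer = sd.build_dimer_model(two_domain_model, "side_by_side_parallel")
        q = np.linspace(0.05, 2.5, 200)
        monomer_curve = sd.debye_intensity(two_domain_model, q)
        rs = []
        for f_d in (0.0, 0.2, 0.5, 0.8):
            mix = sd.MixtureSpec(dimer_fraction=f_d, noise_level=0.0, seed=1)
            target = sd.simulate_saxs_curve(
                [(two_domain_model, 1.0 - f_d), (dimer, f_d)], mix, q
            )
            r, _ = sd.r_factor(target, monomer_curve, fit_scale=True)
            rs.append(r)
        assert rs == sorted(rs)
        assert rs[0] == pytest.approx(0.0, abs=1e-6)
        assert rs[-1] > rs[0] + 1.0
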