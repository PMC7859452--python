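"""Mass-action K_D conversions and dimer-site set logic."""

import math

import pytest
from hypothesis import given, strategies as st

import scrdimer as sd


class TestFractionsToKd:
    def test_hand_evaluated_point(self):
        """(f=0.11, 0.5 mg/ml, 38 kDa) -> 94.8 uM (monomer-equivalent)."""
        assert sd.fractions_to_kd(0.11, 0.5, 38000.0) == pytest.approx(94.8, abs=0.1)

    def test_published_single_domain_kd(self):
        """80% dimer at 1.0 mg/ml, 10 kDa monomer -> K_D = 5 uM."""
        assert sd.fractions_to_kd(0.80, 1.0, 10000.0) == pytest.approx(5.0, rel=1e-9)

    def test_no_dimer_is_infinite(self):
        assert sd.fractions_to_kd(0.0, 1.0, 10000.0) == math.inf

    def test_molar_convention_doubles(self):
        a = sd.fractions_to_kd(0.3, 1.0, 20000.0)
        b = sd.fractions_to_kd(0.3, 1.0, 20000.0, convention="molar")
        assert b == pytest.approx(2.0 * a)

    @given(
        f=st.floats(1e-6, 1.0 - 1e-6),
        c=st.floats(0.01, 10.0),
        df=st.floats(1e-4, 0.5),
    )
    def test_decreasing_in_fraction_increasing_in_concentration(self, f, c, df):
        f2 = min(f + df, 1.0 - 1e-9)
        kd1 = sd.fractions_to_kd(f, c, 20000.0)
        assert sd.fractions_to_kd(f2, c, 20000.0) < kd1
        assert sd.fractions_to_kd(f, 2.0 * c, 20000.0) > kd1


class TestMassAction:
    def test_dilution_limit(self):
        assert sd.mass_action_fraction(1e-12, 10.0, 20000.0) == pytest.approx(0.0, abs=1e-6)

    def test_fraction_at_c_equal_kd(self):
        """At c = K_D (molar) the dimer fraction is (3 - sqrt(5))/2."""
        mass = 2e5  # chosen so 1 mg/ml = 5 uM monomer-equivalent
        f = sd.mass_action_fraction(1.0, 5.0, mass)
        assert f == pytest.approx((3.0 - math.sqrt(5.0)) / 2.0, rel=1e-12)

    @given(
        c=st.floats(1e-3, 50.0),
        kd=st.floats(1e-3, 1e4),
        mass=st.floats(5e3, 2e5),
    )
    def test_exact_inverse_of_fractions_to_kd(self, c, kd, mass):
        f = sd.mass_action_fraction(c, kd, mass)
        assert sd.fractions_to_kd(f, c, mass) == pytest.approx(kd, rel=1e-10)

    def test_infinite_kd_gives_zero(self):
        assert sd.mass_action_fraction(1.0, math.inf, 20000.0) == 0.0


class TestKdFromSeries:
    def test_published_two_point_series(self):
        """(0.5 mg/ml, 11%) and (2.0 mg/ml, 30%) average to ~90 uM."""
        est = sd.kd_from_series([(0.5, 0.11), (2.0, 0.30)], 38000.0)
        assert est.kd == pytest.approx(90.4, abs=0.1)
        assert est.n_points == 2

    def test_single_point_has_zero_spread(self):
        est = sd.kd_from_series([(1.0, 0.5)], 20000.0)
        assert est.spread == 0.0

    def test_round_trip_on_noiseless_series(self):
        planted = 17.0
        pts = [(c, sd.mass_action_fraction(c, planted, 20000.0)) for c in (0.3, 1.0, 3.0)]
        est = sd.kd_from_series(pts, 20000.0)
        assert est.kd == pytest.approx(planted, rel=0.01)

    def test_monomeric_series_reported_infinite(self):
        est = sd.kd_from_series([(0.5, 0.0), (2.0, 0.0)], 20000.0)
        assert est.kd == math.inf
        assert est.n_excluded == 2

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            sd.kd_from_series([], 20000.0)


class TestLocalizeSite:
    def test_seven_fragment_panel(self, observed_kd_panel):
        """The nested deletion panel places the primary site on domain 17
        with domain 18 contributing."""
        site = sd.localize_site(observed_kd_panel, strong_threshold=10.0)
        assert site.primary_domains == frozenset({17})
        assert site.contributing_domains == frozenset({18})
        assert site.status == "ok"
        assert site.evidence["SCR-19/20"] == "monomeric"
        assert site.evidence["SCR-17/18H"] == "strong"

    def test_order_invariance(self, observed_kd_panel):
        fwd = sd.localize_site(observed_kd_panel)
        rev = sd.localize_site(list(reversed(observed_kd_panel)))
        assert fwd.primary_domains == rev.primary_domains
        assert fwd.contributing_domains == rev.contributing_domains

    def test_all_monomeric_is_no_site(self):
        panel = [
            (sd.FragmentSpec("a", (1, 2), 1e4), math.inf),
            (sd.FragmentSpec("b", (2, 3), 1e4), math.inf),
        ]
        site = sd.localize_site(panel)
        assert site.status == "no_site"
        assert not site.primary_domains

    def test_planted_site_recovery_exhaustive(self):
        """Brute-force: every contiguous planted site over domains 16-20 is
        recovered exactly from a noiseless all-contiguous-fragments panel."""
        domains = list(range(16, 21))
        fragments = [
            sd.FragmentSpec(f"F{a}-{b}", tuple(range(a, b + 1)), 7000.0 * (b - a + 1))
            for a in domains
            for b in range(a, 21)
        ]
        for a in domains:
            for b in range(a, 21):
                planted = frozenset(range(a, b + 1))
                panel = [
                    (f, 5.0 if planted <= f.domain_set else math.inf)
                    for f in fragments
                ]
                site = sd.localize_site(panel, strong_threshold=10.0)
                assert site.primary_domains == planted, f"failed for {sorted(planted)}"
                assert site.status == "ok"

    def test_generated_panel_round_trip(self):
        """default panel -> K_D estimates -> site comes back {17} + {18}."""
        panel = sd.default_panel(seed=5)
        ests = [
            (e.spec, sd.kd_from_series(e.points, e.spec.monomer_mass).kd)
            for e in panel.entries
        ]
        site = sd.localize_site(ests, strong_threshold=10.0)
        assert site.primary_domains == frozenset({17})
        assert site.contributing_domains == frozenset({18})

    def test_too_small_panel_rejected(self):
        with pytest.raises(ValueError):
            sd.localize_site([(sd.FragmentSpec("a", (1,), 1e4), 5.0)])


class TestGeneratePanel:
    def test_fragment_without_site_stays_monomeric(self):
        panel = sd.generate_panel(
            site={17, 18},
            kd_map=sd.DEFAULT_KD_MAP,
            concentrations=[0.5, 2.0],
            seed=0,
        )
        by_name = {e.spec.name: e for e in panel.entries}
        assert all(f == 0.0 for _, f in by_name["SCR-19/20"].points)
        assert all(f > 0.0 for _, f in by_name["SCR-17H"].points)

    def test_planted_kd_recovered_to_one_percent(self):
        panel = sd.default_panel(seed=0)
        for e in panel.entries:
            planted = sd.DEFAULT_KD_MAP[e.spec.name]
            est = sd.kd_from_series(e.points, e.spec.monomer_mass)
            if math.isinf(planted):
                assert est.kd == math.inf
            else:
                assert est.kd == pytest.approx(planted, rel=0.01)

    def test_jitter_is_seeded(self):
        a = sd.default_panel(seed=3, jitter=0.05)
        b = sd.default_panel(seed=3, jitter=0.05)
        c = sd.default_panel(seed=4, jitter=0.05)
        pa = [f for e in a.entries for _, f in e.points]
        pb = [f for e in b.entries for _, f in e.points]
        pc = [f for e in c.entries for _, f in e.points]
        assert pa == pb
        assert pa != pc

    def test_uncovered_fragment_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            sd.generate_panel(site={17}, kd_map={}, concentrations=[1.0])
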