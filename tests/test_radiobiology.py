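"""EQD2, gEUD and LKB NTCP: closed forms, hand values and chain properties."""

import numpy as np
import pytest
from scipy import integrate
from hypothesis import given, settings, strategies as st

from radbio.dvh import DoseVolumeHistogram, FractionationScheme, PlanRecord
from radbio.radiobiology import (
    LKBParameterSet,
    delta_ntcp,
    eqd2,
    eqd2_transform,
    geud,
    lkb_ntcp,
    load_lkb_parameters,
    ntcp_from_plan,
)
from .conftest import uniform_dose_dvh


def params_for(organ, endpoint):
    for p in load_lkb_parameters():
        if p.organ == organ and p.endpoint == endpoint:
            return p
    raise KeyError((organ, endpoint))


class TestEQD2:
    def test_identity_at_two_gray_per_fraction(self):
        # 60 Gy in 30 fractions of 2 Gy is its own EQD2 for any alpha/beta
        for ab in (2.0, 4.0, 10.0):
            assert eqd2(60.0, 30, ab) == pytest.approx(60.0)

    def test_hand_value_standard_course(self):
        # 50.4 Gy / 28 fx, a/b=4: d=1.8, 50.4*(1.8+4)/(2+4) = 48.72
        assert eqd2(50.4, 28, 4.0) == pytest.approx(48.72, abs=1e-12)

    def test_zero_dose_maps_to_zero(self):
        assert eqd2(0.0, 28, 4.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            eqd2(-1.0, 28, 4.0)
        with pytest.raises(ValueError):
            eqd2(50.0, 0, 4.0)
        with pytest.raises(ValueError):
            eqd2(50.0, 28, 0.0)


class TestEQD2Transform:
    def test_bin_doses_mapped_volumes_untouched(self, scheme):
        dvh = DoseVolumeHistogram("s", 100, [0, 25.2, 50.4], [100, 40, 0])
        out = eqd2_transform(dvh, scheme)
        assert out.dose[2] == pytest.approx(48.72)
        np.testing.assert_array_equal(out.values, dvh.values)
        assert out.dose_space == "eqd2"

    def test_double_transform_rejected(self, scheme):
        dvh = DoseVolumeHistogram("s", 100, [0, 25.2, 50.4], [100, 40, 0])
        with pytest.raises(ValueError, match="already"):
            eqd2_transform(eqd2_transform(dvh, scheme), scheme)

    def test_monotone_bin_order_preserved(self, scheme, rng):
        edges = np.sort(np.r_[0.0, rng.uniform(0.1, 54, 30)])
        vals = np.sort(rng.uniform(0, 100, edges.size))[::-1]
        vals[0], vals[-1] = 100.0, 0.0
        out = eqd2_transform(
            DoseVolumeHistogram("s", 10, edges, vals), scheme
        )
        assert np.all(np.diff(out.dose) > 0)


class TestGEUD:
    def test_uniform_dose_identity(self):
        for n in (0.07, 0.15, 0.5, 1.0):
            assert geud(uniform_dose_dvh(48.0), n) == pytest.approx(48.0, rel=1e-6)

    def test_n_equal_one_is_mean(self, simple_cumulative):
        from radbio.dvh import d_mean

        assert geud(simple_cumulative, 1.0) == pytest.approx(
            d_mean(simple_cumulative), rel=1e-9
        )

    def test_small_n_approaches_max(self):
        # half the organ at 20, half at 60: n -> 0+ recovers the maximum
        dvh = DoseVolumeHistogram("x", 10, [0, 40, 80], [50, 50], mode="differential")
        assert geud(dvh, 1e-3) == pytest.approx(60.0, rel=1e-3)

    def test_hand_example_two_bins(self):
        # v=(0.5,0.5), D=(20,60), n=0.15 -> (0.5*20^(1/.15)+0.5*60^(1/.15))^.15
        dvh = DoseVolumeHistogram("x", 10, [0, 40, 80], [50, 50], mode="differential")
        assert geud(dvh, 0.15) == pytest.approx(54.08, abs=0.01)

    def test_extreme_exponent_no_overflow(self):
        # 1/n ~ 14.3 with doses ~60 would overflow a naive power sum
        dvh = DoseVolumeHistogram(
            "x", 10, [0, 1e-6, 40, 80], [20, 40, 40], mode="differential"
        )
        out = geud(dvh, 0.07)
        assert np.isfinite(out) and 0 < out <= 60.0

    def test_bounded_between_mean_and_max(self, rng):
        from radbio.dvh import d_max, d_mean

        for _ in range(20):
            edges = np.sort(np.r_[0.0, rng.uniform(0.5, 60, 12)])
            vals = rng.dirichlet(np.ones(edges.size - 1)) * 100
            dvh = DoseVolumeHistogram("x", 10, edges, vals, mode="differential")
            for n in (0.07, 0.3, 0.9):
                g = geud(dvh, n)
                assert d_mean(dvh) - 1e-9 <= g <= d_max(dvh) + 1e-9

    def test_invalid_n(self, simple_cumulative):
        with pytest.raises(ValueError):
            geud(simple_cumulative, 0.0)
        with pytest.raises(ValueError):
            geud(simple_cumulative, 1.5)


class TestLKB:
    def test_half_probability_at_td50(self):
        p = params_for("stomach", "gastric bleed")
        assert lkb_ntcp(p.td50, p).ntcp == pytest.approx(0.5, abs=1e-15)

    def test_one_sigma_above_td50(self):
        p = params_for("stomach", "gastric bleed")
        res = lkb_ntcp(p.td50 * (1 + p.m), p)
        assert res.t == pytest.approx(1.0, abs=1e-12)
        assert res.ntcp == pytest.approx(0.841344746, abs=1e-6)

    def test_published_stomach_bleed_hand_value(self):
        # TD50=62, m=0.30: uniform 50.4 Gy -> t=-0.6237, Phi(t)=0.266
        p = params_for("stomach", "gastric bleed")
        assert p.td50 == 62.0 and p.m == 0.30 and p.n == 0.07
        assert lkb_ntcp(50.4, p).ntcp == pytest.approx(0.266, abs=0.001)

    def test_matches_gaussian_quadrature(self):
        """Closed-form Phi agrees with numerical integration of the density."""
        p = params_for("small_bowel", "obstruction/perforation")
        for t in np.linspace(-8, 8, 33):
            deff = p.td50 + t * p.m * p.td50
            if deff < 0:
                continue
            expected, _ = integrate.quad(
                lambda x: np.exp(-(x**2) / 2) / np.sqrt(2 * np.pi), -np.inf, t
            )
            assert lkb_ntcp(deff, p).ntcp == pytest.approx(expected, abs=1e-10)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            LKBParameterSet("o", "e", "s", td50=-1, m=0.3, n=0.1)
        with pytest.raises(ValueError):
            LKBParameterSet("o", "e", "s", td50=60, m=0.3, n=1.5)
        with pytest.raises(ValueError, match="bracket"):
            LKBParameterSet(
                "o", "e", "s", td50=60, m=0.3, n=0.1, td50_range=(70, 80)
            )

    def test_packaged_table_complete(self):
        rows = load_lkb_parameters()
        assert len(rows) == 6
        organs = sorted(p.organ for p in rows)
        assert organs == sorted(
            ["stomach", "stomach", "duodenum", "duodenum", "small_bowel", "stoduo"]
        )


class TestChain:
    def make_plan(self, dvh, scheme):
        return PlanRecord(
            "p1", "IMRT", {dvh.structure_label: dvh}, fractionation=scheme
        )

    def test_matches_manual_composition(self, scheme):
        dvh = DoseVolumeHistogram(
            "stomach", 180, [0, 10, 30, 48, 52], [100, 60, 30, 5, 0]
        )
        p = params_for("stomach", "gastric bleed")
        res = ntcp_from_plan(self.make_plan(dvh, scheme), "stomach", p)
        manual = lkb_ntcp(geud(eqd2_transform(dvh, scheme), p.n), p)
        assert res.ntcp == pytest.approx(manual.ntcp, rel=1e-12)
        assert res.deff == pytest.approx(manual.deff, rel=1e-12)

    def test_zero_dose_structure(self, scheme):
        p = params_for("stomach", "gastric bleed")
        dvh = uniform_dose_dvh(0.0)
        dvh = DoseVolumeHistogram(
            "stomach", 100, dvh.dose, dvh.values, mode="differential"
        )
        res = ntcp_from_plan(self.make_plan(dvh, scheme), "stomach", p)
        # deff ~ 0 -> t = -1/m -> essentially zero probability
        from scipy.special import ndtr

        assert res.ntcp == pytest.approx(float(ndtr(-1.0 / p.m)), abs=1e-6)

    def test_dose_scaling_strictly_increases_ntcp(self, scheme):
        p = params_for("stomach", "gastric bleed")
        base = DoseVolumeHistogram(
            "stomach", 180, [0, 10, 30, 48, 52], [100, 60, 30, 5, 0]
        )
        ntcps = []
        for scale in (0.8, 1.0, 1.05):
            scaled = DoseVolumeHistogram(
                "stomach", 180, base.dose * scale, base.values
            )
            ntcps.append(
                ntcp_from_plan(self.make_plan(scaled, scheme), "stomach", p).ntcp
            )
        assert ntcps[0] < ntcps[1] < ntcps[2]

    def test_rebinning_invariance(self, scheme):
        """NTCP is stable under DVH grid refinement (0.05 vs 0.2 GyE)."""
        from radbio.dvh import resample_cumulative

        p = params_for("stomach", "gastric bleed")
        base = DoseVolumeHistogram(
            "stomach", 180, [0, 10, 30, 48, 52], [100, 60, 30, 5, 0]
        )
        vals = {}
        for bw in (0.05, 0.2):
            grid = np.arange(0.0, 52.0 + bw, bw)
            re = resample_cumulative(base, grid)
            vals[bw] = ntcp_from_plan(self.make_plan(re, scheme), "stomach", p).ntcp
        assert vals[0.05] == pytest.approx(vals[0.2], abs=1e-4)

    def test_reference_fractionation_chain_unchanged(self):
        """At 2 Gy/fraction the EQD2 step is the identity for the whole chain."""
        sch = FractionationScheme(50.0, 25, 4.0)
        p = params_for("stomach", "gastric bleed")
        dvh = uniform_dose_dvh(50.0)
        dvh = DoseVolumeHistogram(
            "stomach", 100, dvh.dose, dvh.values, mode="differential"
        )
        with_eqd2 = ntcp_from_plan(self.make_plan(dvh, sch), "stomach", p)
        direct = lkb_ntcp(geud(dvh, p.n), p)
        assert with_eqd2.ntcp == pytest.approx(direct.ntcp, rel=1e-6)

    def test_missing_structure_raises(self, scheme):
        p = params_for("stomach", "gastric bleed")
        plan = PlanRecord("p1", "IMRT", {}, fractionation=scheme)
        with pytest.raises(KeyError):
            ntcp_from_plan(plan, "stomach", p)


class TestDeltaNTCP:
    def r(self, ntcp, endpoint="gastric bleed", label="stomach"):
        from radbio.radiobiology import NTCPResult

        return NTCPResult(label, endpoint, 40.0, 0.0, ntcp)

    def test_identical_plans_give_zero(self):
        assert delta_ntcp(self.r(0.1), self.r(0.1)) == 0.0

    def test_antisymmetry(self):
        a, b = self.r(0.12), self.r(0.07)
        assert delta_ntcp(a, b) == pytest.approx(-delta_ntcp(b, a))
        assert delta_ntcp(a, b) > 0

    def test_endpoint_mismatch_rejected(self):
        with pytest.raises(ValueError, match="endpoint"):
            delta_ntcp(self.r(0.1), self.r(0.1, endpoint="ulceration"))

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=30, deadline=None)
    def test_bounded_in_unit_interval(self, x, y):
        assert -1.0 <= delta_ntcp(self.r(x), self.r(y)) <= 1.0
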