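"""RD scoring: score-table reconstruction, tier binning, both methods,
monotonicity and linearity properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netrd import (
    AspirationalValues,
    HoleEnlargementOutcome,
    HoleEnlargementScoreTable,
    ScoreMatrix,
    SecondaryDamage,
    bin_score,
    hole_enlargement_score_m1,
    penalty_score,
    rd_method1,
    rd_method2,
    score_panel,
)

from conftest import make_record

# Published Method-1 hole-enlargement grid: damage type x end-size band.
HOLE_GRID_M1 = {
    SecondaryDamage.NONE: (100, 80, 40),
    SecondaryDamage.LADDERING: (80, 64, 32),
    SecondaryDamage.UNRAVELLING: (50, 40, 20),
    SecondaryDamage.TEARING_COMBINED: (40, 32, 16),
}
BAND_PROBES_MM = (3.0, 10.0, 25.0)  # one probe per band: <=5, (5,20], >20


class TestHoleEnlargementScoreM1:
    @pytest.mark.parametrize("damage,row", HOLE_GRID_M1.items())
    def test_base_times_multiplier_reproduces_full_grid(self, damage, row):
        for end_mm, expected in zip(BAND_PROBES_MM, row):
            score = hole_enlargement_score_m1(HoleEnlargementOutcome(end_mm, damage))
            assert score == expected

    @pytest.mark.parametrize("end_mm,band_idx", [(5.0, 0), (5.1, 1), (20.0, 1), (20.1, 2)])
    def test_band_edges(self, end_mm, band_idx):
        score = hole_enlargement_score_m1(HoleEnlargementOutcome(end_mm, SecondaryDamage.NONE))
        assert score == HOLE_GRID_M1[SecondaryDamage.NONE][band_idx]


class TestBinScore:
    @pytest.mark.parametrize(
        "value,parameter,expected",
        [
            (250, "bursting", 2.5),
            (249.9, "bursting", 1),
            (299.9, "bursting", 2.5),
            (699.9, "bursting", 22.5),
            (700, "bursting", 25),
            (59, "snag", 5),
            (19.9, "snag", 1),
            (200, "snag", 25),
            (410, "abrasion", 25),
            (10, "abrasion", 1),
            (25, "abrasion", 3),
            (60, "abrasion", 3),  # printed-gap value takes the tier below
            (120, "abrasion", 6),
            (399, "abrasion", 22),
        ],
    )
    def test_tier_lookup(self, value, parameter, expected):
        assert bin_score(value, parameter) == expected

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            bin_score(100, "stretch")

    @given(st.floats(min_value=0, max_value=2000), st.floats(min_value=0, max_value=2000))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_value(self, a, b):
        lo, hi = sorted((a, b))
        for p in ("bursting", "snag", "abrasion"):
            assert bin_score(lo, p) <= bin_score(hi, p)


class TestPenaltyScore:
    @pytest.mark.parametrize(
        "end_mm,damage,sigma,rho",
        [
            (3, SecondaryDamage.LADDERING, 25, 2.5),
            (3, SecondaryDamage.NONE, 25, 0.0),
            (25, SecondaryDamage.TEARING_COMBINED, 10, 3.0),
            (10, SecondaryDamage.UNRAVELLING, 20, 4.0),
        ],
    )
    def test_penalty_is_fraction_of_hole_score(self, end_mm, damage, sigma, rho):
        assert penalty_score(HoleEnlargementOutcome(end_mm, damage)) == (sigma, rho)


class TestMethod1:
    def test_aspirational_inputs_score_exactly_100(self):
        assert rd_method1(make_record()).total == pytest.approx(100.0)

    def test_half_aspirational_scores_50(self):
        # every term at half aspiration: sigma_H 50 = unravelling with a <=5 mm hole
        rec = make_record(bursting=350, snag=100, abrasion=200, end_mm=3,
                          damage=SecondaryDamage.UNRAVELLING)
        assert rd_method1(rec).total == pytest.approx(50.0)

    def test_exceeds_100_when_bursting_doubles_aspiration(self):
        assert rd_method1(make_record(bursting=1400)).total == pytest.approx(125.0)

    def test_linear_in_snag(self):
        base = rd_method1(make_record(snag=80)).total
        doubled = rd_method1(make_record(snag=160)).total
        assert doubled - base == pytest.approx(80 / 200 * 25)

    def test_contributions_sum_to_total(self):
        res = rd_method1(make_record(bursting=433, snag=87, abrasion=311, end_mm=12,
                                     damage=SecondaryDamage.LADDERING))
        assert res.total == pytest.approx(sum(res.contributions.values()), abs=1e-12)
        assert all(v >= 0 for v in res.contributions.values())

    def test_nonpositive_aspirational_rejected(self):
        with pytest.raises(ValueError):
            AspirationalValues(bursting_kpa=0)


class TestMethod2:
    def test_top_tiers_no_penalty_is_100(self):
        assert rd_method2(make_record()).total == 100.0

    def test_worked_mixed_tier_example(self):
        rec = make_record(bursting=250, snag=59, abrasion=410, end_mm=3,
                          damage=SecondaryDamage.LADDERING)
        res = rd_method2(rec)
        assert res.contributions == {
            "bursting": 2.5, "snag": 5, "abrasion": 25, "hole_enlargement": 22.5,
        }
        assert res.total == pytest.approx(55.0)

    def test_floor_is_10(self):
        rec = make_record(bursting=100, snag=10, abrasion=10, end_mm=25,
                          damage=SecondaryDamage.TEARING_COMBINED)
        assert rd_method2(rec).total == pytest.approx(10.0)

    @given(
        st.floats(min_value=1, max_value=1500),
        st.floats(min_value=1, max_value=400),
        st.integers(min_value=0, max_value=600),
        st.floats(min_value=0, max_value=50),
        st.sampled_from(list(SecondaryDamage)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_total_bounded_in_10_100(self, bursting, snag, abrasion, end_mm, damage):
        total = rd_method2(make_record(bursting=bursting, snag=snag, abrasion=abrasion,
                                       end_mm=end_mm, damage=damage)).total
        assert 10.0 <= total <= 100.0


DAMAGE_ORDER = [
    SecondaryDamage.NONE,
    SecondaryDamage.LADDERING,
    SecondaryDamage.UNRAVELLING,
    SecondaryDamage.TEARING_COMBINED,
]


@pytest.mark.parametrize("method", ["method1", "method2"])
class TestMonotonicity:
    """Increasing a strength never lowers RD; worsening the hole outcome
    never raises it — under either method."""

    @given(
        base=st.floats(min_value=1, max_value=1000),
        bump=st.floats(min_value=0, max_value=500),
    )
    @settings(max_examples=100, derandomize=True)
    def test_strength_parameters(self, method, base, bump):
        score = lambda **kw: score_panel([make_record(**kw)], method)[0].total
        assert score(bursting=base + bump) >= score(bursting=base)
        assert score(snag=base + bump) >= score(snag=base)
        assert score(abrasion=int(base + bump)) >= score(abrasion=int(base))

    @given(end=st.floats(min_value=0, max_value=40), worse=st.floats(min_value=0, max_value=40))
    @settings(max_examples=100, derandomize=True)
    def test_hole_band(self, method, end, worse):
        lo, hi = sorted((end, worse))
        score = lambda mm: score_panel([make_record(end_mm=mm)], method)[0].total
        assert score(hi) <= score(lo)

    @given(st.integers(min_value=0, max_value=2))
    @settings(max_examples=20, derandomize=True)
    def test_damage_severity(self, method, i):
        score = lambda d: score_panel([make_record(damage=d)], method)[0].total
        assert score(DAMAGE_ORDER[i + 1]) <= score(DAMAGE_ORDER[i])


class TestScorePanel:
    def test_order_preserved_and_method_tagged(self, synthetic_panel):
        results = score_panel(synthetic_panel, "method2")
        assert [r.net_id for r in results] == [r.net_id for r in synthetic_panel]
        assert {r.method for r in results} == {"method2"}

    def test_deterministic(self, synthetic_panel):
        a = score_panel(synthetic_panel, "method1")
        b = score_panel(synthetic_panel, "method1")
        assert [r.total for r in a] == [r.total for r in b]

    def test_synthetic_totals_finite(self, synthetic_panel):
        import math

        totals = [r.total for r in score_panel(synthetic_panel, "method1")]
        assert len(totals) == 16 and all(math.isfinite(t) for t in totals)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            score_panel([], "method1")


class TestConfigOverrides:
    def test_score_matrix_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            ScoreMatrix(edges={"bursting": [300, 250], "snag": [20], "abrasion": [25]},
                        scores={"bursting": [1, 2, 3], "snag": [1, 2], "abrasion": [1, 2]})

    def test_custom_aspirational_values(self):
        asp = AspirationalValues(bursting_kpa=1000)
        res = rd_method1(make_record(bursting=1000), aspirational=asp)
        assert res.contributions["bursting"] == pytest.approx(25.0)

    def test_matrix_from_dict_round_trip(self):
        m = ScoreMatrix.from_dict({"hole_scores": {"le_5mm": 25, "6_20mm": 20, "ge_21mm": 10}})
        assert m.hole_scores["6_20mm"] == 20.0
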