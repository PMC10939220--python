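"""Life-table personalization: odds adjustment, annual split, life expectancy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import perlife as pl
from perlife.life_tables import PROFILE_TERMS, _split_two_year


def _baseline_trajectory(baseline_profile, sex, from_age, to_age):
    g = baseline_profile.data[baseline_profile.data.sex == sex].set_index("age")
    return g.loc[from_age:to_age, list(PROFILE_TERMS)]


class TestTwoYearProb:
    @pytest.mark.parametrize(
        "qa, qb, expected",
        [(0.0, 0.0, 0.0), (1.0, 0.3, 1.0), (0.01, 0.02, 0.0298)],
    )
    def test_values(self, qa, qb, expected):
        assert pl.two_year_prob(qa, qb) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pl.two_year_prob(-0.1, 0.5)


class TestAdjustOdds:
    def test_identity_when_predictors_match(self):
        assert pl.adjust_odds(0.37, 1.234, 1.234) == pytest.approx(0.37, abs=1e-15)

    def test_odds_algebra(self):
        assert pl.adjust_odds(0.5, np.log(2.0), 0.0) == pytest.approx(2 / 3)

    def test_rare_event_limit(self):
        q2 = 0.001
        out = pl.adjust_odds(q2, np.log(3.0), 0.0)
        assert out == pytest.approx(0.002994, abs=1e-6)
        # relative deviation from the multiplicative small-q approximation
        # is itself of order the adjusted probability
        assert abs(out - 3 * q2) / (3 * q2) <= 3 * q2

    def test_degenerate_passthrough_warns(self):
        with pytest.warns(UserWarning):
            assert pl.adjust_odds(1.0, 1.0, 0.0) == 1.0

    @settings(derandomize=True, max_examples=100)
    @given(
        q=st.floats(1e-6, 1 - 1e-6),
        d=st.floats(-5, 5, allow_nan=False),
    )
    def test_monotone_in_delta_and_in_range(self, q, d):
        out = pl.adjust_odds(q, d, 0.0)
        assert 0.0 < out < 1.0
        if d > 0:
            assert out >= q
        elif d < 0:
            assert out <= q


class TestSplitTwoYear:
    @settings(derandomize=True, max_examples=200)
    @given(
        qa=st.floats(1e-6, 0.5),
        qb=st.floats(1e-6, 0.5),
        d=st.floats(-3, 3, allow_nan=False),
    )
    def test_round_trip_reproduces_adjusted_two_year(self, qa, qb, d):
        q2_adj = pl.adjust_odds(pl.two_year_prob(qa, qb), d, 0.0)
        qa2, qb2 = _split_two_year(qa, qb, q2_adj)
        assert pl.two_year_prob(qa2, qb2) == pytest.approx(q2_adj, abs=1e-12)

    def test_identity_split_returns_inputs(self):
        qa, qb = 0.013, 0.017
        q2 = pl.two_year_prob(qa, qb)
        qa2, qb2 = _split_two_year(qa, qb, q2)
        assert qa2 == pytest.approx(qa, abs=1e-14)
        assert qb2 == pytest.approx(qb, abs=1e-14)


class TestPersonalize:
    def test_baseline_trajectory_returns_population_table(
        self, life_table, baseline_profile, reference_model
    ):
        for sex, age in (("male", 30), ("female", 45)):
            traj = _baseline_trajectory(
                baseline_profile, sex, age, life_table.omega(sex)
            )
            pt = pl.personalize(
                life_table, reference_model, baseline_profile, traj, sex, age
            )
            pop_q = life_table.qx(sex).loc[age:]
            assert np.abs(pt.qx - pop_q).max() < 1e-12

    def test_extra_smoking_raises_mortality_at_every_age(
        self, life_table, baseline_profile, reference_model
    ):
        sex, age = "male", 40
        omega = life_table.omega(sex)
        traj = _baseline_trajectory(baseline_profile, sex, age, omega).copy()
        traj["x3"] += 1.0
        pt = pl.personalize(life_table, reference_model, baseline_profile, traj, sex, age)
        pop_q = life_table.qx(sex).loc[age:]
        assert (pt.qx.loc[: omega - 1] > pop_q.loc[: omega - 1]).all()
        assert pt.qx.loc[omega] == 1.0
        assert ((pt.qx > 0) & (pt.qx <= 1)).all()

    def test_odd_current_age_steps_from_current_age(
        self, life_table, baseline_profile, reference_model
    ):
        sex, age = "female", 33
        traj = _baseline_trajectory(baseline_profile, sex, age, life_table.omega(sex))
        pt = pl.personalize(life_table, reference_model, baseline_profile, traj, sex, age)
        assert int(pt.qx.index.min()) == age

    def test_trajectory_gap_rejected(self, life_table, baseline_profile, reference_model):
        traj = _baseline_trajectory(baseline_profile, "male", 30, 90)
        with pytest.raises(ValueError, match="missing ages"):
            pl.personalize(life_table, reference_model, baseline_profile, traj, "male", 30)


class TestLifeExpectancy:
    def test_certain_death_gives_half_year(self):
        qx = pd.Series({70: 1.0})
        assert pl.life_expectancy(qx, 70) == 0.5

    def test_constant_hazard_geometric_closed_form(self):
        # constant annual q: LE = (1 - q)/q + 0.5; truncation negligible
        q = 0.5
        ages = np.arange(0, 120)
        qx = pd.Series(np.full(len(ages), q), index=ages)
        qx.iloc[-1] = 1.0
        assert pl.life_expectancy(qx, 0) == pytest.approx((1 - q) / q + 0.5, abs=1e-9)

    def test_bounded_by_remaining_support(self, life_table):
        for sex in ("male", "female"):
            omega = life_table.omega(sex)
            for age in (20, 50, 80):
                le = life_table.life_expectancy(sex, age)
                assert 0.5 <= le <= omega - age + 0.5

    def test_outside_support_rejected(self, life_table):
        with pytest.raises(ValueError):
            life_table.life_expectancy("male", 200)


class TestLeDirections:
    """Life expectancy must respond to risk factors with the fitted signs."""

    @pytest.mark.parametrize(
        "term, delta, direction",
        [("x3", 2.0, -1), ("x4", 5.0, -1), ("x6", 5.0, +1)],
    )
    def test_monotone_response(
        self, life_table, baseline_profile, reference_model, term, delta, direction
    ):
        sex, age = "male", 30
        traj = _baseline_trajectory(baseline_profile, sex, age, life_table.omega(sex))
        base_le = pl.personalize(
            life_table, reference_model, baseline_profile, traj, sex, age
        ).life_expectancy(age)
        shifted = traj.copy()
        shifted[term] += delta
        le = pl.personalize(
            life_table, reference_model, baseline_profile, shifted, sex, age
        ).life_expectancy(age)
        assert np.sign(le - base_le) == direction


@pytest.fixture(scope="module")
def profiles(cohort, reference_model, baseline_profile, life_table,
             trajectory_model, disease_params):
    out = {}
    for sex in ("male", "female"):
        out[sex] = pl.le_percentile_profiles(
            cohort, reference_model, baseline_profile, life_table,
            trajectory_model, disease_params, [10, 25, 50, 75, 90], 30, sex,
        )
    return out


class TestLePercentileProfiles:
    def test_le_monotone_in_rank(self, profiles):
        for sex, prof in profiles.items():
            le = prof.sort_values("percentile")["life_expectancy"].to_numpy()
            assert (np.diff(le) > 0).all(), sex

    def test_gap_widens_with_rank_spread(self, profiles):
        for sex, prof in profiles.items():
            le = prof.set_index("percentile")["life_expectancy"]
            assert le[90] - le[10] > le[75] - le[25], sex

    def test_invalid_percentile_rejected(self, cohort, reference_model,
                                         baseline_profile, life_table,
                                         trajectory_model, disease_params):
        with pytest.raises(ValueError):
            pl.le_percentile_profiles(
                cohort, reference_model, baseline_profile, life_table,
                trajectory_model, disease_params, [0], 30, "male",
            )


class TestPeriodLifeTableIO:
    def test_hmd_style_columns_accepted(self, tmp_path):
        path = tmp_path / "hmd.csv"
        path.write_text(
            "Year,Age,mx,qx,lx\n"
            + "\n".join(f"2014,{a},0.01,{0.01 + a * 1e-4},100000" for a in range(0, 110))
            + "\n2014,110+,1.0,1.0,100\n"
        )
        t = pl.PeriodLifeTable.from_csv(path, sex="female")
        assert t.omega("female") == 110
        assert t.qx("female").loc[0] == pytest.approx(0.01)

    def test_round_trip(self, life_table, tmp_path):
        path = tmp_path / "lt.csv"
        life_table.to_csv(path)
        back = pl.PeriodLifeTable.from_csv(path)
        pd.testing.assert_frame_equal(back.data, life_table.data)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError, match="terminal"):
            pl.PeriodLifeTable(pd.DataFrame(
                {"sex": "male", "age": [20, 21], "qx": [0.1, 0.5]}
            ))
        with pytest.raises(ValueError, match="contiguous"):
            pl.PeriodLifeTable(pd.DataFrame(
                {"sex": "male", "age": [20, 22, 23], "qx": [0.1, 0.5, 1.0]}
            ))
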