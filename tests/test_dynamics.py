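import numpy as np
import pytest

from deterrence.dynamics import (
    DETERRENCE,
    NO_DETERRENCE,
    PopulationState,
    basin_fraction,
    best_responses,
    challenger_payoffs,
    defender_indifference,
    defender_payoff,
    deterrence_fighter_level,
    ess_scan,
    integrate_br,
    project,
    randomization_dominance_check,
    simplex_grid,
)
from deterrence.game import ChallengerKind, PayoffParams

from oracles import mc_challenger_payoff, mc_defender_payoff

P15 = PayoffParams(1.0, 1.5, 0.1)
P11 = PayoffParams(1.0, 1.0, 0.2)


class TestChallengerPayoffs:
    def test_indifference_at_q_star(self):
        pay = challenger_payoffs(P15.q_star, P15)
        assert pay[ChallengerKind.ALLT] == pytest.approx(pay[ChallengerKind.ALLR], abs=1e-12)

    def test_all_yielders(self):
        pay = challenger_payoffs(0.0, P15)
        assert pay[ChallengerKind.ALLT] == pytest.approx(1.0)
        assert pay[ChallengerKind.DISC] == pytest.approx(0.9)
        assert pay[ChallengerKind.ALLR] == 0.0

    @pytest.mark.parametrize("kind", ["AllR", "AllT", "Disc", "IR", "IT", "Par"])
    @pytest.mark.parametrize("y", [0.0, 0.4, 1.0])
    def test_matches_match_play_oracle(self, kind, y):
        pay = challenger_payoffs(y, P15)[ChallengerKind(kind)]
        sim = mc_challenger_payoff(kind, y, P15.v, P15.c, P15.a, n=120_000, seed=11)
        assert pay == pytest.approx(sim, abs=1e-2)

    def test_checking_variants_strictly_dominated_for_positive_cost(self):
        """IR < AllR, IT < AllT and Par < max(AllR, AllT) at every fighter
        share when information is costly."""
        ys = np.linspace(0, 1, 101)
        pay = challenger_payoffs(ys, P15)
        assert (pay[ChallengerKind.IR] < pay[ChallengerKind.ALLR]).all()
        assert (pay[ChallengerKind.IT] < pay[ChallengerKind.ALLT]).all()
        best_plain = np.maximum(pay[ChallengerKind.ALLR], pay[ChallengerKind.ALLT])
        assert (pay[ChallengerKind.PAR] < best_plain).all()

    def test_rejects_invalid_fighter_share(self):
        with pytest.raises(ValueError):
            challenger_payoffs(1.2, P15)


class TestDefenderPayoff:
    @pytest.mark.parametrize(
        "q,x,expected",
        [
            (1.0, (0, 1, 0), -1.0),
            (0.0, (0, 1, 0), 0.0),
            (0.5, (0, 0.5, 0.5), None),  # computed against the MC oracle
        ],
    )
    def test_known_values(self, q, x, expected):
        p = PayoffParams(1.0, 1.0) if expected is not None else P15
        got = defender_payoff(q, x, p)
        if expected is None:
            assert got == pytest.approx(-1 / 6, abs=1e-12)
        else:
            assert got == pytest.approx(expected)

    @pytest.mark.parametrize(
        "q,x", [(0.5, (0, 0.5, 0.5)), (0.3, (0.3, 0.3, 0.4)), (0.9, (0.1, 0.2, 0.7))]
    )
    def test_matches_single_defender_simulation(self, q, x):
        pay = defender_payoff(q, x, P15)
        sim = mc_defender_payoff(q, x, P15.v, P15.c, rounds=250_000, seed=5)
        assert pay == pytest.approx(sim, abs=1e-2)

    def test_rejects_off_simplex(self):
        with pytest.raises(ValueError):
            defender_payoff(0.5, (0.5, 0.5, 0.5), P15)


def test_randomization_dominance_on_simplex_grid():
    """No interior fighting probability strictly beats both pure reactions,
    for any challenger mixture on a 21x21 simplex grid."""
    report = randomization_dominance_check(simplex_grid(21), P15, q_resolution=101)
    assert report["dominated"], report["counterexamples"]
    # and the two corner mixtures behave as expected
    assert defender_payoff(0.0, (0, 1, 0), P15) > defender_payoff(1.0, (0, 1, 0), P15)
    pays = defender_payoff(np.linspace(0, 1, 11), np.array([1.0, 0, 0]), P15)
    assert np.allclose(pays, P15.v)  # never attacked: q irrelevant


class TestBestResponses:
    def test_heavy_fighters_make_respect_optimal(self):
        ch, _ = best_responses(PopulationState((1 / 3, 1 / 3, 1 / 3), 0.9), PayoffParams(1, 1, 0.2))
        assert ch == {ChallengerKind.ALLR}

    def test_all_yielders_make_taking_optimal(self):
        ch, _ = best_responses(PopulationState((1 / 3, 1 / 3, 1 / 3), 0.0), P15)
        assert ch == {ChallengerKind.ALLT}

    def test_defender_side_follows_indifference_sign(self):
        x = (0.0, 0.3, 0.7)
        g = defender_payoff(1.0, x, P15) - defender_payoff(0.0, x, P15)
        _, df = best_responses(PopulationState(x, 0.5), P15)
        assert g > 0 and df == {1.0}
        x2 = (0.0, 0.9, 0.1)
        _, df2 = best_responses(PopulationState(x2, 0.5), P15)
        assert defender_payoff(1.0, x2, P15) < defender_payoff(0.0, x2, P15)
        assert df2 == {0.0}

    def test_no_attackers_leaves_defenders_indifferent(self):
        _, df = best_responses(PopulationState((1, 0, 0), 0.5), P15)
        assert df == {0.0, 1.0}


class TestIntegrateBR:
    def test_no_deterrence_corner_is_stationary(self):
        traj = integrate_br(PopulationState((0, 1, 0), 0.0), P11, horizon=50)
        assert traj.label == NO_DETERRENCE
        final = traj.final()
        assert final.x[1] == pytest.approx(1.0) and final.y == pytest.approx(0.0)

    def test_near_deterrence_corner_stays_there(self):
        traj = integrate_br(PopulationState((0.97, 0.015, 0.015), 0.97), P11, horizon=50)
        assert traj.label == DETERRENCE

    def test_step_halving_preserves_labels(self):
        """Forward-Euler labels are converged in the step size."""
        starts = [
            PopulationState((1 / 3, 1 / 3, 1 / 3), 0.5),
            PopulationState((0.1, 0.8, 0.1), 0.1),
            PopulationState((0.2, 0.2, 0.6), 0.7),
        ]
        for s0 in starts:
            coarse = integrate_br(s0, P11, step=2e-3).label
            fine = integrate_br(s0, P11, step=1e-3).label
            assert coarse == fine

    def test_states_stay_on_prism(self):
        traj = integrate_br(PopulationState((0.2, 0.5, 0.3), 0.4), P11, record_every=50)
        x = traj.states[:, :3]
        y = traj.states[:, 3]
        assert np.all(x >= -1e-9) and np.allclose(x.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((y >= -1e-9) & (y <= 1 + 1e-9))


class TestProject:
    def test_indifference_plane_maps_to_fixed_height(self):
        # g(x) = 0 along x_Disc/x_AllT = c/v
        x = np.array([0.0, 1 / (1 + 1.5), 1.5 / (1 + 1.5)])
        _, vert = project(PopulationState(tuple(x), 0.3), P15)
        assert vert == pytest.approx(P15.v / (P15.v + P15.c))
        assert defender_indifference(x, P15) == pytest.approx(0.0, abs=1e-12)

    def test_taker_states_plot_above_the_line(self):
        h, vert_takers = project(PopulationState((0, 1, 0), 0.3), P15)
        _, vert_line = project(PopulationState((1, 0, 0), 0.3), P15)
        assert h == 0.3
        assert vert_takers > vert_line  # yielder-favouring above

    def test_pure_respect_sits_on_the_line(self):
        _, vert = project(PopulationState((1, 0, 0), 0.8), P15)
        assert vert == pytest.approx(P15.v / (P15.v + P15.c))


class TestESS:
    def test_take_and_yield_is_the_unique_ess(self):
        assert ess_scan(P15) == [("AllT", 0.0)]

    def test_deterrence_states_fail_by_drift_or_information_cost(self):
        stable = ess_scan(P11)
        assert ("AllR", 1.0) not in stable  # defender reactions drift
        assert ("Disc", 1.0) not in stable  # checking cost is wasted
        assert stable == [("AllT", 0.0)]


class TestBasin:
    def test_costlier_information_enlarges_the_no_deterrence_basin(self):
        free = basin_fraction(PayoffParams(1, 1, 0.0), grid_resolution=9, horizon=100)
        costly = basin_fraction(PayoffParams(1, 1, 0.5), grid_resolution=9, horizon=100)
        assert free < costly

    def test_basin_is_small_for_cheap_information(self):
        frac = basin_fraction(P11, grid_resolution=9, horizon=100)
        assert 0.0 < frac < 0.5

    def test_deterrence_level_definition(self):
        assert deterrence_fighter_level(P11) == pytest.approx(0.8)
        assert deterrence_fighter_level(P15) == pytest.approx(0.9)
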