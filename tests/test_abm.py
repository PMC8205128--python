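import dataclasses

import numpy as np
import pandas as pd
import pytest

from deterrence.abm import (
    SimConfig,
    init_population,
    play_round,
    revise_strategies,
    run_simulation,
    behavior_class_frequencies,
)
from deterrence.fixtures import make_fixture
from deterrence.game import PayoffParams
from deterrence.reputation import SchemeSpec


def small_config(**kw):
    base = dict(N=200, N_F=20, rounds=50, seed=42)
    base.update(kw)
    return SimConfig(**base)


class TestInit:
    def test_kinds_roughly_uniform(self):
        cfg = SimConfig(N=6000, N_F=10, seed=1)
        pop = init_population(cfg)
        counts = np.bincount(pop.chall, minlength=6)
        # binomial 3-sigma band around N/6
        sigma = np.sqrt(6000 * (1 / 6) * (5 / 6))
        assert np.all(np.abs(counts - 1000) < 3 * sigma)

    def test_no_agent_is_its_own_friend_and_friends_are_distinct(self):
        pop = init_population(small_config())
        for i in range(pop.N):
            row = pop.friends[i]
            assert i not in row
            assert len(set(row.tolist())) == len(row)

    def test_reinit_is_deterministic(self):
        cfg = small_config()
        a, b = init_population(cfg), init_population(cfg)
        for f in ("chall", "q", "wealth", "friends", "buf", "nrec", "nfight"):
            assert np.array_equal(getattr(a, f), getattr(b, f))

    def test_reputation_initialisation_modes(self):
        empty = init_population(small_config(initial_reputation="empty"))
        assert empty.nrec.sum() == 0
        coin = init_population(small_config(initial_reputation="coin_flip"))
        assert np.all(coin.nrec == 1)
        assert 0 < coin.nfight.sum() < coin.N  # fair mixture of images

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(N=201)
        with pytest.raises(ValueError):
            SimConfig(N=100, N_F=100)
        with pytest.raises(ValueError):
            SimConfig(delta=1.5)
        with pytest.raises(ValueError):
            SimConfig(rounds=0)


class TestPlayRound:
    def test_all_respecters_produce_no_takes(self):
        pop, cfg = make_fixture("homogeneous", 40, seed=0,
                                config=small_config(N=40, epsilon=0.0))
        rng = np.random.default_rng(1)
        stats = play_round(pop, cfg, rng)
        assert stats.n_take == stats.n_fight == stats.n_check == 0
        assert stats.mean_pay_defender == pytest.approx(cfg.params.v)
        assert stats.mean_pay_challenger == 0.0

    def test_forced_conflict_when_takers_meet_fighters(self):
        cfg = small_config(N=40, epsilon=0.0)
        pop, _ = make_fixture("homogeneous", 40, seed=0, config=cfg)
        pop.chall[:] = 1   # AllT
        pop.q[:] = 1.0
        stats = play_round(pop, cfg, np.random.default_rng(2))
        assert stats.n_take == stats.n_fight == 20
        assert stats.mean_pay_challenger == pytest.approx(-cfg.params.c)
        assert stats.mean_pay_defender == pytest.approx(-cfg.params.c)

    def test_discriminators_respect_tough_defenders(self):
        cfg = small_config(N=40, epsilon=0.0, delta=0.0)
        pop, _ = make_fixture("homogeneous", 40, seed=0, config=cfg)
        pop.chall[:] = 2   # Disc
        pop.buf[:, 0] = 1  # everyone carries a tough image
        pop.nrec[:] = 1
        pop.nfight[:] = 1
        stats = play_round(pop, cfg, np.random.default_rng(3))
        assert stats.n_take == 0
        assert stats.n_check == 20
        assert stats.mean_pay_challenger == pytest.approx(-cfg.params.a)
        assert stats.mean_pay_defender == pytest.approx(cfg.params.v)

    def test_accounting_identity_every_round(self):
        """Total emitted payoff equals v*(respects + successful takes)
        - 2c*fights - a*checks, each round, with all noise channels on."""
        cfg = small_config(rounds=120, epsilon=0.05, delta=0.05, mu=0.02, u=0.1)
        stats = run_simulation(cfg, progress_every=0)
        M = cfg.N // 2
        total = M * (stats["mean_pay_challenger"] + stats["mean_pay_defender"])
        n_respect = M - stats["n_take"]
        n_take_yield = stats["n_take"] - stats["n_fight"]
        expect = (
            cfg.params.v * (n_respect + n_take_yield)
            - 2 * cfg.params.c * stats["n_fight"]
            - cfg.params.a * stats["n_check"]
        )
        assert np.allclose(total, expect, atol=1e-8)


class TestRevision:
    def test_wealthiest_strategy_is_imitated(self):
        cfg = small_config(N=40, u=1.0, mu=0.0, q_continuous=False)
        pop, _ = make_fixture("two_block", 40, seed=0, config=cfg)
        pop.wealth[:20] = 5.0   # the AllT / q=0 block is rich
        pop.wealth[20:] = 1.0
        revise_strategies(pop, cfg, np.random.default_rng(0))
        # every agent whose friend set reaches the rich block adopts AllT/q=0
        assert np.mean(pop.chall == 1) > 0.9
        assert np.mean(pop.q == 0.0) > 0.9

    def test_single_candidate_revision_is_a_noop(self):
        cfg = small_config(N=40, u=1.0, mu=0.0)
        pop, _ = make_fixture("homogeneous", 40, seed=0, config=cfg)
        pop.wealth[:] = np.random.default_rng(5).random(40)
        revise_strategies(pop, cfg, np.random.default_rng(1))
        assert np.all(pop.chall == 0)
        assert np.all(pop.q == 1.0)

    def test_full_experimentation_randomises_strategies(self):
        cfg = small_config(N=2000, N_F=10, u=0.0, mu=1.0)
        pop = init_population(cfg)
        pop.chall[:] = 0
        revise_strategies(pop, cfg, np.random.default_rng(3))
        freqs = np.bincount(pop.chall, minlength=6) / cfg.N
        assert np.all(np.abs(freqs - 1 / 6) < 0.05)

    def test_no_update_channels_freeze_the_population(self):
        cfg = small_config(N=40, u=0.0, mu=0.0, rounds=30)
        pop, _ = make_fixture("two_block", 40, seed=0, config=cfg)
        stats = run_simulation(cfg, population=pop.copy(), progress_every=0)
        assert stats["freq_AllT"].nunique() == 1
        assert stats["freq_AllR"].nunique() == 1


class TestRunSimulation:
    def test_bitwise_deterministic(self):
        cfg = small_config(rounds=80)
        a = run_simulation(cfg, progress_every=0)
        b = run_simulation(cfg, progress_every=0)
        pd.testing.assert_frame_equal(a, b)

    def test_frequencies_sum_to_one(self):
        stats = run_simulation(small_config(rounds=40), progress_every=0)
        kind_cols = [c for c in stats.columns if c.startswith("freq_")]
        q_cols = [c for c in stats.columns if c.startswith("q_hist_")]
        assert np.allclose(stats[kind_cols].sum(axis=1), 1.0)
        assert np.allclose(stats[q_cols].sum(axis=1), 1.0)
        classes = behavior_class_frequencies(stats)
        assert np.allclose(classes.sum(axis=1), 1.0)

    def test_memory_one_frequency_scheme_reproduces_last_action(self):
        """With k = 1 the fighting-frequency scheme takes the same decisions
        as last-action: identical seeds give bitwise-identical runs once the
        initial-reputation mode is pinned."""
        base = dict(N=200, N_F=20, rounds=150, seed=7, initial_reputation="coin_flip")
        la = run_simulation(SimConfig(scheme=SchemeSpec("last_action"), **base),
                            progress_every=0)
        ff = run_simulation(
            SimConfig(scheme=SchemeSpec("fighting_frequency", memory_k=1), **base),
            progress_every=0)
        pd.testing.assert_frame_equal(la, ff)

    def test_reputation_records_stay_within_memory(self):
        cfg = small_config(scheme=SchemeSpec("fighting_frequency", memory_k=3),
                           rounds=60)
        rng = np.random.default_rng(cfg.seed)
        pop = init_population(cfg, rng)
        for r in range(cfg.rounds):
            play_round(pop, cfg, rng, r)
            assert np.all(pop.nrec <= 3)
            assert np.all(pop.nfight <= pop.nrec)
        assert pop.nrec.max() == 3  # histories do fill up


def test_grid_mode_keeps_defenders_on_the_grid():
    cfg = small_config(q_continuous=False, rounds=60, mu=0.05)
    stats = run_simulation(cfg, progress_every=0)
    rng = np.random.default_rng(cfg.seed)
    pop = init_population(cfg, rng)
    for r in range(cfg.rounds):
        play_round(pop, cfg, rng, r)
        revise_strategies(pop, cfg, rng)
    assert set(np.round(np.unique(pop.q), 10)) <= set(cfg.q_grid)
    assert stats.shape[0] == cfg.rounds
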