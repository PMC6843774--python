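"""Synthetic observations and toy keys: round trips, noise, oracle checks."""

import numpy as np
import pytest

from diatomkey import (
    NoiseSpec,
    batch_identify,
    enumerate_leaves,
    generate_observation,
    generate_observation_table,
    identify_observation,
    paths_for_species,
    toy_key,
    validate,
)
from diatomkey.model import Status, TargetKind


class TestGenerateObservation:
    def test_rhoicosphenia_round_trips_via_each_of_its_routes(self, key, db):
        n = len(paths_for_species(key, "rhoicosphenia_abbreviata"))
        assert n >= 3
        seen_routes = set()
        for k in range(n):
            obs = generate_observation(key, db, "rhoicosphenia_abbreviata", k)
            res = identify_observation(key, db, obs)
            assert res.status is Status.IDENTIFIED
            assert res.species_id == "rhoicosphenia_abbreviata"
            seen_routes.add(res.charts_visited)
        assert len(seen_routes) == n  # girdle view, via C6, via C10

    def test_forced_out_of_range_always_restarts_never_misidentifies(self, key, db):
        noise = NoiseSpec(out_of_range_prob=1.0, seed=5)
        for sid in sorted(enumerate_leaves(key))[::7]:
            obs = generate_observation(key, db, sid, 0, noise)
            res = identify_observation(key, db, obs)
            assert res.status is Status.NO_MATCH_RESTART
            assert res.species_id is None

    def test_same_seed_same_observation(self, key, db):
        a = generate_observation(key, db, "nitzschia_palea", 0, NoiseSpec(seed=9))
        b = generate_observation(key, db, "nitzschia_palea", 0, NoiseSpec(seed=9))
        assert a == b

    def test_invalid_path_index_rejected(self, key, db):
        with pytest.raises(Exception, match="path_index"):
            generate_observation(key, db, "nitzschia_palea", 99)


class TestObservationTable:
    def test_no_noise_table_recovers_every_species(self, key, db, tmp_path):
        path = tmp_path / "obs.csv"
        generate_observation_table(key, db, n_per_species=1, out=path)
        result = batch_identify(key, db, path)
        assert result.counts == {"identified": 60}
        for row in result.rows:
            assert row["label"].startswith(row["species_id"])

    def test_all_unknown_rows_are_unresolved(self, key, db):
        text = generate_observation_table(
            key, db, n_per_species=1, noise=NoiseSpec(unknown_prob=1.0)
        )
        import io
        import pandas as pd

        result = batch_identify(key, db, pd.read_csv(io.StringIO(text), dtype=str))
        assert result.counts == {"unresolved": 60}

    def test_identical_seed_byte_identical_csv(self, key, db):
        a = generate_observation_table(key, db, 2, NoiseSpec(seed=3))
        b = generate_observation_table(key, db, 2, NoiseSpec(seed=3))
        assert a == b


class TestToyKey:
    def test_small_toy_key_validates_with_two_leaves(self):
        toy, toy_db = toy_key(n_charts=1, n_leaves=2, seed=1)
        assert validate(toy, toy_db).ok
        assert len(enumerate_leaves(toy)) == 2

    def test_full_size_toy_key_matches_bundled_shape(self):
        toy, toy_db = toy_key(n_charts=12, n_leaves=60, seed=2)
        rep = validate(toy, toy_db)
        assert rep.ok
        assert rep.stats["chart_count"] == 12
        assert rep.stats["leaf_count"] == 60
        assert rep.stats["species_reachable"] == 60

    def test_impossible_sizes_rejected(self):
        with pytest.raises(ValueError):
            toy_key(n_charts=5, n_leaves=2, seed=0)
        with pytest.raises(ValueError):
            toy_key(n_charts=0, n_leaves=1, seed=0)


def brute_force_identify(key, answers):
    """Independent oracle: enumerate all root-to-leaf paths and keep those
    whose every step agrees with the observation's answers."""
    from diatomkey.model import all_leaf_paths

    hits = []
    for trace, sid in all_leaf_paths(key):
        if all(answers.get(s.node_id) == s.answer for s in trace):
            hits.append(sid)
    return hits


class TestEngineOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_engine_agrees_with_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        toy, toy_db = toy_key(
            n_charts=int(rng.integers(1, 4)),
            n_leaves=int(rng.integers(3, 9)),
            seed=seed,
        )
        assert len(toy.nodes) <= 20
        leaves = sorted(enumerate_leaves(toy))
        sid = leaves[int(rng.integers(0, len(leaves)))]
        n_paths = len(paths_for_species(toy, sid))
        obs = generate_observation(toy, toy_db, sid, int(rng.integers(0, n_paths)),
                                   NoiseSpec(seed=seed))
        res = identify_observation(toy, toy_db, obs)
        oracle = brute_force_identify(toy, obs.answers)
        assert res.status is Status.IDENTIFIED
        assert oracle == [res.species_id] == [sid]


def test_out_of_range_fraction_matches_binomial_expectation(key, db):
    # calibration: with per-field probability q, an observation fails iff
    # any of its fields was displaced, so the no-match rate over n trials
    # should track p = 1-(1-q)^k within 3 binomial standard errors
    q, n, sid = 0.3, 200, "gomphonema_olivaceum"
    rec = db[sid]
    k = sum(rec.range_for(f) is not None for f in
            ("length_um", "width_um", "striae_per_10um", "fibulae_per_10um"))
    p = 1 - (1 - q) ** k
    failures = 0
    for i in range(n):
        noise = NoiseSpec(out_of_range_prob=q, seed=1000 + i)
        obs = generate_observation(key, db, sid, 0, noise)
        res = identify_observation(key, db, obs)
        assert res.status in (Status.IDENTIFIED, Status.NO_MATCH_RESTART)
        failures += res.status is Status.NO_MATCH_RESTART
    assert abs(failures / n - p) <= 3 * np.sqrt(p * (1 - p) / n)
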