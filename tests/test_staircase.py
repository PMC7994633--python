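import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noxep.observers import Observer
from noxep.staircase import (
    MatchingTarget,
    familiarization_target,
    next_energy,
    run_matching,
)


def scripted_callback(order, per_staircase_ratings):
    """Rating callback that replays fixed per-staircase rating sequences,
    regardless of the energies presented."""
    iters = {sid: iter(seq) for sid, seq in per_staircase_ratings.items()}
    pos = {"i": 0}

    def rate(_energy):
        sid = order[pos["i"]]
        pos["i"] += 1
        return next(iters[sid])

    return rate


class TestNextEnergy:
    @pytest.mark.parametrize(
        "current, rating, target, expected",
        [
            (1.5, 0, 3, 2.0),  # no pain felt: large step up
            (2.0, 2, 3, 2.25),  # below target: small step up
            (2.25, 4, 3, 2.0),  # above target: small step down
            (2.0, 3, 3, 2.0),  # at target: hold
        ],
    )
    def test_update_rule(self, current, rating, target, expected):
        assert next_energy(current, rating, target) == expected

    def test_tie_down_variant(self):
        assert next_energy(2.0, 3, 3, tie="down") == 1.75

    def test_clamping(self):
        assert next_energy(5.0, 0, 3, energy_cap=5.0) == 5.0
        assert next_energy(0.25, 5, 3) == 0.25  # floor at one small step

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            next_energy(0.0, 2, 3)
        with pytest.raises(ValueError):
            next_energy(2.0, 11, 3)
        with pytest.raises(ValueError):
            next_energy(2.0, 2, 3, tie="sideways")


class TestFamiliarizationTarget:
    @pytest.mark.parametrize(
        "ratings, expected",
        [
            ([9, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3], 3.0),  # first discarded
            ([5, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0], 0.0),
            ([1, 1, 2, 3, 4, 5, 4, 3, 2, 1, 4], 2.9),  # mean of last 10
        ],
    )
    def test_first_stimulus_discarded(self, ratings, expected):
        assert familiarization_target(ratings).target_nrs == pytest.approx(expected)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="11"):
            familiarization_target([3] * 10)

    def test_target_bounds(self):
        with pytest.raises(ValueError):
            MatchingTarget(target_nrs=11.0)


class TestHandTrace:
    def test_scripted_trajectory_reproduces_hand_simulation(self):
        """Ratings [0,0,2,4,2,4,3,3,3,3] per staircase, target 3, start 1.5 J
        must walk 1.5->2.0->2.5->2.75->2.5->2.75->2.5 and then hold: the
        sequence obtained by applying the update rule by hand."""
        seq = [0, 0, 2, 4, 2, 4, 3, 3, 3, 3]
        order = ["A", "B"] * 10
        rate = scripted_callback(order, {"A": list(seq), "B": list(seq)})
        runs, result = run_matching(rate, MatchingTarget(3.0), order=order)
        expected = [1.5, 2.0, 2.5, 2.75, 2.5, 2.75, 2.5, 2.5, 2.5, 2.5]
        assert runs["A"].energies == expected
        assert runs["B"].energies == expected
        assert result.median_energy_a == 2.5
        assert result.median_energy_b == 2.5
        assert result.matched_energy == 2.5
        assert not result.correction_applied  # median NRS 3 is not below target

    def test_correction_when_median_rating_below_target(self):
        seq = [0, 0, 1, 1, 2, 2, 2, 2, 2, 2]  # never reaches target 5
        order = ["A", "B"] * 10
        rate = scripted_callback(order, {"A": list(seq), "B": list(seq)})
        _, result = run_matching(rate, MatchingTarget(5.0), order=order)
        assert result.correction_applied
        assert result.matched_energy == (result.median_energy_a + result.median_energy_b) / 2 + 0.25


class TestRunMatching:
    def test_twenty_trials_and_interleaving_constraint(self):
        obs = Observer(seed=1)
        runs, _ = run_matching(obs.simulate_rating, MatchingTarget(3.0), seed=5)
        assert len(runs["A"].trials) == 10 and len(runs["B"].trials) == 10

    def test_interleaving_never_exceeds_three_consecutive(self):
        from noxep.staircase import _interleaving

        rng = np.random.default_rng(0)
        for _ in range(200):
            order = _interleaving(rng, 10)
            assert order.count("A") == 10 and order.count("B") == 10
            run = 1
            for prev, cur in zip(order, order[1:]):
                run = run + 1 if cur == prev else 1
                assert run <= 3

    def test_interleaving_permutation_leaves_result_unchanged(self):
        """Same per-staircase rating sequences under different random
        interleavings give the identical MatchResult (median robustness)."""
        seq_a = [0, 1, 2, 4, 3, 4, 2, 3, 4, 2]
        seq_b = [0, 0, 1, 3, 4, 2, 3, 4, 3, 3]
        results = []
        for seed in (1, 2, 3):
            from noxep.staircase import _interleaving

            order = _interleaving(np.random.default_rng(seed), 10)
            rate = scripted_callback(order, {"A": list(seq_a), "B": list(seq_b)})
            _, result = run_matching(rate, MatchingTarget(3.0), order=order)
            results.append(result)
        assert results[0] == results[1] == results[2]

    def test_deterministic_observer_holds_at_target(self):
        """An observer rating exactly the target at every painful energy keeps
        both staircases flat once pain is reached; no correction applies."""

        def rate(energy):
            return 3 if energy >= 2.0 else 0

        runs, result = run_matching(rate, MatchingTarget(3.0), seed=0)
        for run in runs.values():
            painful = [e for e, r in run.trials if r > 0]
            assert all(e == painful[0] for e in painful)
        assert not result.correction_applied

    def test_grid_offsets_from_start(self):
        obs = Observer(rating_noise_sd=2.0, seed=9)
        runs, result = run_matching(obs.simulate_rating, MatchingTarget(4.0), seed=9)
        for run in runs.values():
            for e in run.energies:
                assert (round(e / 0.25, 6)).is_integer()
        # mean of two 0.25 J-grid medians lies on the 0.125 J grid
        assert (round(result.matched_energy / 0.125, 6)).is_integer()

    def test_callback_failure_preserves_partial_trajectory(self):
        calls = {"n": 0}

        def flaky(_energy):
            calls["n"] += 1
            if calls["n"] > 5:
                raise RuntimeError("stimulator fault")
            return 2

        with pytest.raises(RuntimeError) as exc_info:
            run_matching(flaky, MatchingTarget(3.0), seed=0)
        runs = exc_info.value.staircase_runs
        assert sum(len(r.trials) for r in runs.values()) == 5

    def test_divergence_flagged_but_still_averaged(self):
        order = ["A", "B"] * 10
        rate = scripted_callback(
            order,
            {"A": [0] * 10, "B": [5] * 10},  # A climbs, B descends
        )
        _, result = run_matching(rate, MatchingTarget(3.0), order=order)
        assert result.diverged
        assert result.matched_energy > 0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        ratings=st.lists(st.integers(0, 10), min_size=20, max_size=20),
        target=st.floats(0.0, 10.0),
        seed=st.integers(0, 10_000),
    )
    def test_grid_property_random_sequences(self, ratings, target, seed):
        it = iter(ratings)
        runs, result = run_matching(lambda e: next(it), MatchingTarget(target), seed=seed)
        for run in runs.values():
            assert len(run.trials) == 10
            for e in run.energies:
                assert 0 < e <= 5.0
                assert abs(e / 0.25 - round(e / 0.25)) < 1e-9

    def test_convergence_oscillates_around_bracketing_energy(self):
        """Noiseless monotone observer: after the first reversal, energies stay
        within one small step of the grid energy whose rating brackets the
        target."""
        obs = Observer(pain_threshold_energy=1.0, slope=2.5, rating_noise_sd=0.0)
        # rating(E) = round(2.5 (E - 1)): target 3.5 is bracketed between
        # E = 2.25 (rating 3) and E = 2.5 (rating 4)
        runs, _ = run_matching(obs.simulate_rating, MatchingTarget(3.5), seed=2)
        for run in runs.values():
            e = np.array(run.energies)
            steps = np.sign(np.diff(e))
            nz = np.flatnonzero(steps != 0)
            rev = None
            for i, j in zip(nz, nz[1:]):
                if steps[i] != steps[j]:
                    rev = j
                    break
            assert rev is not None, "staircase never reversed"
            assert np.all(np.abs(e[rev:] - 2.375) <= 0.125 + 1e-9)
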