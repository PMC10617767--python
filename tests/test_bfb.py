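import itertools

import pytest

from ampliconlens.bfb import (
    UNDECIDED,
    BFBCall,
    BFBString,
    CountVector,
    bfb_confidence,
    check_bfb_string,
    enumerate_bfb_strings,
    is_bfb_count_vector,
    nearest_bfb_poisson,
    reconstruct_amplicon,
    simulate_bfb,
)
from ampliconlens.rearrangements import detect_foldbacks


# -- independent enumeration oracle ----------------------------------------

def _inv(u):
    return tuple(-x for x in reversed(u))


def oracle_enumerate(k, max_count, max_cycles=8):
    """Brute-force BFS over BFB strings, independent of the package
    implementation: start from (1..k), repeatedly truncate at every
    boundary and append the inverted prefix, pruning on per-segment count
    caps.  Returns the set of reachable strings."""
    ref = tuple(range(1, k + 1))
    seen = {ref}
    frontier = [ref]
    for _ in range(max_cycles):
        new = []
        for s in frontier:
            for p in range(1, len(s) + 1):
                u = s[:p]
                t = u + _inv(u)
                counts = [0] * k
                for x in t:
                    counts[abs(x) - 1] += 1
                if max(counts) > max_count:
                    continue
                if t not in seen:
                    seen.add(t)
                    new.append(t)
        frontier = new
        if not frontier:
            break
    return seen


def oracle_counts(s, k):
    c = [0] * k
    for x in s:
        c[abs(x) - 1] += 1
    return tuple(c)


class TestSimulate:
    def test_zero_cycles_is_reference(self):
        sim = simulate_bfb(4, 0, seed=1)
        assert sim.string.symbols == (1, 2, 3, 4)
        assert sim.count_vector.counts == (1, 1, 1, 1)
        assert sim.foldbacks == []
        assert not sim.telomeric_loss

    def test_single_cycle_hand_execution(self):
        sim = simulate_bfb(3, 1, breaks=[2], boundaries=[0, 100, 200, 300])
        assert sim.string.symbols == (1, 2, -2, -1)
        assert sim.count_vector.counts == (2, 2, 0)
        assert len(sim.foldbacks) == 1
        assert sim.telomeric_loss
        # fold-back at the genomic end of segment 2, lower flanks retained
        fb = sim.foldbacks[0]
        assert fb.junction.a.pos == 200
        assert fb.junction.orientation_class == "tail_to_tail"

    def test_seed_determinism(self):
        a = simulate_bfb(5, 4, seed=123)
        b = simulate_bfb(5, 4, seed=123)
        assert a.string == b.string
        assert a.count_vector == b.count_vector
        assert [f.junction for f in a.foldbacks] == [f.junction for f in b.foldbacks]

    def test_invalid_break_index(self):
        with pytest.raises(ValueError, match="break index"):
            simulate_bfb(3, 1, breaks=[7])

    def test_foldback_count_equals_cycles_and_all_detected(self):
        for seed in range(10):
            sim = simulate_bfb(5, 3, seed=seed)
            assert len(sim.foldbacks) == 3
            detected = detect_foldbacks([fb.junction for fb in sim.foldbacks])
            assert len(detected) == 3

    def test_conservation_total_symbols_equals_count_sum(self):
        for seed in range(10):
            sim = simulate_bfb(4, 3, seed=seed)
            assert len(sim.string.symbols) == sim.count_vector.total()


class TestCheckString:
    def test_reference_true(self):
        assert check_bfb_string((1, 2, 3))

    def test_one_cycle_strings_match_enumeration(self):
        ref = (1, 2, 3)
        for p in range(1, 4):
            u = ref[:p]
            assert check_bfb_string(u + _inv(u))

    def test_non_palindromic_tail_false(self):
        assert not check_bfb_string((1, 2, 1))

    def test_agrees_with_enumeration_small(self):
        for k in (2, 3):
            reachable = oracle_enumerate(k, max_count=4, max_cycles=3)
            # every enumerated string passes; simple corruptions fail
            for s in reachable:
                assert check_bfb_string(s), s
            assert not check_bfb_string((2, 1))
            assert not check_bfb_string((1, -1, 1))

    def test_every_simulator_output_passes(self):
        for seed in range(20):
            sim = simulate_bfb(5, 4, seed=seed)
            assert check_bfb_string(sim.string)


class TestIsCountVector:
    def test_reference_vector(self):
        assert is_bfb_count_vector((1, 1, 1, 1)) is True

    def test_hand_enumerated_positive(self):
        assert is_bfb_count_vector((2, 2, 0)) is True

    def test_hand_enumerated_negative(self):
        assert is_bfb_count_vector((1, 2)) is False

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            is_bfb_count_vector((1, -1))

    def test_agrees_with_enumeration_k3_counts4(self):
        reachable = {
            oracle_counts(s, 3) for s in oracle_enumerate(3, max_count=6)
        }
        for counts in itertools.product(range(5), repeat=3):
            expected = counts in reachable
            got = is_bfb_count_vector(counts)
            assert got is expected, (counts, got, expected)

    def test_undecided_at_tiny_cycle_bound(self):
        # a deep vector cannot be decided within one cycle
        sim = simulate_bfb(3, 4, seed=5)
        got = is_bfb_count_vector(sim.count_vector.counts, max_cycles=1)
        assert got in (UNDECIDED, True)


class TestNearestPoisson:
    def test_achievable_vector_returned_exactly(self):
        sim = simulate_bfb(4, 2, seed=9)
        call = nearest_bfb_poisson(
            [float(c) for c in sim.count_vector.counts], baseline=0
        )
        assert call.approximation.counts == sim.count_vector.counts

    def test_noisy_vector_rounds_to_achievable(self):
        call = nearest_bfb_poisson((2.1, 1.9, 0.2), baseline=0)
        assert call.approximation.counts == (2, 2, 0)

    def test_baseline_subtraction(self):
        call = nearest_bfb_poisson((3.1, 2.9, 1.2), baseline=1.0)
        assert call.approximation.counts == (2, 2, 0)

    def test_all_zero_degenerate(self):
        call = nearest_bfb_poisson((0.1, 0.2), baseline=0)
        assert call.approximation.counts == (0, 0)
        assert call.log_poisson_likelihood == 0.0

    def test_exhaustive_search_oracle(self):
        # best candidate over all achievable vectors, scored independently
        import math

        def logp(x, lam):
            if lam == 0:
                return 0.0 if round(x) == 0 else -30.0
            return x * math.log(lam) - lam - math.lgamma(x + 1)

        observed = (3.2, 1.7, 0.4)
        achievable = {
            oracle_counts(s, 3) for s in oracle_enumerate(3, max_count=6)
        }
        best = max(
            sorted(achievable),
            key=lambda cand: sum(logp(x, l) for x, l in zip(observed, cand)),
        )
        call = nearest_bfb_poisson(observed, baseline=0, count_cap=6)
        got_ll = call.log_poisson_likelihood
        best_ll = sum(logp(x, l) for x, l in zip(observed, best))
        assert got_ll == pytest.approx(best_ll)


class TestConfidence:
    def _call(self, n_segments, foldbacks, telomeric, approx=True):
        return BFBCall(
            observed=(1.0,) * n_segments,
            approximation=CountVector((1,) * n_segments) if approx else None,
            log_poisson_likelihood=0.0,
            n_segments_in_approximation=n_segments,
            foldback_support=foldbacks,
            telomeric_loss=telomeric,
        )

    def test_nine_segments_with_foldbacks_is_high(self):
        assert bfb_confidence(self._call(9, True, True)) == "high"

    def test_five_segments_is_ambiguous(self):
        assert bfb_confidence(self._call(5, True, True)) == "ambiguous"

    def test_eight_segments_without_foldbacks_is_ambiguous(self):
        assert bfb_confidence(self._call(8, False, True)) == "ambiguous"

    def test_no_approximation_is_excluded(self):
        assert bfb_confidence(self._call(3, True, True, approx=False)) == "excluded"

    def test_pure_function_of_inputs(self):
        # telomeric loss is metadata, not a gate
        assert bfb_confidence(self._call(9, True, False)) == "high"
        assert bfb_confidence(self._call(9, True, True)) == "high"


class TestReconstruct:
    def test_round_trip_fixed_seed(self):
        boundaries = [i * 1_000_000 for i in range(5)]
        sim = simulate_bfb(4, 3, seed=11, boundaries=boundaries)
        ranked = reconstruct_amplicon(
            sim.foldbacks, sim.count_vector.counts, boundaries
        )
        assert ranked
        assert ranked[0].symbols == sim.string.symbols

    def test_single_foldback_single_cycle(self):
        boundaries = [0, 100, 200]
        sim = simulate_bfb(2, 1, breaks=[1], boundaries=boundaries)
        ranked = reconstruct_amplicon(sim.foldbacks, (2, 0), boundaries)
        assert ranked[0].symbols == (1, -1)

    def test_contradictory_inputs_empty(self):
        boundaries = [0, 100, 200]
        sim = simulate_bfb(2, 1, breaks=[1], boundaries=boundaries)
        # fold-back present but counts are flat reference counts
        assert reconstruct_amplicon(sim.foldbacks, (1, 1), boundaries) == []


class TestRoundTripProperty:
    @pytest.mark.parametrize("seed", range(25))
    def test_simulated_vectors_accepted_and_reconstructed(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        cycles = int(rng.integers(0, 5))
        boundaries = [i * 500_000 for i in range(k + 1)]
        sim = simulate_bfb(k, cycles, seed=seed, boundaries=boundaries)
        assert is_bfb_count_vector(sim.count_vector.counts, max_cycles=8) is True
        assert len(sim.foldbacks) == cycles
        ranked = reconstruct_amplicon(
            sim.foldbacks, sim.count_vector.counts, boundaries,
            max_cycles=cycles + 1,
        )
        assert ranked
        assert ranked[0].symbols == sim.string.symbols


class TestEnumerateStrings:
    def test_cycle_history_replays_to_string(self):
        strings = enumerate_bfb_strings([3, 3, 3], max_cycles=3)
        for sym, bstr in strings.items():
            cur = tuple(range(1, 4))
            for p in bstr.break_positions:
                u = cur[:p]
                cur = u + _inv(u)
            assert cur == sym
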