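import numpy as np
import pytest

from mitar.amosa import (
    Archive,
    Schedule,
    Solution,
    cluster_reduce,
    dominates,
    domination_amount,
    initialize,
    run,
)


def ones_first_half(bits):
    return (float(sum(bits[: len(bits) // 2])), float(sum(bits[len(bits) // 2 :])))


def conflicting(bits):
    return (float(sum(bits)), float(len(bits) - sum(bits)))


SMALL = Schedule(
    Tmax=1.0, Tmin=0.01, alpha=0.5, iters_per_temp=15,
    n_init=5, hc_iters=10, HL=8, SL=16, seed=0,
)


class TestDominance:
    def test_weak_dominance_with_one_strict(self):
        assert dominates((0.9, 0.9), (0.8, 0.9))

    def test_incomparable(self):
        assert not dominates((0.9, 0.7), (0.8, 0.8))
        assert not dominates((0.8, 0.8), (0.9, 0.7))

    def test_self_never_dominates(self):
        assert not dominates((0.5, 0.5), (0.5, 0.5))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            dominates((1, 2), (1, 2, 3))


class TestDominationAmount:
    def test_equal_vectors_zero(self):
        assert domination_amount((0.5, 0.5), (0.5, 0.5), (1, 1)) == 0.0

    def test_product_of_normalized_gaps(self):
        assert domination_amount((0.8, 0.6), (0.6, 0.5), (1, 1)) == pytest.approx(0.02)

    def test_equal_component_skipped(self):
        assert domination_amount((0.8, 0.5), (0.6, 0.5), (1, 1)) == pytest.approx(0.2)

    def test_symmetry_and_nonnegativity(self):
        a, b, R = (0.3, 0.9, 0.1), (0.5, 0.2, 0.1), (1.0, 0.5, 2.0)
        assert domination_amount(a, b, R) == domination_amount(b, a, R) >= 0

    def test_nonpositive_range_errors(self):
        with pytest.raises(ValueError):
            domination_amount((1,), (0,), (0,))


class TestArchive:
    def test_insert_keeps_only_nondominated(self):
        arc = Archive(HL=5, SL=10)
        arc.insert(Solution((1, 0), (0.5, 0.5)))
        arc.insert(Solution((0, 1), (0.9, 0.9)))  # dominates the first
        assert len(arc) == 1 and arc.members[0].objectives == (0.9, 0.9)
        assert not arc.insert(Solution((1, 1), (0.1, 0.1)))  # dominated

    def test_sl_must_cover_hl(self):
        with pytest.raises(ValueError):
            Archive(HL=10, SL=5)


class TestClusterReduce:
    def _arc(self, objs):
        arc = Archive(HL=2, SL=4)
        arc.members = [Solution((i,), (o,)) for i, o in enumerate(objs)]
        return arc

    def test_hand_worked_1d_case(self):
        """{0, 0.1} and {1} cluster apart; nearest-mean member represents."""
        arc = self._arc([0.0, 0.1, 1.0])
        red = cluster_reduce(arc, 2)
        got = sorted(m.objectives[0] for m in red.members)
        assert got[1] == 1.0
        assert got[0] in (0.0, 0.1)

    def test_within_target_is_identity(self):
        arc = self._arc([0.0, 1.0])
        assert cluster_reduce(arc, 2) is arc

    def test_identical_objectives_single_representative(self):
        arc = self._arc([0.5, 0.5, 0.5])
        red = cluster_reduce(arc, 1)
        assert len(red) == 1
        # ties break to the lexicographically smallest bitstring
        assert red.members[0].bits == (0,)


class TestInitialize:
    def test_archive_mutually_nondominated(self):
        arc = initialize(ones_first_half, 10, SMALL)
        for a in arc.members:
            for b in arc.members:
                if a is not b:
                    assert not dominates(a.objectives, b.objectives)

    def test_single_init_solution(self):
        sch = Schedule(Tmax=1, Tmin=0.5, alpha=0.6, iters_per_temp=1, n_init=1,
                      hc_iters=3, HL=4, SL=8, seed=1)
        assert len(initialize(ones_first_half, 10, sch)) == 1

    def test_deterministic_under_seed(self):
        a = initialize(ones_first_half, 10, SMALL)
        b = initialize(ones_first_half, 10, SMALL)
        assert [m.bits for m in a.members] == [m.bits for m in b.members]


class TestRun:
    def test_archive_invariants_throughout(self):
        """Non-domination and the SL cap hold after every archive change."""

        def check(arc):
            assert len(arc) <= arc.SL
            for a in arc.members:
                for b in arc.members:
                    if a is not b:
                        assert not dominates(a.objectives, b.objectives)

        for evaluator in (ones_first_half, conflicting):
            for seed in range(3):
                sch = Schedule(**{**SMALL.__dict__, "seed": seed})
                final = run(evaluator, 10, sch, on_archive_change=check)
                check(final)
                assert len(final) <= sch.HL

    def test_single_optimum_reaches_all_ones(self):
        """All-ones dominates every string; the anneal should find it."""
        hits = 0
        for seed in range(10):
            sch = Schedule(**{**SMALL.__dict__, "seed": seed})
            arc = run(ones_first_half, 10, sch)
            hits += any(m.bits == (1,) * 10 for m in arc.members)
        assert hits >= 9

    def test_conflicting_objectives_distinct_ones_counts(self):
        arc = run(conflicting, 8, SMALL)
        counts = [sum(m.bits) for m in arc.members]
        assert len(counts) == len(set(counts))

    def test_fixed_seed_identical_archive(self):
        a = run(conflicting, 8, SMALL)
        b = run(conflicting, 8, SMALL)
        assert [(m.bits, m.objectives) for m in a.members] == [
            (m.bits, m.objectives) for m in b.members
        ]

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            Schedule(Tmax=1, Tmin=2, alpha=0.5)
        with pytest.raises(ValueError):
            Schedule(alpha=1.5)

    def test_run_log_written(self, tmp_path):
        path = tmp_path / "log.tsv"
        run(conflicting, 8, SMALL, log_path=str(path))
        lines = path.read_text().strip().split("\n")
        assert lines[0].startswith("temperature")
        assert len(lines) > 10
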