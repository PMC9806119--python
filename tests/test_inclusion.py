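import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicefidelity.inclusion import (
    ExonEvent,
    collapse_duplicate_exons,
    differential_inclusion,
    exon_commitment_score,
    exon_inclusion_level,
)
from splicefidelity.simulate import psi_to_inclusion_weight

from .oracles import fisher_two_sided_exact


def _event(eid, inc, skip, exon=(100, 150), gene="G"):
    return ExonEvent(
        event_id=eid,
        gene_id=gene,
        contig="c",
        strand="+",
        exon=exon,
        upstream_exon=(1, 50),
        downstream_exon=(200, 250),
        inclusion_reads=inc,
        skip_reads=skip,
    )


class TestInclusionLevel:
    def test_length_normalised_formula(self):
        assert exon_inclusion_level(20, 5) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("inc,skip,expected", [(7, 0, 1.0), (0, 9, 0.0)])
    def test_full_inclusion_and_skipping(self, inc, skip, expected):
        assert exon_inclusion_level(inc, skip) == expected

    def test_undefined_at_zero_depth(self):
        with pytest.raises(ValueError):
            exon_inclusion_level(0, 0)

    @given(
        inc=st.integers(min_value=0, max_value=500),
        skip=st.integers(min_value=0, max_value=500),
    )
    @settings(derandomize=True)
    def test_bounded_and_monotone_in_inclusion(self, inc, skip):
        if inc + skip == 0:
            return
        psi = exon_inclusion_level(inc, skip)
        assert 0.0 <= psi <= 1.0
        assert exon_inclusion_level(inc + 1, skip) >= psi


class TestCollapseDuplicates:
    def test_minimum_rule(self):
        events = [_event("a", 80, 20), _event("b", 30, 70)]  # psi 2/3 vs ~0.176
        (kept,) = collapse_duplicate_exons(events)
        assert kept.event_id == "b"

    def test_unique_exon_unchanged(self):
        events = [_event("a", 10, 0, exon=(1, 9)), _event("b", 0, 10, exon=(20, 29))]
        assert len(collapse_duplicate_exons(events)) == 2

    def test_min_of_three(self):
        events = [
            _event("a", 100, 0),
            _event("b", 198, 1),
            _event("c", 20, 10),
        ]
        (kept,) = collapse_duplicate_exons(events)
        assert kept.psi == pytest.approx(0.5)


def commitment_oracle(psis, hi=0.99, lo=0.01):
    return sum(1 for p in psis if p > hi or p < lo) / len(psis)


class TestCommitmentScore:
    def _events_from_psi(self, psis, depth=1000):
        out = []
        for i, psi in enumerate(psis):
            w = psi_to_inclusion_weight(psi)
            inc = round(depth * w)
            out.append(_event(f"e{i}", inc, depth - inc, exon=(i * 100, i * 100 + 50)))
        return out

    def test_printed_formula(self):
        events = self._events_from_psi([1.0, 0.0, 0.5, 0.995, 0.005], depth=100000)
        res = exon_commitment_score(events, min_depth=1)
        assert res.score == pytest.approx(0.8)

    def test_boundaries_are_strict(self):
        # I = 198, S = 1 gives psi = 0.99 exactly; I = 2, S = 99 gives 0.01
        hi = _event("hi", 198, 1, exon=(1, 50))
        lo = _event("lo", 2, 99, exon=(100, 150))
        assert hi.psi == 0.99 and lo.psi == 0.01
        res = exon_commitment_score([hi, lo], min_depth=1)
        assert res.score == 0.0

    def test_all_committed(self):
        events = self._events_from_psi([0.0, 1.0, 1.0], depth=100)
        assert exon_commitment_score(events, min_depth=1).score == 1.0

    def test_uncommitted_event_never_raises_score(self):
        base = self._events_from_psi([1.0, 0.0], depth=100)
        with_middle = base + self._events_from_psi([0.5], depth=100)
        with_middle[-1].exon = (900, 950)
        assert (
            exon_commitment_score(with_middle, min_depth=1).score
            <= exon_commitment_score(base, min_depth=1).score
        )

    def test_low_depth_events_excluded(self):
        events = self._events_from_psi([1.0], depth=5) + self._events_from_psi(
            [0.5], depth=100
        )
        events[-1].exon = (900, 950)
        res = exon_commitment_score(events, min_depth=10)
        assert res.n_total == 1 and res.score == 0.0

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            exon_commitment_score([], min_depth=1)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            psis = rng.uniform(0, 1, size=rng.integers(1, 30))
            events = self._events_from_psi(psis, depth=10**6)
            for i, ev in enumerate(events):
                ev.exon = (1000 * i, 1000 * i + 10)
            est = [ev.psi for ev in events]
            res = exon_commitment_score(events, min_depth=1)
            assert res.score == pytest.approx(commitment_oracle(est))


class TestDifferentialInclusion:
    def test_identical_proportions(self):
        d = differential_inclusion([_event("e", 10, 10)], [_event("e", 10, 10)])
        assert d[0].p_value == pytest.approx(1.0)
        assert d[0].inc_level_difference == 0.0

    def test_extreme_table_matches_enumeration(self):
        d = differential_inclusion([_event("e", 30, 0)], [_event("e", 0, 30)])
        assert d[0].inc_level_difference == pytest.approx(1.0)
        assert d[0].p_value == pytest.approx(float(fisher_two_sided_exact(30, 0, 0, 30)), rel=1e-9)

    @pytest.mark.parametrize("table", [(5, 3, 2, 7), (10, 0, 4, 6), (1, 19, 8, 12)])
    def test_fisher_matches_enumeration_small_tables(self, table):
        a, b, c, d = table
        res = differential_inclusion([_event("e", a, b)], [_event("e", c, d)])
        assert res[0].p_value == pytest.approx(float(fisher_two_sided_exact(a, b, c, d)), rel=1e-9)

    def test_unmatched_events_skipped(self):
        d = differential_inclusion([_event("x", 5, 5)], [_event("y", 5, 5)])
        assert d == []

    def test_bh_fdr_bounds(self):
        rng = np.random.default_rng(3)
        e1 = [_event(f"e{i}", int(rng.integers(5, 50)), int(rng.integers(5, 50))) for i in range(40)]
        e2 = [_event(f"e{i}", int(rng.integers(5, 50)), int(rng.integers(5, 50))) for i in range(40)]
        diffs = differential_inclusion(e1, e2)
        for d in diffs:
            assert d.fdr >= d.p_value - 1e-12


class TestPsiRecovery:
    def test_rmse_shrinks_with_depth(self):
        rng = np.random.default_rng(9)
        psi_true = 0.4
        w = psi_to_inclusion_weight(psi_true)

        def rmse(depth, reps=150):
            errs = []
            for _ in range(reps):
                inc = rng.binomial(depth, w)
                if inc + (depth - inc) == 0:
                    continue
                errs.append(exon_inclusion_level(inc, depth - inc) - psi_true)
            return float(np.sqrt(np.mean(np.square(errs))))

        assert rmse(400) < rmse(25)
        assert rmse(400) < 0.05
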