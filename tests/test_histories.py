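"""Gain-history enumeration and the allele-state spectrum map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaintimer.histories import (
    CNConfig,
    ConfigurationError,
    UnsupportedStateError,
    allele_states,
    enumerate_histories,
    expected_q,
    simplex_grid,
)

from conftest import timeable_states


# --- brute-force oracle: explicit copy-lineage duplication trees -----------


def _oracle_histories(cn: CNConfig) -> set:
    """Enumerate history matrices by brute force over explicit duplication
    trees: every ordering of "which copy duplicates next" is replayed, copy
    lineages are tracked in a genealogy, and the matrix is read off from the
    per-stage final-descendant counts.  Independent of the implementation's
    split-multiset recursion."""
    n_states = cn.n_states
    targets = {"M": cn.nt} if cn.nb == 0 else {"M": cn.major, "m": cn.nb}

    def all_event_orders():
        # event (a, i): the i-th current copy of allele a duplicates
        def rec(counts, log):
            if all(counts[a] == targets[a] for a in counts):
                yield tuple(log)
                return
            for a in sorted(counts):
                if counts[a] < targets[a]:
                    for i in range(counts[a]):
                        counts2 = dict(counts)
                        counts2[a] += 1
                        yield from rec(counts2, log + [(a, i)])

        yield from rec({a: 1 for a in targets}, [])

    mats = set()
    for order in all_event_orders():
        genealogy = {}
        current = {a: [(a, 0)] for a in targets}
        next_id = {a: 1 for a in targets}
        snapshots = [{a: list(current[a]) for a in current}]
        for (a, i) in order:
            child = (a, next_id[a])
            next_id[a] += 1
            genealogy[child] = current[a][i]
            current[a].append(child)
            snapshots.append({b: list(current[b]) for b in current})

        final = [c for a in current for c in current[a]]

        def ancestor_at(copy, alive):
            while copy not in alive:
                copy = genealogy[copy]
            return copy

        cols = []
        for snap in snapshots:
            alive = {c for a in snap for c in snap[a]}
            counts = {c: 0 for c in alive}
            for f in final:
                counts[ancestor_at(f, alive)] += 1
            col = [0] * n_states
            for k in counts.values():
                col[k - 1] += 1
            cols.append(tuple(col))
        mats.add(tuple(cols))

    return {tuple(np.array(m).T.flatten()) for m in mats}


# --- allele states ---------------------------------------------------------


@pytest.mark.parametrize(
    "cn,expected",
    [
        (CNConfig(5, 1), [1 / 5, 2 / 5, 3 / 5, 4 / 5]),
        (CNConfig(2, 0), [1 / 2, 1.0]),
        (CNConfig(6, 2), [1 / 6, 2 / 6, 3 / 6, 4 / 6]),
    ],
)
def test_allele_states_examples(cn, expected):
    np.testing.assert_allclose(allele_states(cn), expected)


def test_allele_states_properties():
    for cn in timeable_states():
        a = allele_states(cn)
        assert len(a) == cn.nt - cn.nb
        assert np.all(np.diff(a) > 0)
        assert a[-1] == pytest.approx((cn.nt - cn.nb) / cn.nt)


def test_non_timeable_states_rejected():
    assert not CNConfig(2, 1).timeable
    with pytest.raises(ConfigurationError):
        allele_states(CNConfig(2, 1))
    with pytest.raises(UnsupportedStateError):
        allele_states(CNConfig(8, 1))
    with pytest.raises(ConfigurationError):
        CNConfig(3, 2)  # minor above major


# --- enumeration -----------------------------------------------------------


def test_single_gain_history_is_unique():
    (h,) = enumerate_histories(CNConfig(3, 1))
    assert h.A.tolist() == [[1, 3], [1, 0]]
    (h20,) = enumerate_histories(CNConfig(2, 0))
    assert h20.A.tolist() == [[0, 2], [1, 0]]


def test_five_to_one_has_two_histories():
    assert len(enumerate_histories(CNConfig(5, 1))) == 2


def test_history_matrix_invariants():
    for cn in timeable_states():
        js = np.arange(1, cn.n_states + 1)
        for h in enumerate_histories(cn):
            s = h.s
            # stage k holds k+2 observable copies (k+1 under LOH)
            base = 1 if cn.nb == 0 else 2
            assert np.array_equal(s, np.arange(h.n_stages) + base)
            # every final copy has exactly one stage-k ancestor
            assert np.all(js @ h.A == cn.nt)
            # final stage: all copies produce single-state SSNVs
            assert h.A[0, -1] == s[-1]
            assert np.all(h.A[1:, -1] == 0)
            assert h.n_stages == cn.n_gains + 1


def test_enumeration_matches_lineage_oracle():
    """The split-multiset recursion agrees with explicit duplication trees."""
    for cn in timeable_states(max_cn=6):
        impl = {tuple(h.A.flatten()) for h in enumerate_histories(cn)}
        oracle = _oracle_histories(cn)
        assert impl == oracle, f"mismatch for {cn.nt}:{cn.nb}"


def test_histories_deduplicated():
    for cn in timeable_states():
        hs = enumerate_histories(cn)
        assert len(hs) == len(set(hs))


# --- expected_q ------------------------------------------------------------


@pytest.mark.parametrize(
    "cn,t,expected",
    [
        (CNConfig(3, 1), [0.0, 1.0], [1.0, 0.0]),
        (CNConfig(3, 1), [1.0, 0.0], [0.5, 0.5]),
    ],
)
def test_expected_q_examples(cn, t, expected):
    (h,) = enumerate_histories(cn)
    np.testing.assert_allclose(expected_q(h, np.array(t)), expected)


def test_expected_q_chain_history_all_lead_time():
    hs = enumerate_histories(CNConfig(5, 1))
    for h in hs:
        q = expected_q(h, np.array([0.0, 0.0, 0.0, 1.0]))
        np.testing.assert_allclose(q, [1, 0, 0, 0])


def test_expected_q_simplex_over_grid():
    for cn in timeable_states():
        hs = enumerate_histories(cn)
        grid = simplex_grid(hs[0].n_stages, 0.25)
        for h in hs:
            for t in grid:
                q = expected_q(h, t)
                assert np.all(q >= 0)
                assert q.sum() == pytest.approx(1.0)


def test_expected_q_monotone_in_lead_time():
    """More lead time -> single-state SSNVs dominate more."""
    for cn in (CNConfig(5, 1), CNConfig(6, 2), CNConfig(7, 0)):
        for h in enumerate_histories(cn):
            prev = -1.0
            for tK in (0.0, 0.25, 0.5, 0.75, 1.0):
                rest = (1 - tK) / (h.n_stages - 1)
                t = np.full(h.n_stages, rest)
                t[-1] = tK
                q1 = expected_q(h, t)[0]
                assert q1 > prev
                prev = q1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_spectrum_and_bound_invariants_hold_on_arbitrary_durations(data):
    """For any stage-duration vector, the spectrum is a distribution and the
    reported timing bounds never undercut the generating durations."""
    from gaintimer.timing import bounds_from_spectrum

    cn = data.draw(st.sampled_from(timeable_states(max_cn=6)))
    hs = enumerate_histories(cn)
    A = data.draw(st.sampled_from(hs))
    weights = data.draw(
        st.lists(st.integers(0, 8), min_size=A.n_stages, max_size=A.n_stages)
        .filter(lambda w: sum(w) > 0)
    )
    t = np.asarray(weights, dtype=float)
    t /= t.sum()
    q = expected_q(A, t)
    assert q.sum() == pytest.approx(1.0)
    assert np.all(q >= 0)
    bounds, _ = bounds_from_spectrum(hs, q)
    assert bounds["tK"] >= t[-1] - 1e-6
    assert bounds["t0"] >= t[0] - 1e-6


def test_expected_q_degenerate_t_rejected():
    (h,) = enumerate_histories(CNConfig(3, 1))
    with pytest.raises(ValueError):
        expected_q(h, np.zeros(2))
    with pytest.raises(ValueError):
        expected_q(h, np.ones(3))
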