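"""Exact inversion, LP bounds and end-to-end segment timing."""

import numpy as np
import pandas as pd
import pytest

from gaintimer.allele_em import InsufficientDataError, SampleMeta, SSNVTable
from gaintimer.benchmark import SimConfig, simulate_ssnvs
from gaintimer.histories import (
    CNConfig,
    ConfigurationError,
    TimeFractions,
    UnsupportedStateError,
    enumerate_histories,
    expected_q,
    simplex_grid,
)
from gaintimer.timing import (
    INVERTIBLE_STATES,
    LPOptions,
    SingularHistoryError,
    TimingEstimate,
    TimingOptions,
    bounds_from_spectrum,
    classify_gain,
    lp_upper_bound,
    merge_identical_segments,
    solve_exact,
    time_segment,
)

from conftest import timeable_states


# --- solve_exact -----------------------------------------------------------


def test_exact_solution_examples():
    (h,) = enumerate_histories(CNConfig(3, 1))
    np.testing.assert_allclose(solve_exact(h, np.array([1.0, 0.0])).t, [0, 1], atol=1e-12)
    np.testing.assert_allclose(solve_exact(h, np.array([0.5, 0.5])).t, [1, 0], atol=1e-12)
    assert solve_exact(h, np.array([0.0, 1.0])) is None  # raw t = (1.5, -0.5)


def test_exact_requires_invertible_history():
    hs = enumerate_histories(CNConfig(5, 1))
    singular = [h for h in hs if abs(np.linalg.det(h.A.astype(float))) < 1e-9]
    assert singular  # one of the two 5:1 histories is singular
    with pytest.raises(SingularHistoryError):
        solve_exact(singular[0], np.array([0.25, 0.25, 0.25, 0.25]))


def test_exact_roundtrip_on_invertible_states(rng):
    for nt, nb in sorted(INVERTIBLE_STATES):
        (h,) = enumerate_histories(CNConfig(nt, nb))
        for _ in range(20):
            t_true = rng.dirichlet(np.ones(h.n_stages))
            q = expected_q(h, t_true)
            sol = solve_exact(h, q)
            np.testing.assert_allclose(sol.t, t_true, atol=1e-9)


# --- LP --------------------------------------------------------------------


def test_lp_examples():
    hs5 = enumerate_histories(CNConfig(5, 1))
    _, v, slack = lp_upper_bound(hs5[0], np.array([1.0, 0, 0, 0]), LPOptions("tK"))
    assert v == pytest.approx(1.0)
    assert slack == pytest.approx(0.0, abs=1e-9)

    (h31,) = enumerate_histories(CNConfig(3, 1))
    _, v, slack = lp_upper_bound(h31, np.array([0.5, 0.5]), LPOptions("tK"))
    assert v == pytest.approx(0.0, abs=1e-9)

    q = expected_q(hs5[0], np.array([0.25, 0.25, 0.25, 0.25]))
    _, v, slack = lp_upper_bound(hs5[0], q, LPOptions("tK"))
    assert v >= 0.25 - 1e-9
    assert slack == pytest.approx(0.0, abs=1e-8)


def test_lp_matches_exact_on_invertible_states(rng):
    for nt, nb in sorted(INVERTIBLE_STATES):
        (h,) = enumerate_histories(CNConfig(nt, nb))
        for _ in range(25):
            q = expected_q(h, rng.dirichlet(np.ones(h.n_stages)))
            sol = solve_exact(h, q)
            for obj, idx in (("t0", 0), ("tK", -1)):
                _, v, _ = lp_upper_bound(h, q, LPOptions(obj))
                assert v == pytest.approx(sol.t[idx], abs=1e-6)


def test_custom_simplex_agrees_with_highs(rng):
    """The compiled solver and scipy's HiGGS agree on the penalized optimum."""
    for cn in (CNConfig(5, 1), CNConfig(6, 2), CNConfig(7, 0)):
        hs = enumerate_histories(cn)
        for _ in range(20):
            h = hs[rng.integers(len(hs))]
            q = rng.dirichlet(np.ones(cn.n_states))
            for obj in ("t0", "tK"):
                _, v1, s1 = lp_upper_bound(h, q, LPOptions(obj), method="simplex")
                _, v2, s2 = lp_upper_bound(h, q, LPOptions(obj), method="highs")
                assert v1 - 100 * s1 == pytest.approx(v2 - 100 * s2, abs=1e-7)


def test_upper_bound_guarantee_sample(rng):
    """Noise-free spectra can never beat their own true stage durations.

    (The exhaustive sweep over every state, history and lattice point runs in
    the acceptance suite; this spot-checks random simplex points.)
    """
    for cn in (CNConfig(6, 1), CNConfig(6, 2), CNConfig(7, 3)):
        hs = enumerate_histories(cn)
        for _ in range(10):
            h = hs[rng.integers(len(hs))]
            t_true = rng.dirichlet(np.ones(h.n_stages))
            q = expected_q(h, t_true)
            bounds, _ = bounds_from_spectrum(hs, q)
            assert bounds["tK"] >= t_true[-1] - 1e-6
            assert bounds["t0"] >= t_true[0] - 1e-6


# --- time_segment ----------------------------------------------------------


def test_time_segment_recovers_late_gain():
    cn = CNConfig(6, 1)
    hs = enumerate_histories(cn)
    t_true = TimeFractions(np.array([0.04, 0.02, 0.02, 0.02, 0.9]))
    table = simulate_ssnvs(SimConfig(A=hs[0], t=t_true, M=100, P=1.0,
                                     mean_depth=100, seed=5))
    est = time_segment(table, cn, SampleMeta(1.0),
                       TimingOptions(bootstrap=100, seed=2))
    assert 0.8 <= est.tK_upper <= 1.0
    assert est.tK_ci[0] <= 0.9 <= est.tK_ci[1]
    assert est.n_ssnv == 100
    assert len(est.per_matrix) == 2 * len(hs)


def test_time_segment_skip_reasons():
    meta = SampleMeta(1.0)
    small = SSNVTable.from_counts(m=[5] * 5, d=[10] * 5)
    with pytest.raises(InsufficientDataError, match="5 SSNVs"):
        time_segment(small, CNConfig(5, 1), meta, TimingOptions(bootstrap=0))
    table = SSNVTable.from_counts(m=[5] * 20, d=[10] * 20)
    with pytest.raises(ConfigurationError):
        time_segment(table, CNConfig(2, 1), meta, TimingOptions(bootstrap=0))
    with pytest.raises(UnsupportedStateError):
        time_segment(table, CNConfig(8, 1), meta, TimingOptions(bootstrap=0))


def test_bootstrap_ci_brackets_point_estimate():
    cn = CNConfig(5, 1)
    hs = enumerate_histories(cn)
    t_true = TimeFractions(np.array([0.3, 0.2, 0.2, 0.3]))
    table = simulate_ssnvs(SimConfig(A=hs[0], t=t_true, M=150, P=0.8,
                                     mean_depth=120, seed=9))
    est = time_segment(table, cn, SampleMeta(0.8),
                       TimingOptions(bootstrap=100, seed=3))
    lo, hi = est.tK_ci
    assert lo <= hi
    assert 0.0 <= lo and hi <= 1.0


def test_ci_width_shrinks_with_more_ssnvs(rng):
    cn = CNConfig(6, 1)
    hs = enumerate_histories(cn)
    # paired design: the same histories and stage durations at every M
    draws = []
    for rep in range(12):
        A = hs[rng.integers(len(hs))]
        draws.append((A, TimeFractions(rng.dirichlet(np.ones(A.n_stages)))))
    widths = []
    for M in (20, 50, 100):
        w = []
        for rep, (A, t) in enumerate(draws):
            table = simulate_ssnvs(SimConfig(A=A, t=t, M=M,
                                             P=1.0, mean_depth=100), rng)
            est = time_segment(table, cn, SampleMeta(1.0),
                               TimingOptions(bootstrap=60, seed=rep))
            w.append(est.tK_ci[1] - est.tK_ci[0])
        widths.append(np.median(w))
    assert widths[0] > widths[1] > widths[2]


# --- classification and pooling -------------------------------------------


def _estimate(t0, tK):
    return TimingEstimate(segment_id="s", cn=CNConfig(3, 1), n_ssnv=50,
                          t0_upper=t0, tK_upper=tK)


@pytest.mark.parametrize(
    "t0,tK,label",
    [
        (0.6, 0.1, "late"),
        (0.1, 0.6, "early"),
        (0.5, 0.5, "intermediate"),
        (0.1, 0.1, "both"),
        (0.2, 0.2, "both"),  # boundary inclusive
    ],
)
def test_classify_gain(t0, tK, label):
    assert classify_gain(_estimate(t0, tK)) == label


def test_merge_identical_segments():
    segs = pd.DataFrame({
        "chrom": ["1", "1", "1", "2"],
        "start": [100, 20_000, 900_000, 100],
        "end": [10_000, 500_000, 1_200_000, 5_000],
        "nt": [5, 5, 5, 5],
        "nb": [1, 1, 0, 1],
    })
    merged = merge_identical_segments(segs, max_gap=1_000_000)
    assert len(merged) == 3  # first two pool; 5:0 and chr2 stay
    pooled = merged.iloc[0]
    assert pooled.start == 100 and pooled.end == 500_000
    assert len(pooled.members) == 2

    ssnvs = {
        "1:100-10000": SSNVTable.from_counts(m=[3] * 4, d=[10] * 4),
        "1:20000-500000": SSNVTable.from_counts(m=[4] * 6, d=[10] * 6),
    }
    merged2, pooled_ssnvs = merge_identical_segments(segs, ssnvs,
                                                     max_gap=1_000_000)
    assert len(pooled_ssnvs[merged2.iloc[0].segment_id]) == 10


def test_merge_rejects_overlap_and_handles_empty():
    segs = pd.DataFrame({
        "chrom": ["1", "1"], "start": [100, 5_000], "end": [10_000, 20_000],
        "nt": [5, 5], "nb": [1, 1],
    })
    with pytest.raises(ValueError, match="overlap"):
        merge_identical_segments(segs)
    empty = merge_identical_segments(segs.iloc[:0])
    assert empty.empty
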