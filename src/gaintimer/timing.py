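"""Upper bounds on initiation and lead time of copy-number gains.

For a history matrix ``A`` with stage copy counts ``s`` and an allele-state
spectrum ``q``, the stage durations satisfy ``A t / (s . t) = q``, i.e.
``(A - q s^T) t = 0`` together with the simplex constraints.  For single and
double gains (2:0, 3:1, 3:0, 4:1) ``A`` is unique and invertible and the
system solves exactly; otherwise it is underdetermined and the initiation
time ``t_0`` and lead time ``t_K`` are bounded from above by maximizing each
via linear programming, relaxed by slack variables (penalty 100 per unit) to
tolerate noise in the estimated spectrum.  The bound for a copy-number state
is the maximum over all of its history matrices; confidence intervals come
from a percentile bootstrap over SSNV records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linprog

from .allele_em import EMOptions, SampleMeta, SSNVTable, em_allele_distribution
from .histories import CNConfig, HistoryMatrix, TimeFractions, enumerate_histories

logger = logging.getLogger("gaintimer")

__all__ = [
    "LPOptions",
    "TimingOptions",
    "PerMatrixRecord",
    "TimingEstimate",
    "SingularHistoryError",
    "solve_exact",
    "lp_upper_bound",
    "bounds_from_spectrum",
    "time_segment",
    "classify_gain",
    "merge_identical_segments",
    "INVERTIBLE_STATES",
]

#: Copy-number states whose (unique) history matrix is invertible, allowing a
#: direct solve: single gains 2:0 and 3:1, double gains 3:0 and 4:1.
INVERTIBLE_STATES = frozenset({(2, 0), (3, 1), (3, 0), (4, 1)})


class SingularHistoryError(np.linalg.LinAlgError):
    """Raised when an exact solve is requested for a singular history matrix."""


@dataclass(frozen=True)
class LPOptions:
    objective: str = "tK"            # "tK" (lead time) or "t0" (initiation)
    slack_penalty: float = 100.0     # per-unit cost of constraint violation
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.objective not in ("t0", "tK"):
            raise ValueError("objective must be 't0' or 'tK'")
        if self.slack_penalty <= 0:
            raise ValueError("slack penalty must be positive")


@dataclass(frozen=True)
class TimingOptions:
    min_ssnv: int = 10
    bootstrap: int = 200             # bootstrap replicates (0 disables the CI)
    ci_level: float = 0.95
    slack_penalty: float = 100.0
    em: EMOptions = field(default_factory=EMOptions)
    seed: int | None = None


@dataclass(frozen=True)
class PerMatrixRecord:
    """LP outcome for a single history matrix and objective."""

    objective: str
    value: float
    total_slack: float
    feasible: bool                    # total slack within tolerance


@dataclass
class TimingEstimate:
    segment_id: str
    cn: CNConfig
    n_ssnv: int
    t0_upper: float
    tK_upper: float
    t0_ci: tuple[float, float] | None = None
    tK_ci: tuple[float, float] | None = None
    per_matrix: list[PerMatrixRecord] = field(default_factory=list)
    q: np.ndarray | None = None

    @property
    def arrival(self) -> float:
        return 1.0 - self.tK_upper


def solve_exact(A: HistoryMatrix, q: np.ndarray, tol: float = 1e-9) -> TimeFractions | None:
    """Directly invert ``t = c A^{-1} q`` with ``c`` fixed by ``sum(t) = 1``.

    Returns ``None`` when the algebraic solution leaves the simplex (any
    component below ``-tol``), signalling that the spectrum is not exactly
    realizable under this history.
    """
    mat = A.A.astype(float)
    if mat.shape[0] != mat.shape[1]:
        raise SingularHistoryError(
            "history matrix is not square; use the linear-programming bound"
        )
    if abs(np.linalg.det(mat)) < 1e-12:
        raise SingularHistoryError(
            "history matrix is singular; use the linear-programming bound"
        )
    raw = np.linalg.solve(mat, np.asarray(q, dtype=float))
    total = raw.sum()
    if abs(total) < 1e-12:
        return None
    t = raw / total
    if np.any(t < -tol):
        return None
    return TimeFractions(np.clip(t, 0.0, None) / np.clip(t, 0.0, None).sum())


@njit(cache=False)
def _simplex_min(A_full, b, c, max_iter=20_000):
    """Bland's-rule tableau simplex for ``min c.x, A x = b, x >= 0``.

    Expects a starting basis already encoded: ``A_full``/``b`` are passed in
    raw form together with a basis index per row (returned by the caller via
    the canonicalization below).  Kept tiny on purpose: the timing LPs have
    at most 7 rows and 19 variables, and this runs orders of magnitude
    faster than a general-purpose solver across the exhaustive history x
    spectrum sweeps.

    Returns (status, x) with status 0 = optimal, 1 = iteration cap,
    2 = unbounded.
    """
    m, n = A_full.shape
    T = np.empty((m, n + 1))
    T[:, :n] = A_full
    T[:, n] = b
    basis = np.empty(m, dtype=np.int64)

    # starting basis: t_0 covers the simplex row (last), and per constraint
    # row one of the slack pair, chosen so the tableau is feasible
    last = m - 1
    # eliminate t_0 (column 0) from constraint rows using the simplex row
    for i in range(last):
        f = T[i, 0]
        if f != 0.0:
            for j in range(n + 1):
                T[i, j] -= f * T[last, j]
    basis[last] = 0
    S = n - 2 * (m - 1)  # number of t variables
    for i in range(last):
        if T[i, n] >= 0.0:
            basis[i] = S + i              # u+ basic (coefficient +1)
        else:
            for j in range(n + 1):        # flip so b >= 0; u- becomes +1
                T[i, j] = -T[i, j]
            basis[i] = S + (m - 1) + i    # u- basic

    tol = 1e-9
    it = 0
    while it < max_iter:
        it += 1
        # reduced costs r_j = c_j - c_B . T[:, j]
        enter = -1
        for j in range(n):
            r = c[j]
            for i in range(m):
                r -= c[basis[i]] * T[i, j]
            if r < -tol:
                enter = j
                break  # Bland: smallest index
        if enter < 0:
            x = np.zeros(n)
            for i in range(m):
                x[basis[i]] = T[i, n]
            return 0, x
        # ratio test with Bland tie-break (smallest basis index)
        leave = -1
        best = 0.0
        for i in range(m):
            if T[i, enter] > tol:
                ratio = T[i, n] / T[i, enter]
                if leave < 0 or ratio < best - 1e-12 or (
                    abs(ratio - best) <= 1e-12 and basis[i] < basis[leave]
                ):
                    leave = i
                    best = ratio
        if leave < 0:
            return 2, np.zeros(n)
        piv = T[leave, enter]
        for j in range(n + 1):
            T[leave, j] /= piv
        for i in range(m):
            if i != leave and T[i, enter] != 0.0:
                f = T[i, enter]
                for j in range(n + 1):
                    T[i, j] -= f * T[leave, j]
        basis[leave] = enter
    return 1, np.zeros(n)


def lp_upper_bound(
    A: HistoryMatrix, q: np.ndarray, opts: LPOptions = LPOptions(), method: str = "simplex"
) -> tuple[np.ndarray, float, float]:
    """Maximize a stage duration subject to the spectrum constraints.

        max  t_obj - penalty * sum(u+ + u-)
        s.t. (A - q s^T) t + u+ - u- = 0,   1 . t = 1,   t, u+, u- >= 0

    Returns ``(t*, attained objective component, total slack)``.  The default
    solver is the package's compiled Bland's-rule simplex (these LPs have at
    most 7 rows); ``method="highs"`` routes through scipy instead and is used
    as an independent cross-check.
    """
    mat = A.A.astype(float)
    J, S = mat.shape
    qv = np.asarray(q, dtype=float)
    if qv.size != J:
        raise ValueError(f"q has length {qv.size}, expected {J}")
    s = mat.sum(axis=0)

    B = mat - np.outer(qv, s)            # J x S equality block
    n_var = S + 2 * J                    # t, slack+, slack-
    c = np.zeros(n_var)
    c[0 if opts.objective == "t0" else S - 1] = -1.0
    c[S:] = opts.slack_penalty

    A_eq = np.zeros((J + 1, n_var))
    A_eq[:J, :S] = B
    A_eq[:J, S : S + J] = np.eye(J)
    A_eq[:J, S + J :] = -np.eye(J)
    A_eq[J, :S] = 1.0
    b_eq = np.zeros(J + 1)
    b_eq[J] = 1.0

    if method == "simplex":
        status, x = _simplex_min(A_eq, b_eq, c)
        if status != 0:  # pragma: no cover - bounded non-degenerate family
            raise RuntimeError(f"simplex solver failed with status {status}")
    elif method == "highs":
        res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
        if not res.success:  # pragma: no cover
            raise RuntimeError(f"LP solver failed: {res.status} {res.message}")
        x = res.x
    else:
        raise ValueError(f"unknown LP method {method!r}")
    t = x[:S]
    slack = float(x[S:].sum())
    value = float(t[0] if opts.objective == "t0" else t[-1])
    return t, value, slack


def bounds_from_spectrum(
    histories, q, slack_penalty: float = 100.0
) -> tuple[dict[str, float], list[PerMatrixRecord]]:
    """Upper bounds of ``t0`` and ``tK`` for a known allele-state spectrum.

    Per objective, every history matrix is solved by the slack-relaxed LP and
    histories are compared on the penalized objective
    ``value - penalty * slack``: a history that can only accommodate the
    spectrum by violating its constraints is disfavored even if the violation
    buys a larger stage duration.  The reported bound is the attained stage
    duration of the winning history (ties go to the larger value).  On a
    noise-free spectrum the generating history has zero slack, so the winner's
    value can never drop below the true duration and the result is a genuine
    upper bound.
    """
    out = {}
    records = []
    for obj in ("t0", "tK"):
        opts = LPOptions(objective=obj, slack_penalty=slack_penalty)
        best_pen = -np.inf
        best_val = -np.inf
        for h in histories:
            _, value, slack = lp_upper_bound(h, q, opts)
            records.append(
                PerMatrixRecord(objective=obj, value=value, total_slack=slack,
                                feasible=slack <= 1e-6)
            )
            pen = value - opts.slack_penalty * slack
            if pen > best_pen + 1e-12 or (pen > best_pen - 1e-12 and value > best_val):
                best_pen = pen
                best_val = value
        out[obj] = best_val
    return out, records


def time_segment(
    ssnvs: SSNVTable,
    cn: CNConfig,
    meta: SampleMeta,
    opts: TimingOptions = TimingOptions(),
    segment_id: str = "segment",
) -> TimingEstimate:
    """Upper-bound the initiation and lead time of one gained segment.

    Runs the allele-state EM, then for every enumerated history maximizes
    ``t_0`` and ``t_K`` by LP; the reported upper bound is the maximum across
    histories.  Percentile bootstrap CIs resample SSNV records and repeat the
    whole EM + LP pipeline.
    """
    cn.validate_supported()
    em_opts = replace(opts.em, min_ssnv=opts.min_ssnv)
    est = em_allele_distribution(ssnvs, cn, meta, em_opts)
    histories = enumerate_histories(cn)

    bounds, records = bounds_from_spectrum(histories, est.q, opts.slack_penalty)
    result = TimingEstimate(
        segment_id=segment_id,
        cn=cn,
        n_ssnv=len(ssnvs),
        t0_upper=bounds["t0"],
        tK_upper=bounds["tK"],
        per_matrix=records,
        q=est.q,
    )

    if opts.bootstrap > 0:
        rng = np.random.default_rng(opts.seed)
        n = len(ssnvs)
        t0_bs = np.empty(opts.bootstrap)
        tK_bs = np.empty(opts.bootstrap)
        for b in range(opts.bootstrap):
            idx = rng.integers(0, n, size=n)
            est_b = em_allele_distribution(ssnvs.subset(idx), cn, meta, em_opts)
            bounds_b, _ = bounds_from_spectrum(histories, est_b.q, opts.slack_penalty)
            t0_bs[b] = bounds_b["t0"]
            tK_bs[b] = bounds_b["tK"]
        alpha = 1.0 - opts.ci_level
        qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
        result.t0_ci = tuple(np.percentile(t0_bs, qs))
        result.tK_ci = tuple(np.percentile(tK_bs, qs))
    return result


def classify_gain(est: TimingEstimate, threshold: float = 0.2) -> str:
    """Label a gain by when it happened relative to truncal time.

    A gain is *late* when even the upper bound of its lead time puts it in the
    last ``threshold`` fraction of truncal evolution, *early* when the
    initiation-time bound puts its start in the first ``threshold`` fraction;
    *both* when the two hold together and *intermediate* otherwise.
    """
    late = est.tK_upper <= threshold
    early = est.t0_upper <= threshold
    if late and early:
        return "both"
    if late:
        return "late"
    if early:
        return "early"
    return "intermediate"


def merge_identical_segments(
    segments: pd.DataFrame,
    ssnvs: dict[str, SSNVTable] | None = None,
    max_gap: int = 1_000_000,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, SSNVTable]]:
    """Pool nearby segments sharing one copy-number state.

    Adjacent segments on a chromosome with identical ``(nt, nb)`` and a gap of
    at most ``max_gap`` bases are merged so their SSNVs can be timed jointly;
    the member segment ids are retained in a ``members`` column.  Expects
    columns chrom/start/end/nt/nb (+ optional segment_id), 1-based inclusive,
    sorted and non-overlapping per chromosome.  When ``ssnvs`` maps member
    segment ids to their SSNV tables, the member tables are concatenated per
    pooled segment (SSNVs in the gaps stay excluded) and returned alongside.
    """
    required = {"chrom", "start", "end", "nt", "nb"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"segments table missing columns: {sorted(missing)}")
    if segments.empty:
        out = segments.copy()
        out["members"] = pd.Series(dtype=object)
        return (out, {}) if ssnvs is not None else out
    segs = segments.copy()
    if "segment_id" not in segs.columns:
        segs["segment_id"] = [
            f"{c}:{s}-{e}" for c, s, e in zip(segs.chrom, segs.start, segs.end)
        ]
    segs = segs.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    prev_end = segs.groupby("chrom")["end"].shift()
    if ((segs["start"] <= prev_end).fillna(False)).any():
        raise ValueError("segments overlap within a chromosome")

    rows = []
    for _, chrom_df in segs.groupby("chrom", sort=False):
        current = None
        for rec in chrom_df.itertuples(index=False):
            if (
                current is not None
                and (rec.nt, rec.nb) == (current["nt"], current["nb"])
                and rec.start - current["end"] - 1 <= max_gap
            ):
                current["end"] = rec.end
                current["members"].append(rec.segment_id)
            else:
                if current is not None:
                    rows.append(current)
                current = {
                    "chrom": rec.chrom,
                    "start": rec.start,
                    "end": rec.end,
                    "nt": rec.nt,
                    "nb": rec.nb,
                    "members": [rec.segment_id],
                }
        if current is not None:
            rows.append(current)
    out = pd.DataFrame(rows)
    out["segment_id"] = ["+".join(m) for m in out["members"]]
    if ssnvs is None:
        return out
    pooled: dict[str, SSNVTable] = {}
    for rec in out.itertuples(index=False):
        tables = [ssnvs[m] for m in rec.members if m in ssnvs]
        if not tables:
            continue
        pooled[rec.segment_id] = SSNVTable(
            chrom=np.concatenate([t.chrom for t in tables]),
            pos=np.concatenate([t.pos for t in tables]),
            m=np.concatenate([t.m for t in tables]),
            d=np.concatenate([t.d for t in tables]),
        )
    return out, pooled
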