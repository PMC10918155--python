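"""Gain-history matrices for clonal copy-number gains.

A clonal gained segment with allele-specific copy number ``nt:nb`` (total and
minor copy number) is reached from the germline 1:1 state through a sequence of
``K`` single-copy duplications, partitioning truncal evolution into ``K + 1``
stages with time fractions ``t = (t_0, ..., t_K)``, ``sum(t) = 1``.  An SSNV
acquired in stage ``k`` on a copy that leaves ``j`` descendant copies in the
final state is observed at allele state (multiplicity) ``j``.  The history
matrix ``A`` records, for every stage ``k``, how many observable copies leave
``j`` final descendants; the expected allele-state spectrum of SSNVs is then
``q = A t / (s . t)`` where ``s`` holds the per-stage copy numbers.

Several duplication orderings can share one matrix, and several matrices can
realize the same final copy-number state; :func:`enumerate_histories` returns
the full deduplicated set, which downstream timing maximizes over.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CNConfig",
    "HistoryMatrix",
    "TimeFractions",
    "ConfigurationError",
    "UnsupportedStateError",
    "allele_states",
    "enumerate_histories",
    "expected_q",
    "simplex_grid",
]

#: Largest supported total copy number.  Higher states tend to keep evolving
#: (e.g. on extrachromosomal DNA) and break the fixed-history assumption.
MAX_TOTAL_CN = 7


class ConfigurationError(ValueError):
    """Raised for copy-number states the timing model cannot handle."""


class UnsupportedStateError(ConfigurationError):
    """Raised for total copy number above :data:`MAX_TOTAL_CN`."""


@dataclass(frozen=True, order=True)
class CNConfig:
    """Allele-specific copy-number state of a clonal gained segment.

    Parameters
    ----------
    nt
        Total copy number (2..7).
    nb
        Minor-allele copy number, ``0 <= nb <= nt - nb``.  ``nb == 0`` is
        loss of heterozygosity (LOH).
    """

    nt: int
    nb: int

    def __post_init__(self) -> None:
        if not (isinstance(self.nt, (int, np.integer)) and isinstance(self.nb, (int, np.integer))):
            raise ConfigurationError(f"copy numbers must be integers, got {self.nt}:{self.nb}")
        if self.nt < 2 or self.nb < 0:
            raise ConfigurationError(f"invalid copy-number state {self.nt}:{self.nb}")
        if self.nb > self.nt - self.nb:
            raise ConfigurationError(
                f"minor copy number exceeds major in {self.nt}:{self.nb}; "
                "pass the state as total:minor with minor <= major"
            )

    @property
    def major(self) -> int:
        return self.nt - self.nb

    @property
    def timeable(self) -> bool:
        """Whether SSNV multiplicities carry timing signal.

        Requires at least one gain producing multiplicity >= 2: any state with
        ``nt - nb >= 2``, plus copy-neutral LOH 2:0.  The diploid 2:1 state has
        no gain and is never timeable.
        """
        return self.major >= 2 or (self.nt, self.nb) == (2, 0)

    @property
    def n_states(self) -> int:
        """Number of possible allele states (multiplicities 1..major)."""
        return self.major

    @property
    def n_gains(self) -> int:
        """Number of single-copy gain events K separating the K+1 stages."""
        if self.nb == 0:
            return self.nt - 1
        return (self.major - 1) + (self.nb - 1)

    def validate_supported(self) -> None:
        if self.nt > MAX_TOTAL_CN:
            raise UnsupportedStateError(
                f"total copy number {self.nt} exceeds supported maximum {MAX_TOTAL_CN}"
            )
        if not self.timeable:
            raise ConfigurationError(f"copy-number state {self.nt}:{self.nb} is not timeable")


@dataclass(frozen=True)
class HistoryMatrix:
    """One gain history of a copy-number state.

    ``A[j-1, k]`` is the number of copies observable in stage ``k`` whose
    descendants in the final state number ``j`` (so stage-``k`` SSNVs on those
    copies end at allele state ``j``).  ``s[k] = A[:, k].sum()`` is the number
    of observable copies in stage ``k``.
    """

    cn: CNConfig
    A: np.ndarray = field(compare=False)
    _key: tuple = field(repr=False)

    @classmethod
    def from_array(cls, cn: CNConfig, A: np.ndarray) -> "HistoryMatrix":
        A = np.asarray(A, dtype=np.int64)
        A.setflags(write=False)
        return cls(cn=cn, A=A, _key=(cn.nt, cn.nb, A.tobytes()))

    def __hash__(self) -> int:
        return hash(self._key)

    def __eq__(self, other) -> bool:
        return isinstance(other, HistoryMatrix) and self._key == other._key

    @property
    def n_stages(self) -> int:
        return self.A.shape[1]

    @property
    def s(self) -> np.ndarray:
        """Per-stage observable copy counts (column sums of ``A``)."""
        return self.A.sum(axis=0)


@dataclass(frozen=True)
class TimeFractions:
    """Stage durations as fractions of truncal time; ``t0`` is the initiation
    time, the last entry ``tK`` the lead time, and ``1 - tK`` the arrival
    time."""

    t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("t must be a 1-D vector")
        if np.any(t < -1e-12):
            raise ValueError("stage durations must be non-negative")
        if abs(t.sum() - 1.0) > 1e-8:
            raise ValueError("stage durations must sum to 1")
        object.__setattr__(self, "t", t)

    @property
    def t0(self) -> float:
        return float(self.t[0])

    @property
    def tK(self) -> float:
        return float(self.t[-1])


def allele_states(cn: CNConfig) -> np.ndarray:
    """Possible SSNV allele states ``j / nt`` for ``j = 1..(nt - nb)``.

    The largest multiplicity is bounded by the major-allele copy number: the
    two parental alleles never merge, so no variant can sit on more than
    ``nt - nb`` copies.
    """
    cn.validate_supported()
    return np.arange(1, cn.n_states + 1) / cn.nt


# ---------------------------------------------------------------------------
# History enumeration
#
# A history is generated stage by stage as a pair of multisets of final
# descendant counts, one per parental allele.  A gain duplicates one copy:
# in descendant-count terms a copy carrying c >= 2 final descendants splits
# into two copies carrying c1 + c2 = c.  Every duplication tree induces such
# a split sequence and every split sequence is realized by some tree, so
# enumerating split sequences (and deduplicating matrices) covers all gain
# orderings, including interleavings of major- and minor-allele gains.
# ---------------------------------------------------------------------------


def _splits(c: int):
    """Unordered ways to split a descendant count c into two positive parts."""
    return [(c1, c - c1) for c1 in range(1, c // 2 + 1)]


def _stage_column(major: tuple, minor: tuple, n_states: int) -> tuple:
    col = [0] * n_states
    for c in itertools.chain(major, minor):
        col[c - 1] += 1
    return tuple(col)


def enumerate_histories(cn: CNConfig) -> list[HistoryMatrix]:
    """All distinct history matrices for a copy-number state.

    For LOH states (``nb == 0``) only the retained allele is modeled: the lost
    allele's SSNVs are unobservable, so stage 0 (one observable copy destined
    for ``nt`` descendants) absorbs both the pre-loss and the post-loss,
    pre-gain time, and the retained copy climbs ``1 -> nt`` through ``nt - 1``
    gains.  The loss is taken to precede all gains.

    Returns the matrices sorted by a stable byte key; the set is deduplicated
    so that orderings permuting symmetric copies collapse.
    """
    cn.validate_supported()
    n_states = cn.n_states
    n_cols = cn.n_gains + 1

    if cn.nb == 0:
        init = ((cn.nt,), ())
    else:
        init = ((cn.major,), (cn.nb,) * 1)

    seen: dict[tuple, np.ndarray] = {}

    def recurse(major: tuple, minor: tuple, cols: tuple) -> None:
        if len(cols) == n_cols:
            key = cols
            if key not in seen:
                A = np.array(cols, dtype=np.int64).T
                seen[key] = A
            return
        # split one copy on either allele
        for which, counts in (("M", major), ("m", minor)):
            done = set()
            for i, c in enumerate(counts):
                if c < 2 or c in done:
                    continue
                done.add(c)
                rest = counts[:i] + counts[i + 1 :]
                for c1, c2 in _splits(c):
                    new = tuple(sorted(rest + (c1, c2)))
                    nmaj, nmin = (new, minor) if which == "M" else (major, new)
                    recurse(nmaj, nmin, cols + (_stage_column(nmaj, nmin, n_states),))

    first_col = _stage_column(init[0], init[1], n_states)
    recurse(init[0], init[1], (first_col,))

    mats = [HistoryMatrix.from_array(cn, A) for _, A in sorted(seen.items())]
    return mats


def expected_q(A: HistoryMatrix | np.ndarray, t: TimeFractions | np.ndarray) -> np.ndarray:
    """Expected allele-state spectrum ``q = A t / (s . t)``.

    The chance that a random truncal SSNV arises in stage ``k`` on a copy
    destined for multiplicity ``j`` is proportional to ``A[j,k] * t[k]``; the
    normalizer ``c = s . t`` is the copy-time total.
    """
    mat = A.A if isinstance(A, HistoryMatrix) else np.asarray(A)
    tv = t.t if isinstance(t, TimeFractions) else np.asarray(t, dtype=float)
    if tv.ndim != 1 or tv.size != mat.shape[1]:
        raise ValueError(f"t has length {tv.size}, expected {mat.shape[1]}")
    c = float(mat.sum(axis=0) @ tv)
    if c <= 0:
        raise ValueError("degenerate stage durations: copy-time normalizer is zero")
    return (mat @ tv) / c


def simplex_grid(dim: int, step: float = 0.25) -> np.ndarray:
    """Lattice of points on the probability simplex with the given step.

    Used for exhaustive checks of the upper-bound guarantee over all true
    stage-duration vectors.
    """
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    pts = []
    for comp in itertools.combinations_with_replacement(range(dim), n):
        v = np.zeros(dim)
        for i in comp:
            v[i] += step
        pts.append(v)
    return np.unique(np.array(pts), axis=0)
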