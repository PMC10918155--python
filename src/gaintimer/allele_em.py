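"""Allele-state spectrum estimation from SSNV read counts.

Given the clonal SSNVs inside a gained segment, with mutant read counts
``m_i`` out of depth ``d_i``, tumor purity ``P`` and the segment copy-number
state ``nt:nb``, the latent quantity of interest is the vector ``q`` over
allele states ``j = 1..(nt-nb)``: the probability that a random truncal SSNV
in the region sits on ``j`` copies.  Reads from an SSNV at state ``j`` are
binomial with success probability equal to the purity-adjusted variant allele
fraction; conditioning on the variant having been detected at all removes the
zero-read mass.  ``q`` is fitted by maximizing the detection-conditioned
mixture log-likelihood

    sum_i log( sum_j q_j Pr(m_i | f_j) / sum_j q_j Pr(detect_i | f_j) )

with a minorize-maximize scheme that reduces to classical EM when detection
is certain and increases the objective at every iterate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .histories import CNConfig

__all__ = [
    "SSNVTable",
    "SampleMeta",
    "AlleleStateDistribution",
    "EMOptions",
    "InsufficientDataError",
    "expected_vaf",
    "em_allele_distribution",
]


class InsufficientDataError(ValueError):
    """Raised when a segment has too few detected SSNVs to estimate q."""


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: tumor purity ``P`` in (0, 1]; SSNV loci are
    assumed diploid (copy number 2) in contaminating normal cells."""

    purity: float
    normal_cn: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")


@dataclass
class SSNVTable:
    """Read counts of detected clonal SSNVs in one segment.

    ``m`` holds mutant-allele depths (all >= 1: an undetected variant carries
    no information under the detection-conditioned likelihood and is rejected
    at ingest), ``d`` total depths.
    """

    chrom: np.ndarray
    pos: np.ndarray
    m: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=np.int64)
        n = len(self.m)
        if not (len(self.chrom) == len(self.pos) == len(self.d) == n):
            raise ValueError("SSNV columns have mismatched lengths")
        if np.any(self.m < 1):
            raise ValueError("mutant read counts must be >= 1 (undetected SSNVs rejected)")
        if np.any(self.d < self.m):
            raise ValueError("total depth must be >= mutant depth")

    def __len__(self) -> int:
        return len(self.m)

    @classmethod
    def from_counts(cls, m, d) -> "SSNVTable":
        m = np.asarray(m, dtype=np.int64)
        return cls(chrom=np.repeat(".", len(m)), pos=np.arange(1, len(m) + 1), m=m, d=d)

    def subset(self, idx) -> "SSNVTable":
        return SSNVTable(chrom=self.chrom[idx], pos=self.pos[idx], m=self.m[idx], d=self.d[idx])


@dataclass(frozen=True)
class AlleleStateDistribution:
    """Fitted allele-state spectrum with the attained log-likelihood."""

    q: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    cn: CNConfig


@dataclass(frozen=True)
class EMOptions:
    min_ssnv: int = 10          # segments below this are not timed
    tol: float = 1e-8           # |delta loglik| stopping rule
    max_iter: int = 2000
    detection_min_reads: int = 1  # detection means m >= this


def expected_vaf(j: int | np.ndarray, cn: CNConfig, meta: SampleMeta) -> float | np.ndarray:
    """Expected variant-allele fraction of an SSNV on ``j`` of ``nt`` copies.

    Mutant reads come only from tumor cells (``j`` copies each), while total
    reads mix ``nt`` tumor copies with 2 normal copies:
    ``f = j P / (nt P + 2 (1 - P))``.
    """
    j_arr = np.asarray(j)
    if np.any(j_arr < 1) or np.any(j_arr > cn.n_states):
        raise ValueError(f"allele state out of range 1..{cn.n_states}")
    P = meta.purity
    f = j_arr * P / (cn.nt * P + meta.normal_cn * (1.0 - P))
    return float(f) if np.isscalar(j) else f


def _mixture_terms(ssnvs: SSNVTable, cn: CNConfig, meta: SampleMeta, opts: EMOptions):
    """Per-record component likelihoods and detection probabilities."""
    f = expected_vaf(np.arange(1, cn.n_states + 1), cn, meta)
    d = ssnvs.d[:, None]
    m = ssnvs.m[:, None]
    pmf = stats.binom.pmf(m, d, f[None, :])
    # Pr(m_i >= r | state j): survival of the read-count binomial at the
    # detection threshold.
    det = stats.binom.sf(opts.detection_min_reads - 1, d, f[None, :])
    return pmf, det


def _loglik(q: np.ndarray, pmf: np.ndarray, det: np.ndarray) -> float:
    num = pmf @ q
    den = det @ q
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(num) - np.log(den)))


def _mm_update(q: np.ndarray, pmf: np.ndarray, det: np.ndarray) -> np.ndarray:
    """One minorize-maximize step on the detection-conditioned likelihood.

    The mixture numerator is minorized by Jensen's inequality (the usual EM
    responsibilities R_j), the convex -log of the detection denominator by its
    tangent (coefficients C_j); the surrogate max over the simplex is
    ``q_j = R_j / (lam + C_j)`` with ``lam`` solving ``sum_j q_j = 1``.
    """
    w = pmf * q
    resp = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
    R = resp.sum(axis=0)
    den = np.maximum(det @ q, 1e-300)
    C = (det / den[:, None]).sum(axis=0)

    active = R > 0
    if not np.any(active):  # pragma: no cover - all-zero responsibilities
        return q

    def g(lam: float) -> float:
        return float(np.sum(R[active] / (lam + C[active])) - 1.0)

    lo = -C[active].min()
    eps = 1e-12 + 1e-12 * abs(lo)
    a = lo + eps
    while g(a) < 0:  # g -> +inf as lam -> lo+, guard numeric undershoot
        eps *= 0.5
        a = lo + eps
        if eps < 1e-300:  # pragma: no cover
            break
    b = max(abs(lo), 1.0)
    while g(b) > 0:
        b = b * 2 + 1
    lam = optimize.brentq(g, a, b, xtol=1e-12, rtol=1e-14)

    q_new = np.zeros_like(q)
    q_new[active] = R[active] / (lam + C[active])
    q_new = np.clip(q_new, 0.0, None)
    return q_new / q_new.sum()


def em_allele_distribution(
    ssnvs: SSNVTable,
    cn: CNConfig,
    meta: SampleMeta,
    opts: EMOptions = EMOptions(),
    return_trace: bool = False,
):
    """Estimate the allele-state spectrum ``q`` by EM.

    Starts from a uniform spectrum and iterates monotone MM updates until the
    log-likelihood changes by less than ``opts.tol``.  Raises
    :class:`InsufficientDataError` below ``opts.min_ssnv`` records; on
    non-convergence the best iterate is returned with a warning.
    """
    cn.validate_supported()
    if len(ssnvs) < opts.min_ssnv:
        raise InsufficientDataError(
            f"{len(ssnvs)} SSNVs < required minimum {opts.min_ssnv}"
        )
    pmf, det = _mixture_terms(ssnvs, cn, meta, opts)
    J = cn.n_states
    q = np.full(J, 1.0 / J)
    ll = _loglik(q, pmf, det)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        q = _mm_update(q, pmf, det)
        ll_new = _loglik(q, pmf, det)
        trace.append(ll_new)
        if abs(ll_new - ll) < opts.tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        warnings.warn(
            f"EM did not converge in {opts.max_iter} iterations; returning best iterate",
            RuntimeWarning,
        )
    result = AlleleStateDistribution(q=q, loglik=ll, n_iter=it, converged=converged, cn=cn)
    if return_trace:
        return result, np.array(trace)
    return result
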