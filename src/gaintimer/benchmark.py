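"""Synthetic SSNV benchmark for the timing method.

Generates read-count data for a known gain history and stage durations —
allele states drawn from a multinomial over the expected spectrum, depths
from a negative binomial (mean ``u_D``, dispersion ``u_D / 10``), mutant
reads binomial at the purity-adjusted allele fraction — and scores timing
predictions against a time threshold ``T`` with precision / TPR / FPR, the
design used to characterize the method's accuracy and bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .allele_em import SampleMeta, SSNVTable, expected_vaf
from .histories import CNConfig, HistoryMatrix, TimeFractions, enumerate_histories, expected_q
from .timing import TimingOptions, time_segment

__all__ = [
    "SimConfig",
    "EvalConfig",
    "simulate_ssnvs",
    "evaluate_threshold",
    "random_time_fractions",
    "run_grid",
]


@dataclass(frozen=True)
class SimConfig:
    """One simulated segment: history ``A``, stage durations ``t``, number of
    detected SSNVs ``M``, purity ``P``, and the depth model (negative binomial
    with mean ``mean_depth`` and dispersion/size ``depth_dispersion``,
    defaulting to ``mean_depth / 10`` so the variance is ``11 * mean``)."""

    A: HistoryMatrix
    t: TimeFractions
    M: int
    P: float = 1.0
    mean_depth: float = 100.0
    depth_dispersion: float | None = None   # NB size; default mean/10
    seed: int | None = None
    keep_undetected: bool = False           # drop m=0 instead of redrawing

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")

    @property
    def dispersion(self) -> float:
        return self.depth_dispersion if self.depth_dispersion is not None else self.mean_depth / 10.0


@dataclass(frozen=True)
class EvalConfig:
    """Threshold ``T`` in (0,1) used to call early/late events."""

    threshold: float

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")


def _draw_depths(rng: np.random.Generator, n: int, mean: float, size: float) -> np.ndarray:
    # numpy parameterization: n = size, p = size / (size + mean)
    p = size / (size + mean)
    d = rng.negative_binomial(size, p, size=n)
    return np.maximum(d, 1)


def simulate_ssnvs(cfg: SimConfig, rng: np.random.Generator | None = None) -> SSNVTable:
    """Draw a detected SSNV read-count table for a known history and timing.

    Allele-state counts are multinomial over ``q = expected_q(A, t)``; depths
    are negative binomial; mutant reads binomial at the purity-adjusted VAF.
    Records drawn with zero mutant reads are redrawn (holding the allele state
    fixed) so exactly ``M`` detected records are returned; with the
    ``keep_undetected`` flag set they are dropped instead and fewer than ``M``
    records may result.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cn = cfg.A.cn
    meta = SampleMeta(purity=cfg.P)
    q = expected_q(cfg.A, cfg.t)
    counts = rng.multinomial(cfg.M, q)
    states = np.repeat(np.arange(1, cn.n_states + 1), counts)
    f = expected_vaf(states, cn, meta)

    d = _draw_depths(rng, cfg.M, cfg.mean_depth, cfg.dispersion)
    m = rng.binomial(d, f)
    if cfg.keep_undetected:
        keep = m >= 1
        d, m = d[keep], m[keep]
    else:
        undet = m < 1
        while np.any(undet):
            idx = np.flatnonzero(undet)
            d[idx] = _draw_depths(rng, idx.size, cfg.mean_depth, cfg.dispersion)
            m[idx] = rng.binomial(d[idx], f[idx])
            undet = m < 1
    return SSNVTable.from_counts(m=m, d=d)


def evaluate_threshold(
    true_values, predicted_values, cfg: EvalConfig
) -> dict[str, float]:
    """Precision, TPR and FPR of thresholded event calls.

    A positive call means the predicted time is below ``T``; it is true when
    the actual time is also below ``T``.  Ratios with empty denominators are
    returned as NaN.
    """
    truth = np.asarray(true_values, dtype=float)
    pred = np.asarray(predicted_values, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError("true and predicted vectors must have equal length")
    T = cfg.threshold
    pp = pred < T
    ap = truth < T
    tp = int(np.sum(pp & ap))
    fp = int(np.sum(pp & ~ap))
    fn = int(np.sum(~pp & ap))
    tn = int(np.sum(~pp & ~ap))

    def ratio(a: int, b: int) -> float:
        return a / b if b > 0 else float("nan")

    return {
        "precision": ratio(tp, tp + fp),
        "tpr": ratio(tp, tp + fn),
        "fpr": ratio(fp, fp + tn),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def random_time_fractions(
    n_stages: int, t0: float, rng: np.random.Generator, eps: float = 0.01
) -> TimeFractions:
    """Stage durations with fixed initiation time and a random lead time.

    ``t_K`` is uniform on ``(0, 1 - t0 - eps)``; the remaining mass is spread
    uniformly over the intermediate stages.
    """
    if n_stages < 2:
        raise ValueError("need at least two stages")
    tK = rng.uniform(0.0, max(1.0 - t0 - eps, 0.0))
    t = np.empty(n_stages)
    t[0] = t0
    t[-1] = tK
    if n_stages > 2:
        t[1:-1] = (1.0 - t0 - tK) / (n_stages - 2)
    else:
        t[-1] = 1.0 - t0
    return TimeFractions(t / t.sum())


def run_grid(
    cn_list,
    t0_levels=(0.1, 0.2, 0.3),
    M_grid=(100,),
    depth_grid=(100.0,),
    purity_grid=(1.0,),
    reps: int = 10,
    seed: int = 0,
    timing_opts: TimingOptions | None = None,
) -> pd.DataFrame:
    """Simulate-and-time over a factorial grid; one tidy row per replicate.

    For each cell a history matrix is drawn uniformly from the state's
    enumerated set, stage durations via :func:`random_time_fractions`, data
    via :func:`simulate_ssnvs`, and the segment timed end to end.  Bootstrap
    CIs are disabled by default here (``reps`` replicates already quantify
    spread); pass ``timing_opts`` to override.
    """
    if timing_opts is None:
        timing_opts = TimingOptions(bootstrap=0)
    rng = np.random.default_rng(seed)
    rows = []
    for cn in cn_list:
        cn = cn if isinstance(cn, CNConfig) else CNConfig(*cn)
        histories = enumerate_histories(cn)
        for t0 in t0_levels:
            for M in M_grid:
                for depth in depth_grid:
                    for P in purity_grid:
                        for rep in range(reps):
                            A = histories[rng.integers(len(histories))]
                            t = random_time_fractions(A.n_stages, t0, rng)
                            cfg = SimConfig(A=A, t=t, M=M, P=P, mean_depth=depth)
                            ssnvs = simulate_ssnvs(cfg, rng)
                            est = time_segment(
                                ssnvs, cn, SampleMeta(purity=P), timing_opts
                            )
                            rows.append({
                                "nt": cn.nt, "nb": cn.nb, "t0_true": t.t0,
                                "tK_true": t.tK, "M": M, "depth": depth,
                                "purity": P, "rep": rep,
                                "t0_upper": est.t0_upper,
                                "tK_upper": est.tK_upper,
                            })
    columns = ["nt", "nb", "t0_true", "tK_true", "M", "depth", "purity",
               "rep", "t0_upper", "tK_upper"]
    return pd.DataFrame(rows, columns=columns)
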