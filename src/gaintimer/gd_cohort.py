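"""Genome-doubling detection, cohort recurrence, multiplicity and clonality.

Whole (or partial) genome doubling shows up as a synchronized burst of gains:
a tight cluster of segment arrival times.  :func:`detect_gd` finds it by
kernel-density clustering of arrival times — a GD call requires the cluster
to hold more than 40% of all timed segments and to be concentrated (small
standard deviation); segments arriving more than 1.3 cluster-SDs before or
after the cluster mean are labeled pre-/post-GD events.

Cohort recurrence works on a patients x 1-Mbp-bin matrix of timing values:
per patient, bins are ranked (with jitter to break ties) and their deviation
from the middle rank summed across patients; dividing by the null standard
deviation gives per-bin z-scores that are approximately standard normal when
no region is recurrently early or late.

Per-variant utilities estimate the number of copies carrying an SSNV
(binomial maximum likelihood over allele states) and flag clonality by
whether the 95% CI of the cancer cell fraction covers 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .allele_em import SampleMeta, expected_vaf
from .histories import CNConfig

__all__ = [
    "GDOptions",
    "GDCall",
    "detect_gd",
    "pre_post_rates",
    "recurrence_zscores",
    "multiplicity_mle",
    "clonality_flag",
]


@dataclass(frozen=True)
class GDOptions:
    min_segments: int = 10     # fewer timed segments -> no call
    min_fraction: float = 0.4  # burst must hold > this fraction of segments
    max_sigma: float = 0.15    # concentration requirement on the cluster SD
    sigma_factor: float = 1.3  # pre/post boundary in cluster SDs
    level_frac: float = 0.5    # mode core = component at this fraction of peak density
    grid_size: int = 512


@dataclass
class GDCall:
    detected: bool
    reason: str = ""
    gd_time: float = float("nan")
    sigma: float = float("nan")
    member_fraction: float = float("nan")
    members: np.ndarray | None = None
    pre_events: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    post_events: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))


def _mode_cores(values: np.ndarray, opts: GDOptions):
    """Candidate burst clusters: density-mode cores of a Gaussian KDE.

    For each local mode of the Silverman-bandwidth KDE on [0, 1], the core is
    the connected component of ``{density >= level_frac * peak}`` containing
    the mode (a full-width-at-half-maximum interval by default) and its
    members are the points inside it.  A diffuse sample never concentrates:
    its density stays above half of any of its shallow peaks nearly
    everywhere, so the core swallows the whole range and fails the
    concentration test downstream.  Yields (peak_density, member_mask)
    sorted by decreasing peak density.
    """
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, opts.grid_size)
    dens = kde(grid)
    n = opts.grid_size
    cores = []
    for i in range(n):
        left = dens[i - 1] if i > 0 else -np.inf
        right = dens[i + 1] if i < n - 1 else -np.inf
        if dens[i] >= left and dens[i] > right:
            lam = opts.level_frac * dens[i]
            a = i
            while a > 0 and dens[a - 1] >= lam:
                a -= 1
            b = i
            while b < n - 1 and dens[b + 1] >= lam:
                b += 1
            mask = (values >= grid[a]) & (values <= grid[b])
            cores.append((float(dens[i]), mask))
    cores.sort(key=lambda c: -c[0])
    return cores


def detect_gd(
    arrival_times,
    segment_ids=None,
    opts: GDOptions = GDOptions(),
) -> GDCall:
    """Call genome doubling from per-segment arrival times.

    ``arrival_times`` are the per-segment arrival times (1 - lead-time bound)
    in [0, 1].  Returns a no-call with a reason when fewer than
    ``opts.min_segments`` segments are available or no concentrated cluster
    holds more than ``opts.min_fraction`` of them.
    """
    values = np.asarray(arrival_times, dtype=float)
    if segment_ids is None:
        segment_ids = np.arange(values.size)
    segment_ids = np.asarray(segment_ids)
    if values.size != segment_ids.size:
        raise ValueError("arrival_times and segment_ids length mismatch")
    if values.size < opts.min_segments:
        return GDCall(detected=False,
                      reason=f"only {values.size} timed segments "
                             f"(minimum {opts.min_segments})")
    if np.any((values < -1e-9) | (values > 1 + 1e-9)):
        raise ValueError("arrival times must lie in [0, 1]")

    if np.ptp(values) < 1e-9:
        cores = [(np.inf, np.ones(values.size, dtype=bool))]
    else:
        cores = _mode_cores(values, opts)
    best = None
    for peak, members in cores:
        frac = members.mean()
        sigma = float(values[members].std(ddof=0))
        if frac > opts.min_fraction and sigma <= opts.max_sigma:
            best = (frac, sigma, members)
            break  # cores are sorted by peak density: take the most prominent
    if best is None:
        return GDCall(detected=False,
                      reason="no concentrated cluster holds more than "
                             f"{opts.min_fraction:.0%} of timed segments")
    frac, sigma, members = best
    gd_time = float(values[members].mean())
    lo = gd_time - opts.sigma_factor * sigma
    hi = gd_time + opts.sigma_factor * sigma
    pre = segment_ids[values < lo]
    post = segment_ids[values > hi]
    return GDCall(
        detected=True,
        gd_time=gd_time,
        sigma=sigma,
        member_fraction=float(frac),
        members=segment_ids[members],
        pre_events=pre,
        post_events=post,
    )


def pre_post_rates(pre_count: int, post_count: int, gd_time: float) -> dict[str, float]:
    """Gain rates per unit truncal time before and after genome doubling."""
    if not (0.0 <= gd_time <= 1.0):
        raise ValueError("gd_time must be in [0, 1]")
    pre_rate = pre_count / gd_time if gd_time > 0 else float("nan")
    post_rate = post_count / (1.0 - gd_time) if gd_time < 1 else float("nan")
    return {"pre_rate": pre_rate, "post_rate": post_rate}


def recurrence_zscores(
    bins: pd.DataFrame,
    mode: str = "initiation",
    seed: int | None = None,
    z_crit: float = 1.645,
) -> pd.DataFrame:
    """Per-bin recurrence z-scores across patients.

    ``bins`` is a patients (rows) x genomic bins (columns) matrix of timing
    values (initiation times, or arrival times for ``mode="arrival"``); NaN
    marks bins without a timed gain in a patient.  Within each patient the
    non-missing bins are ranked after adding Uniform(-1e-6, 1e-6) jitter;
    deviations from the middle rank ``(B + 1) / 2`` (``B`` = that patient's
    bin count) are summed per bin and divided by the null standard deviation
    ``sqrt(sum_p (B_p^2 - 1) / 12)``.  Bins with ``|z| > z_crit`` (default:
    two-sided 90% confidence) are flagged: negative z = recurrently early,
    positive z = recurrently late.
    """
    if mode not in ("initiation", "arrival"):
        raise ValueError("mode must be 'initiation' or 'arrival'")
    if bins.shape[0] == 0:
        raise ValueError("no patients in the bin matrix")
    values = bins.to_numpy(dtype=float)
    n_pat, n_bin = values.shape
    usable = (~np.isnan(values)).sum(axis=1) >= 2
    if usable.sum() == 0:
        raise ValueError("no patient has >= 2 non-missing bins")
    if usable.sum() == 1:
        import warnings

        warnings.warn("single usable patient: recurrence z-scores are underpowered",
                      UserWarning)

    rng = np.random.default_rng(seed)
    dev_sum = np.zeros(n_bin)
    var_sum = np.zeros(n_bin)
    for p in range(n_pat):
        if not usable[p]:
            continue
        present = ~np.isnan(values[p])
        B = int(present.sum())
        jittered = values[p, present] + rng.uniform(-1e-6, 1e-6, size=B)
        ranks = stats.rankdata(jittered, method="ordinal")
        dev_sum[present] += ranks - (B + 1) / 2.0
        var_sum[present] += (B * B - 1) / 12.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = dev_sum / np.sqrt(var_sum)
    flag = np.where(np.abs(z) > z_crit,
                    np.where(z < 0, "recurrent_early", "recurrent_late"), "")
    return pd.DataFrame({"bin": bins.columns, "z": z, "flag": flag,
                         "n_patients": (~np.isnan(values)).sum(axis=0)})


def multiplicity_mle(m: int, d: int, cn: CNConfig, meta: SampleMeta) -> int:
    """Maximum-likelihood number of segment copies carrying a variant.

    Argmax over allele states ``j = 1..(nt - nb)`` of the binomial likelihood
    of ``m`` mutant reads in depth ``d`` at the purity-adjusted VAF; ties
    break toward the smaller multiplicity.
    """
    if m < 1:
        raise ValueError("multiplicity estimation requires m >= 1")
    if d < m:
        raise ValueError("depth must be >= mutant reads")
    js = np.arange(1, cn.n_states + 1)
    f = expected_vaf(js, cn, meta)
    ll = stats.binom.logpmf(m, d, f)
    return int(js[np.argmax(ll)])  # argmax takes the first (smallest j) on ties


def clonality_flag(
    m: int, d: int, cn: CNConfig, meta: SampleMeta, multiplicity: int,
    level: float = 0.95,
) -> str:
    """Flag a variant clonal when the CCF confidence interval covers 1.

    The cancer cell fraction is ``(m/d) (nt P + 2 (1-P)) / (P * multiplicity)``;
    a Clopper-Pearson CI on the VAF is propagated through the same linear map.
    """
    if d <= 0:
        raise ValueError("depth must be positive")
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    P = meta.purity
    factor = (cn.nt * P + meta.normal_cn * (1.0 - P)) / (P * multiplicity)
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2, m, d - m + 1) if m > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, m + 1, d - m) if m < d else 1.0
    ccf_lo, ccf_hi = lo * factor, hi * factor
    return "clonal" if ccf_lo <= 1.0 <= ccf_hi else "subclonal"
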