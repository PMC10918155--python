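"""Two-type branching-process models of post-genome-doubling evolution.

Both models start from a single cell that has just undergone genome doubling
(GD).  In the *neutral* model all cells divide at rate ``a0``, die at rate
``b0`` (net growth ``lambda0 = a0 - b0 > 0``) and accumulate neutral
passenger gains at rate ``u0`` under the infinite-sites convention.
Conditioned on non-extinction, the number of post-GD gains that reach
fixation is geometric with parameter ``lambda0 / (lambda0 + u0)`` (mean
``u0 / lambda0``), and the expected number of *dominant* gains (carried by at
least 90% of cells) at tumor size ``N`` is ``N / ceil(0.9 N) * u0 / lambda0``
— barely larger, so without selection GD must be one of the last events
before the tumor's most recent common ancestor.

In the *selection* model, type-0 cells additionally convert at rate ``u1`` to
type-1 cells carrying a beneficial post-GD gain (birth ``a1``, death ``b1``,
``lambda1 > lambda0``).  The survival function of ``sigma1``, the birth time
of the first type-1 cell with an infinite line of descent, has the closed
form ``(alpha + beta) / (alpha + beta * exp(zeta t))`` with
``alpha = a0 (1 - q0)``, ``beta = u1 (1 - q1) / (1 - q0)``,
``zeta = alpha + beta``, where ``q1 = b1/a1`` and ``q0`` is the type-0
extinction probability.  Integrating it against the passenger rate gives the
expected passenger load of that first type-1 cell.

Simulators are exact event-driven (Gillespie) implementations conditioned on
non-extinction by rejection.  Two exact devices keep them fast: a cell alive
at a census survives forever with probability ``lambda/a`` independently of
everything else, so infinite-horizon questions (fixation, lineage survival)
are settled by Bernoulli draws at the census; and constant-rate type-1 clades
can have their survival decided the moment they are founded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import integrate

__all__ = [
    "BranchingParams",
    "Lemma1Terms",
    "DriverOrderParams",
    "SelectionTrajectory",
    "neutral_clonal_gain_pmf",
    "expected_dominant_gains",
    "lemma1_terms",
    "lemma1_survival",
    "expected_passengers_at_sigma1",
    "closed_form_passengers_at_sigma1",
    "simulate_neutral_model",
    "simulate_selection_model",
    "sample_sigma1",
    "driver_order_fraction",
]

_RESTART_CAP = 1_000_000


@dataclass(frozen=True)
class BranchingParams:
    """Rates of the two-type model: type-0 birth/death ``a0``/``b0``,
    passenger gain rate ``u0``, beneficial gain rate ``u1``, type-1
    birth/death ``a1``/``b1``."""

    a0: float
    b0: float
    u0: float = 0.0
    u1: float = 0.0
    a1: float = 0.0
    b1: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a0", "b0", "u0", "u1", "a1", "b1"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative")
        if self.lambda0 <= 0:
            raise ValueError("type-0 net growth rate lambda0 = a0 - b0 must be positive")
        if self.u1 > 0 and self.lambda1 <= self.lambda0:
            raise ValueError("beneficial gains require lambda1 > lambda0")

    @property
    def lambda0(self) -> float:
        return self.a0 - self.b0

    @property
    def lambda1(self) -> float:
        return self.a1 - self.b1


@dataclass(frozen=True)
class Lemma1Terms:
    """Derived quantities of the sigma1 survival function."""

    q0: float     # extinction probability of a type-0 rooted lineage
    q1: float     # extinction probability of a type-1 rooted lineage
    alpha: float  # a0 (1 - q0)
    beta: float   # u1 (1 - q1) / (1 - q0)
    zeta: float   # alpha + beta


@dataclass(frozen=True)
class DriverOrderParams:
    """Two-driver race: driver one arrives at rate ``u1`` adding ``delta1``
    to the birth rate, driver two at ``u2`` adding ``delta2``."""

    u1: float
    u2: float
    delta1: float
    delta2: float
    a0: float = 1.0
    b0: float = 0.9
    reps: int = 10_000

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if min(self.u1, self.u2) <= 0:
            raise ValueError("driver rates must be positive")
        if min(self.delta1, self.delta2) < 0:
            raise ValueError("fitness increments must be non-negative")
        if self.a0 + self.delta1 + self.delta2 <= self.b0:
            raise ValueError("double mutants must be supercritical")


@dataclass(frozen=True)
class SelectionTrajectory:
    """One conditioned run of the selection (or neutral, ``u1 = 0``) model."""

    sigma1: float              # NaN when no type-1 lineage survives at census
    founder_passengers: float  # passenger load of the first surviving type-1 cell
    clonal_gains: int          # passenger gains fixed forever
    dominant_gains: int        # passenger gains in >= 90% of census cells
    census_size: int


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------


def neutral_clonal_gain_pmf(k, u0: float, lambda0: float):
    """Geometric law of the number of fixed post-GD gains in the neutral
    model: ``p (1-p)^k`` with ``p = lambda0 / (lambda0 + u0)``."""
    if lambda0 <= 0:
        raise ValueError("lambda0 must be positive")
    if u0 < 0:
        raise ValueError("u0 must be non-negative")
    k_arr = np.asarray(k)
    p = lambda0 / (lambda0 + u0)
    pmf = np.where(k_arr >= 0, p * (1.0 - p) ** np.maximum(k_arr, 0), 0.0)
    return float(pmf) if np.isscalar(k) else pmf


def expected_dominant_gains(N: int, u0: float, lambda0: float) -> float:
    """Expected number of post-GD gains in >= 90% of cells at size ``N``:
    ``N / ceil(0.9 N) * u0 / lambda0`` (prefactor ~= 1.11 for large N)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if lambda0 <= 0:
        raise ValueError("lambda0 must be positive")
    return (N / math.ceil(0.9 * N)) * (u0 / lambda0)


def lemma1_terms(params: BranchingParams) -> Lemma1Terms:
    if params.u1 <= 0:
        raise ValueError("sigma1 requires a positive beneficial gain rate u1")
    a0, b0, u1 = params.a0, params.b0, params.u1
    q1 = params.b1 / params.a1
    disc = (a0 + b0 + u1) ** 2 - 4.0 * a0 * (u1 * q1 + b0)
    q0 = (a0 + b0 + u1 - math.sqrt(disc)) / (2.0 * a0)
    alpha = a0 * (1.0 - q0)
    beta = u1 * (1.0 - q1) / (1.0 - q0)
    return Lemma1Terms(q0=q0, q1=q1, alpha=alpha, beta=beta, zeta=alpha + beta)


def lemma1_survival(t, params: BranchingParams):
    """``P(sigma1 > t | non-extinction)`` for the selection model."""
    terms = lemma1_terms(params)
    t_arr = np.asarray(t, dtype=float)
    # (alpha+beta) / (alpha + beta e^{zeta t}), written overflow-safely
    decay = np.exp(-terms.zeta * t_arr)
    val = (terms.alpha + terms.beta) * decay / (terms.alpha * decay + terms.beta)
    return float(val) if np.isscalar(t) else val


def closed_form_passengers_at_sigma1(params: BranchingParams, u0: float) -> float:
    """Analytic value of the survival-function integral:
    ``(u0 / alpha) * log((alpha + beta) / beta)``."""
    terms = lemma1_terms(params)
    return (u0 / terms.alpha) * math.log((terms.alpha + terms.beta) / terms.beta)


def expected_passengers_at_sigma1(params: BranchingParams, u0: float) -> float:
    """Expected passenger gains carried by the first surviving type-1 cell,
    ``integral_0^inf P(sigma1 > t | non-extinction) u0 dt`` by adaptive
    quadrature."""
    if u0 < 0:
        raise ValueError("u0 must be non-negative")
    if u0 == 0:
        return 0.0
    value, err = integrate.quad(
        lambda t: lemma1_survival(t, params) * u0, 0.0, np.inf, limit=200
    )
    if not np.isfinite(value) or err > 1e-6 * max(abs(value), 1.0):  # pragma: no cover
        raise RuntimeError("quadrature for the expected passenger load did not converge")
    return value


# ---------------------------------------------------------------------------
# Exact stochastic simulators (numba kernels)
# ---------------------------------------------------------------------------
# Status codes: 0 = census reached, 1 = extinct, 2 = event cap, 3 = node-array
# overflow.


@njit(cache=False)
def _census_kernel(a0, b0, u0, u1, a1, b1, s0, s1, N, seed, max_events, node_cap):
    """Grow the two-type process to ``N`` cells, tracking the mutation tree,
    then settle infinite-horizon questions by per-cell survival draws."""
    np.random.seed(seed)
    cells0 = np.empty(N + 2, dtype=np.int64)
    cells1 = np.empty(N + 2, dtype=np.int64)
    parent = np.empty(node_cap, dtype=np.int64)
    kind = np.empty(node_cap, dtype=np.uint8)    # 0 root, 1 passenger, 2 driver
    born = np.empty(node_cap, dtype=np.float64)
    npass = np.empty(node_cap, dtype=np.int64)
    parent[0] = -1
    kind[0] = 0
    born[0] = 0.0
    npass[0] = 0
    n_nodes = 1
    cells0[0] = 0
    n0 = 1
    n1 = 0
    t = 0.0
    events = 0

    r0 = a0 + b0 + u0 + u1
    r1 = a1 + b1 + u0

    while n0 + n1 < N:
        if n0 + n1 == 0:
            return 1, 0, 0, np.nan, -1, 0
        if events >= max_events:
            return 2, 0, 0, np.nan, -1, 0
        events += 1
        R = n0 * r0 + n1 * r1
        t += np.random.exponential(1.0 / R)
        r = np.random.random() * R
        if r < n0 * r0:
            idx = np.random.randint(n0)
            r -= 0.0
            x = r / n0
            if x < a0:
                cells0[n0] = cells0[idx]
                n0 += 1
            elif x < a0 + b0:
                cells0[idx] = cells0[n0 - 1]
                n0 -= 1
            elif x < a0 + b0 + u0:
                if n_nodes >= node_cap:
                    return 3, 0, 0, np.nan, -1, 0
                parent[n_nodes] = cells0[idx]
                kind[n_nodes] = 1
                born[n_nodes] = t
                npass[n_nodes] = npass[cells0[idx]] + 1
                cells0[idx] = n_nodes
                n_nodes += 1
            else:
                if n_nodes >= node_cap:
                    return 3, 0, 0, np.nan, -1, 0
                parent[n_nodes] = cells0[idx]
                kind[n_nodes] = 2
                born[n_nodes] = t
                npass[n_nodes] = npass[cells0[idx]]
                cells1[n1] = n_nodes
                n1 += 1
                n_nodes += 1
                cells0[idx] = cells0[n0 - 1]
                n0 -= 1
        else:
            r -= n0 * r0
            idx = np.random.randint(n1)
            x = r / n1
            if x < a1:
                cells1[n1] = cells1[idx]
                n1 += 1
            elif x < a1 + b1:
                cells1[idx] = cells1[n1 - 1]
                n1 -= 1
            else:
                if n_nodes >= node_cap:
                    return 3, 0, 0, np.nan, -1, 0
                parent[n_nodes] = cells1[idx]
                kind[n_nodes] = 1
                born[n_nodes] = t
                npass[n_nodes] = npass[cells1[idx]] + 1
                cells1[idx] = n_nodes
                n_nodes += 1

    # census: subtree counts of alive cells and of cells whose lineage
    # survives forever (independent Bernoulli draws, exact by the branching
    # property)
    cnt = np.zeros(n_nodes, dtype=np.int64)
    skel = np.zeros(n_nodes, dtype=np.int64)
    for i in range(n0):
        cnt[cells0[i]] += 1
        if np.random.random() < s0:
            skel[cells0[i]] += 1
    for i in range(n1):
        cnt[cells1[i]] += 1
        if np.random.random() < s1:
            skel[cells1[i]] += 1
    for node in range(n_nodes - 1, 0, -1):
        cnt[parent[node]] += cnt[node]
        skel[parent[node]] += skel[node]

    total = n0 + n1
    total_skel = skel[0]
    if total_skel == 0:
        # the census population is doomed: the run does not satisfy
        # non-extinction, reject it
        return 1, 0, 0, np.nan, -1, total

    thresh = int(math.ceil(0.9 * total))
    clonal = 0
    dominant = 0
    for node in range(1, n_nodes):
        if kind[node] == 1:
            if skel[node] == total_skel:
                clonal += 1
            if cnt[node] >= thresh:
                dominant += 1

    sigma1 = np.nan
    founder_pass = -1
    for node in range(1, n_nodes):
        if kind[node] == 2 and skel[node] > 0:
            sigma1 = born[node]
            founder_pass = npass[node]
            break
    return 0, clonal, dominant, sigma1, founder_pass, total


@njit(cache=False)
def _first_type1_kernel(a0, b0, u0, u1, surv1, seed, max_events, pop_cap):
    """Run the type-0 population until the first type-1 founder whose clade
    survives (decided by an immediate Bernoulli(1 - b1/a1) draw).

    Returns (status, sigma1, founder passenger count, type-0 size at sigma1).
    """
    np.random.seed(seed)
    passengers = np.zeros(pop_cap, dtype=np.int64)
    n0 = 1
    t = 0.0
    events = 0
    rate = a0 + b0 + u0 + u1
    while True:
        if n0 == 0:
            return 1, np.nan, -1, 0
        if events >= max_events or n0 >= pop_cap - 1:
            return 2, np.nan, -1, n0
        events += 1
        t += np.random.exponential(1.0 / (n0 * rate))
        idx = np.random.randint(n0)
        x = np.random.random() * rate
        if x < a0:
            passengers[n0] = passengers[idx]
            n0 += 1
        elif x < a0 + b0:
            passengers[idx] = passengers[n0 - 1]
            n0 -= 1
        elif x < a0 + b0 + u0:
            passengers[idx] += 1
        else:
            # a type-1 founder; its clade has constant rates, so survival is
            # Bernoulli(1 - b1/a1) now.  Doomed clades cannot found further
            # type-1 lineages and never matter for sigma1 or non-extinction.
            if np.random.random() < surv1:
                return 0, t, passengers[idx], n0
            passengers[idx] = passengers[n0 - 1]
            n0 -= 1


@njit(cache=False)
def _two_driver_kernel(a0, b0, u1, u2, d1, d2, surv3, seed, max_events):
    """Race two drivers; returns (status, 1 if driver one arrived first in
    the first non-extinct doubly-mutant lineage else 0)."""
    np.random.seed(seed)
    n00 = 1
    n10 = 0
    n01 = 0
    r00 = a0 + b0 + u1 + u2
    r10 = a0 + d1 + b0 + u2
    r01 = a0 + d2 + b0 + u1
    events = 0
    while True:
        if n00 + n10 + n01 == 0:
            return 1, 0
        if events >= max_events:
            return 2, 0
        events += 1
        R = n00 * r00 + n10 * r10 + n01 * r01
        r = np.random.random() * R
        if r < n00 * r00:
            x = r / n00
            if x < a0:
                n00 += 1
            elif x < a0 + b0:
                n00 -= 1
            elif x < a0 + b0 + u1:
                n00 -= 1
                n10 += 1
            else:
                n00 -= 1
                n01 += 1
        elif r < n00 * r00 + n10 * r10:
            x = (r - n00 * r00) / n10
            if x < a0 + d1:
                n10 += 1
            elif x < a0 + d1 + b0:
                n10 -= 1
            else:
                # driver two lands on a driver-one cell
                if np.random.random() < surv3:
                    return 0, 1
                n10 -= 1
        else:
            x = (r - n00 * r00 - n10 * r10) / n01
            if x < a0 + d2:
                n01 += 1
            elif x < a0 + d2 + b0:
                n01 -= 1
            else:
                if np.random.random() < surv3:
                    return 0, 0
                n01 -= 1


def _seed_stream(seed: int | None):
    """Endless stream of distinct 31-bit kernel seeds derived from ``seed``."""
    chunk = 0
    base = 0 if seed is None else int(seed)
    while True:
        block = np.random.SeedSequence((base, chunk)).generate_state(4096)
        for s in block % (2**31 - 1) + 1:
            yield int(s)
        chunk += 1


def simulate_neutral_model(
    a0: float,
    b0: float,
    u0: float,
    stop_size: int = 10_000,
    seed: int | None = None,
    max_events: int = 50_000_000,
) -> SelectionTrajectory:
    """One conditioned neutral-model run (selection model with ``u1 = 0``)."""
    params = BranchingParams(a0=a0, b0=b0, u0=u0)
    return simulate_selection_model(params, stop_size=stop_size, seed=seed,
                                    max_events=max_events)


def simulate_selection_model(
    params: BranchingParams,
    stop_size: int = 10_000,
    seed: int | None = None,
    max_events: int = 50_000_000,
    restart_cap: int = _RESTART_CAP,
) -> SelectionTrajectory:
    """Exact conditioned run of the two-type model to a census of
    ``stop_size`` cells.

    Restarts on extinction (rejection conditioning on non-extinction).
    Returns the fixed and dominant passenger-gain counts at the census and,
    when a surviving type-1 lineage exists, the birth time ``sigma1`` and
    passenger load of its founder.
    """
    if params.u1 > 0:
        terms = lemma1_terms(params)
        s0, s1 = 1.0 - terms.q0, 1.0 - terms.q1
    else:
        s0, s1 = params.lambda0 / params.a0, 0.0

    node_cap = int(
        4.0 * stop_size * (params.u0 + params.u1 + 1e-9) / params.lambda0
    ) + 4096
    seeds = _seed_stream(seed)
    attempt = 0
    while attempt < restart_cap:
        status, clonal, dominant, sigma1, founder_pass, total = _census_kernel(
            params.a0, params.b0, params.u0, params.u1, params.a1, params.b1,
            s0, s1, stop_size, next(seeds), max_events, node_cap,
        )
        attempt += 1
        if status == 0:
            return SelectionTrajectory(
                sigma1=float(sigma1),
                founder_passengers=float(founder_pass) if founder_pass >= 0 else float("nan"),
                clonal_gains=int(clonal),
                dominant_gains=int(dominant),
                census_size=int(total),
            )
        if status == 3:
            node_cap *= 2
    raise RuntimeError("restart cap exceeded while conditioning on non-extinction")


def sample_sigma1(
    params: BranchingParams,
    n: int,
    seed: int | None = None,
    u0: float = 0.0,
    max_events: int = 40_000_000,
    pop_cap: int = 1 << 21,
) -> np.ndarray:
    """Draw ``n`` conditioned samples of ``sigma1`` (and passenger loads).

    Uses the reduced exact sampler: only the type-0 population is simulated
    and each type-1 founder's survival is decided on the spot.  Returns an
    array of shape (n, 2) with columns (sigma1, founder passenger count).
    Runs hitting the event or population cap (a tiny late-``sigma1`` tail)
    are restarted.
    """
    if params.u1 <= 0:
        raise ValueError("sigma1 sampling requires u1 > 0")
    surv1 = 1.0 - params.b1 / params.a1
    seeds = _seed_stream(seed)
    out = np.empty((n, 2))
    for i in range(n):
        while True:
            status, sigma1, founder_pass, _ = _first_type1_kernel(
                params.a0, params.b0, u0, params.u1, surv1,
                next(seeds), max_events, pop_cap,
            )
            if status == 0:
                out[i, 0] = sigma1
                out[i, 1] = founder_pass
                break
    return out


def driver_order_fraction(
    p: DriverOrderParams, seed: int | None = None, max_events: int = 10_000_000
) -> dict[str, float]:
    """Monte-Carlo fraction of conditioned runs in which driver one arrives
    before driver two in the first non-extinct doubly-mutant lineage.

    Returns the fraction and its binomial standard error.
    """
    a3 = p.a0 + p.delta1 + p.delta2
    surv3 = 1.0 - p.b0 / a3
    seeds = _seed_stream(seed)
    wins = 0
    for _ in range(p.reps):
        while True:
            status, first = _two_driver_kernel(
                p.a0, p.b0, p.u1, p.u2, p.delta1, p.delta2, surv3,
                next(seeds), max_events,
            )
            if status == 0:
                wins += int(first)
                break
    frac = wins / p.reps
    se = math.sqrt(max(frac * (1 - frac), 1e-12) / p.reps)
    return {"fraction_first": frac, "se": se, "reps": p.reps}
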