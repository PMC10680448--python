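"""Network-level structure: NODF nestedness, bipartite modularity, null models.

Nestedness is measured with NODF (paired overlap under decreasing fill,
0-100).  Modularity is Barber's bipartite Q, optimised by simulated
annealing over module reassignments in the QuanBiMo family.  Significance of
either metric is assessed against an ensemble of random binary matrices that
conserve the network's dimensions and number of links (and hence its
connectance), with a marginal-conserving swap model available as a
sensitivity alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_tables import IncidenceMatrix

#: Default annealing step budget.  Large enough to saturate matrices of a few
#: hundred species; overridable everywhere it is used.
DEFAULT_STEPS = 100_000

#: Sentinel reported for a z-score whose null distribution has zero spread.
Z_UNDEFINED = float("nan")


class UndefinedPairsError(ValueError):
    """NODF needs at least two rows or two columns to form a pair."""


class PartitionError(ValueError):
    """A module partition does not cover every species in the matrix."""


@dataclass
class ModulePartition:
    """Assignment of every host and guest to a module, with its Barber Q."""

    module_of_host: dict[str, int]
    module_of_guest: dict[str, int]
    q: float

    @property
    def n_modules(self) -> int:
        labels = set(self.module_of_host.values()) | set(self.module_of_guest.values())
        return len(labels)

    def labels(self, matrix: IncidenceMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Module ids as arrays aligned with the matrix ordering."""
        try:
            gh = np.array([self.module_of_host[h] for h in matrix.hosts])
            gg = np.array([self.module_of_guest[g] for g in matrix.guests])
        except KeyError as exc:
            raise PartitionError(f"species missing from partition: {exc}") from None
        return gh, gg


@dataclass
class NullEnsembleResult:
    """An observed metric against its null-model distribution."""

    observed: float
    null_values: np.ndarray
    z: float
    p: float
    metric: str = ""
    model: str = "fill"

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "observed": float(self.observed),
            "null_mean": float(np.mean(self.null_values)),
            "null_sd": float(np.std(self.null_values, ddof=1)),
            "z": float(self.z),
            "p": float(self.p),
            "n_null": int(len(self.null_values)),
            "model": self.model,
        }


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

def _nodf_axis(a: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap percentages over all row pairs of ``a``.

    For each unordered row pair the contribution is 100 * |N_i & N_j| / k_min
    when the marginal totals differ (decreasing fill), and 0 when they are
    equal.  Returns (sum, number of pairs).
    """
    k = a.sum(axis=1)
    n = a.shape[0]
    if n < 2:
        return 0.0, 0
    overlap = (a @ a.T).astype(float)
    ki = k[:, None].astype(float)
    kj = k[None, :].astype(float)
    kmin = np.minimum(ki, kj)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where((ki != kj) & (kmin > 0), 100.0 * overlap / kmin, 0.0)
    iu = np.triu_indices(n, k=1)
    return float(contrib[iu].sum()), n * (n - 1) // 2


def nodf(matrix: IncidenceMatrix | np.ndarray) -> float:
    """NODF nestedness of a binary matrix, as a percentage in [0, 100].

    Averages the paired-overlap contributions over the full set of row pairs
    and column pairs together (Almeida-Neto et al. convention); a pair with
    equal marginal totals contributes zero.
    """
    a = matrix.cells if isinstance(matrix, IncidenceMatrix) else np.asarray(matrix)
    a = (a > 0).astype(np.int64)
    if a.size == 0:
        raise UndefinedPairsError("empty matrix")
    rows_sum, rows_n = _nodf_axis(a)
    cols_sum, cols_n = _nodf_axis(a.T)
    total_pairs = rows_n + cols_n
    if total_pairs == 0:
        raise UndefinedPairsError(
            "NODF is undefined for a single-row, single-column matrix"
        )
    return (rows_sum + cols_sum) / total_pairs


# ---------------------------------------------------------------------------
# Barber bipartite modularity
# ---------------------------------------------------------------------------

def _barber_q_arrays(a: np.ndarray, gh: np.ndarray, gg: np.ndarray) -> float:
    """Q = (1/m) sum_ij (A_ij - k_i d_j / m) * delta(g_i, g_j)."""
    m = a.sum()
    if m == 0:
        return 0.0
    k = a.sum(axis=1).astype(float)
    d = a.sum(axis=0).astype(float)
    labels = np.unique(np.concatenate([gh, gg]))
    q = 0.0
    for s in labels:
        hs = gh == s
        gs = gg == s
        e_s = a[np.ix_(hs, gs)].sum()
        q += e_s - k[hs].sum() * d[gs].sum() / m
    return q / m


def barber_q(matrix: IncidenceMatrix, partition: ModulePartition) -> float:
    """Barber's bipartite modularity of a given partition."""
    gh, gg = partition.labels(matrix)
    return _barber_q_arrays(matrix.cells.astype(np.int64), gh, gg)


class _AnnealState:
    """Incremental Barber-Q bookkeeping for single-node label moves.

    Q*m*m = sum_s ( m * e_s  -  K_s * D_s ), with e_s the number of links
    inside module s, K_s the summed host degrees and D_s the summed guest
    degrees of module s.  Moving one node updates only two modules.
    """

    def __init__(self, a: np.ndarray, gh: np.ndarray, gg: np.ndarray, n_mod: int):
        self.a = a
        self.m = int(a.sum())
        self.k = a.sum(axis=1).astype(np.int64)
        self.d = a.sum(axis=0).astype(np.int64)
        self.gh = gh.copy()
        self.gg = gg.copy()
        self.n_mod = n_mod
        self.host_neighbors = [np.nonzero(a[i])[0] for i in range(a.shape[0])]
        self.guest_neighbors = [np.nonzero(a[:, j])[0] for j in range(a.shape[1])]
        self.K = np.zeros(n_mod, dtype=np.int64)
        self.D = np.zeros(n_mod, dtype=np.int64)
        self.E = np.zeros(n_mod, dtype=np.int64)
        for i in range(a.shape[0]):
            self.K[gh[i]] += self.k[i]
        for j in range(a.shape[1]):
            self.D[gg[j]] += self.d[j]
        for i in range(a.shape[0]):
            for j in self.host_neighbors[i]:
                if gh[i] == gg[j]:
                    self.E[gh[i]] += 1

    def q(self) -> float:
        if self.m == 0:
            return 0.0
        return float((self.m * self.E.sum() - (self.K * self.D).sum()) / (self.m**2))

    def links_to_module(self, is_host: bool, idx: int, s: int) -> int:
        if is_host:
            return int(np.count_nonzero(self.gg[self.host_neighbors[idx]] == s))
        return int(np.count_nonzero(self.gh[self.guest_neighbors[idx]] == s))

    def delta_q(self, is_host: bool, idx: int, target: int) -> float:
        """Change in Q if node (is_host, idx) moves to module ``target``."""
        src = self.gh[idx] if is_host else self.gg[idx]
        if src == target:
            return 0.0
        e_src = self.links_to_module(is_host, idx, src)
        e_tgt = self.links_to_module(is_host, idx, target)
        deg = self.k[idx] if is_host else self.d[idx]
        if is_host:
            d_penalty = deg * (self.D[target] - self.D[src])
        else:
            d_penalty = deg * (self.K[target] - self.K[src])
        return float(self.m * (e_tgt - e_src) - d_penalty) / (self.m**2)

    def move(self, is_host: bool, idx: int, target: int) -> None:
        src = self.gh[idx] if is_host else self.gg[idx]
        if src == target:
            return
        e_src = self.links_to_module(is_host, idx, src)
        e_tgt = self.links_to_module(is_host, idx, target)
        self.E[src] -= e_src
        self.E[target] += e_tgt
        deg = self.k[idx] if is_host else self.d[idx]
        if is_host:
            self.K[src] -= deg
            self.K[target] += deg
            self.gh[idx] = target
        else:
            self.D[src] -= deg
            self.D[target] += deg
            self.gg[idx] = target


def _optimize_labels(
    a: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    t0: float,
    cooling: float,
    n_restarts: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Simulated-annealing search for the best-Q label assignment."""
    r, c = a.shape
    n = r + c
    best_q = -np.inf
    best = None
    steps_per_restart = max(1, n_steps // max(1, n_restarts))
    for _ in range(max(1, n_restarts)):
        n_mod = min(n, max(2, min(r, c)))
        gh = rng.integers(0, n_mod, size=r)
        gg = rng.integers(0, n_mod, size=c)
        state = _AnnealState(a, gh, gg, n_mod)
        cur_q = state.q()
        loc_best_q = cur_q
        loc_best = (state.gh.copy(), state.gg.copy())
        t = t0
        # pre-draw random numbers in blocks for speed
        for step in range(steps_per_restart):
            if step % 1024 == 0:
                picks = rng.integers(0, n, size=1024)
                targets = rng.integers(0, n_mod, size=1024)
                us = rng.random(size=1024)
            i = int(picks[step % 1024])
            tgt = int(targets[step % 1024])
            is_host = i < r
            idx = i if is_host else i - r
            dq = state.delta_q(is_host, idx, tgt)
            if dq >= 0 or us[step % 1024] < math.exp(dq / max(t, 1e-12)):
                state.move(is_host, idx, tgt)
                cur_q += dq
                if cur_q > loc_best_q:
                    loc_best_q = cur_q
                    loc_best = (state.gh.copy(), state.gg.copy())
            t *= cooling
        if loc_best_q > best_q:
            best_q = loc_best_q
            best = loc_best
    gh, gg = best
    # final greedy hill-climb: single-node best moves until no improvement
    state = _AnnealState(a, gh, gg, int(max(gh.max(initial=0), gg.max(initial=0)) + 1))
    improved = True
    while improved:
        improved = False
        for i in range(n):
            is_host = i < r
            idx = i if is_host else i - r
            dqs = [state.delta_q(is_host, idx, s) for s in range(state.n_mod)]
            s_best = int(np.argmax(dqs))
            if dqs[s_best] > 1e-15:
                state.move(is_host, idx, s_best)
                improved = True
    return state.gh, state.gg, state.q()


def optimize_modules(
    matrix: IncidenceMatrix,
    n_steps: int = DEFAULT_STEPS,
    seed: int | np.random.Generator | None = 0,
    t0: float = 0.02,
    cooling: float | None = None,
    n_restarts: int = 2,
) -> ModulePartition:
    """Find a high-Q module partition by simulated annealing.

    Single-species reassignments with Metropolis acceptance exp(dQ/T) under
    geometric cooling, followed by a greedy hill-climb, so the reported Q is
    a local maximum under single-node moves.  Reproducible given ``seed``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    a = matrix.cells.astype(np.int64)
    if a.sum() == 0:
        return ModulePartition(
            module_of_host={h: 0 for h in matrix.hosts},
            module_of_guest={g: 0 for g in matrix.guests},
            q=0.0,
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if cooling is None:
        # reach ~1e-4 of T0 over the budget
        cooling = math.exp(math.log(1e-4) / max(1, n_steps // max(1, n_restarts)))
    gh, gg, q = _optimize_labels(a, n_steps, rng, t0, cooling, n_restarts)
    # compact labels
    labels = {s: i for i, s in enumerate(np.unique(np.concatenate([gh, gg])))}
    part = ModulePartition(
        module_of_host={h: labels[gh[i]] for i, h in enumerate(matrix.hosts)},
        module_of_guest={g: labels[gg[j]] for j, g in enumerate(matrix.guests)},
        q=float(q),
    )
    return part


# ---------------------------------------------------------------------------
# Null models
# ---------------------------------------------------------------------------

class ImpossibleInputError(ValueError):
    pass


def _null_fill(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    r, c = a.shape
    m = int(a.sum())
    if m > r * c:
        raise ImpossibleInputError("more links than cells")
    flat = rng.choice(r * c, size=m, replace=False)
    out = np.zeros(r * c, dtype=np.int8)
    out[flat] = 1
    return out.reshape(r, c)


def _null_curveball(a: np.ndarray, rng: np.random.Generator, n_sweeps: int = 5) -> np.ndarray:
    """Curveball trades: conserves every row and column total exactly."""
    r = a.shape[0]
    rows = [set(np.nonzero(a[i])[0].tolist()) for i in range(r)]
    n_trades = n_sweeps * max(1, r)
    for _ in range(n_trades):
        i, j = rng.integers(0, r, size=2)
        if i == j:
            continue
        ri, rj = rows[i], rows[j]
        shared = ri & rj
        only_i = list(ri - shared)
        only_j = list(rj - shared)
        n_swap = min(len(only_i), len(only_j))
        if n_swap == 0:
            continue
        pool = only_i + only_j
        perm = rng.permutation(len(pool))
        new_i = {pool[t] for t in perm[: len(only_i)]}
        new_j = {pool[t] for t in perm[len(only_i):]}
        rows[i] = shared | new_i
        rows[j] = shared | new_j
    out = np.zeros_like(a)
    for i, s in enumerate(rows):
        out[i, list(s)] = 1
    return out


def null_matrices(
    matrix: IncidenceMatrix,
    n: int,
    model: str = "fill",
    seed: int | np.random.Generator | None = 0,
) -> list[IncidenceMatrix]:
    """Draw ``n`` random matrices under the chosen null model.

    ``fill``: m ones placed uniformly among the R x C cells, conserving
    dimensions and connectance (the default).  ``marginals``: curveball
    trades conserving every row and column total.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model not in ("fill", "marginals"):
        raise ValueError(f"unknown null model {model!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = matrix.cells.astype(np.int8)
    draws = []
    for _ in range(n):
        b = _null_fill(a, rng) if model == "fill" else _null_curveball(a, rng)
        draws.append(IncidenceMatrix(hosts=matrix.hosts, guests=matrix.guests, cells=b))
    return draws


def significance(
    matrix: IncidenceMatrix,
    metric: str = "nodf",
    n_null: int = 1000,
    seed: int | np.random.Generator | None = 0,
    model: str = "fill",
    optimizer_steps: int = DEFAULT_STEPS,
) -> NullEnsembleResult:
    """Test a structure metric against the null ensemble.

    The p-value is the one-sided upper-tail proportion with the (r+1)/(n+1)
    continuity correction, so p is never exactly zero.  For modularity every
    null matrix is optimised with the same step budget as the observed one.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if metric == "nodf":
        def measure(mat: IncidenceMatrix) -> float:
            return nodf(mat)
    elif metric == "modularity":
        def measure(mat: IncidenceMatrix) -> float:
            return optimize_modules(mat, n_steps=optimizer_steps, seed=rng).q
    else:
        raise ValueError(f"unknown metric {metric!r}")
    observed = measure(matrix)
    nulls = np.array(
        [measure(nm) for nm in null_matrices(matrix, n_null, model=model, seed=rng)]
    )
    sd = float(np.std(nulls, ddof=1)) if len(nulls) > 1 else 0.0
    z = (observed - float(np.mean(nulls))) / sd if sd > 0 else Z_UNDEFINED
    p = (int(np.sum(nulls >= observed)) + 1) / (len(nulls) + 1)
    return NullEnsembleResult(
        observed=observed, null_values=nulls, z=z, p=p, metric=metric, model=model
    )
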