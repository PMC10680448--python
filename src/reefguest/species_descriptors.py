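"""Seven complementary species-level structural descriptors.

For every host sponge: degree, betweenness, closeness, Katz centrality,
among-module connectivity (c), standardized within-module degree (z), and
nestedness contribution (cn).  Path-based centralities are computed on the
full bipartite graph treated as an undirected unipartite graph over
hosts + guests (a one-mode projection is available as a sensitivity switch).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_tables import IncidenceMatrix
from .network_structure import ModulePartition, nodf

DESCRIPTOR_COLUMNS = [
    "degree",
    "betweenness",
    "closeness",
    "katz",
    "ci",
    "zi",
    "cni",
]


class DivergenceError(ValueError):
    """Katz attenuation at or beyond the spectral radius bound."""


class UndefinedContributionError(ValueError):
    """Nestedness contribution of a degree-zero species is undefined."""


def _full_graph(matrix: IncidenceMatrix) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(matrix.hosts, bipartite=0)
    g.add_nodes_from(matrix.guests, bipartite=1)
    rows, cols = np.nonzero(matrix.cells)
    g.add_edges_from(
        (matrix.hosts[i], matrix.guests[j]) for i, j in zip(rows, cols)
    )
    return g


def _adjacency_full(matrix: IncidenceMatrix) -> np.ndarray:
    """(R+C) x (R+C) symmetric adjacency with hosts first."""
    a = matrix.cells.astype(float)
    r, c = a.shape
    full = np.zeros((r + c, r + c))
    full[:r, r:] = a
    full[r:, :r] = a.T
    return full


def degree(matrix: IncidenceMatrix, host: str) -> int:
    """Number of guest species linked to ``host`` (matrix row sum)."""
    return int(matrix.cells[matrix.host_index(host)].sum())


def path_centralities(
    matrix: IncidenceMatrix, projection: bool = False
) -> tuple[dict[str, float], dict[str, float]]:
    """Betweenness and closeness for every species.

    Betweenness is Brandes shortest-path betweenness with Freeman
    normalisation over the full vertex count.  Closeness is computed within
    connected components, (reachable - 1) / sum of geodesic distances, and 0
    for isolated vertices.  With ``projection=True`` both are computed on the
    one-mode host projection instead of the full bipartite graph.
    """
    if projection:
        g = nx.bipartite.projected_graph(_full_graph(matrix), matrix.hosts)
    else:
        g = _full_graph(matrix)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    return betweenness, closeness


def spectral_radius(matrix: IncidenceMatrix) -> float:
    """Largest eigenvalue of the full bipartite adjacency matrix."""
    return float(np.max(np.abs(np.linalg.eigvalsh(_adjacency_full(matrix)))))


def katz(matrix: IncidenceMatrix, alpha: float | None = None) -> dict[str, float]:
    """Katz centrality: attenuated count of walks from each species.

    K = row sums of sum_{t>=1} alpha^t A^t, computed in closed form as
    (I - alpha A)^{-1} - I applied to the all-ones vector.  ``alpha`` must be
    below 1/lambda_max; the default is 0.9/lambda_max.
    """
    full = _adjacency_full(matrix)
    lam = float(np.max(np.abs(np.linalg.eigvalsh(full)))) if full.any() else 0.0
    if alpha is None:
        alpha = 0.9 / lam if lam > 0 else 0.1
    if lam > 0 and alpha >= 1.0 / lam:
        raise DivergenceError(
            f"alpha={alpha} >= 1/lambda_max={1.0 / lam} (lambda_max={lam})"
        )
    n = full.shape[0]
    scores = np.linalg.solve(np.eye(n) - alpha * full, np.ones(n)) - 1.0
    names = matrix.hosts + matrix.guests
    return {name: float(s) for name, s in zip(names, scores)}


def module_roles(
    matrix: IncidenceMatrix, partition: ModulePartition
) -> tuple[dict[str, float], dict[str, float]]:
    """Participation coefficient (c) and within-module degree z-score (z).

    c_i = 1 - sum_s (k_is / k_i)^2 over modules s measures how evenly a
    species spreads its links across modules; z_i standardises the species'
    within-own-module link count against the members of its module (z = 0
    when the module's within-degrees have zero spread).
    """
    gh, gg = partition.labels(matrix)
    a = matrix.cells.astype(np.int64)
    r, c = a.shape
    labels = np.unique(np.concatenate([gh, gg]))
    names = matrix.hosts + matrix.guests
    own = np.concatenate([gh, gg])
    # links from each node to each module (hosts link to guest modules and
    # vice versa)
    k_to_mod = np.zeros((r + c, len(labels)))
    for si, s in enumerate(labels):
        k_to_mod[:r, si] = a[:, gg == s].sum(axis=1)
        k_to_mod[r:, si] = a[gh == s, :].sum(axis=0)
    deg = k_to_mod.sum(axis=1)
    ci = np.zeros(r + c)
    nz = deg > 0
    ci[nz] = 1.0 - np.sum((k_to_mod[nz] / deg[nz, None]) ** 2, axis=1)
    # within-own-module degree, standardised within the module's members
    label_pos = {s: i for i, s in enumerate(labels)}
    within = np.array([k_to_mod[v, label_pos[own[v]]] for v in range(r + c)])
    zi = np.zeros(r + c)
    for s in labels:
        members = own == s
        mu = within[members].mean()
        sd = within[members].std(ddof=0)
        if sd > 0:
            zi[members] = (within[members] - mu) / sd
    return (
        {name: float(v) for name, v in zip(names, ci)},
        {name: float(v) for name, v in zip(names, zi)},
    )


def _bascompte_row_probs(matrix: IncidenceMatrix) -> np.ndarray:
    """Probabilistic-null cell probabilities p_ij = (k_i/C + d_j/R)/2."""
    r, c = matrix.shape
    k = matrix.host_degrees / c
    d = matrix.guest_degrees / r
    return (k[:, None] + d[None, :]) / 2.0


def nestedness_contribution(
    matrix: IncidenceMatrix,
    host: str,
    n_rand: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Per-species nestedness contribution cn as a z-score.

    The focal host's row is replaced ``n_rand`` times by a random row of the
    same degree, partners drawn without replacement with probability
    proportional to the probabilistic-null cell probabilities of the original
    matrix; cn = (NODF_obs - mean NODF_rand) / sd NODF_rand (0 when sd = 0).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    i = matrix.host_index(host)
    k_i = int(matrix.cells[i].sum())
    if k_i == 0:
        raise UndefinedContributionError(f"{host!r} has no links")
    obs = nodf(matrix)
    probs = _bascompte_row_probs(matrix)[i]
    probs = probs / probs.sum()
    c = matrix.shape[1]
    work = matrix.cells.copy()
    vals = np.empty(n_rand)
    for t in range(n_rand):
        partners = rng.choice(c, size=k_i, replace=False, p=probs)
        work[i] = 0
        work[i, partners] = 1
        vals[t] = nodf(work)
    sd = float(vals.std(ddof=1))
    if sd == 0:
        return 0.0
    return (obs - float(vals.mean())) / sd


@dataclass
class DescriptorTable:
    """Per-host values of the seven species-level descriptors."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESCRIPTOR_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"descriptor table missing columns: {missing}")

    @property
    def hosts(self) -> list[str]:
        return list(self.table.index)

    def values(self) -> np.ndarray:
        return self.table[DESCRIPTOR_COLUMNS].to_numpy(dtype=float)

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index_label="host_species")


def descriptor_table(
    matrix: IncidenceMatrix,
    partition: ModulePartition,
    alpha: float | None = None,
    n_rand: int = 1000,
    seed: int | np.random.Generator | None = 0,
    projection: bool = False,
) -> DescriptorTable:
    """Assemble the seven descriptors for every host sponge.

    Guests receive descriptor values internally (the graph metrics are
    defined over all species) but only host rows are exported: importance is
    scored for the sponges.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    bet, clo = path_centralities(matrix, projection=projection)
    kz = katz(matrix, alpha=alpha)
    ci, zi = module_roles(matrix, partition)
    rows = {}
    for h in matrix.hosts:
        rows[h] = {
            "degree": degree(matrix, h),
            "betweenness": bet.get(h, 0.0),
            "closeness": clo.get(h, 0.0),
            "katz": kz[h],
            "ci": ci[h],
            "zi": zi[h],
            "cni": nestedness_contribution(matrix, h, n_rand=n_rand, seed=rng),
        }
    return DescriptorTable(pd.DataFrame.from_dict(rows, orient="index"))
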