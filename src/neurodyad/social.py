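"""Sociometric rosters and the social graphs derived from them.

A roster-and-rating instrument asks every student to rate, on a five-point
Likert scale (1 = "None" ... 5 = "Most"), how much time they spend with each
peer in their year group.  Ratings are binarised at a threshold (4, "more
than some", or 5, "most") and by default kept only when reciprocated; the
resulting undirected friendship graph supplies

* dyadic **social distance** — geodesic (shortest-path) length,
* **community affiliation** — Louvain modules at resolution γ,
* cohort-level summary metrics — diameter, modularity, mean path length,
  reciprocity, density and eigenvector centrality.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Literal, Sequence

import igraph as ig
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Likert anchors of the roster instrument, in instrument order.
LIKERT_LABELS: dict[int, str] = {
    1: "None",
    2: "A rare amount",
    3: "Some",
    4: "More than some",
    5: "Most",
}

TieMode = Literal["reciprocal", "directed"]


# ---------------------------------------------------------------------------
# roster


@dataclass(frozen=True)
class RosterRating:
    """Who-rates-whom Likert matrix.

    ``ratings`` is a square DataFrame; entry (i, j) is i's rating of j in
    {1..5}, NaN when missing.  The diagonal is always missing (students do
    not rate themselves).
    """

    ids: tuple[str, ...]
    ratings: pd.DataFrame
    cohort: str | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate student IDs in roster")
        df = self.ratings
        if df.shape[0] != df.shape[1]:
            raise ValueError(f"roster must be square, got {df.shape}")
        if tuple(map(str, df.index)) != ids or tuple(map(str, df.columns)) != ids:
            raise ValueError("roster index/columns must equal the ID list")
        vals = df.to_numpy(dtype=float)
        if vals.size and not np.all(np.isnan(np.diag(vals))):
            raise ValueError("roster diagonal must be missing (no self-ratings)")
        off = ~np.eye(len(ids), dtype=bool)
        present = off & ~np.isnan(vals)
        bad = present & ~(np.isin(vals, [1.0, 2.0, 3.0, 4.0, 5.0]))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"rating out of range at ({ids[r]}, {ids[c]}): {vals[r, c]!r}; "
                "ratings must be integers in 1..5"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def rating(self, i: str, j: str) -> float:
        return float(self.ratings.at[i, j])

    def to_csv(self, path) -> None:
        """Write the roster (header row/column of IDs, empty diagonal)."""
        self.ratings.to_csv(path, float_format="%g")


def load_roster(path, cohort: str | None = None) -> RosterRating:
    """Read and validate a roster CSV.

    Students who did not take part in the survey (an entirely missing row
    or an entirely missing column) are dropped, since their outgoing ties
    are unknown and incoming ties to non-participants are removed.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicate student IDs in {path}")
    if set(df.index) != set(df.columns):
        raise ValueError(f"row and column ID sets differ in {path}")
    df = df.loc[:, list(df.index)]
    vals = df.to_numpy(dtype=float)
    np.fill_diagonal(vals, np.nan)
    df = pd.DataFrame(vals, index=df.index, columns=df.columns)

    # drop non-participants (all-missing row or column)
    while len(df) > 1:
        empty = [
            i
            for i in df.index
            if df.loc[i].isna().all() or df[i].isna().all()
        ]
        if not empty:
            break
        logger.info("dropping %d non-participant(s): %s", len(empty), empty)
        keep = [i for i in df.index if i not in set(empty)]
        df = df.loc[keep, keep]

    return RosterRating(ids=tuple(df.index), ratings=df, cohort=cohort)


def count_dyads(n: int) -> int:
    """Number of unordered pairs among ``n`` students, n(n−1)/2."""
    if n < 2:
        raise ValueError(f"need at least 2 students to form a dyad, got {n}")
    return n * (n - 1) // 2


# ---------------------------------------------------------------------------
# graphs


@dataclass(frozen=True)
class SocialGraph:
    """Binarised tie graph at a given rating threshold."""

    ids: tuple[str, ...]
    adjacency: np.ndarray  # bool, (n, n); symmetric iff not directed
    directed: bool
    threshold: int
    cohort: str | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.shape != (len(self.ids), len(self.ids)):
            raise ValueError("adjacency shape does not match IDs")
        if a.diagonal().any():
            raise ValueError("self-loops are not allowed")
        if not self.directed and not np.array_equal(a, a.T):
            raise ValueError("undirected graph must have symmetric adjacency")
        object.__setattr__(self, "adjacency", a)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_edges(self) -> int:
        s = int(self.adjacency.sum())
        return s if self.directed else s // 2

    def to_igraph(self) -> ig.Graph:
        mode = "directed" if self.directed else "undirected"
        g = ig.Graph.Adjacency(self.adjacency.astype(int).tolist(), mode=mode)
        g.vs["name"] = list(self.ids)
        return g

    def edge_list(self) -> pd.DataFrame:
        """Tidy edge list (source, target); one row per edge/arc."""
        rows = []
        a = self.adjacency
        for i in range(self.n):
            for j in range(self.n):
                if a[i, j] and (self.directed or i < j):
                    rows.append((self.ids[i], self.ids[j]))
        return pd.DataFrame(rows, columns=["source", "target"])

    def write_graphml(self, path) -> None:
        self.to_igraph().write_graphml(str(path))


def build_social_graph(
    roster: RosterRating,
    threshold: int = 4,
    mode: TieMode = "reciprocal",
) -> SocialGraph:
    """Binarise a roster into a tie graph.

    ``reciprocal``: undirected edge iff both directed ratings ≥ threshold.
    ``directed``: arc i→j iff i's rating of j ≥ threshold.
    Missing ratings never create ties.
    """
    if threshold not in (4, 5):
        raise ValueError(f"threshold must be 4 or 5, got {threshold}")
    if mode not in ("reciprocal", "directed"):
        raise ValueError(f"unknown tie mode {mode!r}")
    vals = roster.ratings.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        arcs = np.where(np.isnan(vals), False, vals >= threshold)
    np.fill_diagonal(arcs, False)
    if mode == "reciprocal":
        adj = arcs & arcs.T
        return SocialGraph(roster.ids, adj, directed=False, threshold=threshold,
                           cohort=roster.cohort)
    return SocialGraph(roster.ids, arcs, directed=True, threshold=threshold,
                       cohort=roster.cohort)


# ---------------------------------------------------------------------------
# distances


@dataclass(frozen=True)
class SocialDistanceMatrix:
    """Geodesic distances d_ij; ``inf`` marks unreachable pairs."""

    ids: tuple[str, ...]
    values: np.ndarray  # float, (n, n), inf = unreachable

    def distance(self, i: str, j: str) -> float:
        ii, jj = self.ids.index(i), self.ids.index(j)
        return float(self.values[ii, jj])

    @property
    def n_unreachable_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isinf(self.values[iu]).sum())

    def tidy(self) -> pd.DataFrame:
        """One row per unordered pair: subject_i, subject_j, distance."""
        rows = []
        n = len(self.ids)
        for a in range(n):
            for b in range(a + 1, n):
                d = self.values[a, b]
                rows.append((self.ids[a], self.ids[b],
                             np.nan if np.isinf(d) else d))
        return pd.DataFrame(rows, columns=["subject_i", "subject_j", "distance"])


def social_distance(graph: SocialGraph) -> SocialDistanceMatrix:
    """Shortest-path length between every pair of students.

    Defined on the reciprocal (undirected) graph only; unreachable pairs
    are flagged with ``inf`` rather than a number.
    """
    if graph.directed:
        raise ValueError("social distance is defined on the reciprocal graph; "
                         "got a directed graph")
    d = np.asarray(graph.to_igraph().distances(), dtype=float)
    m = SocialDistanceMatrix(graph.ids, d)
    if m.n_unreachable_pairs:
        logger.info("%d unreachable dyad(s) in cohort %s",
                    m.n_unreachable_pairs, graph.cohort)
    return m


# ---------------------------------------------------------------------------
# communities


@dataclass(frozen=True)
class CommunityPartition:
    """Louvain module assignment with its modularity Q."""

    membership: dict[str, int]
    modularity: float
    resolution: float
    seed: int
    restarts: int

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def same_community(self, i: str, j: str) -> int:
        return int(self.membership[i] == self.membership[j])

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.membership.items()), columns=["subject", "community"]
        )


def detect_communities(
    graph: SocialGraph,
    resolution: float = 1.0,
    seed: int = 0,
    restarts: int = 100,
) -> CommunityPartition:
    """Best-of-restarts Louvain partition of an undirected graph.

    Louvain multi-level modularity optimisation is greedy and
    order-dependent, so it is restarted ``restarts`` times under a seeded
    RNG and the partition with maximal Q is kept (ties broken by first
    occurrence in seeded order).  Deterministic given ``seed``.
    """
    if graph.directed:
        raise ValueError("community detection expects the undirected graph")
    g = graph.to_igraph()
    if g.ecount() == 0:
        raise ValueError("cannot detect communities in an edgeless graph")
    rng = random.Random(seed)
    best_q, best_membership = -np.inf, None
    ig.set_random_number_generator(rng)
    try:
        for _ in range(max(1, int(restarts))):
            part = g.community_multilevel(resolution=resolution)
            q = g.modularity(part.membership, resolution=resolution)
            if q > best_q:
                best_q, best_membership = q, list(part.membership)
    finally:
        ig.set_random_number_generator(random)
    membership = {graph.ids[i]: int(c) for i, c in enumerate(best_membership)}
    return CommunityPartition(
        membership=membership,
        modularity=float(best_q),
        resolution=float(resolution),
        seed=int(seed),
        restarts=int(restarts),
    )


# ---------------------------------------------------------------------------
# summary metrics


@dataclass(frozen=True)
class NetworkSummary:
    """Cohort-level network characteristics.

    diameter — longest geodesic between reachable pairs; mean_path_length —
    mean geodesic over ordered reachable pairs (self-pairs excluded);
    reciprocity — fraction of arcs in the directed graph that are mutual;
    density — edges over n(n−1)/2 in the undirected graph; eigenvector
    centrality — principal-eigenvector score, max-normalised to 1.
    """

    diameter: float
    modularity: float
    mean_path_length: float
    reciprocity: float
    density: float
    eigenvector_centrality: pd.Series

    def to_dict(self) -> dict:
        return {
            "diameter": self.diameter,
            "modularity": self.modularity,
            "mean_path_length": self.mean_path_length,
            "reciprocity": self.reciprocity,
            "density": self.density,
            "eigenvector_centrality": {
                k: float(v) for k, v in self.eigenvector_centrality.items()
            },
        }


def network_summary(
    graph: SocialGraph,
    directed_counterpart: SocialGraph,
    seed: int = 0,
    resolution: float = 1.0,
    restarts: int = 100,
) -> NetworkSummary:
    """Summary metrics for a reciprocal graph plus its directed counterpart.

    The directed graph (same roster, same threshold) is needed only for
    reciprocity; all other metrics are computed on the reciprocal graph.
    """
    if graph.directed:
        raise ValueError("network_summary expects the reciprocal graph first")
    if not directed_counterpart.directed:
        raise ValueError("second argument must be the directed counterpart")
    if graph.n_edges == 0:
        raise ValueError("network summary undefined for an edgeless graph")

    dist = social_distance(graph).values
    iu = ~np.eye(graph.n, dtype=bool)
    finite = dist[iu][np.isfinite(dist[iu])]
    diameter = float(finite.max())
    mean_path = float(finite.mean())

    part = detect_communities(graph, resolution=resolution, seed=seed,
                              restarts=restarts)

    a = directed_counterpart.adjacency
    total_arcs = int(a.sum())
    mutual_arcs = int((a & a.T).sum())
    reciprocity = mutual_arcs / total_arcs if total_arcs else 0.0

    density = graph.n_edges / count_dyads(graph.n)

    # principal eigenvector of the symmetric adjacency, max-normalised;
    # dense eigh keeps the result deterministic (ARPACK starts are not)
    a_sym = graph.adjacency.astype(float)
    w, v = np.linalg.eigh(a_sym)
    vec = v[:, int(np.argmax(w))]
    if vec.sum() < 0:
        vec = -vec
    vec = np.abs(vec)
    vec = vec / vec.max() if vec.max() > 0 else vec
    centrality = pd.Series(vec, index=list(graph.ids),
                           name="eigenvector_centrality")

    return NetworkSummary(
        diameter=diameter,
        modularity=part.modularity,
        mean_path_length=mean_path,
        reciprocity=float(reciprocity),
        density=float(density),
        eigenvector_centrality=centrality,
    )


# ---------------------------------------------------------------------------
# direct-tie proximity


def direct_tie_distance(
    roster: RosterRating,
    pairs: Sequence[tuple[str, str]],
    rule: Literal["mean", "min", "max"] = "mean",
) -> pd.DataFrame:
    """Proximity of scanned pairs from the two directed ratings.

    The two members of a dyad may have rated each other differently; the
    pairwise proximity aggregates the two directed ratings with ``rule``
    (mean by default, min/max as robustness options).
    """
    aggs = {"mean": np.mean, "min": np.min, "max": np.max}
    if rule not in aggs:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    rows = []
    for i, j in pairs:
        rij, rji = roster.rating(i, j), roster.rating(j, i)
        if np.isnan(rij) or np.isnan(rji):
            raise ValueError(f"missing rating within pair ({i}, {j})")
        rows.append((i, j, float(aggs[rule]([rij, rji]))))
    return pd.DataFrame(rows, columns=["subject_i", "subject_j", "proximity"])
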