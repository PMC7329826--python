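"""Signed graph-theoretic characterisation of individual connectomes.

Each subject's weighted, signed connectivity matrix is summarised by

* nodal strength — the sum of positive (s⁺) and of rectified negative
  (s⁻) edge weights at each parcel,
* signed modularity Q* — a Louvain-style optimisation of an asymmetric
  objective in which positive weights dominate:
  Q* = Q⁺ − (v⁻ / (v⁺ + v⁻))·Q⁻, with Q± the ordinary weighted
  modularities of the rectified positive/negative layers and v± their
  total weights,
* nodal diversity — the normalised entropy of each node's strength
  distribution across the modules of that subject's own partition.

Dyadic similarity of these summaries (vector correlation for strength and
diversity, absolute difference for modularity) gives outcomes that slot
into the same mixed-model machinery as connectome similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

Objective = Literal["asymmetric", "symmetric"]


@dataclass(frozen=True)
class NodalMetrics:
    """Per-subject graph metrics of one signed connectome."""

    subject_id: str | None
    labels: tuple[str, ...]
    strength_pos: np.ndarray
    strength_neg: np.ndarray
    diversity_pos: np.ndarray
    diversity_neg: np.ndarray
    modularity: float
    partition: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel": list(self.labels),
                "strength_pos": self.strength_pos,
                "strength_neg": self.strength_neg,
                "diversity_pos": self.diversity_pos,
                "diversity_neg": self.diversity_neg,
                "module": self.partition,
            }
        )


def _signed_weights(matrix) -> np.ndarray:
    """Off-diagonal signed weight matrix from a connectivity container or
    raw square array (diagonal zeroed)."""
    w = np.asarray(getattr(matrix, "values", matrix), dtype=float).copy()
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"expected a square matrix, got {w.shape}")
    w = np.where(np.isnan(w), 0.0, w)
    np.fill_diagonal(w, 0.0)
    return (w + w.T) / 2.0


def nodal_strength(matrix) -> pd.DataFrame:
    """Positive and rectified negative strength per node.

    s⁺_i = Σ_j max(w_ij, 0) and s⁻_i = Σ_j max(−w_ij, 0), diagonal masked.
    """
    w = _signed_weights(matrix)
    labels = getattr(matrix, "labels", tuple(map(str, range(w.shape[0]))))
    return pd.DataFrame(
        {
            "strength_pos": np.clip(w, 0.0, None).sum(axis=1),
            "strength_neg": np.clip(-w, 0.0, None).sum(axis=1),
        },
        index=list(labels),
    )


# ---------------------------------------------------------------------------
# signed modularity


def _signed_modularity_matrix(
    w: np.ndarray, gamma: float, objective: Objective
) -> np.ndarray:
    """Generalised modularity matrix M with Q*(g) = Σ_{i≠j} M_ij δ(g_i,g_j)."""
    wp = np.clip(w, 0.0, None)
    wn = np.clip(-w, 0.0, None)
    vp, vn = wp.sum(), wn.sum()
    if vp + vn == 0:
        raise ValueError("all-zero weight matrix has no modular structure")

    def layer(wl: np.ndarray, vl: float) -> np.ndarray:
        if vl == 0:
            return np.zeros_like(wl)
        k = wl.sum(axis=1)
        return wl - gamma * np.outer(k, k) / vl

    bp, bn = layer(wp, vp), layer(wn, vn)
    if objective == "asymmetric":
        # Q⁺ weighted fully, Q⁻ down-weighted by its share of total weight
        m = (bp / vp if vp else bp) - bn / (vp + vn)
    elif objective == "symmetric":
        m = (bp - bn) / (vp + vn)
    else:
        raise ValueError(f"unknown objective {objective!r}")
    return (m + m.T) / 2.0


def signed_modularity_value(
    matrix, partition, gamma: float = 1.0, objective: Objective = "asymmetric"
) -> float:
    """Evaluate the signed modularity objective on a given partition.

    Diagonal null-model terms (δ(g_i, g_i) = 1 always) are included, so
    with no negative weights this equals the ordinary weighted modularity.
    """
    w = _signed_weights(matrix)
    m = _signed_modularity_matrix(w, gamma, objective)
    g = np.asarray(partition)
    same = g[:, None] == g[None, :]
    return float(m[same].sum())


def _local_move(m: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """One sweep of greedy single-node moves; returns True if anything moved.

    With diag(M) = 0, moving a node to community c changes Q* by
    2·(Σ_{j∈c} M[node,j] − Σ_{j∈current} M[node,j]).
    """
    moved = False
    for node in rng.permutation(m.shape[0]):
        current = labels[node]
        comms = np.unique(labels)
        attach = {c: m[node, labels == c].sum() for c in comms}
        best_c = max(attach, key=lambda c: (attach[c], -c))
        if attach[best_c] > attach[current] + 1e-13 and best_c != current:
            labels[node] = best_c
            moved = True
    return moved


def _merge_communities(m: np.ndarray, labels: np.ndarray) -> bool:
    """Greedy pairwise community merges with positive objective gain."""
    comms = list(np.unique(labels))
    best_gain, best_pair = 0.0, None
    for a_idx in range(len(comms)):
        for b_idx in range(a_idx + 1, len(comms)):
            a, b = comms[a_idx], comms[b_idx]
            gain = 2.0 * m[np.ix_(labels == a, labels == b)].sum()
            if gain > best_gain + 1e-13:
                best_gain, best_pair = gain, (a, b)
    if best_pair is None:
        return False
    a, b = best_pair
    labels[labels == b] = a
    return True


def signed_modularity(
    matrix,
    gamma: float = 1.0,
    seed: int = 0,
    restarts: int = 20,
    objective: Objective = "asymmetric",
) -> tuple[float, np.ndarray]:
    """Louvain-style maximisation of the signed modularity objective.

    Greedy single-node moves from a singleton start, interleaved with
    greedy community merges, restarted ``restarts`` times under a seeded
    RNG; the best (Q*, partition) is returned with community labels
    relabelled to 0..m−1 in order of first appearance.  Deterministic
    given ``seed``.
    """
    w = _signed_weights(matrix)
    m_full = _signed_modularity_matrix(w, gamma, objective)
    # diagonal terms are partition-invariant: split them off for the moves
    diag_const = float(np.trace(m_full))
    m = m_full.copy()
    np.fill_diagonal(m, 0.0)
    n = m.shape[0]
    rng = np.random.default_rng(seed)

    best_q, best_labels = -np.inf, None
    for _ in range(max(1, int(restarts))):
        labels = np.arange(n)
        for _outer in range(100):
            changed = False
            while _local_move(m, labels, rng):
                changed = True
            if _merge_communities(m, labels):
                changed = True
            if not changed:
                break
        g = np.asarray(labels)
        q = float(m[g[:, None] == g[None, :]].sum()) + diag_const
        if q > best_q:
            best_q, best_labels = q, labels.copy()

    # canonical labels 0..m−1
    _, canonical = np.unique(best_labels, return_inverse=True)
    order = {}
    out = np.empty(n, dtype=int)
    for i, c in enumerate(canonical):
        out[i] = order.setdefault(int(c), len(order))
    return best_q, out


# ---------------------------------------------------------------------------
# diversity


def nodal_diversity(matrix, partition) -> pd.DataFrame:
    """Normalised entropy of nodal strength across modules.

    h±_i = −(1/log m) Σ_u p±_i(u) log p±_i(u) with p±_i(u) the share of
    node i's positive (negative) strength falling in module u, and
    0·log 0 := 0.  Requires m ≥ 2 modules; a node with zero total strength
    in one sign has diversity 0 for that sign.
    """
    w = _signed_weights(matrix)
    g = np.asarray(partition)
    modules = np.unique(g)
    n_mod = len(modules)
    if n_mod < 2:
        raise ValueError("nodal diversity requires at least 2 modules")
    labels = getattr(matrix, "labels", tuple(map(str, range(w.shape[0]))))

    def entropy(wl: np.ndarray) -> np.ndarray:
        per_mod = np.stack([wl[:, g == u].sum(axis=1) for u in modules], axis=1)
        tot = per_mod.sum(axis=1)
        h = np.zeros(w.shape[0])
        ok = tot > 0
        p = per_mod[ok] / tot[ok, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        h[ok] = -plogp.sum(axis=1) / np.log(n_mod)
        return np.clip(h, 0.0, 1.0)

    return pd.DataFrame(
        {
            "diversity_pos": entropy(np.clip(w, 0.0, None)),
            "diversity_neg": entropy(np.clip(-w, 0.0, None)),
        },
        index=list(labels),
    )


# ---------------------------------------------------------------------------
# per-subject bundle and dyadic similarity


def compute_nodal_metrics(
    matrix,
    gamma: float = 1.0,
    seed: int = 0,
    restarts: int = 20,
    objective: Objective = "asymmetric",
) -> NodalMetrics:
    """All graph metrics of one connectome, using the subject's own signed
    Louvain partition for diversity."""
    strengths = nodal_strength(matrix)
    q, part = signed_modularity(
        matrix, gamma=gamma, seed=seed, restarts=restarts, objective=objective
    )
    if len(np.unique(part)) >= 2:
        div = nodal_diversity(matrix, part)
        dpos = div["diversity_pos"].to_numpy()
        dneg = div["diversity_neg"].to_numpy()
    else:
        dpos = np.zeros(len(strengths))
        dneg = np.zeros(len(strengths))
    labels = getattr(matrix, "labels", tuple(strengths.index))
    return NodalMetrics(
        subject_id=getattr(matrix, "subject_id", None),
        labels=tuple(labels),
        strength_pos=strengths["strength_pos"].to_numpy(),
        strength_neg=strengths["strength_neg"].to_numpy(),
        diversity_pos=dpos,
        diversity_neg=dneg,
        modularity=float(q),
        partition=part,
    )


def metric_similarity(
    metrics_i: NodalMetrics,
    metrics_j: NodalMetrics,
    kind: Literal["strength", "diversity", "modularity"],
    signs: Literal["both", "positive", "negative"] = "both",
) -> float:
    """Dyadic similarity of graph metrics.

    strength / diversity → Pearson correlation of the per-node vectors
    (positive and negative concatenated by default); modularity → absolute
    difference of the scalar Q* values.
    """
    if metrics_i.labels != metrics_j.labels:
        raise ValueError("parcel labels differ between subjects")
    if kind == "modularity":
        return float(abs(metrics_i.modularity - metrics_j.modularity))
    if kind == "strength":
        parts = {"positive": ("strength_pos",), "negative": ("strength_neg",),
                 "both": ("strength_pos", "strength_neg")}[signs]
    elif kind == "diversity":
        parts = {"positive": ("diversity_pos",), "negative": ("diversity_neg",),
                 "both": ("diversity_pos", "diversity_neg")}[signs]
    else:
        raise ValueError(f"unknown metric kind {kind!r}")
    vi = np.concatenate([getattr(metrics_i, p) for p in parts])
    vj = np.concatenate([getattr(metrics_j, p) for p in parts])
    return float(np.corrcoef(vi, vj)[0, 1])
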