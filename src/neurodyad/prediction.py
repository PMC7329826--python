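"""Elastic-net prediction of social distance from edge-level similarity.

Whole-connectome similarity compresses each dyad to one number; this
module instead asks whether the *collection* of local similarities — one
feature per parcel pair, by default −|z_i(p,q) − z_j(p,q)| — encodes
social distance.  An elastic net (L1/L2 mix α, penalty λ) is tuned by
nested cross-validation whose folds are grouped by subject: every dyad
touching a held-out subject leaves the training set, because dyads sharing
a member are dependent and plain k-fold would leak.  A permutation test on
the out-of-fold prediction score provides the significance surface.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

from .connectivity import FisherZMatrix

logger = logging.getLogger(__name__)

FeatureVariant = Literal["neg_abs_diff", "product", "mean"]


@dataclass(frozen=True)
class FeatureTable:
    """Per-dyad edgewise features with subject grouping.

    ``X`` is (n_dyads × n_edges) with one column per parcel pair (p < q,
    row-major); ``y`` the social distance target; the subject columns
    drive grouped cross-validation.
    """

    X: np.ndarray
    y: np.ndarray
    subject_i: tuple[str, ...]
    subject_j: tuple[str, ...]
    edge_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.y), len(self.edge_labels)):
            raise ValueError("feature matrix shape mismatch")
        if len(self.subject_i) != len(self.y) or len(self.subject_j) != len(self.y):
            raise ValueError("subject columns must match the number of dyads")

    @property
    def n_dyads(self) -> int:
        return len(self.y)

    @property
    def subjects(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in (*self.subject_i, *self.subject_j):
            seen.setdefault(s)
        return tuple(seen)

    def save(self, matrix_path, sidecar_path) -> None:
        """Compressed feature matrix plus a dyad-metadata sidecar CSV."""
        np.savez_compressed(matrix_path, X=self.X,
                            edge_labels=np.asarray(self.edge_labels))
        pd.DataFrame(
            {"subject_i": self.subject_i, "subject_j": self.subject_j,
             "distance": self.y}
        ).to_csv(sidecar_path, index=False, float_format="%.17g")

    @classmethod
    def load(cls, matrix_path, sidecar_path) -> "FeatureTable":
        with np.load(matrix_path, allow_pickle=False) as npz:
            x = npz["X"]
            edge_labels = tuple(str(e) for e in npz["edge_labels"])
        meta = pd.read_csv(sidecar_path, float_precision="round_trip")
        return cls(
            X=x, y=meta["distance"].to_numpy(float),
            subject_i=tuple(meta["subject_i"].astype(str)),
            subject_j=tuple(meta["subject_j"].astype(str)),
            edge_labels=edge_labels,
        )


@dataclass
class ENConfig:
    """Hyperparameter search and cross-validation settings.

    ``l1_ratios`` is the L1/L2 mixing grid (α in elastic-net notation);
    the λ path has ``n_lambda`` values log-spaced over ``lambda_decades``
    decades down from λ_max (the smallest λ zeroing every coefficient).
    ``lambdas`` overrides the path with an explicit grid.
    """

    l1_ratios: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0)
    n_lambda: int = 50
    lambda_decades: float = 4.0
    lambdas: tuple[float, ...] | None = None
    outer_folds: int = 5
    inner_folds: int = 3
    max_iter: int = 5000
    tol: float = 1e-4


@dataclass(frozen=True)
class ElasticNetResult:
    """Nested-CV elastic-net outcome."""

    score_r: float
    score_mse: float
    oof_pred: np.ndarray
    chosen: tuple[tuple[float, float], ...]  # (l1_ratio, lambda) per outer fold
    final_l1_ratio: float
    final_lambda: float
    coef: np.ndarray
    n_nonzero: int
    fold_stats_hash: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "score_r": self.score_r,
            "score_mse": self.score_mse,
            "chosen": [list(c) for c in self.chosen],
            "final_l1_ratio": self.final_l1_ratio,
            "final_lambda": self.final_lambda,
            "n_nonzero": self.n_nonzero,
            "fold_stats_hash": self.fold_stats_hash,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class PermutationResult:
    pvalue: float
    observed: float
    perm_scores: np.ndarray
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------
# features


def edgewise_similarity_features(
    zmats: Sequence[FisherZMatrix],
    distances,
    variant: FeatureVariant = "neg_abs_diff",
) -> FeatureTable:
    """One feature per parcel pair and dyad.

    ``neg_abs_diff`` (default): −|z_i(p,q) − z_j(p,q)| — 0 is maximal
    similarity and every feature is symmetric in the two subjects.
    ``product`` and ``mean`` are alternative symmetric constructions.
    Dyads with unreachable social distance are dropped with a logged count.
    """
    if len(zmats) < 2:
        raise ValueError("need at least two subjects")
    labels = zmats[0].labels
    for z in zmats:
        if z.labels != labels:
            raise ValueError("parcel labels differ between subjects")
    p = len(labels)
    iu = np.triu_indices(p, k=1)
    edge_labels = tuple(f"{labels[a]}~{labels[b]}" for a, b in zip(*iu))
    vecs = {z.subject_id: z.upper_triangle() for z in zmats}

    combine = {
        "neg_abs_diff": lambda a, b: -np.abs(a - b),
        "product": lambda a, b: a * b,
        "mean": lambda a, b: (a + b) / 2.0,
    }.get(variant)
    if combine is None:
        raise ValueError(f"unknown feature variant {variant!r}")

    rows, targets, si, sj = [], [], [], []
    n_dropped = 0
    ids = [z.subject_id for z in zmats]
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            d = distances.distance(ids[a], ids[b])
            if not np.isfinite(d):
                n_dropped += 1
                continue
            rows.append(combine(vecs[ids[a]], vecs[ids[b]]))
            targets.append(float(d))
            si.append(ids[a])
            sj.append(ids[b])
    if n_dropped:
        logger.info("dropped %d dyad(s) with unreachable distance", n_dropped)
    return FeatureTable(
        X=np.vstack(rows),
        y=np.asarray(targets, dtype=float),
        subject_i=tuple(si),
        subject_j=tuple(sj),
        edge_labels=edge_labels,
    )


# ---------------------------------------------------------------------------
# grouped folds and the fitting machinery


def _subject_folds(
    subjects: Sequence[str], n_folds: int, rng: np.random.Generator
) -> list[set[str]]:
    ids = list(subjects)
    rng.shuffle(ids)
    return [set(ids[k::n_folds]) for k in range(n_folds)]


def _masks(ft_i, ft_j, held: set[str]) -> tuple[np.ndarray, np.ndarray]:
    touch = np.array([i in held or j in held for i, j in zip(ft_i, ft_j)])
    return ~touch, touch  # train, test


def _lambda_path(xs: np.ndarray, yc: np.ndarray, l1: float, cfg: ENConfig) -> np.ndarray:
    if cfg.lambdas is not None:
        return np.asarray(cfg.lambdas, dtype=float)
    n = len(yc)
    lam_max = np.max(np.abs(xs.T @ yc)) / (n * max(l1, 1e-3))
    lam_max = max(lam_max, 1e-12)
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max) - cfg.lambda_decades, cfg.n_lambda
    )


def _standardise(x_train: np.ndarray):
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _path_predictions(
    x_tr, y_tr, x_te, l1: float, lambdas: np.ndarray, cfg: ENConfig
) -> np.ndarray:
    """Test-set predictions along a decreasing λ path (warm-started)."""
    est = ElasticNet(
        l1_ratio=l1, fit_intercept=True, warm_start=True,
        max_iter=cfg.max_iter, tol=cfg.tol,
    )
    preds = np.empty((len(lambdas), x_te.shape[0]))
    for k, lam in enumerate(lambdas):
        est.set_params(alpha=float(lam))
        est.fit(x_tr, y_tr)
        preds[k] = est.predict(x_te)
    return preds


def _select_hyperparams(
    x, y, si, sj, cfg: ENConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Inner grouped CV: pick (l1_ratio, λ) minimising mean MSE."""
    subjects = list(dict.fromkeys([*si, *sj]))
    folds = _subject_folds(subjects, min(cfg.inner_folds, max(2, len(subjects) // 2)),
                           rng)
    best = (np.inf, cfg.l1_ratios[0], 0.0)
    for l1 in cfg.l1_ratios:
        mu_all, sd_all = _standardise(x)
        lambdas = _lambda_path((x - mu_all) / sd_all, y - y.mean(), l1, cfg)
        errs = np.zeros(len(lambdas))
        counts = np.zeros(len(lambdas))
        for held in folds:
            tr, te = _masks(si, sj, held)
            if tr.sum() < 3 or te.sum() == 0:
                continue
            mu, sd = _standardise(x[tr])
            preds = _path_predictions(
                (x[tr] - mu) / sd, y[tr], (x[te] - mu) / sd, l1, lambdas, cfg
            )
            errs += ((preds - y[te]) ** 2).mean(axis=1)
            counts += 1
        with np.errstate(invalid="ignore"):
            mean_err = errs / np.where(counts == 0, np.nan, counts)
        if np.all(np.isnan(mean_err)):
            continue  # no usable inner fold for this mixing value
        k = int(np.nanargmin(mean_err))
        if mean_err[k] < best[0]:
            best = (float(mean_err[k]), float(l1), float(lambdas[k]))
    if not np.isfinite(best[0]):
        # degenerate grouping: fall back to the midpoint of the first path
        l1 = cfg.l1_ratios[0]
        mu, sd = _standardise(x)
        lambdas = _lambda_path((x - mu) / sd, y - y.mean(), l1, cfg)
        logger.warning("inner CV had no usable folds; using midpoint lambda")
        return float(l1), float(np.median(lambdas))
    return best[1], best[2]


def _fit_single(x_tr, y_tr, l1: float, lam: float, cfg: ENConfig) -> ElasticNet:
    est = ElasticNet(alpha=lam, l1_ratio=l1, fit_intercept=True,
                     max_iter=cfg.max_iter, tol=cfg.tol)
    est.fit(x_tr, y_tr)
    return est


def _score_r(pred: np.ndarray, y: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1])


def fit_elastic_net(
    features: FeatureTable, cv: ENConfig | None = None, seed: int = 0
) -> ElasticNetResult:
    """Nested subject-grouped cross-validation of the elastic net.

    Outer folds hold out subjects (every dyad touching a held-out subject
    leaves the training set; dyads touching several folds' subjects are
    predicted in each and their predictions averaged).  Inner folds select
    (α, λ) by mean squared error.  Feature standardisation is computed on
    training dyads only, per fold.  Returns out-of-fold prediction scores
    (Pearson r and MSE), the per-fold chosen hyperparameters, and a full-
    data refit at the majority hyperparameters for coefficient inspection.
    """
    cfg = cv or ENConfig()
    if features.n_dyads < 20:
        raise ValueError("need at least 20 dyads for nested cross-validation")
    y = features.y
    if np.unique(y).size < 2:
        raise ValueError("degenerate target: a single distance value")
    x = features.X
    si, sj = features.subject_i, features.subject_j
    rng = np.random.default_rng(seed)

    folds = _subject_folds(list(features.subjects), cfg.outer_folds, rng)
    pred_sum = np.zeros(features.n_dyads)
    pred_cnt = np.zeros(features.n_dyads)
    chosen: list[tuple[float, float]] = []
    fold_means: list[np.ndarray] = []
    for held in folds:
        tr, te = _masks(si, sj, held)
        if tr.sum() < 3 or te.sum() == 0:
            continue
        l1, lam = _select_hyperparams(
            x[tr], y[tr],
            tuple(np.asarray(si)[tr]), tuple(np.asarray(sj)[tr]),
            cfg, rng,
        )
        mu, sd = _standardise(x[tr])
        fold_means.append(mu)
        est = _fit_single((x[tr] - mu) / sd, y[tr], l1, lam, cfg)
        pred_sum[te] += est.predict((x[te] - mu) / sd)
        pred_cnt[te] += 1
        chosen.append((l1, lam))
    tested = pred_cnt > 0
    if not tested.any():
        raise RuntimeError("no dyad ever appeared in a test fold")
    if not tested.all():
        logger.warning("%d dyad(s) never appeared in a usable test fold; "
                       "scores computed on the rest", int((~tested).sum()))
    oof = np.where(tested, pred_sum / np.maximum(pred_cnt, 1), np.nan)

    # majority hyperparameters, then a full-data refit for coefficients
    l1s = [c[0] for c in chosen]
    final_l1 = max(set(l1s), key=l1s.count)
    lams = [c[1] for c in chosen if c[0] == final_l1]
    final_lam = float(np.median(lams))
    mu, sd = _standardise(x)
    final = _fit_single((x - mu) / sd, y, final_l1, final_lam, cfg)

    h = hashlib.sha256()
    for m in fold_means:
        h.update(np.ascontiguousarray(m).tobytes())
    return ElasticNetResult(
        score_r=_score_r(oof[tested], y[tested]),
        score_mse=float(np.mean((oof[tested] - y[tested]) ** 2)),
        oof_pred=oof,
        chosen=tuple(chosen),
        final_l1_ratio=float(final_l1),
        final_lambda=final_lam,
        coef=final.coef_,
        n_nonzero=int(np.sum(final.coef_ != 0)),
        fold_stats_hash=h.hexdigest(),
        seed=seed,
    )


def _permute_targets(
    features: FeatureTable, rng: np.random.Generator, scheme: str
) -> tuple[np.ndarray, np.ndarray]:
    """A null draw of the target vector, with a row-keep mask.

    ``subjects`` (default): permute subject identities, i.e.
    y'_(i,j) = y_(π(i), π(j)).  Social distance has strong subject-level
    structure (a peripheral student is distant from everyone); relabelling
    nodes preserves that dyadic structure, which naive dyad-wise shuffling
    destroys — shuffling yields an anti-conservative null.  A dyad whose
    relabelled counterpart was unreachable (absent from the table) is
    dropped for that draw, mirroring how the observed analysis drops
    unreachable dyads.  ``dyads`` shuffles the target across dyads and is
    kept for comparison.
    """
    if scheme == "dyads":
        return rng.permutation(features.y), np.ones(features.n_dyads, bool)
    if scheme != "subjects":
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    subjects = features.subjects
    pos = {frozenset(p): k for k, p in
           enumerate(zip(features.subject_i, features.subject_j))}
    perm = dict(zip(subjects, rng.permutation(np.asarray(subjects))))
    y_perm = np.full(features.n_dyads, np.nan)
    for row, (i, j) in enumerate(zip(features.subject_i, features.subject_j)):
        k = pos.get(frozenset((perm[i], perm[j])))
        if k is not None:
            y_perm[row] = features.y[k]
    return y_perm, np.isfinite(y_perm)


def permutation_test(
    features: FeatureTable,
    n_perm: int = 99,
    seed: int = 0,
    cv: ENConfig | None = None,
    scheme: str = "subjects",
) -> PermutationResult:
    """Permutation p-value for the out-of-fold prediction score.

    Null targets are generated by relabelling subjects by default (see
    :func:`_permute_targets`); the subject-grouped fold structure is
    preserved throughout.  p = (1 + #{permuted score ≥ observed}) /
    (1 + n_perm).  Deterministic given ``seed``.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be ≥ 19 for a meaningful p-value")
    observed = fit_elastic_net(features, cv=cv, seed=seed).score_r
    rng = np.random.default_rng(seed)
    perm_scores = np.empty(n_perm)
    for b in range(n_perm):
        y_perm, keep = _permute_targets(features, rng, scheme)
        ft_b = FeatureTable(
            X=features.X[keep], y=y_perm[keep],
            subject_i=tuple(np.asarray(features.subject_i)[keep]),
            subject_j=tuple(np.asarray(features.subject_j)[keep]),
            edge_labels=features.edge_labels,
        )
        perm_scores[b] = fit_elastic_net(ft_b, cv=cv, seed=seed).score_r
    p = (1.0 + np.sum(perm_scores >= observed)) / (1.0 + n_perm)
    return PermutationResult(
        pvalue=float(p), observed=float(observed), perm_scores=perm_scores,
        n_perm=n_perm, seed=seed,
    )
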