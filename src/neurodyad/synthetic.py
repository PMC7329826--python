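"""Synthetic cohorts with a planted, controllable homophily effect.

The generator produces everything a cohort contributes to the analysis —
a Likert roster with planted friendship groups, per-subject connectivity
matrices whose pairwise similarity rises with shared group membership, and
Gaussian BOLD time series realising those matrices — with full ground
truth, so every downstream stage has a parameter-recovery test.

Connectome construction: subject s in group g receives

    R_s = nearest_correlation( η·C_global + θ·C_g + (1 − η − θ)·E_s )

where C_global is a template shared by the whole cohort, C_g a per-group
template, and E_s subject-unique noise, all random correlation matrices
built from low-rank factor loadings.  θ (the homophily effect) and η (the
global template weight) satisfy θ + η ≤ 1; θ = 0 plants no homophily and
is the null condition for calibration studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._rng import child_rng
from .connectivity import ConnectivityMatrix, ParcelTimeSeries
from .social import RosterRating

import pandas as pd

logger = logging.getLogger(__name__)


class ProjectionError(RuntimeError):
    """Nearest-correlation projection failed to converge."""

    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"alternating projections did not converge after {iterations} "
            f"iterations (residual {residual:.3e})"
        )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_students : cohort size (≥ 2).
    n_parcels : parcels P per connectome (the study parcellation has 272;
        desk-scale runs use 40).
    n_timepoints : BOLD samples T (default 250 ≈ a 10-minute scan).
    p_in, p_out : probability that a directed rating is high (tie-level)
        within / between planted groups.
    n_groups : number of planted friendship groups.
    theta : homophily effect ∈ [0, 1] — weight of the shared-group
        connectome template.
    eta : weight of the cohort-global template ∈ [0, 1]; theta + eta ≤ 1.
    likert_noise : probability of a ±1 jitter on each rating.
    seed : root seed; identical seeds give bit-identical outputs.
    n_factors : rank of the factor loadings behind each template.
    """

    n_students: int
    n_parcels: int = 272
    n_timepoints: int = 250
    p_in: float = 0.9
    p_out: float = 0.2
    n_groups: int = 4
    theta: float = 0.3
    eta: float = 0.3
    likert_noise: float = 0.1
    seed: int = 0
    n_factors: int = 5

    def __post_init__(self) -> None:
        if self.n_students < 2:
            raise ValueError("n_students must be ≥ 2")
        if self.n_parcels < 2:
            raise ValueError("n_parcels must be ≥ 2")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be ≥ 2")
        if self.n_groups < 1 or self.n_groups > self.n_students:
            raise ValueError("n_groups must be in [1, n_students]")
        for name in ("p_in", "p_out", "theta", "eta", "likert_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.theta + self.eta > 1.0 + 1e-12:
            raise ValueError(
                f"theta + eta must be ≤ 1, got {self.theta + self.eta}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure behind a synthetic cohort."""

    groups: np.ndarray  # int label per student
    template_global: np.ndarray
    template_groups: dict[int, np.ndarray]
    subject_matrices: tuple[ConnectivityMatrix, ...]
    theta: float
    eta: float
    seed: int


# ---------------------------------------------------------------------------
# helpers


def planted_groups(config: SimConfig) -> np.ndarray:
    """Deterministic near-equal block assignment of students to groups."""
    return np.sort(np.arange(config.n_students) % config.n_groups)


def student_ids(config: SimConfig) -> tuple[str, ...]:
    return tuple(f"S{i:03d}" for i in range(config.n_students))


def parcel_labels(n_parcels: int) -> tuple[str, ...]:
    return tuple(f"P{i:03d}" for i in range(n_parcels))


def random_correlation_template(
    rng: np.random.Generator, n_parcels: int, n_factors: int = 5
) -> np.ndarray:
    """Random correlation matrix with low-rank factor structure.

    Σ = AAᵀ + D with A ∈ R^{P×k}, D diagonal positive, rescaled to unit
    diagonal; k small gives realistically modular, far-from-identity
    connectomes.
    """
    a = rng.standard_normal((n_parcels, n_factors))
    d = rng.uniform(0.5, 1.5, size=n_parcels)
    sigma = a @ a.T + np.diag(d)
    scale = 1.0 / np.sqrt(np.diag(sigma))
    return scale[:, None] * sigma * scale[None, :]


def nearest_correlation(
    matrix: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> np.ndarray:
    """Nearest correlation matrix in Frobenius norm.

    Alternating projections (with Dykstra correction) between the PSD cone
    and the unit-diagonal affine set; a valid correlation matrix is a fixed
    point and returns unchanged on the first sweep.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("nearest_correlation requires a symmetric matrix")
    a = (a + a.T) / 2.0

    y = a.copy()
    ds = np.zeros_like(a)
    diff = np.inf
    for it in range(1, max_iter + 1):
        r = y - ds
        w, v = np.linalg.eigh(r)
        x = (v * np.clip(w, 0.0, None)) @ v.T
        x = (x + x.T) / 2.0
        ds = x - r
        y_next = x.copy()
        np.fill_diagonal(y_next, 1.0)
        diff = np.linalg.norm(y_next - y, ord="fro") / max(
            1.0, np.linalg.norm(y_next, ord="fro")
        )
        y = y_next
        if diff < tol:
            out = np.clip(y, -1.0, 1.0)
            out = (out + out.T) / 2.0
            np.fill_diagonal(out, 1.0)
            return out
    raise ProjectionError(iterations=max_iter, residual=float(diff))


# ---------------------------------------------------------------------------
# generators


def simulate_social_roster(config: SimConfig) -> RosterRating:
    """Likert roster with planted community structure.

    Each ordered pair is drawn independently (reciprocity is emergent, not
    imposed): a within-group rating is tie-level (5) with probability
    ``p_in``, a between-group rating with probability ``p_out``; all other
    ratings start at 1.  Each rating is then jittered by ±1 with
    probability ``likert_noise`` and clipped to [1, 5], which populates the
    intermediate response options.
    """
    rng = child_rng(config.seed, "roster")
    n = config.n_students
    groups = planted_groups(config)
    same = groups[:, None] == groups[None, :]
    p_high = np.where(same, config.p_in, config.p_out)
    high = rng.random((n, n)) < p_high
    ratings = np.where(high, 5.0, 1.0)

    jitter_mask = rng.random((n, n)) < config.likert_noise
    jitter = rng.choice([-1.0, 1.0], size=(n, n))
    ratings = np.clip(ratings + jitter_mask * jitter, 1.0, 5.0)
    np.fill_diagonal(ratings, np.nan)

    ids = student_ids(config)
    df = pd.DataFrame(ratings, index=list(ids), columns=list(ids))
    return RosterRating(ids=ids, ratings=df, cohort=f"sim{config.seed}")


def simulate_subject_connectomes(
    partition: np.ndarray, config: SimConfig
) -> tuple[list[ConnectivityMatrix], GroundTruth]:
    """Per-subject correlation matrices with planted group similarity.

    ``partition`` supplies one group label per student (normally
    :func:`planted_groups`).  The convex template mixture is passed through
    :func:`nearest_correlation`, which also guards against numerical
    asymmetry.
    """
    partition = np.asarray(partition)
    if partition.shape != (config.n_students,):
        raise ValueError("need exactly one group label per student")
    p = config.n_parcels
    labels = parcel_labels(p)

    c_global = random_correlation_template(
        child_rng(config.seed, "template", "global"), p, config.n_factors
    )
    template_groups = {
        int(g): random_correlation_template(
            child_rng(config.seed, "template", "group", int(g)), p, config.n_factors
        )
        for g in np.unique(partition)
    }

    w_noise = 1.0 - config.theta - config.eta
    matrices = []
    for s, sid in enumerate(student_ids(config)):
        e_s = random_correlation_template(
            child_rng(config.seed, "subject-noise", s), p, config.n_factors
        )
        raw = (
            config.eta * c_global
            + config.theta * template_groups[int(partition[s])]
            + w_noise * e_s
        )
        r = nearest_correlation(raw)
        matrices.append(ConnectivityMatrix(values=r, labels=labels, subject_id=sid))

    truth = GroundTruth(
        groups=partition.copy(),
        template_global=c_global,
        template_groups=template_groups,
        subject_matrices=tuple(matrices),
        theta=config.theta,
        eta=config.eta,
        seed=config.seed,
    )
    return matrices, truth


def simulate_bold(
    matrix: ConnectivityMatrix, n_timepoints: int, seed: int
) -> ParcelTimeSeries:
    """T×P zero-mean Gaussian series with the given parcel correlation.

    The matrix is factorised through its eigendecomposition (valid for any
    PSD correlation matrix, including rank-deficient ones); the series are
    i.i.d. in time.
    """
    r = matrix.values
    w, v = np.linalg.eigh(r)
    if w.min() < -1e-8:
        raise ValueError(
            f"matrix is not positive semi-definite: smallest eigenvalue "
            f"{w.min():.3e}"
        )
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    series = rng.standard_normal((n_timepoints, matrix.n_parcels)) @ factor.T
    return ParcelTimeSeries(
        subject_id=matrix.subject_id or "sim",
        values=series,
        labels=matrix.labels,
    )


def simulate_subject_covariates(
    config: SimConfig, ethnicity_probs: tuple[float, ...] = (0.80, 0.08, 0.06, 0.05, 0.01)
) -> pd.DataFrame:
    """Per-subject demographics and head-motion summaries.

    Ethnicity categories follow roughly the proportions seen in UK
    single-school cohorts; about a third of students board; absolute and
    relative framewise motion are log-normal around 0.15 mm and 0.06 mm.
    """
    rng = child_rng(config.seed, "covariates")
    n = config.n_students
    categories = ["White", "Asian", "Black", "Mixed", "Other"]
    eth = rng.choice(categories, size=n, p=np.asarray(ethnicity_probs))
    boarding = rng.random(n) < 1.0 / 3.0
    motion_abs = np.exp(rng.normal(np.log(0.15), 0.4, size=n))
    motion_rel = np.exp(rng.normal(np.log(0.06), 0.4, size=n))
    return pd.DataFrame(
        {
            "ethnicity": eth,
            "boarding": np.where(boarding, "boarder", "day"),
            "motion_abs": motion_abs,
            "motion_rel": motion_rel,
        },
        index=list(student_ids(config)),
    )
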