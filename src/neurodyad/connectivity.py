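"""Per-subject connectomes and dyadic similarity outcomes.

Parcellated BOLD time series (T×P) are turned into P×P Pearson
connectivity matrices, Fisher z-transformed (z = atanh r, diagonal
removed), optionally restricted to a named resting-state network (DMN,
salience, lFPN, rFPN), and compared between subjects by correlating the
vectorised upper triangles.  One row per unordered subject pair, with the
similarity outcome standardised within cohort (mean 0, SD 1), forms the
dyad table consumed by the mixed-effects models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel scope meaning "no network restriction"
WHOLE_BRAIN = "whole-brain"

#: resting-state networks analysed alongside the whole brain
KNOWN_NETWORKS = ("DMN", "salience", "lFPN", "rFPN")

#: correlations are clipped to ±(1 − FISHER_CLIP) before atanh
FISHER_CLIP = 1e-7

COVARIATE_COLUMNS = (
    "ethnicity_match",
    "boarding_match",
    "motion_abs_mean",
    "motion_abs_diff",
    "motion_rel_mean",
    "motion_rel_diff",
)


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ParcelTimeSeries:
    """T×P parcel-mean BOLD series for one subject."""

    subject_id: str
    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.labels):
            raise ValueError(
                f"time series must be T×P with P={len(self.labels)} labels, "
                f"got shape {v.shape}"
            )
        if np.isnan(v).any():
            raise ValueError(f"missing values in time series of {self.subject_id}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, columns=list(self.labels)).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )

    @classmethod
    def from_tsv(cls, path, subject_id: str) -> "ParcelTimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(subject_id=subject_id, values=df.to_numpy(float),
                   labels=tuple(df.columns))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """P×P Pearson connectivity (symmetric, unit diagonal)."""

    values: np.ndarray
    labels: tuple[str, ...]
    subject_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        p = len(self.labels)
        if v.shape != (p, p):
            raise ValueError(f"expected {p}×{p} matrix, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("connectivity matrix must have unit diagonal")
        if v.min() < -1 - 1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("correlations must lie in [−1, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def n_parcels(self) -> int:
        return len(self.labels)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.labels),
                     columns=list(self.labels)).to_csv(path, float_format="%.17g")


@dataclass(frozen=True)
class FisherZMatrix:
    """Fisher z-transformed connectivity; diagonal masked with NaN."""

    values: np.ndarray
    labels: tuple[str, ...]
    subject_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        p = len(self.labels)
        if v.shape != (p, p):
            raise ValueError(f"expected {p}×{p} matrix, got {v.shape}")
        off = ~np.eye(p, dtype=bool)
        if not np.all(np.isfinite(v[off])):
            raise ValueError("off-diagonal z values must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def n_parcels(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        """Row-major vector of entries z_pq with p < q (diagonal excluded)."""
        iu = np.triu_indices(self.n_parcels, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class NetworkMask:
    """Parcel-label → resting-state-network assignment (parcels may be
    unassigned)."""

    assignment: Mapping[str, str]

    def networks(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.assignment.values())))

    def parcels_for(self, name: str) -> tuple[str, ...]:
        return tuple(p for p, n in self.assignment.items() if n == name)

    @classmethod
    def from_csv(cls, path) -> "NetworkMask":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("mask CSV needs (parcel, network) columns")
        parcels = df.iloc[:, 0].astype(str)
        nets = df.iloc[:, 1].astype(str)
        return cls(assignment=dict(zip(parcels, nets)))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"parcel": list(self.assignment), "network": list(self.assignment.values())}
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations


def correlation_matrix(series: ParcelTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of parcel time series."""
    v = series.values
    if v.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a correlation matrix")
    sd = v.std(axis=0)
    if np.any(sd == 0):
        bad = series.labels[int(np.argmax(sd == 0))]
        raise ValueError(
            f"constant time series in parcel {bad!r} of subject "
            f"{series.subject_id}; correlation undefined"
        )
    r = np.corrcoef(v.T)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, labels=series.labels,
                              subject_id=series.subject_id)


def fisher_z(matrix: ConnectivityMatrix) -> FisherZMatrix:
    """z = atanh(r) with r clipped to ±(1 − 1e−7); diagonal masked."""
    r = np.clip(matrix.values, -1.0 + FISHER_CLIP, 1.0 - FISHER_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    return FisherZMatrix(values=z, labels=matrix.labels,
                         subject_id=matrix.subject_id)


def subset_network(z: FisherZMatrix, mask: NetworkMask, name: str) -> FisherZMatrix:
    """Submatrix over the parcels assigned to ``name`` (label-keyed;
    ``"whole-brain"`` returns the input unchanged)."""
    if name == WHOLE_BRAIN:
        return z
    if name not in mask.networks():
        raise ValueError(
            f"unknown network {name!r}; mask defines {mask.networks()}"
        )
    wanted = set(mask.parcels_for(name))
    idx = [k for k, lab in enumerate(z.labels) if lab in wanted]
    if not idx:
        raise ValueError(f"no parcels of this matrix belong to network {name!r}")
    sub = z.values[np.ix_(idx, idx)]
    return FisherZMatrix(values=sub, labels=tuple(z.labels[k] for k in idx),
                         subject_id=z.subject_id)


def intersubject_similarity(z_i: FisherZMatrix, z_j: FisherZMatrix) -> float:
    """Pearson correlation of two subjects' vectorised connectomes.

    The upper triangles (p < q, row-major) are correlated; symmetric in
    its arguments by construction.
    """
    if z_i.labels != z_j.labels:
        raise ValueError("parcel labels differ between subjects")
    a, b = z_i.upper_triangle(), z_j.upper_triangle()
    return float(np.corrcoef(a, b)[0, 1])


def pairwise_similarities(
    zmats: Sequence[FisherZMatrix],
) -> pd.DataFrame:
    """Inter-subject similarity for every unordered pair of subjects.

    Returns a tidy frame (subject_i, subject_j, similarity) with pairs in
    the order subjects were given.
    """
    if len(zmats) < 2:
        raise ValueError("need at least two subjects")
    labels = zmats[0].labels
    for z in zmats:
        if z.labels != labels:
            raise ValueError("parcel labels differ between subjects")
    vecs = np.vstack([z.upper_triangle() for z in zmats])
    r = np.corrcoef(vecs)
    rows = []
    for a in range(len(zmats)):
        for b in range(a + 1, len(zmats)):
            rows.append((zmats[a].subject_id, zmats[b].subject_id, float(r[a, b])))
    return pd.DataFrame(rows, columns=["subject_i", "subject_j", "similarity"])


# ---------------------------------------------------------------------------
# dyad table


@dataclass
class DyadTable:
    """One row per unordered subject pair within a cohort × scope.

    Columns: subject_i, subject_j, similarity (raw), similarity_std
    (standardised within cohort), distance (NaN when unreachable),
    same_community, plus optional dyad covariates.
    """

    data: pd.DataFrame
    cohort: str
    scope: str = WHOLE_BRAIN

    def __post_init__(self) -> None:
        required = {"subject_i", "subject_j", "similarity_std"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"dyad table missing columns {sorted(missing)}")

    @property
    def n_dyads(self) -> int:
        return len(self.data)

    @property
    def subjects(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for col in ("subject_i", "subject_j"):
            for s in self.data[col]:
                seen.setdefault(str(s))
        return tuple(seen)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, cohort: str, scope: str = WHOLE_BRAIN) -> "DyadTable":
        return cls(data=pd.read_csv(path), cohort=cohort, scope=scope)


def build_dyad_table(
    similarities: pd.DataFrame,
    distances,
    partition,
    covariates: pd.DataFrame | None = None,
    cohort: str = "cohort",
    scope: str = WHOLE_BRAIN,
) -> DyadTable:
    """Assemble the per-dyad modelling table for one cohort × scope.

    ``similarities`` is the tidy output of :func:`pairwise_similarities`;
    ``distances`` a :class:`~neurodyad.social.SocialDistanceMatrix`;
    ``partition`` a :class:`~neurodyad.social.CommunityPartition`.
    ``covariates``, if given, is a per-subject frame indexed by ID with
    columns ethnicity, boarding, motion_abs, motion_rel; match covariates
    are coded 1 = same, 0 = different, and motion enters as the dyad mean
    and absolute difference (exchangeable in the two members).

    The similarity outcome is standardised within this table (one cohort,
    one scope) to mean 0 and SD 1.  Unreachable dyads keep their row with
    ``distance`` = NaN and are excluded later by distance-based models.
    """
    df = similarities.copy()
    df["subject_i"] = df["subject_i"].astype(str)
    df["subject_j"] = df["subject_j"].astype(str)

    known = set(distances.ids)
    dist_vals, same_comm = [], []
    n_unreachable = 0
    for i, j in zip(df["subject_i"], df["subject_j"]):
        if i not in known or j not in known:
            missing = i if i not in known else j
            raise ValueError(
                f"subject {missing!r} missing from the social distance matrix"
            )
        d = distances.distance(i, j)
        if np.isinf(d):
            n_unreachable += 1
            d = np.nan
        dist_vals.append(d)
        same_comm.append(partition.same_community(i, j))
    df["distance"] = dist_vals
    df["same_community"] = same_comm
    if n_unreachable:
        logger.info("%d unreachable dyad(s) flagged in cohort %s",
                    n_unreachable, cohort)

    if covariates is not None:
        cov = covariates.copy()
        cov.index = cov.index.astype(str)
        for col, key in (("ethnicity_match", "ethnicity"),
                         ("boarding_match", "boarding")):
            if key in cov.columns:
                df[col] = [
                    int(cov.at[i, key] == cov.at[j, key])
                    for i, j in zip(df["subject_i"], df["subject_j"])
                ]
        for stem in ("motion_abs", "motion_rel"):
            if stem in cov.columns:
                mi = cov.loc[df["subject_i"], stem].to_numpy(float)
                mj = cov.loc[df["subject_j"], stem].to_numpy(float)
                df[f"{stem}_mean"] = (mi + mj) / 2.0
                df[f"{stem}_diff"] = np.abs(mi - mj)

    sims = df["similarity"].to_numpy(float)
    sd = sims.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(
            f"similarity outcome has zero variance in cohort {cohort!r}; "
            "cannot standardise"
        )
    df["similarity_std"] = (sims - sims.mean()) / sd

    table = DyadTable(data=df, cohort=cohort, scope=scope)
    n = len(table.subjects)
    expected = n * (n - 1) // 2
    if table.n_dyads != expected:
        raise ValueError(
            f"expected {expected} dyads for {n} subjects, got {table.n_dyads}"
        )
    return table
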