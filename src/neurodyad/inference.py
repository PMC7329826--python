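"""Crossed-random-effects dyadic models, meta-analysis, and calibration.

Dyadic outcomes are not independent: every student appears in many dyads,
so ordinary least squares understates uncertainty and inflates type-I
error.  The model fitted here is

    y_ij = β0 + β1·x_ij (+ covariates) + u_i + u_j + ε_ij,

with one random intercept per dyad member drawn from a single shared
variance σ²_u (dyads are unordered, so separate member variances are not
identifiable) and residual variance σ²_ε.  Writing Z for the dyad–member
incidence matrix (two ones per row), V = σ²_ε·(I + λ Z Zᵀ) with
λ = σ²_u/σ²_ε; the restricted likelihood is profiled down to the single
ratio λ via one eigendecomposition of Z Zᵀ, making each fit a 1-D
optimisation.  REML is used throughout (variance components with modest
subject counts).

Per-cohort slope estimates are pooled by a random-effects meta-analysis
(restricted-likelihood τ², inverse-variance weights 1/(SE² + τ²)), and a
power/type-I simulation runs the whole synthetic pipeline end-to-end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._rng import child_int
from .connectivity import COVARIATE_COLUMNS, DyadTable

logger = logging.getLogger(__name__)

Predictor = Literal["distance", "community"]

_LAM_LO, _LAM_HI = 1e-8, 1e5


class ConvergenceError(RuntimeError):
    """REML optimisation failed."""


@dataclass(frozen=True)
class LMEFit:
    """Fitted crossed-random-intercept dyadic model."""

    params: pd.Series
    bse: pd.Series
    statistics: pd.Series
    pvalues: pd.Series
    sigma2_u: float
    sigma2_eps: float
    converged: bool
    singular: bool
    n_dyads: int
    n_subjects: int
    n_dropped: int
    reml_neg2loglik: float
    predictor: str
    df_method: str
    cohort: str | None = None
    scope: str | None = None

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        zq = stats.norm.ppf(0.5 + level / 2.0)
        return (
            float(self.params[name] - zq * self.bse[name]),
            float(self.params[name] + zq * self.bse[name]),
        )

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "statistics": {k: float(v) for k, v in self.statistics.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "sigma2_u": self.sigma2_u,
            "sigma2_eps": self.sigma2_eps,
            "converged": self.converged,
            "singular": self.singular,
            "n_dyads": self.n_dyads,
            "n_subjects": self.n_subjects,
            "n_dropped": self.n_dropped,
            "reml_neg2loglik": self.reml_neg2loglik,
            "predictor": self.predictor,
            "df_method": self.df_method,
            "cohort": self.cohort,
            "scope": self.scope,
        }


def _design(
    table: DyadTable, predictor: Predictor, covariates: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], int]:
    """Response, fixed-effect design, incidence matrix and names."""
    df = table.data
    col = {"distance": "distance", "community": "same_community"}.get(predictor)
    if col is None:
        raise ValueError(f"unknown predictor {predictor!r}")
    if col not in df.columns:
        raise ValueError(f"dyad table lacks a {col!r} column")

    x = df[col].to_numpy(float)
    keep = np.isfinite(x)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d dyad(s) with undefined %s", n_dropped, col)
    sub = df.loc[keep]

    cols = [np.ones(len(sub)), sub[col].to_numpy(float)]
    names = ["intercept", predictor]
    if covariates:
        for c in COVARIATE_COLUMNS:
            if c in sub.columns:
                cols.append(sub[c].to_numpy(float))
                names.append(c)
    xmat = np.column_stack(cols)
    if np.ptp(xmat[:, 1]) == 0:
        raise ValueError(
            f"predictor {col!r} is constant over the retained dyads; "
            "the slope is not identifiable"
        )
    y = sub["similarity_std"].to_numpy(float)

    members = sorted(set(sub["subject_i"].astype(str)) | set(sub["subject_j"].astype(str)))
    index = {s: k for k, s in enumerate(members)}
    z = np.zeros((len(sub), len(members)))
    for row, (i, j) in enumerate(zip(sub["subject_i"].astype(str),
                                     sub["subject_j"].astype(str))):
        z[row, index[i]] = 1.0
        z[row, index[j]] = 1.0
    return y, xmat, z, names, n_dropped


def _profiled_reml(y: np.ndarray, x: np.ndarray, z: np.ndarray):
    """Factory for the profiled −2·REML criterion in λ = σ²_u/σ²_ε."""
    m, p = x.shape
    if m <= p:
        raise ValueError("more fixed effects than dyads")
    evals, q = np.linalg.eigh(z @ z.T)
    evals = np.clip(evals, 0.0, None)
    yt, xt = q.T @ y, q.T @ x

    def pieces(lam: float):
        w = 1.0 + lam * evals
        xw = xt / w[:, None]
        g = xt.T @ xw
        beta = np.linalg.solve(g, xw.T @ yt)
        resid = yt - xt @ beta
        rss = float(np.sum(resid**2 / w))
        sigma2 = rss / (m - p)
        crit = (
            (m - p) * np.log(sigma2)
            + float(np.sum(np.log(w)))
            + float(np.linalg.slogdet(g)[1])
        )
        return crit, beta, sigma2, g

    return pieces, m, p


def fit_dyadic_lme(
    table: DyadTable,
    predictor: Predictor = "distance",
    covariates: bool = False,
    df_method: Literal["normal", "residual"] = "normal",
) -> LMEFit:
    """REML fit of the crossed-random-intercept dyadic model.

    ``predictor`` selects social distance (numeric) or community
    affiliation (binary) as the focal fixed effect; ``covariates`` adds the
    demographic-match and head-motion terms present in the table.  Dyads
    with undefined (unreachable) distance are excluded with a logged count.

    Inference on the coefficients uses a normal approximation by default
    (dyad counts in the hundreds); ``df_method="residual"`` switches to a
    t reference with m − p degrees of freedom for small tables.
    """
    y, x, z, names, n_dropped = _design(table, predictor, covariates)
    pieces, m, p = _profiled_reml(y, x, z)

    res = optimize.minimize_scalar(
        lambda t: pieces(np.exp(t))[0],
        bounds=(np.log(_LAM_LO), np.log(_LAM_HI)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise ConvergenceError(f"REML optimisation failed: {res.message}")
    lam = float(np.exp(res.x))
    crit_hat = float(res.fun)
    crit0 = pieces(0.0)[0]
    singular = crit0 <= crit_hat + 1e-10
    if singular:
        lam, crit_hat = 0.0, float(crit0)

    crit, beta, sigma2, g = pieces(lam)
    cov_beta = sigma2 * np.linalg.inv(g)
    se = np.sqrt(np.diag(cov_beta))
    stat = beta / se
    if df_method == "normal":
        pvals = 2.0 * stats.norm.sf(np.abs(stat))
    elif df_method == "residual":
        pvals = 2.0 * stats.t.sf(np.abs(stat), df=m - p)
    else:
        raise ValueError(f"unknown df_method {df_method!r}")

    return LMEFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        statistics=pd.Series(stat, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2_u=float(lam * sigma2),
        sigma2_eps=float(sigma2),
        converged=bool(res.success),
        singular=bool(singular),
        n_dyads=int(m),
        n_subjects=int(z.shape[1]),
        n_dropped=n_dropped,
        reml_neg2loglik=float(crit),
        predictor=predictor,
        df_method=df_method,
        cohort=table.cohort,
        scope=table.scope,
    )


def reml_criterion(
    table: DyadTable,
    lam: float,
    predictor: Predictor = "distance",
    covariates: bool = False,
) -> float:
    """Profiled −2·REML criterion at a fixed variance ratio λ (diagnostic;
    the fit minimises this)."""
    y, x, z, _, _ = _design(table, predictor, covariates)
    pieces, _, _ = _profiled_reml(y, x, z)
    return float(pieces(float(lam))[0])


# ---------------------------------------------------------------------------
# direct simulation from the dyadic model (oracle / calibration helper)


def simulate_lme_dyads(
    n_subjects: int,
    beta: Sequence[float] = (0.0, 0.0),
    sigma2_u: float = 0.2,
    sigma2_eps: float = 1.0,
    seed: int = 0,
    x_values: Sequence[float] = (1.0, 2.0, 3.0),
) -> DyadTable:
    """Draw a complete dyad table directly from the crossed-effects model.

    The predictor is sampled i.i.d. from ``x_values`` (mimicking small
    social distances); the outcome lands in ``similarity_std`` unchanged,
    so fits on this table recover (β, σ²_u, σ²_ε) exactly as specified.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    ids = [f"S{i:03d}" for i in range(n_subjects)]
    u = rng.normal(0.0, np.sqrt(sigma2_u), size=n_subjects)
    rows = []
    for a in range(n_subjects):
        for b in range(a + 1, n_subjects):
            x = float(rng.choice(np.asarray(x_values, dtype=float)))
            yv = (
                beta[0]
                + beta[1] * x
                + u[a]
                + u[b]
                + rng.normal(0.0, np.sqrt(sigma2_eps))
            )
            rows.append((ids[a], ids[b], yv, yv, x, int(x == 1.0)))
    df = pd.DataFrame(
        rows,
        columns=["subject_i", "subject_j", "similarity", "similarity_std",
                 "distance", "same_community"],
    )
    return DyadTable(data=df, cohort=f"lme-sim-{seed}", scope="simulated")


# ---------------------------------------------------------------------------
# meta-analysis


@dataclass(frozen=True)
class MetaResult:
    """Random-effects pooled estimate across cohorts."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    weights: pd.Series  # normalised, sum to 1
    k: int
    method: str
    coefficient: str
    pvalue: float
    per_study: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "tau2": self.tau2,
            "weights": {k: float(v) for k, v in self.weights.items()},
            "k": self.k,
            "method": self.method,
            "coefficient": self.coefficient,
            "pvalue": self.pvalue,
        }


def meta_neg2reml(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """−2·restricted log-likelihood of the random-effects meta model
    (up to a constant)."""
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    return float(
        np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
    )


def meta_analyze(
    fits: Sequence[LMEFit],
    coefficient: str = "distance",
    method: Literal["REML", "DL", "FE"] = "REML",
    level: float = 0.95,
) -> MetaResult:
    """Pool a coefficient across per-cohort fits.

    REML τ² by 1-D restricted-likelihood optimisation (DerSimonian–Laird
    and fixed-effect pooling available); weights 1/(SE² + τ²); Wald CI
    β̄ ± z·SE(β̄).
    """
    if len(fits) < 2:
        raise ValueError("meta-analysis needs at least 2 cohort fits")
    y = np.array([float(f.params[coefficient]) for f in fits])
    v = np.array([float(f.bse[coefficient]) ** 2 for f in fits])
    if not np.all(np.isfinite(y)) or not np.all(v > 0):
        raise ValueError("non-finite estimates or standard errors")
    labels = [f.cohort or f"study{k}" for k, f in enumerate(fits)]

    if method == "FE":
        tau2 = 0.0
    elif method == "DL":
        w_fe = 1.0 / v
        mu_fe = np.sum(w_fe * y) / np.sum(w_fe)
        q = float(np.sum(w_fe * (y - mu_fe) ** 2))
        c = float(np.sum(w_fe) - np.sum(w_fe**2) / np.sum(w_fe))
        tau2 = max(0.0, (q - (len(y) - 1)) / c)
    elif method == "REML":
        ub = max(10.0 * float(np.var(y)), 100.0 * float(v.max()), 1e-6)
        res = optimize.minimize_scalar(
            meta_neg2reml, args=(y, v), bounds=(0.0, ub), method="bounded",
            options={"xatol": 1e-12},
        )
        tau2 = float(res.x)
        if meta_neg2reml(0.0, y, v) <= meta_neg2reml(tau2, y, v) + 1e-12:
            tau2 = 0.0
    else:
        raise ValueError(f"unknown meta-analysis method {method!r}")

    w = 1.0 / (v + tau2)
    beta = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    pvalue = float(2.0 * stats.norm.sf(abs(beta / se)))
    per_study = pd.DataFrame(
        {"cohort": labels, "beta": y, "se": np.sqrt(v), "weight": w / w.sum()}
    )
    return MetaResult(
        beta=beta,
        se=se,
        ci_low=beta - zq * se,
        ci_high=beta + zq * se,
        tau2=tau2,
        weights=pd.Series(w / w.sum(), index=labels),
        k=len(fits),
        method=method,
        coefficient=coefficient,
        pvalue=pvalue,
        per_study=per_study,
    )


def adjust_pvalues(pvalues, method: Literal["none", "bonferroni"] = "bonferroni"):
    """Multiple-testing adjustment across network scopes.

    Results are reported per scope without correction by default (each
    network is a separate hypothesis of interest); this switch provides a
    family-wise Bonferroni correction over the scopes actually tested.
    """
    p = np.asarray(pvalues, dtype=float)
    if method == "none":
        return p
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    raise ValueError(f"unknown adjustment method {method!r}")


# ---------------------------------------------------------------------------
# power / type-I simulation


@dataclass(frozen=True)
class PowerTable:
    """Rejection rates over a (θ, cohort sizes) grid."""

    data: pd.DataFrame
    alpha: float
    n_replicates: int
    seed: int

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.17g")


def power_simulation(
    thetas: Sequence[float],
    cohort_sizes: Sequence[Sequence[int]],
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    predictor: Predictor = "distance",
    **sim_kwargs,
) -> PowerTable:
    """Monte-Carlo rejection rate of H0: β1 = 0 over a simulation grid.

    For each grid cell (θ, cohort-size tuple) and replicate, full synthetic
    cohorts are generated (roster → social graph → connectomes → dyad
    table), fitted with the dyadic LME, pooled by meta-analysis when more
    than one cohort is present, and H0 tested at level ``alpha``.  Cells
    are seeded independently per (cell, replicate, cohort), so doubling the
    replicate count extends rather than reshuffles the per-cell streams.
    Failed fits are counted and reported, never silently dropped.

    ``sim_kwargs`` are forwarded to the cohort simulator (``n_parcels``,
    ``n_timepoints``, ``p_in``, ``p_out``, ``n_groups`` or per-cohort
    ``group_counts``, ``eta``, ``likert_noise``, ``via_bold``,
    ``louvain_restarts``).
    """
    from .workbench import simulate_dyad_table  # deferred: avoids cycle

    group_counts = sim_kwargs.pop("group_counts", None)
    rows = []
    for cell, (theta, sizes) in enumerate(
        (t, tuple(s)) for t in thetas for s in cohort_sizes
    ):
        rejections, failures = 0, 0
        for rep in range(n_replicates):
            fits = []
            try:
                for c_idx, n in enumerate(sizes):
                    rep_seed = child_int(seed, "power", cell, rep, c_idx)
                    n_groups = (
                        group_counts[c_idx] if group_counts is not None
                        else sim_kwargs.get("n_groups", 4)
                    )
                    kw = {k: v for k, v in sim_kwargs.items() if k != "n_groups"}
                    table = simulate_dyad_table(
                        n_students=n, theta=theta, seed=rep_seed,
                        n_groups=n_groups, cohort=f"c{c_idx}", **kw,
                    )
                    fits.append(fit_dyadic_lme(table, predictor=predictor))
                if len(fits) > 1:
                    p = meta_analyze(fits, coefficient=predictor).pvalue
                else:
                    p = float(fits[0].pvalues[predictor])
            except (ConvergenceError, ValueError) as exc:
                failures += 1
                logger.warning("replicate %d of cell %d failed: %s", rep, cell, exc)
                continue
            rejections += int(p < alpha)
        n_ok = n_replicates - failures
        rate = rejections / n_ok if n_ok else np.nan
        mc_se = float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else np.nan
        rows.append(
            {
                "theta": theta,
                "cohort_sizes": "x".join(map(str, sizes)),
                "alpha": alpha,
                "rejection_rate": rate,
                "mc_se": mc_se,
                "n_replicates": n_replicates,
                "n_failures": failures,
                "seed": seed,
            }
        )
    return PowerTable(
        data=pd.DataFrame(rows), alpha=alpha, n_replicates=n_replicates, seed=seed
    )
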