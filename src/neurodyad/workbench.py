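"""Study orchestration: configs, manifests, synthetic studies, bookkeeping.

Binds the pipeline stages (roster → social graph → distances/communities →
connectomes → similarities → dyad tables → LME fits → meta-analysis) into
reproducible runs driven by a YAML config, and provides the synthetic-study
writer plus the recruitment accounting used to describe a study.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from ._rng import child_int
from .connectivity import (
    KNOWN_NETWORKS,
    WHOLE_BRAIN,
    DyadTable,
    NetworkMask,
    ParcelTimeSeries,
    build_dyad_table,
    correlation_matrix,
    fisher_z,
    pairwise_similarities,
    subset_network,
)
from .inference import LMEFit, MetaResult, fit_dyadic_lme, meta_analyze
from .social import (
    build_social_graph,
    count_dyads,
    detect_communities,
    load_roster,
    network_summary,
    social_distance,
)
from .synthetic import (
    SimConfig,
    parcel_labels,
    planted_groups,
    simulate_bold,
    simulate_social_roster,
    simulate_subject_connectomes,
    simulate_subject_covariates,
    student_ids,
)

logger = logging.getLogger(__name__)

ALL_SCOPES = (WHOLE_BRAIN,) + KNOWN_NETWORKS


# ---------------------------------------------------------------------------
# recruitment accounting


def inclusion_rate(pool: int, sample: int) -> float:
    """Percentage of a year-group pool that joined the survey."""
    if pool <= 0 or sample < 0 or sample > pool:
        raise ValueError(f"invalid pool/sample pair ({pool}, {sample})")
    return 100.0 * sample / pool


def usable_fmri_counts(
    recruited: Sequence[int], excluded: Sequence[int]
) -> tuple[int, ...]:
    """Usable scanned participants per cohort after artefact exclusions."""
    if len(recruited) != len(excluded):
        raise ValueError("recruited and excluded must have equal length")
    out = []
    for r, e in zip(recruited, excluded):
        if e < 0 or e > r:
            raise ValueError(f"cannot exclude {e} of {r} participants")
        out.append(r - e)
    return tuple(out)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CohortPaths:
    name: str
    roster: str
    manifest: str
    covariates: str | None = None


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    cohorts: list[CohortPaths]
    mask: str
    out_dir: str
    threshold: int = 4
    mode: str = "reciprocal"
    scopes: tuple[str, ...] = (WHOLE_BRAIN,)
    predictors: tuple[str, ...] = ("distance", "community")
    covariates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.scopes) - set(ALL_SCOPES)
        if unknown:
            raise ValueError(f"unknown scopes {sorted(unknown)}; "
                             f"choose from {ALL_SCOPES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["cohorts"] = [CohortPaths(**c) for c in raw["cohorts"]]
        for key in ("scopes", "predictors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["scopes"] = list(self.scopes)
        d["predictors"] = list(self.predictors)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        # out_dir is a location, not content: exclude it so reruns into
        # different directories hash identically
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_manifest(path) -> pd.DataFrame:
    """Subject-ID → time-series-path manifest CSV."""
    df = pd.read_csv(path)
    if not {"subject", "path"} <= set(df.columns):
        raise ValueError(f"manifest {path} needs 'subject' and 'path' columns")
    return df


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full per-cohort analysis and cross-cohort meta-analysis.

    Writes per-cohort network artifacts, dyad tables (per scope), LME fit
    JSONs (per predictor × scope), meta-analysis JSONs and a forest-plot
    CSV; returns (and writes) a manifest listing every artifact with its
    content hash, the seed and the config hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask = NetworkMask.from_csv(config.mask)
    artifacts: dict[str, str] = {}
    fits: dict[tuple[str, str, str], LMEFit] = {}
    stage = "setup"
    cohort_name = None
    try:
        for cohort in config.cohorts:
            cohort_name = cohort.name
            cdir = out / cohort.name
            cdir.mkdir(exist_ok=True)

            stage = "social network"
            roster = load_roster(cohort.roster, cohort=cohort.name)
            graph = build_social_graph(roster, threshold=config.threshold,
                                       mode="reciprocal")
            directed = build_social_graph(roster, threshold=config.threshold,
                                          mode="directed")
            distances = social_distance(graph)
            partition = detect_communities(graph, seed=child_int(config.seed, "louvain",
                                                                 cohort.name))
            summary = network_summary(graph, directed,
                                      seed=child_int(config.seed, "summary",
                                                     cohort.name))
            logger.info("cohort %s: n=%d, %d dyads, %d communities",
                        cohort.name, roster.n, count_dyads(roster.n),
                        partition.n_communities)
            graph.edge_list().to_csv(cdir / "edges.csv", index=False)
            graph.write_graphml(cdir / "graph.graphml")
            tidy = distances.tidy()
            tidy["same_community"] = [
                partition.same_community(i, j)
                for i, j in zip(tidy["subject_i"], tidy["subject_j"])
            ]
            tidy.to_csv(cdir / "distances.csv", index=False, float_format="%.17g")
            partition.tidy().to_csv(cdir / "communities.csv", index=False)
            _write_json(
                {**summary.to_dict(), "seed": config.seed,
                 "config_hash": config.config_hash(), "version": __version__},
                cdir / "network_summary.json",
            )

            stage = "connectivity"
            manifest = load_manifest(cohort.manifest)
            base = Path(cohort.manifest).parent
            zmats = []
            for _, row in manifest.iterrows():
                ts_path = Path(row["path"])
                if not ts_path.is_absolute():
                    ts_path = base / ts_path
                ts = ParcelTimeSeries.from_tsv(ts_path, subject_id=str(row["subject"]))
                cm = correlation_matrix(ts)
                cm.to_csv(cdir / f"connectome_{cm.subject_id}.csv")
                zmats.append(fisher_z(cm))
            logger.info("cohort %s: %d connectomes", cohort.name, len(zmats))

            covariates = None
            if cohort.covariates:
                covariates = pd.read_csv(cohort.covariates, index_col=0)

            stage = "dyad tables"
            for scope in config.scopes:
                zs = [subset_network(z, mask, scope) for z in zmats]
                sims = pairwise_similarities(zs)
                table = build_dyad_table(
                    sims, distances, partition, covariates=covariates,
                    cohort=cohort.name, scope=scope,
                )
                table.to_csv(cdir / f"dyads_{scope}.csv")
                logger.info("cohort %s scope %s: %d dyad rows",
                            cohort.name, scope, table.n_dyads)

                stage = "LME fits"
                for predictor in config.predictors:
                    fit = fit_dyadic_lme(table, predictor=predictor,
                                         covariates=config.covariates)
                    fits[(cohort.name, scope, predictor)] = fit
                    _write_json(
                        {**fit.to_dict(), "seed": config.seed,
                         "config_hash": config.config_hash(),
                         "version": __version__},
                        cdir / f"fit_{scope}_{predictor}.json",
                    )
                stage = "dyad tables"

        stage = "meta-analysis"
        cohort_name = None
        forest_rows = []
        metas: dict[tuple[str, str], MetaResult] = {}
        for scope in config.scopes:
            for predictor in config.predictors:
                cohort_fits = [fits[(c.name, scope, predictor)]
                               for c in config.cohorts]
                for f in cohort_fits:
                    lo, hi = f.ci(predictor)
                    forest_rows.append((f.cohort, scope, predictor,
                                        float(f.params[predictor]), lo, hi))
                if len(cohort_fits) >= 2:
                    meta = meta_analyze(cohort_fits, coefficient=predictor)
                    metas[(scope, predictor)] = meta
                    forest_rows.append(("meta", scope, predictor,
                                        meta.beta, meta.ci_low, meta.ci_high))
                    _write_json(
                        {**meta.to_dict(), "seed": config.seed,
                         "config_hash": config.config_hash(),
                         "version": __version__},
                        out / f"meta_{scope}_{predictor}.json",
                    )
        pd.DataFrame(
            forest_rows,
            columns=["cohort", "scope", "predictor", "beta", "ci_low", "ci_high"],
        ).to_csv(out / "forest.csv", index=False, float_format="%.17g")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}"
            + (f" for cohort {cohort_name!r}" if cohort_name else "")
            + f": {exc}"
        ) from exc

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "run_manifest.json":
            artifacts[str(path.relative_to(out))] = _sha256(path)
    manifest_doc = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_fits": len(fits),
        "n_meta": len(metas),
        "artifacts": artifacts,
    }
    _write_json(manifest_doc, out / "run_manifest.json")
    return manifest_doc


# ---------------------------------------------------------------------------
# synthetic studies


def synthetic_network_mask(n_parcels: int) -> NetworkMask:
    """Assign leading parcels to the four named resting-state networks.

    Roughly 70% of parcels are covered (DMN 25%, salience / lFPN / rFPN
    15% each); the remainder are unassigned, mimicking a whole-brain
    parcellation only partially covered by the network maps.
    """
    labels = parcel_labels(n_parcels)
    shares = {"DMN": 0.25, "salience": 0.15, "lFPN": 0.15, "rFPN": 0.15}
    assignment: dict[str, str] = {}
    start = 0
    for net, share in shares.items():
        size = max(2, int(round(share * n_parcels)))
        for lab in labels[start:start + size]:
            assignment[lab] = net
        start += size
    return NetworkMask(assignment=assignment)


def simulate_dyad_table(
    n_students: int,
    theta: float = 0.0,
    seed: int = 0,
    n_parcels: int = 40,
    n_timepoints: int = 250,
    eta: float = 0.3,
    p_in: float = 0.9,
    p_out: float = 0.2,
    n_groups: int = 4,
    likert_noise: float = 0.1,
    cohort: str = "sim",
    scope: str = WHOLE_BRAIN,
    via_bold: bool = True,
    louvain_restarts: int = 25,
    with_covariates: bool = False,
) -> DyadTable:
    """One synthetic cohort run end-to-end to its dyad table.

    Used by the power/type-I simulation: roster → threshold-4 reciprocal
    graph → distances and Louvain communities → connectomes (realised as
    BOLD series and re-estimated unless ``via_bold=False``) → Fisher z →
    pairwise similarity → standardised dyad table.
    """
    cfg = SimConfig(
        n_students=n_students, n_parcels=n_parcels, n_timepoints=n_timepoints,
        p_in=p_in, p_out=p_out, n_groups=n_groups, theta=theta, eta=eta,
        likert_noise=likert_noise, seed=seed,
    )
    roster = simulate_social_roster(cfg)
    graph = build_social_graph(roster, threshold=4, mode="reciprocal")
    distances = social_distance(graph)
    partition = detect_communities(
        graph, seed=child_int(seed, "louvain"), restarts=louvain_restarts
    )
    matrices, _ = simulate_subject_connectomes(planted_groups(cfg), cfg)
    zmats = []
    for s, matrix in enumerate(matrices):
        if via_bold:
            ts = simulate_bold(matrix, cfg.n_timepoints,
                               seed=child_int(seed, "bold", s))
            matrix = correlation_matrix(ts)
        zmats.append(fisher_z(matrix))
    sims = pairwise_similarities(zmats)
    covariates = simulate_subject_covariates(cfg) if with_covariates else None
    return build_dyad_table(sims, distances, partition, covariates=covariates,
                            cohort=cohort, scope=scope)


def simulate_study(
    out_dir,
    sizes: Sequence[int] = (23, 17, 28),
    group_counts: Sequence[int] = (4, 3, 4),
    theta: float = 0.3,
    eta: float = 0.3,
    n_parcels: int = 40,
    n_timepoints: int = 250,
    seed: int = 0,
    **sim_kwargs,
) -> RunConfig:
    """Write a complete synthetic multi-cohort study to disk.

    Per cohort: roster CSV, per-subject time-series TSVs, subject-covariate
    CSV, manifest CSV and ground-truth JSON; one shared network-mask CSV
    and a ready-to-run pipeline YAML.  Returns the matching RunConfig.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask = synthetic_network_mask(n_parcels)
    mask.to_csv(out / "mask.csv")

    cohorts = []
    for c_idx, (n, n_groups) in enumerate(zip(sizes, group_counts)):
        name = f"cohort{c_idx + 1}"
        cdir = out / name
        cdir.mkdir(exist_ok=True)
        cfg = SimConfig(
            n_students=n, n_parcels=n_parcels, n_timepoints=n_timepoints,
            n_groups=n_groups, theta=theta, eta=eta,
            seed=child_int(seed, "cohort", c_idx), **sim_kwargs,
        )
        roster = simulate_social_roster(cfg)
        roster.to_csv(cdir / "roster.csv")
        logger.info("cohort %s: n=%d students, %d dyad entries",
                    name, n, count_dyads(n))

        matrices, truth = simulate_subject_connectomes(planted_groups(cfg), cfg)
        rows = []
        for s, matrix in enumerate(matrices):
            ts = simulate_bold(matrix, cfg.n_timepoints,
                               seed=child_int(cfg.seed, "bold", s))
            ts_path = cdir / f"ts_{matrix.subject_id}.tsv"
            ts.to_tsv(ts_path)
            rows.append((matrix.subject_id, ts_path.name))
        pd.DataFrame(rows, columns=["subject", "path"]).to_csv(
            cdir / "manifest.csv", index=False
        )
        simulate_subject_covariates(cfg).to_csv(cdir / "covariates.csv")
        _write_json(
            {
                "groups": {sid: int(g) for sid, g in
                           zip(student_ids(cfg), truth.groups)},
                "theta": cfg.theta,
                "eta": cfg.eta,
                "seed": cfg.seed,
                "n_parcels": cfg.n_parcels,
                "n_timepoints": cfg.n_timepoints,
                "version": __version__,
            },
            cdir / "ground_truth.json",
        )
        cohorts.append(CohortPaths(
            name=name,
            roster=str(cdir / "roster.csv"),
            manifest=str(cdir / "manifest.csv"),
            covariates=str(cdir / "covariates.csv"),
        ))

    config = RunConfig(
        cohorts=cohorts, mask=str(out / "mask.csv"),
        out_dir=str(out / "results"), seed=seed,
    )
    config.to_yaml(out / "study.yaml")
    return config
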