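"""Connectomes, Fisher z, inter-subject similarity and the dyad table."""

import math

import numpy as np
import pandas as pd
import pytest

from neurodyad.connectivity import (
    ConnectivityMatrix,
    FisherZMatrix,
    NetworkMask,
    ParcelTimeSeries,
    build_dyad_table,
    correlation_matrix,
    fisher_z,
    intersubject_similarity,
    pairwise_similarities,
    subset_network,
)
from neurodyad.social import build_social_graph, detect_communities, social_distance
from neurodyad.synthetic import SimConfig, simulate_bold, simulate_social_roster


def zmat_from(values, labels=None, subject="s") -> FisherZMatrix:
    v = np.asarray(values, dtype=float)
    labels = labels or tuple(f"P{k}" for k in range(v.shape[0]))
    v = (v + v.T) / 2
    np.fill_diagonal(v, np.nan)
    return FisherZMatrix(values=v, labels=tuple(labels), subject_id=subject)


class TestCorrelationMatrix:
    def test_identical_and_negated_columns(self):
        t = np.arange(10.0)
        ts = ParcelTimeSeries("s", np.column_stack([t, t + 3.0, -t]),
                              ("a", "b", "c"))
        r = correlation_matrix(ts).values
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_three_point_series(self):
        # x=(1,2,3), y=(1,3,2): cov=0.5·(1+0+0)=…, Pearson r = 0.5
        ts = ParcelTimeSeries("s", np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0]]),
                              ("x", "y"))
        r = correlation_matrix(ts).values
        assert r[0, 1] == pytest.approx(0.5)

    def test_constant_column_names_parcel(self):
        ts = ParcelTimeSeries("s", np.column_stack([np.arange(5.0), np.ones(5)]),
                              ("ok", "flat"))
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(ts)

    def test_too_few_timepoints(self):
        ts = ParcelTimeSeries("s", np.array([[0.0, 1.0], [1.0, 0.0]]), ("a", "b"))
        with pytest.raises(ValueError, match="3 timepoints"):
            correlation_matrix(ts)


class TestFisherZ:
    def test_closed_form_values(self):
        c = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.5], [0.5, 0.5, 1.0]])
        z = fisher_z(ConnectivityMatrix(values=c, labels=("a", "b", "c")))
        assert z.values[0, 1] == pytest.approx(0.0)
        assert z.values[0, 2] == pytest.approx(math.atanh(0.5))
        assert np.isnan(np.diag(z.values)).all()

    def test_perfect_correlation_clipped_finite(self):
        c = np.array([[1.0, 1.0], [1.0, 1.0]])
        z = fisher_z(ConnectivityMatrix(values=c, labels=("a", "b")))
        assert np.isfinite(z.values[0, 1])
        assert z.values[0, 1] > 7  # atanh(1 − 1e−7) ≈ 8.4


class TestSubsetNetwork:
    def test_submatrix_shape(self, rng):
        p = 40
        labels = tuple(f"P{k:03d}" for k in range(p))
        z = zmat_from(rng.standard_normal((p, p)), labels)
        mask = NetworkMask({lab: "DMN" for lab in labels[:10]})
        sub = subset_network(z, mask, "DMN")
        assert sub.values.shape == (10, 10)
        assert sub.labels == labels[:10]

    def test_whole_brain_sentinel_identity(self, rng):
        z = zmat_from(rng.standard_normal((5, 5)))
        out = subset_network(z, NetworkMask({}), "whole-brain")
        np.testing.assert_array_equal(
            np.nan_to_num(out.values), np.nan_to_num(z.values)
        )

    def test_selection_is_label_keyed(self, rng):
        labels = ("a", "b", "c", "d")
        z = zmat_from(rng.standard_normal((4, 4)), labels)
        m1 = NetworkMask({"b": "DMN", "d": "DMN"})
        m2 = NetworkMask({"d": "DMN", "b": "DMN"})  # permuted mask rows
        s1, s2 = subset_network(z, m1, "DMN"), subset_network(z, m2, "DMN")
        assert s1.labels == s2.labels == ("b", "d")
        np.testing.assert_array_equal(
            np.nan_to_num(s1.values), np.nan_to_num(s2.values)
        )

    def test_unknown_network_rejected(self, rng):
        z = zmat_from(rng.standard_normal((3, 3)))
        with pytest.raises(ValueError, match="unknown network"):
            subset_network(z, NetworkMask({"P0": "DMN"}), "salience")


class TestIntersubjectSimilarity:
    def test_self_and_negated(self, rng):
        z = zmat_from(rng.standard_normal((6, 6)))
        z_neg = zmat_from(-z.values)
        assert intersubject_similarity(z, z) == pytest.approx(1.0)
        assert intersubject_similarity(z, z_neg) == pytest.approx(-1.0)

    def test_symmetry_exact(self, rng):
        a = zmat_from(rng.standard_normal((8, 8)), subject="a")
        b = zmat_from(rng.standard_normal((8, 8)), subject="b")
        assert intersubject_similarity(a, b) == intersubject_similarity(b, a)

    def test_matches_bruteforce_pearson_on_enumerated_edges(self, rng):
        """Oracle: explicit loop over upper-triangle pairs, textbook
        Pearson formula, P ≤ 6."""
        for p in (4, 5, 6):
            a = zmat_from(rng.standard_normal((p, p)), subject="a")
            b = zmat_from(rng.standard_normal((p, p)), subject="b")
            xs, ys = [], []
            for i in range(p):
                for j in range(i + 1, p):
                    xs.append(a.values[i, j])
                    ys.append(b.values[i, j])
            n = len(xs)
            mx, my = sum(xs) / n, sum(ys) / n
            num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
            den = math.sqrt(sum((x - mx) ** 2 for x in xs)
                            * sum((y - my) ** 2 for y in ys))
            assert intersubject_similarity(a, b) == pytest.approx(num / den,
                                                                  abs=1e-12)

    def test_mismatched_labels_rejected(self, rng):
        a = zmat_from(rng.standard_normal((4, 4)), ("a", "b", "c", "d"))
        b = zmat_from(rng.standard_normal((4, 4)), ("a", "b", "c", "e"))
        with pytest.raises(ValueError, match="labels"):
            intersubject_similarity(a, b)

    def test_noise_cannot_increase_similarity(self):
        """Adding independent noise to one subject's series cannot
        systematically raise |r_ij| (checked over replicate seeds)."""
        diffs = []
        for seed in range(20):
            cfg = SimConfig(n_students=2, n_parcels=12, n_timepoints=150,
                            n_groups=1, theta=0.0, eta=0.6, seed=seed)
            from neurodyad.synthetic import planted_groups, simulate_subject_connectomes

            mats, _ = simulate_subject_connectomes(planted_groups(cfg), cfg)
            rng = np.random.default_rng(seed)
            ts_i = simulate_bold(mats[0], 150, seed=seed * 2)
            ts_j = simulate_bold(mats[1], 150, seed=seed * 2 + 1)
            z_i = fisher_z(correlation_matrix(ts_i))
            z_j = fisher_z(correlation_matrix(ts_j))
            clean = abs(intersubject_similarity(z_i, z_j))
            noisy_vals = ts_i.values + rng.standard_normal(ts_i.values.shape) * 2.0
            z_i_noisy = fisher_z(correlation_matrix(
                ParcelTimeSeries(ts_i.subject_id, noisy_vals, ts_i.labels)))
            noisy = abs(intersubject_similarity(z_i_noisy, z_j))
            diffs.append(noisy - clean)
        assert np.mean(diffs) < 0


class TestDyadTable:
    def _table(self, n_subjects=23, seed=0):
        cfg = SimConfig(n_students=n_subjects, n_groups=4, seed=seed)
        roster = simulate_social_roster(cfg)
        graph = build_social_graph(roster)
        distances = social_distance(graph)
        partition = detect_communities(graph, seed=0, restarts=10)
        rng = np.random.default_rng(seed)
        zmats = [zmat_from(rng.standard_normal((8, 8)), subject=s)
                 for s in roster.ids]
        sims = pairwise_similarities(zmats)
        return sims, distances, partition

    def test_23_subjects_produce_253_rows(self):
        sims, distances, partition = self._table(23)
        t = build_dyad_table(sims, distances, partition, cohort="c1")
        assert t.n_dyads == 253

    def test_standardisation_is_exact(self):
        sims, distances, partition = self._table(17)
        t = build_dyad_table(sims, distances, partition, cohort="c2")
        col = t.data["similarity_std"]
        assert abs(col.mean()) < 1e-12
        assert abs(col.std(ddof=1) - 1.0) < 1e-12

    def test_constant_similarity_rejected_loudly(self):
        sims, distances, partition = self._table(10)
        sims = sims.assign(similarity=0.5)
        with pytest.raises(ValueError, match="zero variance"):
            build_dyad_table(sims, distances, partition, cohort="c")

    def test_missing_subject_rejected(self):
        sims, distances, partition = self._table(10)
        sims.loc[0, "subject_i"] = "GHOST"
        with pytest.raises(ValueError, match="GHOST"):
            build_dyad_table(sims, distances, partition, cohort="c")

    def test_covariates_are_exchangeable_codings(self):
        sims, distances, partition = self._table(12, seed=3)
        cov = pd.DataFrame(
            {
                "ethnicity": ["White"] * 6 + ["Asian"] * 6,
                "boarding": ["day", "boarder"] * 6,
                "motion_abs": np.linspace(0.1, 0.3, 12),
                "motion_rel": np.linspace(0.02, 0.1, 12),
            },
            index=[f"S{k:03d}" for k in range(12)],
        )
        t = build_dyad_table(sims, distances, partition, covariates=cov,
                             cohort="c")
        row = t.data.iloc[0]
        i, j = row["subject_i"], row["subject_j"]
        assert row["ethnicity_match"] == int(cov.at[i, "ethnicity"]
                                             == cov.at[j, "ethnicity"])
        assert row["motion_abs_mean"] == pytest.approx(
            (cov.at[i, "motion_abs"] + cov.at[j, "motion_abs"]) / 2)
        assert row["motion_abs_diff"] == pytest.approx(
            abs(cov.at[i, "motion_abs"] - cov.at[j, "motion_abs"]))
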