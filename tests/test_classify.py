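import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from patchkit.classify import (
    pca_map,
    prepare_matrix,
    rf_importance,
    ward_cluster,
)
from patchkit.features import FeatureVector
from patchkit.io import FEATURE_COLUMNS


def make_vectors(n=12, seed=0):
    rng = np.random.default_rng(seed)
    vecs = []
    for i in range(n):
        vecs.append(FeatureVector(
            cell_id=f"c{i:02d}",
            rheobase_pA=float(rng.uniform(20, 120)),
            capacitance_pF=float(rng.uniform(40, 120)),
            resting_potential_mV=float(rng.uniform(-75, -60)),
            input_resistance_MOhm=float(rng.uniform(200, 700)),
            max_freq_Hz=float(rng.uniform(20, 90)),
            sag_amplitude_mV=float(rng.uniform(0, 20)),
            rebound=bool(rng.integers(0, 2)),
            burst_or_adaptive=["burst", "adaptive", "neither"][i % 3],
            mean_freq_Hz=float(rng.uniform(5, 40)),
            mAHP_mV=float(rng.uniform(5, 20)),
            fAHP_mV=float(rng.uniform(5, 20)),
            midpoint_pA=float(rng.uniform(40, 250)),
            steepness_Hz_per_pA=float(rng.uniform(0.1, 5)),
            tau_ms=float(rng.uniform(8, 60)),
            threshold_mV=float(rng.uniform(-48, -35)),
            amplitude_change=float(rng.uniform(-0.2, 0)),
            half_width_ms=float(rng.uniform(0.5, 1.5)),
            mean_isi_ms=float(rng.uniform(20, 200)),
        ))
    return vecs


def ward_oracle_merges(X):
    """Exhaustive greedy minimum-variance-increase agglomeration.

    Returns the sequence of member sets produced by each merge, plus the
    Ward dendrogram height sqrt(2 * delta-ESS) of each step.
    """
    clusters = {i: (frozenset([i]), X[i].copy(), 1) for i in range(len(X))}
    merges, heights = [], []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            _, ca, na = clusters[a]
            _, cb, nb = clusters[b]
            d2 = float(np.sum((ca - cb) ** 2))
            delta = na * nb / (na + nb) * d2
            if best is None or delta < best[0]:
                best = (delta, a, b)
        delta, a, b = best
        sa, ca, na = clusters.pop(a)
        sb, cb, nb = clusters.pop(b)
        merged = sa | sb
        centroid = (na * ca + nb * cb) / (na + nb)
        clusters[min(merged)] = (merged, centroid, na + nb)
        merges.append(merged)
        heights.append(np.sqrt(2.0 * delta))
    return merges, heights


def linkage_merge_sets(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_idx, (a, b, _h, _cnt) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        out.append(merged)
    return out


class TestPrepareMatrix:
    def test_columns_are_zscored(self):
        z = prepare_matrix(make_vectors())
        assert np.allclose(z.mean(), 0.0, atol=1e-9)
        assert np.allclose(z.std(ddof=0), 1.0, atol=1e-9)

    def test_dummy_encoding_gives_19_columns(self):
        z = prepare_matrix(make_vectors(), encoding="dummies")
        assert z.shape[1] == 19
        assert {"burst", "adaptive"} <= set(z.columns)

    def test_ordinal_encoding_keeps_18_columns(self):
        z = prepare_matrix(make_vectors(), encoding="ordinal")
        assert z.shape[1] == 18
        assert set(z.columns) == set(FEATURE_COLUMNS)

    def test_constant_column_dropped(self):
        vecs = make_vectors()
        for v in vecs:
            v.sag_amplitude_mV = 3.0
        z = prepare_matrix(vecs)
        assert "sag_amplitude_mV" not in z.columns
        assert z.attrs["dropped_constant"] == ["sag_amplitude_mV"]

    def test_missing_values_imputed_and_flagged(self):
        vecs = make_vectors()
        vecs[3].tau_ms = float("nan")
        z = prepare_matrix(vecs)
        assert not z.isna().any().any()
        assert z.attrs["imputed"]["tau_ms"] == ["c03"]

    def test_identical_cells_map_to_identical_rows(self):
        vecs = make_vectors(6)
        twin = make_vectors(6)
        twin[1] = twin[0]
        frame = pd.DataFrame([v.as_dict() for v in vecs + twin[:2]])
        frame.loc[7] = frame.loc[6]
        frame["cell_id"] = [f"c{i}" for i in range(8)]
        z = prepare_matrix(frame)
        assert np.allclose(z.iloc[6], z.iloc[7])


class TestWardCluster:
    def test_well_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(17)
        centers = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
        X = np.vstack([
            rng.normal(c, 1.0, size=(20, 2)) for c in centers
        ])
        truth = np.repeat([0, 1, 2], 20)
        res = ward_cluster(X, k=3)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_merge_sequence_equals_bruteforce_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        X = rng.normal(size=(n, 3))
        res = ward_cluster(X, k=1)
        got = linkage_merge_sets(res.linkage, n)
        expected, heights = ward_oracle_merges(X)
        assert got == expected
        assert np.allclose(res.linkage[:, 2], heights, rtol=1e-8)

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(3)
        res = ward_cluster(rng.normal(size=(30, 4)), k=3)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)

    def test_duplicated_points_merge_at_height_zero(self):
        X = np.vstack([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        res = ward_cluster(X, k=2)
        assert res.linkage[0, 2] == 0.0

    def test_labels_renumbered_by_descending_size(self):
        rng = np.random.default_rng(4)
        X = np.vstack([
            rng.normal(0, 0.5, size=(4, 2)),
            rng.normal(10, 0.5, size=(12, 2)),
        ])
        res = ward_cluster(X, k=2)
        sizes = res.sizes()
        assert sizes[0] == 12 and sizes[1] == 4

    def test_row_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(8)
        X = np.vstack([
            rng.normal(c, 1.0, size=(10, 3))
            for c in ([0, 0, 0], [7, 0, 0], [0, 7, 0])
        ])
        base = ward_cluster(X, k=3).labels
        perm = rng.permutation(len(X))
        shuffled = ward_cluster(X[perm], k=3).labels
        restored = np.empty_like(shuffled)
        restored[perm] = shuffled
        assert adjusted_rand_score(base, restored) == 1.0

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            ward_cluster(np.zeros((3, 2)), k=5)


class TestRandomForestImportance:
    def _labeled_data(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 6))
        y = (X[:, 1] > 0).astype(int) + 1  # only feature f1 matters
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(6)]), y

    def test_informative_feature_ranks_first(self):
        X, y = self._labeled_data()
        report = rf_importance(X, y, n_trees=200, seed=1)
        assert report.importances.index[0] == "f1"
        assert report.importances.sum() == pytest.approx(1.0, abs=1e-9)
        assert report.cv_accuracy > 0.8

    def test_permuted_labels_give_chance_accuracy(self):
        X, y = self._labeled_data(seed=2, n=90)
        rng = np.random.default_rng(9)
        y_perm = rng.permutation(np.repeat([1, 2, 3], 30))
        report = rf_importance(X, y_perm, n_trees=200, seed=1)
        p = 1.0 / 3.0
        band = 1.96 * np.sqrt(p * (1 - p) / len(y_perm))
        assert abs(report.cv_accuracy - p) <= band + 0.05

    def test_deterministic_given_seed(self):
        X, y = self._labeled_data()
        a = rf_importance(X, y, n_trees=100, seed=7)
        b = rf_importance(X, y, n_trees=100, seed=7)
        assert a.importances.equals(b.importances)
        assert a.cv_accuracy == b.cv_accuracy

    def test_small_class_switches_to_leave_one_out(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(13, 4)))
        y = np.array([1] * 10 + [2] * 3)
        report = rf_importance(X, y, n_trees=50, seed=0)
        assert "leave-one-out" in report.cv_method


class TestPCAMap:
    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        X = (X - X.mean(0)) / X.std(0)
        res = pca_map(X)
        assert res.explained_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)

    def test_correlated_pair_loads_on_diagonal_axis(self):
        """rho = 0.95 bivariate data: PC1 within 2 degrees of (1,1)/sqrt2."""
        rng = np.random.default_rng(12)
        cov = np.array([[1.0, 0.95], [0.95, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=4000)
        res = pca_map((X - X.mean(0)) / X.std(0))
        pc1 = res.loadings["PC1"].to_numpy()
        angle = np.degrees(np.arccos(
            abs(pc1 @ (np.ones(2) / np.sqrt(2)))
        ))
        assert angle < 2.0

    def test_sign_convention(self):
        rng = np.random.default_rng(2)
        res = pca_map(rng.normal(size=(30, 4)))
        for col in res.loadings:
            vals = res.loadings[col].to_numpy()
            assert vals[np.argmax(np.abs(vals))] > 0
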