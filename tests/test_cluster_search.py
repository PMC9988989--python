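import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import crestscope as cs
from crestscope.cluster_search import (
    EmbeddingParams,
    cosine_distance,
    embed_fit_transform,
    enumerate_search,
    find_markers,
    merge_clusters,
    qual_score,
    snn_cluster,
)
from crestscope.panel_io import CountMatrix, ValidationError

from conftest import make_counts, make_meta


def brute_force_qual(labels: pd.Series, meta):
    """Independent evaluation of the control-anchored score: plain loops,
    same target-cluster tie rule (most controls, smaller cluster, lower id)."""
    sizes = {}
    for cl in labels:
        sizes[cl] = sizes.get(cl, 0) + 1

    def term(source):
        cells = [c for c in meta.cells_of_source(source) if c in labels.index]
        if not cells:
            return (1 + 0) / math.sqrt(1 + 0)
        counts = {}
        for c in cells:
            counts[labels[c]] = counts.get(labels[c], 0) + 1
        best = None
        for cl in counts:
            key = (-counts[cl], sizes[cl], cl)
            if best is None or key < best[0]:
                best = (key, cl)
        cl = best[1]
        return (1 + counts[cl]) / math.sqrt(1 + sizes[cl])

    return term("control_iri") + term("control_mel")


class TestCosineDistance:
    def test_identity_zero(self):
        assert cosine_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_unit(self):
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert cosine_distance([1, 0], [1, 1]) == pytest.approx(1 - 1 / math.sqrt(2))

    def test_zero_norm_error(self):
        with pytest.raises(ValidationError):
            cosine_distance([0, 0], [1, 1])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-5, 5).map(lambda v: 0.0 if abs(v) < 1e-3 else v),
                 min_size=2, max_size=6),
        st.lists(st.floats(-5, 5).map(lambda v: 0.0 if abs(v) < 1e-3 else v),
                 min_size=2, max_size=6),
    )
    def test_symmetry_and_range(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if not any(x) or not any(y):
            return
        d = cosine_distance(x, y)
        assert d == pytest.approx(cosine_distance(y, x))
        assert -1e-9 <= d <= 2 + 1e-9


def three_type_logged(n_per=60, seed=0):
    """Well-separated three-type logged matrix, no dropout."""
    rng = np.random.default_rng(seed)
    progs = [
        [200, 2, 2, 2, 100, 2],
        [2, 200, 2, 100, 2, 2],
        [2, 2, 200, 2, 2, 100],
    ]
    rows, types = [], []
    for t, p in enumerate(progs):
        lam = np.array(p, dtype=float)
        rows.append(rng.poisson(lam, size=(n_per, len(p))))
        types += [t] * n_per
    X = np.log2(1 + np.vstack(rows).astype(float))
    m = make_counts(X, stage="logged")
    return m, np.array(types)


class TestEmbedding:
    def test_determinism_and_shape(self):
        m, _ = three_type_logged()
        p = EmbeddingParams(n_neighbors=15, seed=3)
        a = embed_fit_transform(m, p)
        b = embed_fit_transform(m, p)
        assert a.shape == (len(m.cells), 2)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_knn_purity_on_separated_types(self):
        m, types = three_type_logged()
        p = EmbeddingParams(n_neighbors=15, seed=0)
        emb = embed_fit_transform(m, p).to_numpy()
        from sklearn.neighbors import KNeighborsClassifier

        knn = KNeighborsClassifier(n_neighbors=5).fit(emb, types)
        purity = (knn.predict(emb) == types).mean()
        assert purity >= 0.9

    def test_fit_subset_transforms_all_cells(self):
        m, types = three_type_logged(n_per=40)
        sources = ["regular"] * 60 + ["sox10mut"] * 60
        meta = make_meta(m.cells, sources)
        p = EmbeddingParams(n_neighbors=15, seed=0,
                            fit_subset=cs.cluster_search.WT_SOURCES)
        emb = embed_fit_transform(m, p, meta)
        assert list(emb.index) == m.cells  # mutants embedded too

    def test_fit_subset_smaller_than_neighbors_errors(self):
        m, _ = three_type_logged(n_per=4)
        with pytest.raises(ValidationError, match="smaller than n_neighbors"):
            embed_fit_transform(m, EmbeddingParams(n_neighbors=25))

    def test_tsne_alternative(self):
        m, types = three_type_logged(n_per=25)
        p = EmbeddingParams(method="tsne", seed=0, max_iter=300)
        emb = embed_fit_transform(m, p)
        assert emb.shape == (75, 2)


class TestSnnCluster:
    @pytest.fixture
    def blobs(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.3, size=(50, 2))
        b = rng.normal(10, 0.3, size=(50, 2))
        X = np.vstack([a, b])
        return pd.DataFrame(X, index=[f"c{i}" for i in range(100)],
                            columns=["dim1", "dim2"])

    def test_two_blobs(self, blobs):
        # modest resolution: each far-apart blob is one community
        labels = snn_cluster(blobs, resolution=0.1, seed=0, k=15)
        truth = [0] * 50 + [1] * 50
        assert labels.nunique() == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_cell(self):
        emb = pd.DataFrame([[0.0, 0.0]], index=["c0"], columns=["dim1", "dim2"])
        assert snn_cluster(emb, 1.0).tolist() == [0]

    def test_zero_resolution_limit(self):
        # on a connected neighbor graph the modularity limit is one community
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1.0, size=(60, 2))
        emb = pd.DataFrame(X, index=[f"c{i}" for i in range(60)],
                           columns=["dim1", "dim2"])
        labels = snn_cluster(emb, resolution=1e-6, seed=0, k=15)
        assert labels.nunique() == 1

    def test_permutation_invariance(self, blobs):
        labels = snn_cluster(blobs, 0.1, seed=0, k=15)
        perm = blobs.sample(frac=1.0, random_state=5)
        labels2 = snn_cluster(perm, 0.1, seed=0, k=15)
        aligned = labels2.loc[labels.index]
        assert adjusted_rand_score(labels.to_numpy(), aligned.to_numpy()) == 1.0


class TestQualScore:
    def test_no_controls(self):
        labels = pd.Series([0, 0, 1], index=["a", "b", "c"])
        meta = make_meta(["a", "b", "c"], ["regular"] * 3)
        q, qi = qual_score(labels, meta)
        assert q == pytest.approx(2.0)
        assert qi.n_irido == qi.n_melo == 0

    def test_pure_control_clusters(self):
        cells = [f"i{k}" for k in range(25)] + [f"m{k}" for k in range(19)]
        labels = pd.Series([0] * 25 + [1] * 19, index=cells)
        meta = make_meta(cells, ["control_iri"] * 25 + ["control_mel"] * 19)
        q, qi = qual_score(labels, meta)
        assert q == pytest.approx(math.sqrt(26) + math.sqrt(20))
        assert (qi.n_irido, qi.n_clust_irido) == (25, 25)

    def test_diluted_control_clusters(self):
        cells = ([f"i{k}" for k in range(25)] + [f"r{k}" for k in range(75)]
                 + [f"m{k}" for k in range(19)] + [f"s{k}" for k in range(31)])
        labels = pd.Series([0] * 100 + [1] * 50, index=cells)
        meta = make_meta(cells, ["control_iri"] * 25 + ["regular"] * 75
                         + ["control_mel"] * 19 + ["regular"] * 31)
        q, _ = qual_score(labels, meta)
        assert q == pytest.approx(26 / math.sqrt(101) + 20 / math.sqrt(51))

    def test_matches_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(5, 60)
            cells = [f"c{i}" for i in range(n)]
            sources = rng.choice(
                ["regular", "control_iri", "control_mel", "tail"], size=n,
                p=[0.6, 0.15, 0.15, 0.1],
            )
            meta = make_meta(cells, list(sources))
            labels = pd.Series(rng.integers(0, max(2, n // 5), size=n), index=cells)
            q, _ = qual_score(labels, meta)
            assert q == brute_force_qual(labels, meta)


class TestSearchAndMarkers:
    @pytest.fixture(scope="class")
    def small_logged(self):
        m, types = three_type_logged(n_per=40, seed=2)
        sources = (["control_iri"] * 10 + ["regular"] * 30
                   + ["control_mel"] * 10 + ["regular"] * 30
                   + ["regular"] * 40)
        meta = make_meta(m.cells, sources)
        return m, meta, types

    def test_single_combination_grid(self, small_logged):
        m, meta, _ = small_logged
        grid = [(EmbeddingParams(n_neighbors=15), 1.0)]
        best, table = enumerate_search(m, grid, meta, replicates=2, seed=0)
        assert len(table) == 2
        assert best.resolution == 1.0

    def test_argmax_property_and_determinism(self, small_logged):
        m, meta, _ = small_logged
        grid = [(EmbeddingParams(n_neighbors=15), r) for r in (0.5, 1.0)]
        best, table = enumerate_search(m, grid, meta, replicates=2, seed=4)
        assert best.qual >= table["qual"].max() - 1e-12
        best2, table2 = enumerate_search(m, grid, meta, replicates=2, seed=4)
        assert best2.qual == best.qual
        assert best2.labels.equals(best.labels)
        assert table2.equals(table)

    def test_controls_concentrate(self, small_logged):
        m, meta, _ = small_logged
        grid = [(EmbeddingParams(n_neighbors=15), 1.0)]
        best, _ = enumerate_search(m, grid, meta, replicates=2, seed=0)
        iri = meta.cells_of_source("control_iri")
        top = best.labels.loc[iri].value_counts().iloc[0]
        assert top / len(iri) >= 0.9

    def test_markers_exclusive_probe(self):
        X = np.zeros((20, 3))
        X[:10, 0] = 5.0  # g0 only in cluster A
        X[:, 2] = 1.0
        m = make_counts(X, stage="logged")
        labels = pd.Series([0] * 10 + [1] * 10, index=m.cells)
        markers = find_markers(m, labels, 1)
        assert markers[0] == ["g0"]

    def test_markers_n_exceeds_probes(self):
        X = np.random.default_rng(0).uniform(0, 5, (10, 3))
        m = make_counts(X, stage="logged")
        labels = pd.Series([0] * 5 + [1] * 5, index=m.cells)
        markers = find_markers(m, labels, 10)
        assert sorted(markers[0]) == ["g0", "g1", "g2"]

    def test_markers_tie_alphabetical(self):
        X = np.zeros((10, 2))
        X[:5, 0] = 3.0
        X[:5, 1] = 3.0  # identical difference for g0 and g1
        m = make_counts(X, stage="logged")
        labels = pd.Series([0] * 5 + [1] * 5, index=m.cells)
        assert find_markers(m, labels, 2)[0] == ["g0", "g1"]


class TestMerge:
    def test_duplicate_programs_merge(self):
        rng = np.random.default_rng(0)
        same = rng.normal(5, 1, size=(60, 6))
        other = rng.normal(0, 1, size=(30, 6)) + np.array([20, 0, 0, 0, 0, 0])
        X = np.clip(np.vstack([same, other]), 0, None)
        m = make_counts(X, stage="logged")
        labels = pd.Series([0] * 30 + [1] * 30 + [2] * 30, index=m.cells)
        merged = merge_clusters(m, labels)
        assert merged.nunique() == 2
        assert merged.iloc[0] == merged.iloc[30]  # the two halves united

    def test_separable_clusters_not_merged(self):
        X = np.zeros((40, 4))
        X[:20, 0] = 10.0
        X[20:, 1] = 10.0
        m = make_counts(X, stage="logged")
        labels = pd.Series([0] * 20 + [1] * 20, index=m.cells)
        merged = merge_clusters(m, labels)
        assert merged.nunique() == 2

    def test_single_cluster_unchanged(self):
        X = np.random.default_rng(0).uniform(0, 5, (10, 3))
        m = make_counts(X, stage="logged")
        labels = pd.Series([0] * 10, index=m.cells)
        assert merge_clusters(m, labels).nunique() == 1

    def test_never_increases_cluster_count(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 5, (50, 5))
        m = make_counts(X, stage="logged")
        labels = pd.Series(rng.integers(0, 5, 50), index=m.cells)
        assert merge_clusters(m, labels).nunique() <= labels.nunique()

    def test_control_clusters_protected(self):
        # two statistically identical clusters, one holding all control
        # iridophores: the control cluster must survive merging
        rng = np.random.default_rng(2)
        X = rng.normal(5, 1, size=(40, 4)).clip(0)
        m = make_counts(X, stage="logged")
        labels = pd.Series([0] * 20 + [1] * 20, index=m.cells)
        meta = make_meta(m.cells, ["control_iri"] * 20 + ["regular"] * 20)
        merged = merge_clusters(m, labels, meta=meta)
        assert merged.loc[m.cells[:20]].nunique() == 1
        assert merged.nunique() == 2  # protected pair not merged
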