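"""Embedding, SNN clustering, the control-anchored qual score, and the
enumerative parameter search.

Clustering quality is anchored on purified control cells: a partition is
good when the cluster richest in control iridophores and the cluster
richest in control melanocytes are both large in control content and small
in total size, quantified by

    qual = (1 + N_irido) / sqrt(1 + N_clust_irido)
         + (1 + N_melo)  / sqrt(1 + N_clust_melo)

where N_irido / N_melo count control cells inside their target cluster and
N_clust_* are the target clusters' total sizes.  The enumerative search
re-runs every (embedding parameters, resolution) combination several times
with distinct derived seeds — non-linear embeddings are stochastic — and
keeps the argmax.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestCentroid, NearestNeighbors

from .panel_io import CellMeta, CellSource, CountMatrix, ValidationError

log = logging.getLogger("crestscope")

#: fit-subset alias: wild-type cells only (the embedding transform is
#: estimated on WT cells, then applied to the complete data set)
WT_SOURCES = ("regular", "tail", "control_mel", "control_iri")


def cosine_distance(x, y) -> float:
    """d(x, y) = 1 - x.y / (|x||y|), in [0, 2]; zero-norm input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("cosine_distance: shape mismatch")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValidationError("cosine_distance: zero-norm vector")
    return float(1.0 - float(np.dot(x, y)) / (nx * ny))


@dataclass(frozen=True)
class EmbeddingParams:
    method: str = "umap"           # "umap" | "tsne"
    min_dist: float = 4.0
    spread: float = 9.0
    n_neighbors: int = 25
    metric: str = "cosine"
    perplexity: float = 20.0       # tsne only
    theta: float = 0.0
    eta: float = 500.0
    max_iter: int = 50000
    seed: int = 0
    fit_subset: tuple[str, ...] | None = None  # source classes to fit on

    def __post_init__(self):
        if self.n_neighbors < 2:
            raise ValidationError("n_neighbors must be >= 2")
        if self.method not in ("umap", "tsne"):
            raise ValidationError(f"unknown embedding method {self.method!r}")


@dataclass(frozen=True)
class QualInputs:
    n_irido: int = 0
    n_melo: int = 0
    n_clust_irido: int = 0
    n_clust_melo: int = 0

    def __post_init__(self):
        if not (0 <= self.n_irido <= max(self.n_clust_irido, 0)) and self.n_clust_irido:
            raise ValidationError("n_irido exceeds its cluster size")
        if not (0 <= self.n_melo <= max(self.n_clust_melo, 0)) and self.n_clust_melo:
            raise ValidationError("n_melo exceeds its cluster size")


@dataclass
class ClusterSolution:
    labels: pd.Series
    params: EmbeddingParams
    resolution: float
    replicate_seed: int
    qual: float
    qual_inputs: QualInputs


def embed_fit_transform(
    m: CountMatrix, p: EmbeddingParams, meta: CellMeta | None = None
) -> pd.DataFrame:
    """2-D embedding of all cells; the transform is fitted on the cells of
    ``p.fit_subset`` (e.g. WT only) and applied to the complete matrix."""
    m.require_stage("logged")
    X = m.values.to_numpy(dtype=float)
    cells = m.cells
    if p.fit_subset is not None:
        if meta is None:
            raise ValidationError("fit_subset requires cell metadata")
        subset = set(p.fit_subset)
        fit_idx = [i for i, c in enumerate(cells) if meta.source_of(c) in subset]
    else:
        fit_idx = list(range(len(cells)))
    if len(fit_idx) < p.n_neighbors:
        raise ValidationError(
            f"fit subset ({len(fit_idx)} cells) smaller than n_neighbors ({p.n_neighbors})"
        )

    if p.method == "umap":
        import umap

        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=p.n_neighbors,
            min_dist=p.min_dist,
            spread=p.spread,
            metric=p.metric,
            random_state=p.seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(fit_idx) == len(cells):
                coords = reducer.fit_transform(X)
            else:
                reducer.fit(X[fit_idx])
                coords = reducer.transform(X)
    else:  # tsne: no out-of-sample transform available; fit on all cells
        from sklearn.manifold import TSNE

        if len(fit_idx) != len(cells):
            log.warning("tSNE has no out-of-sample transform; fitting on all cells")
        tsne = TSNE(
            n_components=2,
            perplexity=min(p.perplexity, (len(cells) - 1) / 3),
            learning_rate=p.eta,
            method="exact" if p.theta == 0 else "barnes_hut",
            angle=p.theta if p.theta > 0 else 0.5,
            max_iter=p.max_iter,
            metric=p.metric,
            init="random",
            random_state=p.seed,
        )
        coords = tsne.fit_transform(X)
    return pd.DataFrame(np.asarray(coords, dtype=float), index=cells,
                        columns=["dim1", "dim2"])


def snn_cluster(
    emb: pd.DataFrame,
    resolution: float,
    seed: int = 0,
    k: int = 25,
    metric: str = "euclidean",
    prune: float = 1 / 15,
) -> pd.Series:
    """Shared-nearest-neighbor clustering by modularity optimization.

    Builds a k-NN graph, weights each edge by the Jaccard overlap of the
    two endpoints' neighbor sets (edges below ``prune`` dropped), and
    partitions it with the Leiden algorithm at the given resolution.
    """
    cells = list(emb.index)
    n = len(cells)
    if n < 1:
        raise ValidationError("empty embedding")
    if n == 1:
        return pd.Series([0], index=cells)
    X = emb.to_numpy(dtype=float)
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1, metric=metric).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row) | {i} for i, row in enumerate(idx)]

    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            if j <= i:
                continue
            w = len(neigh[i] & neigh[j]) / len(neigh[i] | neigh[j])
            if w >= prune:
                edges.append((i, int(j)))
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.array(part.membership)
    # relabel by first occurrence for a deterministic, order-stable output
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    return pd.Series(labels, index=cells)


def qual_score(labels: pd.Series, meta: CellMeta) -> tuple[float, QualInputs]:
    """Evaluate the control-anchored cluster-quality score.

    For each control type, the target cluster is the one containing the
    most cells of that type; ties go to the smaller cluster, then the
    lower cluster id.  An absent control set contributes (1+0)/sqrt(1+0).
    """
    sizes = labels.value_counts().to_dict()

    def component(source: str) -> tuple[int, int]:
        cells = [c for c in meta.cells_of_source(source) if c in labels.index]
        if not cells:
            return 0, 0
        counts = labels.loc[cells].value_counts().to_dict()
        best = sorted(counts, key=lambda cl: (-counts[cl], sizes[cl], cl))[0]
        return int(counts[best]), int(sizes[best])

    n_iri, n_cl_iri = component(CellSource.CONTROL_IRI)
    n_mel, n_cl_mel = component(CellSource.CONTROL_MEL)
    qual = (1 + n_iri) / np.sqrt(1 + n_cl_iri) + (1 + n_mel) / np.sqrt(1 + n_cl_mel)
    return float(qual), QualInputs(n_iri, n_mel, n_cl_iri, n_cl_mel)


def enumerate_search(
    m: CountMatrix,
    grid: list[tuple[EmbeddingParams, float]],
    meta: CellMeta,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[ClusterSolution, pd.DataFrame]:
    """Score every (embedding params, resolution) combination ``replicates``
    times with distinct derived seeds; return the qual-argmax and the full
    audit table.  Ties break toward the lowest grid index, then replicate."""
    if not grid:
        raise ValidationError("empty parameter grid")
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s % (2**31)) for s in ss.generate_state(replicates)]

    emb_cache: dict[tuple, pd.DataFrame] = {}
    rows = []
    best: ClusterSolution | None = None
    for gi, (params, resolution) in enumerate(grid):
        for ri, rs in enumerate(rep_seeds):
            key = (replace(params, seed=0), rs)
            if key not in emb_cache:
                emb_cache[key] = embed_fit_transform(
                    m, replace(params, seed=rs), meta
                )
            emb = emb_cache[key]
            labels = snn_cluster(emb, resolution, seed=rs, k=params.n_neighbors)
            q, qi = qual_score(labels, meta)
            rows.append(
                {
                    "grid_index": gi, "replicate": ri, "seed": rs,
                    "method": params.method, "min_dist": params.min_dist,
                    "spread": params.spread, "n_neighbors": params.n_neighbors,
                    "resolution": resolution, "n_clusters": labels.nunique(),
                    "qual": q, "n_irido": qi.n_irido, "n_melo": qi.n_melo,
                    "n_clust_irido": qi.n_clust_irido,
                    "n_clust_melo": qi.n_clust_melo,
                }
            )
            if best is None or q > best.qual:
                best = ClusterSolution(labels, params, resolution, rs, q, qi)
    table = pd.DataFrame(rows)
    log.info("enumerate_search: best qual %.4f over %d runs", best.qual, len(rows))
    return best, table


def find_markers(m: CountMatrix, labels: pd.Series, n: int) -> dict[int, list[str]]:
    """Top-n markers per cluster by mean log-expression difference
    (cluster vs rest); ties broken alphabetically by probe id."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValidationError("need >= 2 clusters to rank markers")
    out: dict[int, list[str]] = {}
    vals = m.values
    for cl in clusters:
        inside = vals.loc[labels.index[labels == cl]].mean(axis=0)
        outside = vals.loc[labels.index[labels != cl]].mean(axis=0)
        diff = inside - outside
        ranked = sorted(m.probes, key=lambda p: (-diff[p], p))
        out[cl] = ranked[:n]
    return out


def _pair_accuracy(
    m: CountMatrix, labels: pd.Series, a: int, b: int, markers: list[str]
) -> float:
    """5-fold CV accuracy of a nearest-centroid classifier separating
    clusters a and b on the given marker probes."""
    cells = labels.index[labels.isin([a, b])]
    X = m.values.loc[cells, markers].to_numpy(dtype=float)
    y = (labels.loc[cells] == b).to_numpy(dtype=int)
    smallest = min((y == 0).sum(), (y == 1).sum())
    if smallest < 2:
        clf = NearestCentroid().fit(X, y)
        return float((clf.predict(X) == y).mean())
    folds = min(5, int(smallest))
    accs = []
    for tr, te in StratifiedKFold(n_splits=folds).split(X, y):
        clf = NearestCentroid().fit(X[tr], y[tr])
        accs.append((clf.predict(X[te]) == y[te]).mean())
    return float(np.mean(accs))


def merge_clusters(
    m: CountMatrix,
    labels: pd.Series,
    top_n: int = 4,
    acc_cutoff: float = 0.9,
    meta: CellMeta | None = None,
) -> pd.Series:
    """Merge cluster pairs a nearest-centroid classifier cannot separate.

    For each pair, the classifier uses the union of both clusters' top_n
    markers; pairs with cross-validated accuracy < acc_cutoff are merged,
    repeatedly, scanning pairs in canonical (sorted) order.  Clusters
    holding the majority of control melanocytes or iridophores are never
    merged away (requires ``meta``).
    """
    labels = labels.copy()

    def protected_set() -> set[int]:
        if meta is None:
            return set()
        prot = set()
        for source in (CellSource.CONTROL_MEL, CellSource.CONTROL_IRI):
            cells = [c for c in meta.cells_of_source(source) if c in labels.index]
            if not cells:
                continue
            counts = labels.loc[cells].value_counts()
            if counts.iloc[0] > len(cells) / 2:
                prot.add(int(counts.index[0]))
        return prot

    merged = True
    while merged and labels.nunique() > 1:
        merged = False
        markers = find_markers(m, labels, top_n)
        prot = protected_set()
        clusters = sorted(labels.unique())
        for i, a in enumerate(clusters):
            for b in clusters[i + 1 :]:
                if a in prot or b in prot:
                    continue
                union = sorted(set(markers[a]) | set(markers[b]))
                acc = _pair_accuracy(m, labels, a, b, union)
                if acc < acc_cutoff:
                    labels[labels == b] = a
                    merged = True
                    break
            if merged:
                break
    # compress ids to 0..K-1 preserving order of first occurrence
    remap: dict[int, int] = {}
    out = labels.copy()
    for c in labels:
        if c not in remap:
            remap[c] = len(remap)
    return out.map(remap)
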