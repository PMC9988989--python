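"""Cluster-anchored lineage inference and pseudotime.

Clusters are summarized by their centroids in the full log-expression
space; a minimum spanning tree under cosine distance connects them, and
each lineage is the unique tree path from a designated start cluster
(the early multipotent progenitor) to a terminal cluster (melanocytes,
iridophores).  Per-cell pseudotime is arc length along the L2-normalized
centroid polyline: every cell projects onto the polyline segment arriving
at its own cluster's centroid (start-cluster cells use the first outgoing
segment), so lineages sharing a path prefix assign identical pseudotime
to cells of the shared clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_search import cosine_distance
from .panel_io import CellMeta, CellSource, CountMatrix, ValidationError

log = logging.getLogger("crestscope")


@dataclass
class Lineage:
    lineage_id: str
    path: tuple            # ordered cluster ids, start ... terminal
    pseudotime: pd.Series | None = None  # cell_id -> arc length (lineage cells only)


def cluster_centroids(m: CountMatrix, labels: pd.Series) -> dict:
    """Arithmetic mean profile per cluster in the full gene space."""
    out = {}
    for cl in sorted(labels.unique()):
        cells = labels.index[labels == cl]
        if len(cells) == 0:
            raise ValidationError(f"empty cluster {cl}")
        out[cl] = m.values.loc[cells].mean(axis=0).to_numpy(dtype=float)
    return out


def _mst_edges(centroids: dict) -> list[tuple]:
    """Kruskal MST over the complete cluster graph under cosine distance;
    ties broken by (weight, lower id pair)."""
    nodes = sorted(centroids)
    edges = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            edges.append((cosine_distance(centroids[a], centroids[b]), a, b))
    edges.sort(key=lambda e: (e[0], str(e[1]), str(e[2])))
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst = []
    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            mst.append((a, b, w))
    return mst


def build_lineages(centroids: dict, start, terminals) -> list[Lineage]:
    """One lineage per terminal: the unique MST path start -> terminal."""
    nodes = set(centroids)
    if start not in nodes:
        raise ValidationError(f"start cluster {start!r} not found")
    missing = [t for t in terminals if t not in nodes]
    if missing:
        raise ValidationError(f"terminal clusters not found: {missing}")
    if len(nodes) < 2:
        raise ValidationError("need >= 2 clusters to build lineages")

    adj: dict = {n: [] for n in nodes}
    for a, b, _ in _mst_edges(centroids):
        adj[a].append(b)
        adj[b].append(a)

    def path_to(t):
        # DFS on a tree: unique path
        stack = [(start, [start])]
        seen = {start}
        while stack:
            node, path = stack.pop()
            if node == t:
                return tuple(path)
            for nb in sorted(adj[node], key=str):
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, path + [nb]))
        raise ValidationError("MST unexpectedly disconnected")

    lineages = []
    for t in sorted(terminals, key=str):
        if t == start:
            log.warning("lineage %r: start equals terminal; degenerate path", t)
            lineages.append(Lineage(str(t), (start,)))
        else:
            lineages.append(Lineage(str(t), path_to(t)))
    return lineages


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValidationError("zero-norm expression vector cannot be normalized")
    return X / norms


def assign_pseudotime(
    m: CountMatrix, labels: pd.Series, lineage: Lineage
) -> Lineage:
    """Arc-length pseudotime along the lineage's normalized centroid polyline.

    A cell of the cluster at path index i projects (clamped) onto segment
    (i-1, i); start-cluster cells project onto segment (0, 1).  Cells of
    clusters off the path get no pseudotime.
    """
    path = lineage.path
    cents = cluster_centroids(m, labels)
    P = _normalize_rows(np.vstack([cents[c] for c in path]))
    if len(path) == 1:
        cells = labels.index[labels == path[0]]
        return Lineage(lineage.lineage_id, path, pd.Series(0.0, index=cells))

    seg_vec = P[1:] - P[:-1]
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    pt = {}
    for i, cl in enumerate(path):
        cells = labels.index[labels == cl]
        if len(cells) == 0:
            continue
        seg = max(i - 1, 0)  # segment arriving at this cluster (or first outgoing)
        p0, v, L = P[seg], seg_vec[seg], seg_len[seg]
        X = _normalize_rows(m.values.loc[cells].to_numpy(dtype=float))
        if L == 0:
            t = np.zeros(len(cells))
        else:
            t = np.clip((X - p0) @ v / (L * L), 0.0, 1.0)
        for c, tc in zip(cells, t):
            pt[c] = float(cum[seg] + tc * L)
    return Lineage(lineage.lineage_id, path, pd.Series(pt))


def suggest_anchors(labels: pd.Series, meta: CellMeta) -> dict:
    """Suggest (never auto-commit) a start cluster (most tail-cell-enriched)
    and terminal clusters (holding most control melanocytes / iridophores)."""
    def top_cluster(source):
        cells = [c for c in meta.cells_of_source(source) if c in labels.index]
        if not cells:
            return None
        return int(labels.loc[cells].value_counts().index[0])

    sizes = labels.value_counts()
    tail = [c for c in meta.cells_of_source(CellSource.TAIL) if c in labels.index]
    start = None
    if tail:
        frac = labels.loc[tail].value_counts() / sizes
        start = int(frac.idxmax())
    return {
        "start": start,
        "terminal_mel": top_cluster(CellSource.CONTROL_MEL),
        "terminal_iri": top_cluster(CellSource.CONTROL_IRI),
    }
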