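"""Detection calls, co-expression/multipotency summaries, balanced dot-plot
tables, cosine-ordered heat-map layouts and the 2x2 chi-square test.

A cell "detects" a gene when its count (or relative expression) reaches a
stated threshold — 30 counts in the main panels, 5 for the low-expression
sox10-mutant display — or, for Ct data, when Ct falls at or below a cutoff.
Co-expression summaries ask: of the cells positive for an anchor gene, what
fraction is also positive for at least one gene of a query set?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import pdist
from scipy.stats import chi2 as chi2_dist

from .panel_io import CountMatrix, CtMatrix, ValidationError
from .taqman import RelExprMatrix, detectable_subset


class UndefinedFractionError(ValueError):
    """No anchor-positive cells: the co-expression fraction is undefined."""


@dataclass
class DetectionMatrix:
    values: pd.DataFrame  # boolean cells x genes
    threshold: float
    source: str           # "counts" | "ct"

    @property
    def cells(self):
        return list(self.values.index)

    @property
    def genes(self):
        return list(self.values.columns)


@dataclass
class CoexprSummary:
    anchor: str
    gene_set: tuple
    n_anchor: int
    n_anchor_and_set: int

    @property
    def fraction(self) -> float:
        return self.n_anchor_and_set / self.n_anchor


def binarize(m, threshold: float) -> DetectionMatrix:
    """Detection calls: value >= threshold for expression matrices;
    Ct <= threshold for Ct matrices (lower Ct = more molecules)."""
    if threshold < 0:
        raise ValidationError("threshold must be nonnegative")
    if isinstance(m, CtMatrix):
        calls = pd.DataFrame(False, index=m.cells, columns=m.assays)
        for g in m.assays:
            for c in detectable_subset(m, g, ct_max=threshold):
                calls.at[c, g] = True
        return DetectionMatrix(calls, threshold, "ct")
    values = m.values if isinstance(m, (CountMatrix, RelExprMatrix)) else pd.DataFrame(m)
    return DetectionMatrix(values >= threshold, threshold, "counts")


def coexpression_fraction(
    d: DetectionMatrix, anchor: str, others
) -> CoexprSummary:
    """Of the anchor-positive cells, the fraction positive for >=1 gene of
    ``others``.  Raises UndefinedFractionError when no cell is
    anchor-positive (a 0/0 is not reported as 0)."""
    others = tuple(others)
    if not others:
        raise ValidationError("empty query gene set")
    for g in (anchor, *others):
        if g not in d.values.columns:
            raise ValidationError(f"gene {g!r} absent from detection matrix")
    pos = d.values[anchor]
    n_a = int(pos.sum())
    if n_a == 0:
        raise UndefinedFractionError(f"no cells positive for anchor {anchor!r}")
    n_both = int((d.values.loc[pos, list(others)].any(axis=1)).sum())
    return CoexprSummary(anchor, others, n_a, n_both)


def dotplot_table(
    m: CountMatrix, labels: pd.Series, detection_threshold: float = 0.0
) -> pd.DataFrame:
    """Balanced dot-plot table: one row per (cluster, gene).

    ``colour_value`` rescales the cluster-mean expression by the global
    min/max over *all* (cluster, gene) pairs — a single colour scale for
    the whole panel, not per gene.  A degenerate scale maps to 0.
    """
    rows = []
    for cl in sorted(labels.unique()):
        sub = m.values.loc[labels.index[labels == cl]]
        for g in m.probes:
            col = sub[g]
            expressing = col >= detection_threshold if detection_threshold > 0 else col > 0
            n_exp = int(expressing.sum())
            rows.append(
                {
                    "cluster": cl,
                    "gene": g,
                    "fraction_expressing": n_exp / len(col),
                    "mean_expression": float(col.mean()),
                    "mean_expression_of_expressers": (
                        float(col[expressing].mean()) if n_exp else 0.0
                    ),
                }
            )
    df = pd.DataFrame(rows)
    lo, hi = df["mean_expression"].min(), df["mean_expression"].max()
    if hi > lo:
        df["colour_value"] = (df["mean_expression"] - lo) / (hi - lo)
    else:
        df["colour_value"] = 0.0
    return df


def feature_table(
    m: CountMatrix, emb: pd.DataFrame, gene: str, min_cutoff: float = 3.0
) -> pd.DataFrame:
    """Feature-plot table: embedding coordinates plus the gene's expression
    clamped below at ``min_cutoff`` for display; stored data untouched."""
    if gene not in m.probes:
        raise ValidationError(f"gene {gene!r} absent from matrix")
    out = emb.copy()
    out["expression"] = m.values[gene].reindex(emb.index)
    out["display_value"] = out["expression"].clip(lower=min_cutoff)
    return out


def heatmap_order(m, axis: str = "rows") -> list:
    """Leaf order from average-linkage hierarchical clustering under cosine
    distance, for heat-map layout.  Deterministic; zero-norm items error."""
    values = m.values if hasattr(m, "values") and not isinstance(m, pd.DataFrame) else pd.DataFrame(m)
    if axis == "cols":
        values = values.T
    elif axis != "rows":
        raise ValidationError("axis must be 'rows' or 'cols'")
    ids = list(values.index)
    if len(ids) < 2:
        raise ValidationError("need >= 2 items to order")
    X = values.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        offender = ids[int(np.argmax(norms == 0))]
        raise ValidationError(f"zero-norm item {offender!r} has no cosine direction")
    d = pdist(X, metric="cosine")
    Z = optimal_leaf_ordering(linkage(d, method="average"), d)
    return [ids[i] for i in leaves_list(Z)]


def chi2_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table (1 df).

    chi2 = n (ad - bc)^2 / (r1 r2 c1 c2); optional Yates continuity
    correction.  Any zero margin is an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("table must be 2x2 nonnegative")
    (a, b), (c, d) = t
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValidationError("zero margin in contingency table")
    det = a * d - b * c
    if yates:
        det = max(abs(det) - n / 2.0, 0.0)
    chi2 = n * det * det / (r1 * r2 * c1 * c2)
    p = float(chi2_dist.sf(chi2, df=1))
    return float(chi2), p
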