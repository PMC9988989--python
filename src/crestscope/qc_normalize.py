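"""QC and normalization cascade for targeted-panel molecule counts.

Pipeline order is fixed: cell/probe filters -> background correction ->
housekeeping normalization -> count flooring -> dropout imputation -> log
transform.  Each stage advances the matrix ``stage_tag`` and refuses
out-of-order input.

The reference class for normalization is the union of housekeeping and
spike-in probes (in the study: the *rpl13* internal control plus the
*kanamycin* spike-in).  Background is the per-cell "mean + 2 sd" of the
negative-control probes; counts below the floor (default 30) are nullified,
then zeros are imputed by a consensus of k-means partitions over
rank-transformed profiles, and finally log(1 + x) is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .panel_io import CountMatrix, ProbeClass, ProbePanel, ValidationError

log = logging.getLogger("crestscope")

#: machine-readable reason codes for removed cells
LOW_SIGNAL = "low_signal"
POOR_NORM_FACTOR = "poor_norm_factor"
NOISY_BACKGROUND = "noisy_background"
LOW_PREVALENCE = "low_prevalence"


@dataclass
class QCReport:
    removed_cells: list[tuple[str, str]] = field(default_factory=list)
    removed_probes: list[tuple[str, str]] = field(default_factory=list)
    norm_factors: dict[str, float] = field(default_factory=dict)
    background: dict[str, float] = field(default_factory=dict)
    n_cells_in: int = 0
    n_cells_surviving: int = 0
    n_zeros_imputed: int = 0
    frac_zeros_imputed: float = 0.0

    def removed_cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed_cells, columns=["cell_id", "reason"])

    def removed_probes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed_probes, columns=["probe_id", "reason"])


def filter_cells_by_signal(
    m: CountMatrix, panel: ProbePanel, min_total: int
) -> tuple[CountMatrix, list[tuple[str, str]]]:
    """Remove cells whose summed endogenous counts fall below ``min_total``.

    Housekeeping / spike-in / negative probes are excluded from the sum:
    a cell can have huge control counts yet no usable biological signal.
    """
    if min_total < 0:
        raise ValidationError("min_total must be >= 0")
    m.require_stage("raw")
    endo = [p for p in m.probes if panel.probe_class[p] is ProbeClass.ENDOGENOUS]
    sums = m.values[endo].sum(axis=1)
    removed = [(c, LOW_SIGNAL) for c in m.cells if sums[c] < min_total]
    keep = [c for c in m.cells if sums[c] >= min_total]
    return CountMatrix(m.values.loc[keep], "raw"), removed


def filter_probes_by_prevalence(
    m: CountMatrix, panel: ProbePanel, min_cells: int, detect_at: float = 1.0
) -> tuple[CountMatrix, list[tuple[str, str]]]:
    """Remove endogenous probes detected (>= detect_at) in < min_cells cells.

    Control-class probes are never removed; an undetected control only
    triggers a warning, because normalization needs the reference class.
    """
    m.require_stage("raw")
    detected = (m.values >= detect_at).sum(axis=0)
    removed, keep = [], []
    for p in m.probes:
        if panel.probe_class[p] is ProbeClass.ENDOGENOUS and detected[p] < min_cells:
            removed.append((p, LOW_PREVALENCE))
        else:
            if panel.probe_class[p] is not ProbeClass.ENDOGENOUS and detected[p] == 0:
                log.warning("control probe %s undetected in every cell; retained", p)
            keep.append(p)
    return CountMatrix(m.values[keep], "raw"), removed


def background_correct(
    m: CountMatrix, panel: ProbePanel
) -> tuple[CountMatrix, list[tuple[str, str]], dict[str, float]]:
    """Subtract per-cell background b = mean(neg) + 2*sd(neg) (sample sd).

    Applies to every non-negative-class entry, clipping at zero.  Cells
    whose endogenous signal lies entirely below their background are
    flagged ``noisy_background`` (the caller removes them).  With fewer
    than two negative probes the stage is skipped with a log notice.
    """
    m.require_stage("raw")
    negs = [p for p in m.probes if panel.probe_class[p] is ProbeClass.NEGATIVE]
    if len(negs) < 2:
        log.info("background correction skipped: %d negative probe(s) in panel", len(negs))
        return CountMatrix(m.values.copy(), "background_corrected"), [], {}
    neg_vals = m.values[negs].to_numpy(dtype=float)
    b = neg_vals.mean(axis=1) + 2.0 * neg_vals.std(axis=1, ddof=1)
    background = dict(zip(m.cells, b))
    endo = [p for p in m.probes if panel.probe_class[p] is ProbeClass.ENDOGENOUS]
    corrected = m.values.astype(float).copy()
    non_neg = [p for p in m.probes if panel.probe_class[p] is not ProbeClass.NEGATIVE]
    corrected[non_neg] = np.maximum(0.0, corrected[non_neg].sub(b, axis=0))
    flagged = [
        (c, NOISY_BACKGROUND)
        for c in m.cells
        if endo and (m.values.loc[c, endo].to_numpy(dtype=float) < background[c]).all()
    ]
    return CountMatrix(corrected, "background_corrected"), flagged, background


def housekeeping_normalize(
    m: CountMatrix,
    panel: ProbePanel,
    factor_bounds: tuple[float, float] = (1 / 3, 3.0),
) -> tuple[CountMatrix, list[tuple[str, str]], dict[str, float]]:
    """Scale each cell so its housekeeping + spike-in sum matches the mean.

    factor f_c = mean_c(ref sum) / ref_sum(c); every entry of cell c is
    multiplied by f_c.  Cells with a zero reference sum are removed as
    ``low_signal``; cells with f_c outside ``factor_bounds`` as
    ``poor_norm_factor``.
    """
    m.require_stage("background_corrected", "raw")
    lo, hi = factor_bounds
    ref = [p for p in m.probes if p in set(panel.reference)]
    if not ref:
        raise ValidationError("no housekeeping/spike-in probes in matrix")
    sums = m.values[ref].sum(axis=1).astype(float)
    removed = [(c, LOW_SIGNAL) for c in m.cells if sums[c] <= 0]
    alive = [c for c in m.cells if sums[c] > 0]
    if not alive:
        raise ValidationError("all cells removed: zero housekeeping signal everywhere")
    mean_sum = float(sums[alive].mean())
    factors = {c: mean_sum / float(sums[c]) for c in alive}
    keep = [c for c in alive if lo <= factors[c] <= hi]
    removed += [(c, POOR_NORM_FACTOR) for c in alive if not lo <= factors[c] <= hi]
    if not keep:
        raise ValidationError("all cells removed by norm-factor bounds")
    scaled = m.values.loc[keep].astype(float).mul(
        pd.Series({c: factors[c] for c in keep}), axis=0
    )
    return CountMatrix(scaled, "normalized"), removed, factors


def floor_counts(m: CountMatrix, floor: float = 30.0) -> CountMatrix:
    """Nullify entries strictly below ``floor`` (values < 30 in the study)."""
    m.require_stage("normalized")
    vals = m.values.astype(float).where(m.values >= floor, 0.0)
    return CountMatrix(vals, "floored")


def impute_zeros(
    m: CountMatrix, ks: tuple[int, ...] = (5, 6, 7), seed: int = 0
) -> tuple[CountMatrix, int]:
    """Consensus dropout imputation; nonzero entries are never changed.

    For each k, cells are partitioned by k-means on rank-transformed
    profiles (a Spearman-geometry surrogate).  The candidate for a zero
    entry is the mean of the *nonzero* values of that probe within the
    cell's cluster; the final value averages the candidates across ks.
    Zeros with no nonzero donors in any partition stay zero.
    """
    if not ks:
        raise ValidationError("ks must be nonempty")
    m.require_stage("floored")
    X = m.values.to_numpy(dtype=float)
    n_cells = X.shape[0]
    zero_mask = X == 0
    if not zero_mask.any() or n_cells < 2:
        return CountMatrix(m.values.astype(float), "imputed"), 0

    ranks = np.vstack([rankdata(row) for row in X])
    consensus = np.zeros_like(X)
    for i, k in enumerate(ks):
        k_eff = min(k, n_cells)
        km = KMeans(n_clusters=k_eff, random_state=seed + i, n_init=10)
        labels = km.fit_predict(ranks)
        for cl in range(k_eff):
            members = labels == cl
            sub = X[members]
            nz = sub != 0
            with np.errstate(invalid="ignore"):
                donor_mean = np.where(
                    nz.sum(axis=0) > 0,
                    sub.sum(axis=0) / np.maximum(nz.sum(axis=0), 1),
                    0.0,
                )
            rows = np.where(members)[0]
            consensus[np.ix_(rows, range(X.shape[1]))] += np.where(
                zero_mask[rows], donor_mean, 0.0
            )
    consensus /= len(ks)
    out = np.where(zero_mask, consensus, X)
    n_imputed = int(((consensus > 0) & zero_mask).sum())
    return (
        CountMatrix(pd.DataFrame(out, index=m.cells, columns=m.probes), "imputed"),
        n_imputed,
    )


def log_transform(m: CountMatrix, base: float = 2.0) -> CountMatrix:
    """x -> log_base(1 + x); monotone, zero-preserving."""
    m.require_stage("imputed")
    vals = np.log1p(m.values.astype(float)) / np.log(base)
    return CountMatrix(vals, "logged")


def run_qc(
    m: CountMatrix,
    panel: ProbePanel,
    min_total: int = 100,
    min_cells: int = 3,
    detect_at: float = 1.0,
    factor_bounds: tuple[float, float] = (1 / 3, 3.0),
    count_floor: float = 30.0,
    impute_ks: tuple[int, ...] = (5, 6, 7),
    log_base: float = 2.0,
    seed: int = 0,
) -> tuple[CountMatrix, QCReport, ProbePanel]:
    """Full cascade raw -> logged, returning the QC report and pruned panel."""
    report = QCReport(n_cells_in=len(m.cells))
    m, rem = filter_cells_by_signal(m, panel, min_total)
    report.removed_cells += rem
    m, remp = filter_probes_by_prevalence(m, panel, min_cells, detect_at)
    report.removed_probes += remp
    panel = panel.subset(m.probes)

    m, flagged, background = background_correct(m, panel)
    report.background = background
    if flagged:
        report.removed_cells += flagged
        keep = [c for c in m.cells if c not in {f[0] for f in flagged}]
        m = CountMatrix(m.values.loc[keep], m.stage_tag)

    m, rem, factors = housekeeping_normalize(m, panel, factor_bounds)
    report.removed_cells += rem
    report.norm_factors = {c: factors[c] for c in m.cells}

    # the analysis space is the endogenous gene space: control probes have
    # served their purpose (background, normalization) and would otherwise
    # dominate cosine geometry downstream
    endo = [p for p in m.probes if panel.probe_class[p] is ProbeClass.ENDOGENOUS]
    m = CountMatrix(m.values[endo], m.stage_tag)

    m = floor_counts(m, count_floor)
    n_zeros = int((m.values.to_numpy() == 0).sum())
    m, n_imputed = impute_zeros(m, impute_ks, seed=seed)
    report.n_zeros_imputed = n_imputed
    report.frac_zeros_imputed = n_imputed / n_zeros if n_zeros else 0.0

    m = log_transform(m, base=log_base)
    report.n_cells_surviving = len(m.cells)
    assert report.n_cells_surviving == report.n_cells_in - len(report.removed_cells)
    return m, report, panel
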