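"""Single-cell qRT-PCR (TaqMan) Ct processing.

Ct values count amplification cycles to threshold: lower Ct means higher
abundance; no signal within 40 cycles is "Undetermined".  Pre-amplification
QC rejects samples on the control assays (kanamycin spike-in Ct < 14:
poorly amplified; rpl13 Ct < 24: poor RNA quality or empty well).  The
normalization cascade then converts Ct to log expression,
Expression = (40 - Ct) * log10(2), trims kanamycin outliers, subtracts the
per-cell spike-in expression, trims low-signal cells, shifts the matrix to
a zero minimum and nullifies values below the noise floor (4.8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import MISSING, UNDETERMINED, CtMatrix, ValidationError

KANAMYCIN = "kanamycin"
RPL13 = "rpl13"


@dataclass
class RelExprMatrix:
    """Relative expression in shifted log units, with cascade provenance."""

    values: pd.DataFrame
    provenance: list = field(default_factory=list)
    floor: float = 4.8

    def __post_init__(self):
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("relative expression must be nonnegative")


def sample_qc(
    ct: CtMatrix,
    kan_reject: float = 14.0,
    rpl13_reject: float = 24.0,
    reject_low: bool = True,
) -> tuple[CtMatrix, pd.DataFrame]:
    """Reject cells on control-assay Ct values (strict inequalities).

    ``reject_low=False`` flips the comparison direction (low Ct = high
    signal, so the printed direction is surprising; both are supported).
    """
    for assay in (KANAMYCIN, RPL13):
        if assay not in ct.assays:
            raise ValidationError(f"control assay {assay!r} absent from Ct matrix")

    def bad(v, cutoff):
        if isinstance(v, str):  # UNDETERMINED / MISSING never numerically below
            return False
        return (v < cutoff) if reject_low else (v > cutoff)

    rows = []
    keep = []
    for c in ct.cells:
        kan, rp = ct.values.at[c, KANAMYCIN], ct.values.at[c, RPL13]
        if bad(kan, kan_reject):
            rows.append({"cell_id": c, "reason": "poorly_amplified", "ct": kan})
        elif bad(rp, rpl13_reject):
            rows.append({"cell_id": c, "reason": "poor_rna_or_empty", "ct": rp})
        else:
            keep.append(c)
    report = pd.DataFrame(rows, columns=["cell_id", "reason", "ct"])
    return ct.subset_cells(keep), report


def ct_to_logexpr(ct_value, base: float = 2.0) -> float:
    """Expression = (40 - Ct) * log10(base); Undetermined -> Ct 40 -> 0;
    missing entries map to NaN (resolved to 0 later in the cascade)."""
    if ct_value == MISSING:
        return math.nan
    if ct_value == UNDETERMINED:
        return 0.0
    c = float(ct_value)
    if not 0.0 <= c <= 40.0:
        raise ValidationError(f"Ct value {c} outside [0, 40]")
    return (40.0 - c) * math.log10(base)


def _trim_cells(order: pd.Series, frac: float, ascending: bool) -> list[str]:
    """Cells to drop: the ceil(frac*n) most extreme, ties by cell_id."""
    n = len(order)
    k = math.ceil(frac * n)
    if k == 0:
        return []
    ranked = sorted(order.items(), key=lambda kv: (kv[1] if ascending else -kv[1], kv[0]))
    return [c for c, _ in ranked[:k]]


def normalize_cascade(
    ct: CtMatrix,
    taqman_floor: float = 4.8,
    trim_top_frac: float = 0.05,
    trim_bottom_frac: float = 0.05,
    base: float = 2.0,
) -> RelExprMatrix:
    """The full Ct -> relative-expression cascade, steps in printed order:

    1. Ct -> log expression for every entry;
    2. discard the ceil(frac*n) cells with highest kanamycin expression;
    3. per cell, subtract its kanamycin expression from every assay;
    4. NA -> 0;
    5. discard the ceil(frac*n) cells with lowest total expression;
    6. subtract the global matrix minimum (shift to min exactly 0);
    7. nullify entries below the noise floor.
    """
    if KANAMYCIN not in ct.assays:
        raise ValidationError("kanamycin assay required for normalization")
    prov = []

    def check_n(df, step):
        if len(df) < 3:
            raise ValidationError(f"fewer than 3 cells remaining after {step}")

    E = ct.values.map(lambda v: ct_to_logexpr(v, base=base)).astype(float)
    prov.append(("ct_to_logexpr", len(E)))

    kan = E[KANAMYCIN].fillna(0.0)
    drop = _trim_cells(kan, trim_top_frac, ascending=False)
    E = E.drop(index=drop)
    prov.append(("trim_top_kanamycin", len(drop)))
    check_n(E, "kanamycin trim")

    E = E.sub(E[KANAMYCIN].fillna(0.0), axis=0)
    prov.append(("subtract_kanamycin", len(E)))

    E = E.fillna(0.0)
    prov.append(("na_to_zero", len(E)))

    totals = E.sum(axis=1)
    drop = _trim_cells(totals, trim_bottom_frac, ascending=True)
    E = E.drop(index=drop)
    prov.append(("trim_bottom_total", len(drop)))
    check_n(E, "low-signal trim")

    E = E - float(E.to_numpy().min())
    prov.append(("shift_to_zero_min", len(E)))

    E = E.where(E >= taqman_floor, 0.0)
    prov.append(("nullify_below_floor", len(E)))

    return RelExprMatrix(E, provenance=prov, floor=taqman_floor)


def detectable_subset(ct: CtMatrix, gene: str, ct_max: float = 29.0) -> list[str]:
    """Cells with numeric Ct <= ct_max for the gene (inclusive bound);
    Undetermined and missing entries never qualify."""
    if gene not in ct.assays:
        raise ValidationError(f"unknown assay {gene!r}")
    out = []
    for c in ct.cells:
        v = ct.values.at[c, gene]
        if not isinstance(v, str) and float(v) <= ct_max:
            out.append(c)
    return out
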