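"""Tables, domain types and validation for the targeted-panel pipeline.

Everything the pipeline touches on disk is delimited text (CSV or TSV,
autodetected from the file extension).  The in-memory containers are thin
dataclasses around pandas objects with the invariants the downstream stages
rely on: unique identifiers, nonnegative counts, a probe panel that names at
least one normalization reference, and Ct values confined to [0, 40].
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("crestscope")

# Sentinels for non-numeric Ct entries.
UNDETERMINED = "UNDETERMINED"
MISSING = "MISSING"


class ProbeClass(str, Enum):
    ENDOGENOUS = "endogenous"
    HOUSEKEEPING = "housekeeping"
    SPIKE_IN = "spike_in"
    NEGATIVE = "negative"


class CellSource(str, Enum):
    REGULAR = "regular"
    TAIL = "tail"
    SOX10MUT = "sox10mut"
    CONTROL_MEL = "control_mel"
    CONTROL_IRI = "control_iri"


#: Stages of the count-matrix QC/normalization cascade, in pipeline order.
STAGES = ("raw", "background_corrected", "normalized", "floored", "imputed", "logged")


class ValidationError(ValueError):
    """Raised when an input table violates a domain-type invariant."""


@dataclass(frozen=True)
class ProbePanel:
    """Probe annotation: which probes are genes, controls or spike-ins."""

    probe_ids: tuple[str, ...]
    probe_class: Mapping[str, ProbeClass]

    def __post_init__(self):
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids in panel")
        missing = [p for p in self.probe_ids if p not in self.probe_class]
        if missing:
            raise ValidationError(f"probes without a class annotation: {missing}")
        refs = self.of_class(ProbeClass.HOUSEKEEPING) + self.of_class(ProbeClass.SPIKE_IN)
        if not refs:
            raise ValidationError(
                "panel needs at least one housekeeping or spike_in probe "
                "(normalization reference)"
            )

    def of_class(self, *classes: ProbeClass) -> list[str]:
        return [p for p in self.probe_ids if self.probe_class[p] in classes]

    @property
    def endogenous(self) -> list[str]:
        return self.of_class(ProbeClass.ENDOGENOUS)

    @property
    def reference(self) -> list[str]:
        """Housekeeping + spike-in probes: the normalization reference class."""
        return self.of_class(ProbeClass.HOUSEKEEPING, ProbeClass.SPIKE_IN)

    @property
    def negatives(self) -> list[str]:
        return self.of_class(ProbeClass.NEGATIVE)

    def subset(self, keep: Sequence[str]) -> "ProbePanel":
        keep_set = set(keep)
        ids = tuple(p for p in self.probe_ids if p in keep_set)
        return ProbePanel(ids, {p: self.probe_class[p] for p in ids})


@dataclass(frozen=True)
class CellMeta:
    """Per-cell annotation: source class and (optional) stage in hpf."""

    table: pd.DataFrame  # index: cell_id; columns: source, stage_hpf

    def __post_init__(self):
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate cell ids in metadata")
        if "source" not in self.table.columns:
            raise ValidationError("metadata needs a 'source' column")
        bad = set(self.table["source"]) - {s.value for s in CellSource}
        if bad:
            raise ValidationError(f"unknown source classes: {sorted(bad)}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    def source_of(self, cell_id: str) -> str:
        return self.table.at[cell_id, "source"]

    def cells_of_source(self, source: CellSource | str) -> list[str]:
        source = CellSource(source).value
        return list(self.table.index[self.table["source"] == source])

    def subset(self, cells: Sequence[str]) -> "CellMeta":
        return CellMeta(self.table.loc[list(cells)])


@dataclass
class CountMatrix:
    """Cells x probes matrix of nonnegative expression values.

    ``stage_tag`` records the cascade stage; the QC module refuses
    out-of-order input based on it.
    """

    values: pd.DataFrame  # index: cell_id, columns: probe_id
    stage_tag: str = "raw"

    def __post_init__(self):
        if self.stage_tag not in STAGES:
            raise ValidationError(f"unknown stage tag {self.stage_tag!r}")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate cell ids in count matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate probe ids in count matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric entries in count matrix")
        if np.isnan(arr).any():
            raise ValidationError("NaN entries in count matrix")
        if (arr < 0).any():
            raise ValidationError("negative entries in count matrix")
        if self.stage_tag == "raw" and not np.allclose(arr, np.round(arr)):
            raise ValidationError("raw counts must be integers")

    @property
    def cells(self) -> list[str]:
        return list(self.values.index)

    @property
    def probes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, stage_tag: str) -> "CountMatrix":
        return CountMatrix(values, stage_tag)

    def require_stage(self, *stages: str) -> None:
        if self.stage_tag not in stages:
            raise ValidationError(
                f"operation expects stage in {stages}, got {self.stage_tag!r}"
            )


@dataclass
class CtMatrix:
    """Cells x assays matrix of qPCR cycle-threshold values.

    Stored as an object-dtype frame whose entries are floats in [0, 40] or
    the sentinels ``UNDETERMINED`` (no signal within 40 cycles) and
    ``MISSING`` (failed experiment / NA).
    """

    values: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate cell ids in Ct matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate assay ids in Ct matrix")
        for col in self.values.columns:
            for cell, v in self.values[col].items():
                if isinstance(v, str):
                    if v not in (UNDETERMINED, MISSING):
                        raise ValidationError(
                            f"unrecognized Ct token {v!r} at ({cell}, {col})"
                        )
                elif not (0.0 <= float(v) <= 40.0):
                    raise ValidationError(
                        f"Ct value {v} outside [0, 40] at ({cell}, {col})"
                    )

    @property
    def cells(self) -> list[str]:
        return list(self.values.index)

    @property
    def assays(self) -> list[str]:
        return list(self.values.columns)

    def numeric(self) -> pd.DataFrame:
        """Float view: UNDETERMINED -> 40.0, MISSING -> NaN."""
        def conv(v):
            if v == UNDETERMINED:
                return 40.0
            if v == MISSING:
                return math.nan
            return float(v)

        return self.values.map(conv).astype(float)

    def subset_cells(self, cells: Sequence[str]) -> "CtMatrix":
        return CtMatrix(self.values.loc[list(cells)])


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the published constants as defaults."""

    # NanoString cascade
    count_floor: float = 30.0          # counts below this are nullified
    min_total: int = 100               # min summed endogenous counts per cell
    min_cells: int = 3                 # min cells in which a probe is detected
    detect_at: float = 1.0             # detection level for probe prevalence
    norm_factor_bounds: tuple[float, float] = (1 / 3, 3.0)
    impute_ks: tuple[int, ...] = (5, 6, 7)
    log_base: float = 2.0
    # detection thresholds for reports
    detection_threshold: float = 30.0  # 5 for the sox10-mutant panel view
    sox10_detection_threshold: float = 5.0
    # TaqMan cascade
    taqman_floor: float = 4.8
    kan_ct_reject: float = 14.0
    rpl13_ct_reject: float = 24.0
    trim_top_frac: float = 0.05
    trim_bottom_frac: float = 0.05
    taqman_log_base: float = 2.0       # fold change per cycle; expressed in log10 units
    # clustering search
    replicates: int = 3
    merge_top_n: int = 4
    merge_acc_cutoff: float = 0.9
    umap_min_dist: float = 4.0
    umap_spread: float = 9.0
    umap_n_neighbors: int = 25
    grid_min_dist: tuple[float, ...] = (2.0, 4.0, 6.0)
    grid_spread: tuple[float, ...] = (6.0, 9.0, 12.0)
    grid_n_neighbors: tuple[int, ...] = (15, 25, 35)
    grid_resolutions: tuple[float, ...] = (0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6)
    seed: int = 0

    def __post_init__(self):
        for name in ("trim_top_frac", "trim_bottom_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.count_floor < 0 or self.taqman_floor < 0:
            raise ValidationError("floors must be nonnegative")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for k, v in list(raw.items()):
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage sub-seed from the master seed (logged)."""
        sub = int(np.random.SeedSequence([self.seed, abs(hash(stage)) % (2**31)])
                  .generate_state(1)[0] % (2**31))
        log.debug("stage %s sub-seed %d", stage, sub)
        return sub


# ---------------------------------------------------------------------------
# readers / writers


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_panel(path: str | Path) -> ProbePanel:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if not {"probe_id", "probe_class"} <= set(df.columns):
        raise ValidationError("panel file needs columns probe_id, probe_class")
    try:
        classes = {r.probe_id: ProbeClass(r.probe_class) for r in df.itertuples()}
    except ValueError as e:
        raise ValidationError(str(e)) from None
    if len(classes) != len(df):
        raise ValidationError("duplicate probe ids in panel")
    return ProbePanel(tuple(df["probe_id"]), classes)


def read_meta(path: str | Path) -> CellMeta:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"cell_id": str, "source": str})
    if "cell_id" not in df.columns:
        raise ValidationError("metadata file needs a cell_id column")
    if df["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell ids in metadata")
    df = df.set_index("cell_id")
    if "stage_hpf" not in df.columns:
        df["stage_hpf"] = np.nan
    return CellMeta(df)


def read_count_matrix(
    path: str | Path, panel_path: str | Path, meta_path: str | Path
) -> tuple[CountMatrix, ProbePanel, CellMeta]:
    """Read and cross-validate the raw-count triple (counts, panel, metadata)."""
    panel = read_panel(panel_path)
    meta = read_meta(meta_path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValidationError("duplicate cell ids in count matrix")
    extra_probes = set(df.columns) - set(panel.probe_ids)
    if extra_probes:
        raise ValidationError(f"probes absent from panel: {sorted(extra_probes)}")
    extra_cells = set(df.index) - set(meta.cell_ids)
    if extra_cells:
        raise ValidationError(f"cells absent from metadata: {sorted(extra_cells)}")
    m = CountMatrix(df, stage_tag="raw")
    return m, panel, meta.subset(m.cells)


def read_ct_matrix(path: str | Path, undetermined_token: str = "Undetermined") -> CtMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    df.index = df.index.astype(str)

    def conv(v):
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return MISSING
        if str(v).strip() == undetermined_token:
            return UNDETERMINED
        return float(v)

    return CtMatrix(df.map(conv))


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep=_sep_for(path), index_label="cell_id")


def write_panel(panel: ProbePanel, path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": panel.probe_ids,
         "probe_class": [panel.probe_class[p].value for p in panel.probe_ids]}
    ).to_csv(path, sep=_sep_for(path), index=False)


def write_meta(meta: CellMeta, path: str | Path) -> None:
    meta.table.to_csv(path, sep=_sep_for(path), index_label="cell_id")


def write_ct_matrix(ct: CtMatrix, path: str | Path,
                    undetermined_token: str = "Undetermined") -> None:
    def conv(v):
        if v == UNDETERMINED:
            return undetermined_token
        if v == MISSING:
            return ""
        return v

    ct.values.map(conv).to_csv(path, sep=_sep_for(path), index_label="cell_id")


def write_results(obj, path: str | Path) -> None:
    """Write any tabular pipeline product as delimited text, re-readably.

    Accepts a DataFrame (QC report, score table, co-expression summary,
    pseudotime table ...) or a mapping of column -> values.
    """
    if isinstance(obj, pd.DataFrame):
        df = obj
    elif isinstance(obj, Mapping):
        df = pd.DataFrame(obj)
    else:
        raise ValidationError(f"cannot serialize {type(obj).__name__} as a result table")
    df.to_csv(path, sep=_sep_for(path), index=not isinstance(df.index, pd.RangeIndex))


def read_results(path: str | Path, index: bool = False) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path), index_col=0 if index else None)


def read_rcc(path: str | Path) -> pd.Series:
    """Thin read-only adapter for vendor RCC files.

    Extracts the Code_Summary section (probe name -> count) of one lane.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.strip() == "<Code_Summary>")
        end = next(i for i, l in enumerate(lines) if l.strip() == "</Code_Summary>")
    except StopIteration:
        raise ValidationError("no Code_Summary section in RCC file") from None
    block = "\n".join(lines[start + 1 : end])
    df = pd.read_csv(io.StringIO(block))
    counts = pd.Series(df["Count"].astype(int).to_numpy(), index=df["Name"])
    if counts.index.duplicated().any():
        raise ValidationError("duplicate probe names in RCC Code_Summary")
    return counts
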