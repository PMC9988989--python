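"""Synthetic targeted-panel and qPCR fixtures with known ground truth.

The generator emulates the statistical structure the analysis assumes:
a ~45-probe panel; broadly multipotent progenitor populations that
co-express low levels of fate-specification genes for several fates
(mitfa + tfec + pax7b + phox2bb + ltk); differentiated pigment programs
(melanocyte, iridophore, xanthophore); purified control melanocytes and
iridophores; near-constant housekeeping and spike-in probes; overdispersed
negative-binomial molecule counts with class-specific Bernoulli dropout.

Counts for cell c, probe g are NegativeBinomial(mean = program[type(c)][g],
size = dispersion), then zeroed where the dropout mask fires.  Control
probes (housekeeping, spike-in, negative) are exempt from dropout so that
reference-class normalization stays well-posed.

Cycle-threshold fixtures map a latent abundance a through
Ct = clamp(ct_zero - log2(a + 1), 0, 40); a = 0 yields UNDETERMINED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    MISSING,
    UNDETERMINED,
    CellMeta,
    CountMatrix,
    CtMatrix,
    ProbeClass,
    ProbePanel,
    ValidationError,
)

# ---------------------------------------------------------------------------
# default panel and expression programs

HOUSEKEEPING_PROBE = "rpl13"
SPIKEIN_PROBE = "kanamycin"
NEGATIVE_PROBES = ("NEG_A", "NEG_B")

#: 42 endogenous genes: fate-specification, differentiation and early
#: neural-crest markers of the zebrafish pigment-cell system.
ENDOGENOUS_GENES = (
    "alx4a", "alx4b", "aox5", "crestin", "dlx2a", "ednrba", "erbb3b", "ets1",
    "foxd3", "foxo1a", "foxp4", "gch2", "her9", "id2a", "impdh1b", "kita",
    "ltk", "mbpa", "mitfa", "mlphb", "mycla", "myo5aa", "oca2", "pax3a",
    "pax7a", "pax7b", "phox2a", "phox2bb", "plp1a", "pmela", "pnp4a",
    "slc24a5", "snai1b", "snai2", "sox10", "sox9b", "tfap2a", "tfap2e",
    "tfec", "twist1a", "tyr", "tyrp1b",
)

#: Mean molecule counts per cell type.  Unlisted genes default to a small
#: baseline.  HMP programs co-express low levels of several fate genes;
#: differentiated programs are dominated by their effector genes.
PROGRAMS: dict[str, dict[str, float]] = {
    "eHMP": {
        "sox9b": 120, "tfap2e": 100, "tfap2a": 80, "snai1b": 100, "snai2": 80,
        "foxd3": 90, "her9": 80, "id2a": 90, "sox10": 100, "crestin": 100,
        "ets1": 60, "twist1a": 50, "pax3a": 50,
        # low-level multipotent co-expression of fate genes
        "ltk": 8, "mitfa": 8, "tfec": 8, "pax7b": 8, "phox2bb": 8,
    },
    "ltHMP": {
        "ltk": 150, "sox10": 120, "tfec": 60, "her9": 60, "impdh1b": 60,
        "id2a": 60, "foxd3": 40, "snai1b": 30,
        "mitfa": 60, "pax7b": 40, "phox2bb": 40, "mbpa": 15,
    },
    "M": {
        "mitfa": 150, "mlphb": 300, "oca2": 250, "pmela": 400, "slc24a5": 300,
        "tyrp1b": 350, "tyr": 200, "kita": 80, "myo5aa": 60, "her9": 40,
        "sox10": 30,
    },
    # differentiated iridophores retain ltk/tfec/foxd3 only at low levels
    "I": {
        "ltk": 40, "tfec": 60, "pnp4a": 400, "alx4a": 150, "alx4b": 120,
        "impdh1b": 200, "id2a": 120, "her9": 60, "sox10": 60, "foxd3": 30,
    },
    "X": {
        "pax7a": 250, "pax7b": 200, "gch2": 300, "aox5": 250, "mitfa": 40,
        "impdh1b": 60, "her9": 40, "sox10": 30,
    },
}

BASELINE_MEAN = 2.0  # leaky transcription for unlisted endogenous genes

#: True differentiation topology of the default cohort.
DEFAULT_LINEAGES = {"M": ("eHMP", "ltHMP", "M"), "I": ("eHMP", "ltHMP", "I")}
STAGE_INDEX = {"eHMP": 0, "ltHMP": 1, "M": 2, "I": 2, "X": 2}


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    n_cells: int
    source: str                    # CellSource value
    program: Mapping[str, float]   # probe -> mean molecule count
    true_type: str | None = None   # defaults to name

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if any(v < 0 for v in self.program.values()):
            raise ValidationError("program means must be >= 0")


@dataclass(frozen=True)
class SynthSpec:
    cell_types: tuple[CellTypeSpec, ...]
    dispersion: float = 8.0
    dropout_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            "endogenous": 0.2, "housekeeping": 0.0, "spike_in": 0.0, "negative": 0.0,
        }
    )
    housekeeping_mean: float = 1500.0
    spikein_mean: float = 4000.0
    negative_mean: float = 2.0
    ct_zero: float = 36.0
    ct_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not self.cell_types:
            raise ValidationError("empty synthetic spec")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        for cls, p in self.dropout_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"dropout_prob[{cls}] must be in [0, 1]")


@dataclass
class GroundTruth:
    true_type: pd.Series                 # cell_id -> planted type
    lineages: Mapping[str, tuple[str, ...]]
    stage_index: Mapping[str, int]
    dropout_mask: pd.DataFrame | None = None  # True where dropout fired


def default_nanostring_spec(seed: int = 0) -> SynthSpec:
    """Default cohort mirroring the study composition: 444 regular WT cells,
    108 tail cells, 25 control iridophores, 19 control melanocytes (~600
    cells, five planted expression programs)."""
    cts = (
        CellTypeSpec("eHMP", 104, "regular", PROGRAMS["eHMP"]),
        CellTypeSpec("eHMP_tail", 108, "tail", PROGRAMS["eHMP"], true_type="eHMP"),
        CellTypeSpec("ltHMP", 120, "regular", PROGRAMS["ltHMP"]),
        CellTypeSpec("M", 90, "regular", PROGRAMS["M"]),
        CellTypeSpec("I", 70, "regular", PROGRAMS["I"]),
        CellTypeSpec("X", 60, "regular", PROGRAMS["X"]),
        CellTypeSpec("contM", 19, "control_mel", PROGRAMS["M"], true_type="M"),
        CellTypeSpec("contI", 25, "control_iri", PROGRAMS["I"], true_type="I"),
    )
    return SynthSpec(cell_types=cts, seed=seed)


TAQMAN_GENES = (
    "elavl3", "ltk", "mbpa", "mitfa", "neurog1", "pax7b", "phox2bb", "pnp4a",
    "snai1b", "sox10", "sox9b", "tyrp1b", "xdh",
)

#: Extra program entries for assays absent from the count panel.
_TAQMAN_EXTRA = {
    "eHMP": {"neurog1": 8, "elavl3": 5, "xdh": 2},
    "ltHMP": {"neurog1": 25, "elavl3": 10, "xdh": 2},
    "M": {"neurog1": 0, "elavl3": 0, "xdh": 0},
    "I": {"neurog1": 0, "elavl3": 0, "xdh": 0},
    "X": {"neurog1": 0, "elavl3": 0, "xdh": 300},
}


def default_taqman_spec(seed: int = 0) -> SynthSpec:
    """159 WT cells at 30 hpf profiled for 13 genes + kanamycin + rpl13."""
    cts = []
    for name, n in (("eHMP", 40), ("ltHMP", 40), ("M", 30), ("I", 25), ("X", 24)):
        prog = {g: PROGRAMS[name].get(g, BASELINE_MEAN) for g in TAQMAN_GENES}
        prog.update(_TAQMAN_EXTRA[name])
        cts.append(CellTypeSpec(name, n, "regular", prog))
    return SynthSpec(cell_types=tuple(cts), seed=seed)


def default_panel() -> ProbePanel:
    ids = ENDOGENOUS_GENES + (HOUSEKEEPING_PROBE, SPIKEIN_PROBE) + NEGATIVE_PROBES
    classes: dict[str, ProbeClass] = {g: ProbeClass.ENDOGENOUS for g in ENDOGENOUS_GENES}
    classes[HOUSEKEEPING_PROBE] = ProbeClass.HOUSEKEEPING
    classes[SPIKEIN_PROBE] = ProbeClass.SPIKE_IN
    for p in NEGATIVE_PROBES:
        classes[p] = ProbeClass.NEGATIVE
    return ProbePanel(ids, classes)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial with mean/size parametrization; mean 0 -> 0."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = size_param / (size_param + mean[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


def generate_nanostring(
    spec: SynthSpec, panel: ProbePanel | None = None
) -> tuple[CountMatrix, ProbePanel, CellMeta, GroundTruth]:
    """Draw a raw count matrix, panel, metadata and ground truth from a spec."""
    if panel is None:
        panel = default_panel()
    rng = np.random.default_rng(spec.seed)

    cell_ids, sources, true_types = [], [], []
    for ct in spec.cell_types:
        for i in range(ct.n_cells):
            cell_ids.append(f"{ct.name}_{i:04d}")
            sources.append(ct.source)
            true_types.append(ct.true_type or ct.name)

    n_cells, probes = len(cell_ids), list(panel.probe_ids)
    counts = np.zeros((n_cells, len(probes)), dtype=np.int64)
    dropout = np.zeros((n_cells, len(probes)), dtype=bool)

    class_means = {
        ProbeClass.HOUSEKEEPING: spec.housekeeping_mean,
        ProbeClass.SPIKE_IN: spec.spikein_mean,
        ProbeClass.NEGATIVE: spec.negative_mean,
    }
    row = 0
    for ct in spec.cell_types:
        if ct.n_cells == 0:
            continue
        means = np.empty(len(probes))
        for j, g in enumerate(probes):
            cls = panel.probe_class[g]
            if cls is ProbeClass.ENDOGENOUS:
                means[j] = ct.program.get(g, BASELINE_MEAN)
            else:
                means[j] = class_means[cls]
        block = np.vstack(
            [_nb_draw(rng, means, spec.dispersion) for _ in range(ct.n_cells)]
        )
        mask = np.zeros_like(block, dtype=bool)
        for j, g in enumerate(probes):
            p = spec.dropout_prob.get(panel.probe_class[g].value, 0.0)
            if p > 0:
                mask[:, j] = rng.random(ct.n_cells) < p
        block[mask] = 0
        counts[row : row + ct.n_cells] = block
        dropout[row : row + ct.n_cells] = mask
        row += ct.n_cells

    values = pd.DataFrame(counts, index=cell_ids, columns=probes)
    meta = CellMeta(
        pd.DataFrame({"source": sources, "stage_hpf": np.nan}, index=cell_ids)
    )
    truth = GroundTruth(
        true_type=pd.Series(true_types, index=cell_ids),
        lineages=DEFAULT_LINEAGES,
        stage_index=STAGE_INDEX,
        dropout_mask=pd.DataFrame(dropout, index=cell_ids, columns=probes),
    )
    if all(
        sum(ct.program.values()) == 0 and spec.dropout_prob.get("endogenous", 0) == 1
        for ct in spec.cell_types
        if ct.source in ("control_mel", "control_iri")
    ) and any(ct.source in ("control_mel", "control_iri") for ct in spec.cell_types):
        import warnings

        warnings.warn("control cells carry no signal; qual anchoring will be degenerate")
    return CountMatrix(values, stage_tag="raw"), panel, meta, truth


def generate_taqman(spec: SynthSpec) -> tuple[CtMatrix, GroundTruth]:
    """Draw a Ct matrix: Ct = clamp(ct_zero - log2(a + 1), 0, 40), a = 0
    yields UNDETERMINED; the kanamycin spike-in is near-constant."""
    rng = np.random.default_rng(spec.seed)
    assays = list(TAQMAN_GENES) + [SPIKEIN_PROBE, HOUSEKEEPING_PROBE]

    cell_ids, true_types, rows = [], [], []
    for ct in spec.cell_types:
        for i in range(ct.n_cells):
            cell_ids.append(f"{ct.name}_tq{i:03d}")
            true_types.append(ct.true_type or ct.name)
            entries = []
            for g in assays:
                if g == SPIKEIN_PROBE:
                    a = spec.spikein_mean
                elif g == HOUSEKEEPING_PROBE:
                    a = float(_nb_draw(rng, np.array([spec.housekeeping_mean]),
                                       spec.dispersion)[0])
                else:
                    mean = ct.program.get(g, 0.0)
                    a = float(_nb_draw(rng, np.array([mean]), spec.dispersion)[0])
                    if rng.random() < spec.dropout_prob.get("endogenous", 0.0):
                        a = 0.0
                if a <= 0:
                    entries.append(UNDETERMINED)
                else:
                    ct_val = spec.ct_zero - np.log2(a + 1.0)
                    ct_val += rng.normal(0.0, spec.ct_noise_sd)
                    entries.append(float(np.clip(ct_val, 0.0, 40.0)))
            rows.append(entries)

    values = pd.DataFrame(rows, index=cell_ids, columns=assays, dtype=object)
    truth = GroundTruth(
        true_type=pd.Series(true_types, index=cell_ids),
        lineages=DEFAULT_LINEAGES,
        stage_index=STAGE_INDEX,
    )
    return CtMatrix(values), truth
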