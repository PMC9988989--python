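"""Published fate-mapping and injection count tables used by the reports.

These are the printed per-cell-type counts from the reporter fate-mapping
experiments (GFP expression driven by the ltk or sox10 regulatory regions)
and from the constitutively-active-Ltk injection series; the package
recomputes the published percentages and the 2x2 chi-square from them.
"""

from __future__ import annotations

FATE_CLASSES = (
    "melanocyte", "xanthophore", "iridophore", "glia", "drg_neuron",
    "sympathetic_neuron", "enteric_neuron", "cartilage",
)

#: NCC-derivative counts among GFP-labelled cells, by reporter construct.
LTK_REPORTER_FATES = {
    "melanocyte": 7, "xanthophore": 86, "iridophore": 64, "glia": 10,
    "drg_neuron": 9, "sympathetic_neuron": 0, "enteric_neuron": 7,
    "cartilage": 0,
}  # total 183

SOX10_REPORTER_FATES = {
    "melanocyte": 222, "xanthophore": 625, "iridophore": 8, "glia": 27,
    "drg_neuron": 22, "sympathetic_neuron": 0, "enteric_neuron": 14,
    "cartilage": 7,
}  # total 925

#: Injection series: constitutively active NPM-Ltk vs its dead-kinase (DK)
#: control.  "observed" = embryos scored; "gfp_embryos" = embryos with
#: GFP-positive cells; "gfp_melanocytes" = GFP-positive melanocytes among
#: GFP-positive embryos (running text; the printed table splits the active
#: construct by presence of ectopic iridophores).
INJECTION_DK = {"observed": 215, "gfp_embryos": 50, "gfp_melanocytes": 11}
INJECTION_ACTIVE = {"observed": 237, "gfp_embryos": 53, "gfp_melanocytes": 1}


def printed_percentage(count: int, total: int) -> int:
    """Percentage as printed in the tables: rounded to the nearest integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total)


def melanocyte_contingency() -> list[list[int]]:
    """2x2 table of GFP-positive melanocyte occurrence: rows = construct
    (DK control, active), columns = (melanocytes, GFP-embryos without)."""
    return [
        [INJECTION_DK["gfp_melanocytes"],
         INJECTION_DK["gfp_embryos"] - INJECTION_DK["gfp_melanocytes"]],
        [INJECTION_ACTIVE["gfp_melanocytes"],
         INJECTION_ACTIVE["gfp_embryos"] - INJECTION_ACTIVE["gfp_melanocytes"]],
    ]
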