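#!/usr/bin/env python
"""Multipotency co-expression summaries and published worked examples.

From the raw simulated counts: the fraction of ltk-detectable progenitor
cells co-expressing other fate-specification genes (detection at >= 30
counts, and at the permissive >= 5-count threshold used for low-expression
panels).  From the published tables: reporter fate percentages and the
2x2 chi-square on GFP-positive melanocyte occurrence.
"""

import argparse
from pathlib import Path

import pandas as pd

import crestscope as cs
from crestscope import panel_io
from crestscope.coexpr_report import binarize, chi2_2x2, coexpression_fraction
from crestscope.datasets import (
    INJECTION_DK,
    LTK_REPORTER_FATES,
    SOX10_REPORTER_FATES,
    melanocyte_contingency,
    printed_percentage,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/simulated"))
    ap.add_argument("--out", type=Path, default=Path("results/coexpression"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    m, panel, meta = panel_io.read_count_matrix(
        args.sim / "counts.csv", args.sim / "panel.csv", args.sim / "meta.csv"
    )
    rows = []
    for thr in (30, 5):
        det = binarize(m, thr)
        for anchor, others in [
            ("ltk", ["mitfa", "tfec", "pax7b", "phox2bb"]),
            ("phox2bb", ["ltk", "mitfa", "pax7b"]),
        ]:
            s = coexpression_fraction(det, anchor, others)
            rows.append({"threshold": thr, "anchor": anchor,
                         "others": "+".join(others), "n_anchor": s.n_anchor,
                         "n_coexpressing": s.n_anchor_and_set,
                         "fraction": round(s.fraction, 4)})
            print(f"threshold {thr}: {s.n_anchor_and_set}/{s.n_anchor} "
                  f"({100 * s.fraction:.0f}%) {anchor}+ cells co-express "
                  f"one of {'/'.join(others)}")
    panel_io.write_results(pd.DataFrame(rows), args.out / "coexpression.csv")

    ltk_total = sum(LTK_REPORTER_FATES.values())
    sox10_total = sum(SOX10_REPORTER_FATES.values())
    chi2, p = chi2_2x2(melanocyte_contingency())
    print(f"ltk reporter: iridophores {LTK_REPORTER_FATES['iridophore']}/{ltk_total} "
          f"= {printed_percentage(LTK_REPORTER_FATES['iridophore'], ltk_total)}%")
    print(f"sox10 reporter: xanthophores {SOX10_REPORTER_FATES['xanthophore']}/{sox10_total} "
          f"= {printed_percentage(SOX10_REPORTER_FATES['xanthophore'], sox10_total)}%")
    print(f"DK injections: GFP-positive embryos {INJECTION_DK['gfp_embryos']}/"
          f"{INJECTION_DK['observed']} = "
          f"{printed_percentage(INJECTION_DK['gfp_embryos'], INJECTION_DK['observed'])}%")
    print(f"chi-square on GFP-positive melanocytes: chi2 = {chi2:.3f}, p = {p:.5f}")
    panel_io.write_results(
        pd.DataFrame([{"test": "gfp_melanocytes_dk_vs_active",
                       "chi2": chi2, "p": p}]),
        args.out / "chi2.csv",
    )


if __name__ == "__main__":
    main()
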