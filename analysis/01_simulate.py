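#!/usr/bin/env python
"""Generate the default synthetic study cohort.

Writes a ~600-cell NanoString-style count matrix (five planted expression
programs, purified control melanocytes/iridophores, constant housekeeping
and spike-in probes, 20% endogenous dropout) plus a 159-cell TaqMan Ct
matrix, with their ground truth, under results/simulated/.
"""

import argparse
from pathlib import Path

import crestscope as cs
from crestscope import panel_io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/simulated"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    m, panel, meta, truth = cs.generate_nanostring(cs.default_nanostring_spec(args.seed))
    panel_io.write_count_matrix(m, args.out / "counts.csv")
    panel_io.write_panel(panel, args.out / "panel.csv")
    panel_io.write_meta(meta, args.out / "meta.csv")
    truth.true_type.rename("true_type").to_csv(args.out / "truth_nanostring.csv",
                                               index_label="cell_id")
    by_source = meta.table["source"].value_counts().to_dict()
    print(f"nanostring: {m.shape[0]} cells x {m.shape[1]} probes; sources {by_source}")

    ct, ct_truth = cs.generate_taqman(cs.default_taqman_spec(args.seed))
    panel_io.write_ct_matrix(ct, args.out / "ct.csv")
    ct_truth.true_type.rename("true_type").to_csv(args.out / "truth_taqman.csv",
                                                  index_label="cell_id")
    print(f"taqman: {len(ct.cells)} cells x {len(ct.assays)} assays")


if __name__ == "__main__":
    main()
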