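#!/usr/bin/env python
"""Differential methylation: centered heatmap matrix, summaries, deltas.

Consumes the MethScore table from analysis/02 and the sample design from
analysis/01; writes the row-centered matrix (heatmap-ready), per-condition
boxplot summaries, and stress-versus-control deltas with Welch p-values.
Reports which sites respond to stress.
"""

from pathlib import Path

import pandas as pd

from nmquant.diffmeth import (
    ConditionDesign,
    delta_vs_control,
    row_center,
    summarize_replicates,
)

OUT = Path("results")


def main() -> None:
    scores = pd.read_csv(OUT / "methscores.tsv", sep="\t", index_col=[0, 1])
    design = ConditionDesign.from_table(OUT / "simulated" / "design.tsv")

    row_center(scores).to_csv(OUT / "centered.tsv", sep="\t")
    summarize_replicates(scores, design).to_csv(
        OUT / "summary.tsv", sep="\t", index=False
    )
    deltas = delta_vs_control(scores, design, with_tests=True)
    deltas.to_csv(OUT / "deltas.tsv", sep="\t", index=False)

    responsive = deltas[(deltas["delta"].abs() > 0.2) & (deltas["p_welch"] < 0.05)]
    print(f"{len(deltas)} site-condition deltas; "
          f"{len(responsive)} with |delta| > 0.2 and Welch p < 0.05:")
    for _, r in responsive.sort_values("delta", ascending=False).iterrows():
        print(f"  {r.ref_id}:{int(r.position)}  delta={r.delta:+.3f}  p={r.p_welch:.2g}")
    print(f"wrote centered.tsv, summary.tsv, deltas.tsv under {OUT}/")


if __name__ == "__main__":
    main()
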