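#!/usr/bin/env python
"""TaqMan-stage validation: reference selection and ddCt quantification.

Picks the rank-invariant endogenous reference from the normalized discovery
counts (reported; quantification uses the named spike-in + endogenous
reference pair), simulates duplicate-well qPCR for the candidate panel in
both cohorts, and writes per-cohort relative expression plus a group-level
fold-change summary shaped like a differential-expression table.
"""

import argparse
from pathlib import Path

import pandas as pd

from mirsig import io as mio
from mirsig.nanostring import background_zero, global_mean_normalize, lane_normalize
from mirsig.qpcr import ddct_fold_change, relative_ct, select_rank_invariant
from mirsig.study import quantify_cohorts
from mirsig.synthetic import ENDOGENOUS_REFERENCE, SPIKE_IN, SimulationConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--candidates", type=Path,
                    default=Path("results/discovery/candidate_table.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results/validation"))
    args = ap.parse_args()

    counts = mio.read_count_matrix(args.indir / "nanostring_counts.tsv")
    sheet = mio.read_sample_sheet(args.indir / "sample_sheet.csv")
    cand = pd.read_csv(args.candidates, sep="\t", index_col=0)

    normed = background_zero(global_mean_normalize(lane_normalize(counts)))
    picked = select_rank_invariant(normed)
    print(f"most rank-invariant endogenous assay in the discovery data: {picked}")
    print(f"quantifying against geometric mean of {SPIKE_IN} (spike-in) "
          f"and {ENDOGENOUS_REFERENCE} (endogenous)")

    cfg = SimulationConfig(seed=args.seed)
    panel = sorted(set(cand.index) | {ENDOGENOUS_REFERENCE}) + [SPIKE_IN]
    quant = quantify_cohorts(cfg, sheet, panel)

    args.outdir.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for cohort, (rel, _) in quant.items():
        mio.write_relative_expression(
            rel, args.outdir / f"relative_expression_cohort{cohort}.tsv"
        )
        summaries[f"cohort{cohort}"] = rel.summary[["fold_change", "p_value"]]
    summary = pd.concat(summaries, axis=1)
    summary.to_csv(args.outdir / "group_fold_changes.tsv", sep="\t")

    print("\nNC/AD fold changes (down-regulated in AD shown > 1):")
    with pd.option_context("display.float_format", "{:.3f}".format):
        print(summary)


if __name__ == "__main__":
    main()
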