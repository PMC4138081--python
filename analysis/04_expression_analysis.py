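#!/usr/bin/env python
"""Expression analytics over the accepted matures: guide/star roles and
the 50-read retention floor, RPM, phylostratum assignment against the
reference catalog, the miRPAI developmental curve, expression stability
(CV) and the 5x / one-fifth specificity screens.

Runs the discovery stage in memory (deterministic) to recover arm-level
counts, then writes the expression tables under --outdir.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from mirforge import expression as expr
from mirforge import formats_io as fio
from mirforge.pipeline import RunConfig, run_pipeline


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--workdir", type=Path, default=Path("scratch/study"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    rundir = args.workdir / "pipeline"
    report = run_pipeline(RunConfig(seed=args.seed, outdir=str(rundir),
                                    write_fastq=False))
    expr_stage = report["stages"]["express"]
    rpm = fio.read_expression_table(rundir / "rpm.tsv")

    args.outdir.mkdir(parents=True, exist_ok=True)
    with open(args.outdir / "04_mirpai_curve.tsv", "w") as fh:
        fh.write("stage\tmirpai\n")
        for stage, value in expr_stage["mirpai"].items():
            fh.write(f"{stage}\t{value:.4f}\n")
    cvs = {}
    for mid in rpm.index:
        v = rpm.loc[mid]
        if v.mean() > 0:
            cvs[mid] = expr.coefficient_of_variation(v.to_numpy())
    pd.Series(cvs, name="cv").rename_axis("mature_id").round(4).to_csv(
        args.outdir / "04_expression_cv.tsv", sep="\t")

    curve = expr_stage["mirpai"]
    peak = max(curve, key=curve.get)
    print(f"{expr_stage['n_matures']} matures from accepted precursors; "
          f"{expr_stage['n_expression_set']} kept for expression analysis "
          f"(>= 50 reads)")
    print(f"miRPAI peaks at {peak} "
          f"({curve[peak]:.2f}): the developmental profile is youngest "
          f"around mid-development, as designed into the simulator")
    print(f"mean expression CV {expr_stage['mean_cv']:.2f}; "
          f"{expr_stage['specific_high']} specifically-high and "
          f"{expr_stage['specific_low']} specifically-low calls")
    return 0


if __name__ == "__main__":
    sys.exit(main())
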