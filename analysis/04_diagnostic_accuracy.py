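"""Threshold-based diagnostic accuracy.

Dichotomises the updated regression models at the 2.5% low-risk and
10%/30% high-risk cut-offs, and the two fixture point scores at their
proposed cut-offs (score <= 5 low / > 8 high; score >= 3 positive),
reporting sensitivity, specificity and likelihood ratios with 95% CIs
under results/04_accuracy/.
"""

import argparse
import importlib.resources as ir
from pathlib import Path

import pandas as pd

from cpmval.reporting import RunConfig, run

ROOT = Path(__file__).resolve().parents[1]
DATA = ir.files("cpmval") / "data"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=8211)
    args = ap.parse_args()
    out = ROOT / "results" / "04_accuracy"
    run(
        RunConfig(
            models=[
                str(DATA / m)
                for m in ("feverkids_like.json", "sbi_model_like.json", "sbi_score_like.json", "paws_like.json")
            ],
            preset="ernie2",
            n=args.n,
            analysis="all",
            risk_cutoffs=(0.025, 0.10, 0.30),
            outdir=str(out),
            seed=args.seed,
        )
    )
    acc = pd.read_csv(out / "accuracy.csv", keep_default_na=False)  # keep the literal "NA"
    cols = ["model", "category", "cutoff", "sensitivity", "specificity", "lr_pos", "lr_neg"]
    print("diagnostic accuracy at the clinical cut-offs (LR 'NA' = undefined):")
    print(acc[cols].to_string(index=False))


if __name__ == "__main__":
    main()
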