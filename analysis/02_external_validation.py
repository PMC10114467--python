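"""External validation of the fixture prediction models.

Applies the illustrative multinomial/binomial models, with their original
(deliberately un-updated) coefficients, to a fresh synthetic cohort:
conditional pairwise C-statistics, per-category calibration intercepts
and slopes, and flexible calibration curves, written to
results/02_validation/.
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
    out = ROOT / "results" / "02_validation"
    run(
        RunConfig(
            models=[str(DATA / m) for m in ("feverkids_like.json", "craig_like.json", "sbi_model_like.json")],
            preset="ernie2",
            n=args.n,
            analysis="validate",
            outdir=str(out),
            seed=args.seed,
        )
    )
    cstat = pd.read_csv(out / "cstat.csv")
    print("conditional C-statistics of the original fixture models:")
    print(cstat.to_string(index=False))
    cal = pd.read_csv(out / "calibration.csv")
    print("\ncalibration (intercept 0 / slope 1 = perfect):")
    print(cal[["model", "contrast", "intercept", "slope"]].to_string(index=False))


if __name__ == "__main__":
    main()
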