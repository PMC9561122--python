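#!/usr/bin/env python
"""Univariable MR of each exposure on the outcome, all seven estimators.

For each exposure the instrument set from 02 is harmonized with the outcome
and pushed through IVW plus the six robust estimators; consistent estimates
across methods are the triangulation evidence for a causal effect.  Odds
ratios are reported since the outcome is binary.  Writes one row per
method x exposure to results/univariable_mr.tsv.
"""

from pathlib import Path

import pandas as pd

from mrtri import harmonize, read_sumstats
from mrtri.univariable import UNIVARIABLE_METHODS

BASE = Path(__file__).resolve().parent.parent / "results"
SYN = BASE / "synthetic"
SEED = 20_241


def main() -> None:
    outcome = read_sumstats(SYN / "t2d.tsv")
    rows = []
    for trait in ("wc", "liverfat"):
        table = read_sumstats(SYN / f"{trait}.tsv")
        snps = pd.read_csv(BASE / f"instruments_{trait}.tsv", sep="\t")["SNP"]
        h = harmonize([table[table["SNP"].isin(snps)]], outcome)
        for name, fn in UNIVARIABLE_METHODS.items():
            if name in ("weighted_median", "weighted_mode"):
                est = fn(h, n_boot=1000, seed=SEED)
            elif name == "mr_presso":
                est = fn(h, n_sim=1000, seed=SEED)
            else:
                est = fn(h)
            rows.append(est.to_row())
            print(f"{trait} -> t2d  {est.method:24s} "
                  f"log-odds {est.estimate:+.3f} (se {est.se:.3f}) "
                  f"OR {est.odds_ratio:.2f}")
    pd.DataFrame(rows).to_csv(BASE / "univariable_mr.tsv", sep="\t",
                              index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
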