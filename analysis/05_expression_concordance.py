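#!/usr/bin/env python
"""Differential expression and methylation-expression concordance.

Two-sample pooled t tests with linear-scale fold changes on the matched
10v10 log2 expression matrix, restricted to the differentially
methylated genes, then the concordance join: each gene's methylation
direction (HYPER/HYPO) against its expression direction (UP/DOWN), with
the canonical inverse relation flagged.  Writes de.tsv and
concordance.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from wsmeth.array_io import read_sample_sheet, read_table, write_table
from wsmeth.expression import concordance_table, differential_expression

BASE = Path(__file__).resolve().parent.parent / "results"
FIX = BASE / "synthetic"


def main() -> None:
    expr = pd.read_csv(FIX / "expr.tsv", sep="\t", index_col=0)
    groups = read_sample_sheet(FIX / "expr_samples.tsv")

    dmps = read_table(BASE / "dmps.tsv")
    sig = dmps[dmps["significant"]]
    directions: dict = {}
    for _, row in sig.iterrows():
        for g in str(row["genes"]).split(";"):
            if g and g.lower() != "nan":
                directions[g] = row["direction"]
    dmrs = read_table(BASE / "dmrs.tsv")
    for _, row in dmrs.iterrows():
        if row["direction"] in ("HYPER", "HYPO"):
            for g in str(row["genes"]).split(";"):
                if g:
                    directions[g] = row["direction"]

    de = differential_expression(expr, groups, genes=sorted(directions), scale="auto")
    write_table(de, BASE / "de.tsv")
    table = concordance_table(directions, de, de_p=0.05)
    write_table(table, BASE / "concordance.tsv")

    n_sig = int((de["p_value"] < 0.05).sum()) if len(de) else 0
    print(f"{len(de)} differentially methylated genes tested for expression; "
          f"{n_sig} differentially expressed at p < 0.05")
    if len(table):
        n_conc = int((table["de_significant"] & table["concordant"]).sum())
        print(f"{n_conc}/{n_sig} DE-significant genes show the inverse "
              f"methylation-expression relation")


if __name__ == "__main__":
    main()
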