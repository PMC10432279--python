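#!/usr/bin/env python
"""Classify pairwise relatedness in the simulated community.

Reads the EIGENSTRAT files written by 01_simulate_community.py (round-
tripping through the on-disk format on purpose), applies the coverage
filter, estimates the background mismatch rate, classifies every pair's
degree by binomial posterior with parent-offspring/sibling subcalls, and
scores the calls against pedigree truth. Writes results/relatedness.tsv
and results/degree_confusion.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from paleokin import read_eigenstrat, read_metadata
from paleokin.kinship import relatedness_table
from paleokin.pedigree import degree_confusion
from paleokin.qc import filter_low_coverage

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    panel, matrix, _ = read_eigenstrat(
        args.sim / "sim.geno", args.sim / "sim.snp", args.sim / "sim.ind"
    )
    records = read_metadata(args.sim / "sim_metadata.tsv")
    retained, counts = filter_low_coverage(matrix, min_sites=min(20_000, matrix.n_sites))
    print(f"coverage filter: {len(retained)}/{matrix.n_individuals} individuals retained")
    matrix = matrix.subset(retained)

    table = relatedness_table(matrix, panel, records)
    bg = table.attrs["background"]
    print(f"background PMR p0 = {bg.p0:.4f} from {bg.n_pairs_used} pairs "
          f"({bg.iterations} trim iterations)")

    truth = pd.read_csv(args.sim / "sim_true_degrees.tsv", sep="\t", keep_default_na=False)
    confusion = degree_confusion(table, truth)
    print("degree confusion (rows = truth, columns = called):")
    print(confusion.to_string())
    n_po = (table["po_sib_call"] == "PARENT_OFFSPRING").sum()
    n_sib = (table["po_sib_call"] == "SIBLING").sum()
    print(f"first-degree subcalls: {n_po} parent-offspring, {n_sib} sibling")

    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "relatedness.tsv", sep="\t", index=False)
    confusion.to_csv(args.out / "degree_confusion.tsv", sep="\t")
    print(f"wrote {args.out / 'relatedness.tsv'}")


if __name__ == "__main__":
    main()
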