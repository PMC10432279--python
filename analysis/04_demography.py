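#!/usr/bin/env python
"""Demographic and spatial statistics of the community.

Computes exact binomial sex-ratio confidence intervals (for the simulated
cohort and for the published burial counts 27:6 adult and 19:18 subadult
offspring), the occupation duration implied by the reproductive
generations, the father/subadult-son grave-distance permutation test, the
Mantel test of spatial vs genetic distance, and the uniparental-haplogroup
summary. Writes results/demography.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from paleokin import read_metadata
from paleokin.demography import proportion_ci
from paleokin.pedigree import import_pedigree
from paleokin.pipeline import demography_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    parser.add_argument("--relatedness", type=Path, default=ROOT / "results" / "relatedness.tsv")
    parser.add_argument("--pedigrees", type=Path, default=ROOT / "results" / "pedigrees")
    parser.add_argument("--seed", type=int, default=2026)
    parser.add_argument("--perms", type=int, default=9_999)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "demography.json")
    args = parser.parse_args()

    records = read_metadata(args.sim / "sim_metadata.tsv")
    table = pd.read_csv(args.relatedness, sep="\t", keep_default_na=False)
    graphs = [import_pedigree(p) for p in sorted(args.pedigrees.glob("pedigree_*.json"))]

    report = demography_report(records, table, graphs, n_perm=args.perms, seed=args.seed)

    # the published burial counts as a fixed reference computation
    adult = proportion_ci(27, 33)
    sub = proportion_ci(19, 37)
    report["reference_adult_sex_ratio"] = {
        "males": 27, "n": 33, "ratio": adult.ratio,
        "ci_lower_pct": round(100 * adult.lower, 1),
        "ci_upper_pct": round(100 * adult.upper, 1),
    }
    report["reference_subadult_sex_ratio"] = {
        "males": 19, "n": 37, "ratio": sub.ratio,
        "ci_lower_pct": round(100 * sub.lower, 1),
        "ci_upper_pct": round(100 * sub.upper, 1),
    }

    for key in ("adult_sex_ratio", "subadult_sex_ratio", "reference_adult_sex_ratio",
                "reference_subadult_sex_ratio"):
        if key in report:
            r = report[key]
            print(f"{key}: {r['males']}/{r['n']} male, ratio {r['ratio']}, "
                  f"CI {r['ci_lower_pct']}-{r['ci_upper_pct']}%")
    if "father_subadult_son_distance" in report:
        d = report["father_subadult_son_distance"]
        print(f"father-subadult-son distance: mean {d['mean_distance']:.2f} m over "
              f"{d['n_pairs']} pairs, permutation p = {d['p_value']:.4f}")
    if "mantel_spatial_vs_genetic" in report:
        m = report["mantel_spatial_vs_genetic"]
        print(f"Mantel spatial vs genetic: r = {m['r']:.3f}, p = {m['p']:.4f} (n = {m['n']})")
    h = report["haplogroups"]
    print(f"haplogroups: {h['n_mt_haplogroups']} mt among {h['n_individuals_mt']}, "
          f"{h['n_y_haplogroups']} Y among {h['n_individuals_y']}; "
          f"modal mt transmission depth {h['modal_mt_transmission_depth']}")
    if "occupation" in report:
        o = report["occupation"]
        print(f"occupation: {o['max_generations']} generations -> "
              f"{o['reproductive_generations']} reproductive -> "
              f"{o['duration_years'][0]:.0f}-{o['duration_years'][1]:.0f} years")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=2, default=str) + "\n")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
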