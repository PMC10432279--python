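"""Reproducible simulation experiments that exercise the pipeline
end-to-end and score it against ground truth.

Each experiment generates its own data with the community generator at the
study's default conditions (pseudo-haploid calls, Poisson coverage,
symmetric read error), runs the relevant analysis and returns plain-dict
metrics. They back both the validation suite and the result-reproduction
script, and are deliberately sized to run on a single CPU in minutes.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import ADULT, XX, XY, PseudoHaploidMatrix
from .demography import category_distance_test, mantel_test, proportion_ci
from .kinship import (
    PARENT_OFFSPRING,
    SIBLING,
    classify_po_vs_sibling,
    estimate_background,
    pairwise_mismatch,
    relatedness_table,
    windowed_pmr,
)
from .pedigree import build_pedigrees, compare_to_truth
from .simulate import (
    PedNode,
    SimulationConfig,
    TruePedigree,
    drop_genes,
    draw_founder_frequencies,
    make_panel,
    sample_pseudohaploid,
    simulate_dataset_sized,
    true_degree_table,
)


def _merge_truth(table: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    key = lambda df: df.apply(lambda r: frozenset((r["id1"], r["id2"])), axis=1)
    return table.assign(_k=key(table)).merge(
        truth.assign(_k=key(truth))[["_k", "true_degree"]], on="_k"
    )


def degree_recovery(
    seed: int,
    n_snps: int = 100_000,
    coverage: float = 1.0,
    error_rate: float = 0.01,
    min_sampled: int = 18,
    max_sampled: int = 30,
) -> dict:
    """Classify all pairs of a ~20-individual community and score the
    first/second-degree calls against pedigree truth."""
    cfg = SimulationConfig(
        seed=seed, n_generations=4, mean_offspring=3.0, n_snps=n_snps,
        coverage=coverage, error_rate=error_rate,
    )
    ds = simulate_dataset_sized(cfg, min_sampled, max_sampled)
    table = relatedness_table(ds.matrix, ds.panel)
    m = _merge_truth(table, true_degree_table(ds.pedigree))
    d1 = m["true_degree"] == 1
    d2 = m["true_degree"] == 2
    ur = m["true_degree"] == "UNRELATED"
    close = d1 | d2
    correct_close = ((d1 & (m["call"] == 1)) | (d2 & (m["call"] == 2))).sum()
    return {
        "n_individuals": ds.matrix.n_individuals,
        "n_pairs": len(m),
        "n_first_degree": int(d1.sum()),
        "n_second_degree": int(d2.sum()),
        "first_degree_correct": int((d1 & (m["call"] == 1)).sum()),
        "second_degree_correct": int((d2 & (m["call"] == 2)).sum()),
        "close_kin_recovery": float(correct_close / close.sum()) if close.any() else float("nan"),
        "unrelated_called_first_degree": int((ur & (m["call"] == 1)).sum()),
        "n_unrelated": int(ur.sum()),
        "background_pmr": float(table.attrs["background"].p0),
    }


def _nuclear_family(tag: str) -> TruePedigree:
    ped = TruePedigree()
    ped.add(PedNode(f"F{tag}", XY, 1, True, ADULT, 0, mt_hg=f"mtF{tag}", y_hg=f"Y{tag}"))
    ped.add(PedNode(f"M{tag}", XX, 1, True, ADULT, 0, mt_hg=f"mtM{tag}"))
    for c in ("C1", "C2"):
        ped.add(
            PedNode(f"{c}{tag}", XY, 2, True, ADULT, 0, mother_id=f"M{tag}",
                    father_id=f"F{tag}", mt_hg=f"mtM{tag}", y_hg=f"Y{tag}")
        )
    return ped


def po_sib_discrimination(
    seed: int,
    n_families: int = 50,
    n_snps: int = 500_000,
    coverage: float = 1.0,
    error_rate: float = 0.01,
) -> dict:
    """Windowed PMR discrimination of parent-offspring vs full siblings.

    Each replicate family contributes one father-child pair and one
    sibling pair; the background rate comes from cross-family founder
    pairs, which are unrelated by construction.
    """
    cfg = SimulationConfig(seed=seed, n_snps=n_snps, coverage=coverage,
                           error_rate=error_rate)
    rng = np.random.default_rng(seed)
    panel = make_panel(cfg, rng)
    freq = draw_founder_frequencies(cfg, rng, panel.n_sites)

    matrices: list[PseudoHaploidMatrix] = []
    for k in range(n_families):
        ped = _nuclear_family(str(k))
        dip = drop_genes(ped, panel, cfg, rng, founder_freq=freq)
        matrices.append(sample_pseudohaploid(dip, cfg, rng))

    # background: father of family k vs mother of family k+1
    cross = []
    for k in range(n_families):
        j = (k + 1) % n_families
        pair = PseudoHaploidMatrix(
            ["a", "b"],
            np.vstack([matrices[k].row(f"F{k}"), matrices[j].row(f"M{j}")]),
        )
        cross.append(pairwise_mismatch(pair, "a", "b"))
    p0 = estimate_background(cross).p0

    po_correct = sib_correct = 0
    for k, mat in enumerate(matrices):
        series = windowed_pmr(mat, f"F{k}", f"C1{k}", panel)
        po_correct += classify_po_vs_sibling(series, p0)[0] == PARENT_OFFSPRING
        series = windowed_pmr(mat, f"C1{k}", f"C2{k}", panel)
        sib_correct += classify_po_vs_sibling(series, p0)[0] == SIBLING
    return {
        "n_po_pairs": n_families,
        "n_sib_pairs": n_families,
        "po_correct": int(po_correct),
        "sib_correct": int(sib_correct),
        "accuracy": (po_correct + sib_correct) / (2 * n_families),
        "background_pmr": float(p0),
    }


def pedigree_assembly(
    seed: int,
    n_snps: int = 100_000,
    min_sampled: int = 24,
    max_sampled: int = 36,
) -> dict:
    """Assemble a three-generation two-lineage community (~30 sampled
    individuals) and score parent edges."""
    cfg = SimulationConfig(seed=seed, n_generations=3, mean_offspring=4.0,
                           n_founder_couples=2, n_snps=n_snps)
    ds = simulate_dataset_sized(cfg, min_sampled, max_sampled)
    table = relatedness_table(ds.matrix, ds.panel)
    graphs = build_pedigrees(table, ds.records)
    res = compare_to_truth(graphs, ds.pedigree.edges(), ds.matrix.ids)
    res["n_individuals"] = ds.matrix.n_individuals
    res.pop("placeholder_mapping", None)
    return res


def normalized_pmr_checks(seed: int, n_snps: int = 100_000) -> dict:
    """Normalized PMR of duplicate samplings, parent-offspring and
    second-degree pairs against the analytic 1/2, 3/4, 7/8.

    Run error-free: the analytic factors hold exactly only for error-free
    calls. The background comes from a pool of unrelated founders.
    """
    cfg = SimulationConfig(seed=seed, n_snps=n_snps, coverage=1.0, error_rate=0.0)
    rng = np.random.default_rng(seed)
    panel = make_panel(cfg, rng)

    ped = TruePedigree()
    ped.add(PedNode("F", XY, 1, True, ADULT, 0, mt_hg="mtF", y_hg="Y1"))
    ped.add(PedNode("M", XX, 1, True, ADULT, 0, mt_hg="mtM"))
    ped.add(PedNode("W", XX, 2, True, ADULT, 0, mt_hg="mtW"))
    for c in ("C1", "C2"):
        ped.add(PedNode(c, XY, 2, True, ADULT, 0, mother_id="M", father_id="F",
                        mt_hg="mtM", y_hg="Y1"))
    ped.add(PedNode("G", XY, 3, True, ADULT, 0, mother_id="W", father_id="C1",
                    mt_hg="mtW", y_hg="Y1"))
    for u in range(12):
        ped.add(PedNode(f"U{u}", XY, 1, True, ADULT, 0, mt_hg=f"mtU{u}", y_hg=f"YU{u}"))

    dip = drop_genes(ped, panel, cfg, rng)
    mat = sample_pseudohaploid(dip, cfg, rng)
    dup = sample_pseudohaploid(dip, cfg, rng, ids=["F"])
    full = PseudoHaploidMatrix(mat.ids + ["Fdup"], np.vstack([mat.calls, dup.calls]))

    pool = [f"U{u}" for u in range(12)] + ["M", "W"]
    bg = estimate_background([pairwise_mismatch(full, a, b) for a, b in combinations(pool, 2)])
    p0 = bg.p0

    out = {"background_pmr": p0}
    for label, pair, expect in (
        ("duplicate", ("F", "Fdup"), 0.5),
        ("parent_offspring", ("F", "C1"), 0.75),
        ("second_degree", ("C2", "G"), 0.875),
    ):
        s = pairwise_mismatch(full, *pair)
        out[label] = {
            "normalized_pmr": s.pmr / p0,
            "expected": expect,
            "se": s.se / p0,
            "n": s.n,
        }
    return out


def null_calibration(
    seed: int, n_reps: int = 500, n_perm: int = 199
) -> dict:
    """p-value distributions of the spatial tests under their nulls.

    Coordinates (and both distance matrices) are drawn independently of
    the pair labels, so the p-values must be (super-)uniform.
    """
    rng = np.random.default_rng(seed)
    dist_ps, mantel_ps = [], []
    pairs = [(f"I{2 * k}", f"I{2 * k + 1}") for k in range(5)]
    for rep in range(n_reps):
        coords = {f"I{k}": tuple(rng.normal(size=2)) for k in range(14)}
        res = category_distance_test(
            coords, pairs, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        dist_ps.append(res.p_value)

        pts_a = rng.normal(size=(10, 2))
        pts_b = rng.normal(size=(10, 2))
        da = np.hypot(*(pts_a[:, None] - pts_a[None]).transpose(2, 0, 1))
        db = np.hypot(*(pts_b[:, None] - pts_b[None]).transpose(2, 0, 1))
        _, p = mantel_test(da, db, n_perm=n_perm, seed=int(rng.integers(2**31)))
        mantel_ps.append(p)
    return {"distance_test_p": dist_ps, "mantel_p": mantel_ps, "n_reps": n_reps}


def clopper_pearson_coverage(
    seed: int, n_draws: int = 2_000, p: float = 0.3, n: int = 33, level: float = 0.95
) -> dict:
    """Empirical coverage of the exact binomial interval."""
    rng = np.random.default_rng(seed)
    ks = rng.binomial(n, p, size=n_draws)
    covered = 0
    ci_cache: dict[int, tuple[float, float]] = {}
    for k in ks:
        if int(k) not in ci_cache:
            ci = proportion_ci(int(k), n, level)
            ci_cache[int(k)] = (ci.lower, ci.upper)
        lo, hi = ci_cache[int(k)]
        covered += lo <= p <= hi
    return {"coverage": covered / n_draws, "n_draws": n_draws, "p": p, "n": n}
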