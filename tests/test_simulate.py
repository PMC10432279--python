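"""The synthetic community generator: pedigree structure, haplogroup
transmission, gene dropping, pseudo-haploid degradation, grave layout."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from paleokin.datatypes import ADULT, MISSING, SUBADULT, XX, XY
from paleokin.simulate import (
    PedNode,
    SimulationConfig,
    TruePedigree,
    drop_genes,
    draw_founder_frequencies,
    generate_pedigree,
    kinship_coefficient,
    make_panel,
    place_graves,
    sample_pseudohaploid,
    simulate_dataset,
    true_degree,
)
from paleokin.simulate.pedigree import UNRELATED


def manual_pedigree():
    """Three generations built by hand: founder couple, two sons with
    immigrant wives, one grandchild each."""
    ped = TruePedigree()
    ped.add(PedNode("F1", XY, 1, True, ADULT, 0, mt_hg="mtA", y_hg="Y1"))
    ped.add(PedNode("M1", XX, 1, True, ADULT, 0, mt_hg="mtB"))
    for k, son in enumerate(("S1", "S2")):
        ped.add(PedNode(son, XY, 2, True, ADULT, k, mother_id="M1", father_id="F1",
                        mt_hg="mtB", y_hg="Y1"))
        ped.add(PedNode(f"W{k+1}", XX, 2, True, ADULT, 0, mt_hg=f"mtW{k+1}"))
        ped.add(PedNode(f"C{k+1}", XY, 3, True, ADULT, 0, mother_id=f"W{k+1}",
                        father_id=son, mt_hg=f"mtW{k+1}", y_hg="Y1"))
    return ped


class TestGeneratePedigree:
    def test_single_generation_is_one_couple(self):
        ped = generate_pedigree(SimulationConfig(seed=1, n_generations=1))
        assert len(ped.nodes) == 2
        assert ped.edges() == []
        sexes = sorted(n.sex for n in ped.nodes.values())
        assert sexes == [XX, XY]

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(seed=5, n_generations=4)
        a = generate_pedigree(cfg)
        b = generate_pedigree(cfg)
        assert [vars(n) for n in a.nodes.values()] == [vars(n) for n in b.nodes.values()]

    def test_haplogroup_transmission_invariants(self):
        """Every node carries its mother's mt label; every male his
        father's Y label."""
        ped = generate_pedigree(SimulationConfig(seed=11, n_generations=5))
        for node in ped.nodes.values():
            if node.mother_id is not None:
                assert node.mt_hg == ped.nodes[node.mother_id].mt_hg
            if node.sex == XY and node.father_id is not None:
                assert node.y_hg == ped.nodes[node.father_id].y_hg
            assert (node.y_hg is not None) == (node.sex == XY)

    def test_two_parents_of_opposite_sex(self):
        ped = generate_pedigree(SimulationConfig(seed=11, n_generations=4))
        for node in ped.nodes.values():
            parents = ped.parents(node.id)
            assert len(parents) in (0, 2)
            if parents:
                assert sorted(ped.nodes[p].sex for p in parents) == [XX, XY]
                gens = [ped.nodes[p].generation for p in parents]
                assert node.generation == max(gens) + 1

    def test_patrilineal_y_fraction_matches_graph_traversal(self):
        """Fraction of males carrying the founder Y equals the fraction of
        patrilineal descendants found by independent label propagation."""
        ped = generate_pedigree(SimulationConfig(seed=3, n_generations=5, mean_offspring=3.0))
        founder_y = next(
            n.y_hg for n in ped.nodes.values() if n.sex == XY and n.is_founder
        )
        males = [n for n in ped.nodes.values() if n.sex == XY]
        share = sum(1 for n in males if n.y_hg == founder_y) / len(males)

        # oracle: propagate patriline membership over the emitted graph
        patrilineal = set()
        for n in ped.nodes.values():
            if n.sex != XY:
                continue
            cur = n
            while cur.father_id is not None:
                cur = ped.nodes[cur.father_id]
            if cur.is_founder and cur.y_hg == founder_y:
                patrilineal.add(n.id)
        assert share == len(patrilineal) / len(males)


class TestTrueDegree:
    def test_parent_child_first_degree_lineal(self):
        ped = manual_pedigree()
        assert true_degree(ped, "F1", "S1") == (1, "LINEAL")
        assert true_degree(ped, "M1", "C1")[0] == 2

    def test_full_siblings_first_degree_non_lineal(self):
        ped = manual_pedigree()
        assert true_degree(ped, "S1", "S2") == (1, "NON_LINEAL")

    def test_first_cousins_third_degree(self):
        ped = manual_pedigree()
        assert kinship_coefficient(ped, "C1", "C2") == pytest.approx(1 / 16)
        assert true_degree(ped, "C1", "C2") == (3, "NON_LINEAL")

    def test_unrelated_founders(self):
        ped = manual_pedigree()
        assert true_degree(ped, "M1", "W1")[0] == UNRELATED
        assert kinship_coefficient(ped, "F1", "W2") == 0.0

    def test_same_individual_degree_zero(self):
        ped = manual_pedigree()
        assert true_degree(ped, "S1", "S1") == (0, "LINEAL")

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError):
            true_degree(manual_pedigree(), "F1", "nope")


class TestDropGenes:
    CFG = SimulationConfig(seed=9, n_snps=4_400, n_chromosomes=4)

    def test_founder_frequency_matches_truncated_beta_mean(self, rng):
        """Mean simulated frequency within 3 SE of the analytic mean of the
        truncated Beta law."""
        cfg = SimulationConfig(seed=0)
        f = draw_founder_frequencies(cfg, rng, 10_000)
        lo, hi = cfg.founder_freq_min, cfg.founder_freq_max
        dens = beta_dist(cfg.founder_freq_alpha, cfg.founder_freq_beta)
        z = dens.cdf(hi) - dens.cdf(lo)
        mean = quad(lambda x: x * dens.pdf(x) / z, lo, hi)[0]
        var = quad(lambda x: (x - mean) ** 2 * dens.pdf(x) / z, lo, hi)[0]
        assert abs(f.mean() - mean) < 3 * math.sqrt(var / len(f))
        assert f.min() >= lo and f.max() <= hi

    def test_mendelian_consistency_exhaustive(self, rng):
        """Every child allele at every site exists in the designated parent."""
        ped = manual_pedigree()
        panel = make_panel(self.CFG, rng)
        dip = drop_genes(ped, panel, self.CFG, rng)
        for child, parent_attr, hap in (("S1", "mother_id", 0), ("S1", "father_id", 1),
                                        ("C1", "mother_id", 0), ("C1", "father_id", 1)):
            parent = getattr(ped.nodes[child], parent_attr)
            ci, pi = dip.index_of(child), dip.index_of(parent)
            child_hap = dip.alleles[ci, hap]
            in_parent = (child_hap == dip.alleles[pi, 0]) | (child_hap == dip.alleles[pi, 1])
            assert in_parent.all()

    def test_zero_genetic_length_copies_one_parental_haplotype(self, rng):
        cfg = SimulationConfig(seed=2, n_snps=1_000, n_chromosomes=1,
                               morgans_per_chromosome=1e-12)
        ped = manual_pedigree()
        panel = make_panel(cfg, rng)
        dip = drop_genes(ped, panel, cfg, rng)
        ci, fi = dip.index_of("S1"), dip.index_of("F1")
        paternal = dip.alleles[ci, 1]
        assert (paternal == dip.alleles[fi, 0]).all() or (paternal == dip.alleles[fi, 1]).all()

    def test_parent_offspring_ibd1_everywhere(self, rng):
        ped = manual_pedigree()
        panel = make_panel(self.CFG, rng)
        dip = drop_genes(ped, panel, self.CFG, rng)
        states = dip.ibd_states("F1", "S1")
        assert (states == 1).all()

    def test_sibling_ibd2_fraction_quarter(self):
        """IBD2 genome fraction of full sibs ~ 0.25 within 3 SE over 20
        replicate sibships (oracle: the ancestry-label sidecar)."""
        cfg = SimulationConfig(seed=13, n_snps=4_400, n_chromosomes=22)
        rng = np.random.default_rng(cfg.seed)
        panel = make_panel(cfg, rng)
        fracs = []
        for _ in range(20):
            ped = TruePedigree()
            ped.add(PedNode("F", XY, 1, True, ADULT, 0, mt_hg="a", y_hg="y"))
            ped.add(PedNode("M", XX, 1, True, ADULT, 0, mt_hg="b"))
            for s in ("A", "B"):
                ped.add(PedNode(s, XY, 2, True, ADULT, 0, mother_id="M", father_id="F",
                                mt_hg="b", y_hg="y"))
            dip = drop_genes(ped, panel, cfg, rng)
            fracs.append(float((dip.ibd_states("A", "B") == 2).mean()))
        se = np.std(fracs, ddof=1) / math.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.25) < 3 * se + 1e-9


class TestSamplePseudoHaploid:
    def test_high_coverage_no_error_reproduces_homozygotes(self, rng):
        cfg = SimulationConfig(seed=1, n_snps=500, n_chromosomes=1,
                               coverage=50.0, error_rate=0.0)
        ped = manual_pedigree()
        panel = make_panel(cfg, rng)
        dip = drop_genes(ped, panel, cfg, rng)
        mat = sample_pseudohaploid(dip, cfg, rng, ids=["F1"])
        hom = dip.alleles[dip.index_of("F1"), 0] == dip.alleles[dip.index_of("F1"), 1]
        called = mat.calls[0] != MISSING
        assert (mat.calls[0][hom & called] == dip.alleles[dip.index_of("F1"), 0][hom & called]).all()
        assert called.mean() > 0.99

    def test_missing_fraction_poisson_zero_mass(self, rng):
        """At coverage 1 the missing fraction is e^-1 within 3 SE."""
        cfg = SimulationConfig(seed=1, n_snps=100_000, coverage=1.0)
        ped = manual_pedigree()
        panel = make_panel(cfg, rng)
        dip = drop_genes(ped, panel, cfg, rng)
        mat = sample_pseudohaploid(dip, cfg, rng, ids=["F1"])
        p = math.exp(-1)
        frac = float((mat.calls[0] == MISSING).mean())
        se = math.sqrt(p * (1 - p) / cfg.n_snps)
        assert abs(frac - p) < 3 * se

    def test_error_half_makes_calls_uninformative(self, rng):
        """epsilon = 0.5 gives PMR 0.5 between any pair."""
        cfg = SimulationConfig(seed=1, n_snps=50_000, coverage=3.0, error_rate=0.5)
        ped = manual_pedigree()
        panel = make_panel(cfg, rng)
        dip = drop_genes(ped, panel, cfg, rng)
        mat = sample_pseudohaploid(dip, cfg, rng, ids=["F1", "S1"])
        a, b = mat.calls
        both = (a != MISSING) & (b != MISSING)
        pmr = (a[both] != b[both]).mean()
        assert abs(pmr - 0.5) < 3 * math.sqrt(0.25 / both.sum())


class TestPlaceGraves:
    def test_zero_spread_collapses_clusters(self):
        cfg = SimulationConfig(seed=3, n_generations=3, sigma_within=0.0,
                               father_son_shrink=0.0)
        ped = generate_pedigree(cfg)
        coords = place_graves(ped, cfg)
        assert len({tuple(np.round(v, 9)) for v in coords.values()}) <= 2

    def test_father_subadult_son_buried_closer(self):
        """Construction: subadult sons scatter tighter around their father
        than arbitrary pairs scatter around each other."""
        fs, rand = [], []
        for rep in range(50):
            cfg = SimulationConfig(seed=100 + rep, n_generations=4, mean_offspring=3.0,
                                   subadult_death_prob=0.3)
            ped = generate_pedigree(cfg)
            coords = place_graves(ped, cfg)
            ids = sorted(coords)
            rng = np.random.default_rng(rep)
            for node in ped.nodes.values():
                if (node.age_class == SUBADULT and node.sex == XY and node.sampled
                        and node.father_id and ped.nodes[node.father_id].sampled):
                    fs.append(math.dist(coords[node.id], coords[node.father_id]))
            for _ in range(10):
                a, b = rng.choice(len(ids), 2, replace=False)
                rand.append(math.dist(coords[ids[a]], coords[ids[b]]))
        assert np.mean(fs) < np.mean(rand)

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(seed=8, n_generations=3)
        ped = generate_pedigree(cfg)
        assert place_graves(ped, cfg) == place_graves(ped, cfg)


class TestDatasetDeterminism:
    def test_same_seed_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=21, n_generations=3, n_snps=2_200)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        np.testing.assert_array_equal(d1.matrix.calls, d2.matrix.calls)
        assert d1.coords == d2.coords
        d1.write(tmp_path / "a")
        d2.write(tmp_path / "b")
        for name in ("sim.geno", "sim.snp", "sim.ind", "sim_metadata.tsv",
                     "sim_true_degrees.tsv", "sim_true_edges.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
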