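# paleokin

Kinship classification and pedigree reconstruction for low-coverage,
pseudo-haploid ancient-DNA data, with the demographic and spatial
statistics used to interpret a prehistoric burial community, exercised
end-to-end on a forward simulator of patrilineal communities.

## Who this is for

Archaeogeneticists working with shotgun or capture data too shallow for
diploid genotypes. At such coverage each individual is represented by one
randomly sampled read allele per SNP ("pseudo-haploid" calls), and
relatedness must be inferred from allele-sharing summaries rather than
genotype likelihoods. The package takes EIGENSTRAT genotype files plus a
per-individual metadata table (genetic sex, age class, uniparental
haplogroups, grave coordinates) and produces classified pairwise
relationships, assembled pedigrees and community-level statistics.

## The statistics at the core

**Pairwise mismatch rate (PMR).** For individuals *i, j* with *n*
jointly covered SNPs and *k* disagreeing calls, PMR = *k/n*. Between
unrelated members of one population the PMR fluctuates around a
background rate *p₀*; identity-by-descent sharing lowers it:

    E[PMR | degree d] = p0 · (1 − 2^−(d+1))

so duplicate samplings of one genome (or identical twins) sit at
*p₀*/2, first-degree pairs at 0.75 *p₀*, second-degree at 0.875 *p₀*.
*p₀* is estimated from the top of the pairwise PMR distribution
(relatedness only lowers PMR) by a trimmed iterative median.

**Degree classification.** *k* ~ Binomial(*n*, *p_d*) per degree class
*d* ∈ {0, 1, 2, unrelated}; a posterior over classes is computed in log
space with a uniform prior, ties breaking toward the more distant class.

**Parent–offspring vs sibling.** Both are first degree, but
parent–offspring pairs share exactly one haplotype everywhere (IBD1
genome-wide) while full siblings mix IBD states 0/1/2 in ¼ : ½ : ¼
proportions. The genome is tiled into 20-cM windows; a flat profile at
0.75 *p₀* supports parent–offspring, a heterogeneous profile supports
siblings, decided by the summed log-Bayes-factor between a single-rate
binomial model and the three-component IBD mixture.

**Pedigree assembly.** Oriented parent–child duos (orientation by mt and
Y haplogroup transmission, age class, and sibship triangulation) and
sibling sets are merged deterministically; second-degree calls act as
cross-checks that veto contradictory merges; siblings without a sampled
parent receive placeholder parents.

**Demography.** Exact (Clopper–Pearson) binomial confidence intervals
for sex ratios, occupation duration as generations x 28 years,
permutation tests for grave-distance categories, a Mantel test of
spatial vs genetic distance, and uniparental-haplogroup diversity and
transmission-depth summaries.

The `paleokin.simulate` package generates ground truth for all of this:
patrilineal pedigrees with in-migrating unrelated mothers, gene dropping
with Haldane recombination and exact IBD bookkeeping, Poisson coverage
and symmetric read error, and lineage-clustered grave coordinates.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (seed 2026 by default):

```sh
python analysis/01_simulate_community.py
python analysis/02_kinship_classification.py
python analysis/03_build_pedigrees.py
python analysis/04_demography.py
```

which prints, among other things:

```
simulated community: 47 sampled individuals over 5 generations
background PMR p0 = 0.3423 from 786 pairs (3 trim iterations)
degree confusion (rows = truth, columns = called):
called      1    2  UNRELATED
true
1          95    1          0
2           0  113          0
3           0   29         77
...
parent-edge precision 0.969, recall 0.969 (62/64 truth edges recovered)
reference_adult_sex_ratio: 27/33 male, ratio 4.5:1, CI 64.5-93.0%
father-subadult-son distance: mean 1.80 m over 3 pairs, permutation p = 0.0048
Mantel spatial vs genetic: r = 0.241, p = 0.0001 (n = 47)
occupation: 5 generations -> [1, 2] reproductive -> 28-56 years
```

Reading this: 95 of 96 true first-degree and all 113 second-degree pairs
recover their class; third-degree pairs (expected normalized PMR 0.9375,
exactly between the second-degree and unrelated class rates) split
between "2" and "UNRELATED", which is why the classifier does not offer
deeper classes by default. The adult sex-ratio line reproduces the exact
binomial interval for 27 male vs 6 female adults (64.5–93% male), and
the Mantel test recovers the built-in spatial clustering of lineages.

The same pipeline is scriptable (`paleokin run-all --seed 1 --out out/`)
or available as individual subcommands: `simulate`, `sexdet`, `kinship`,
`build-pedigree`, `demography`.

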