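# Methods

## The relatedness model

All genotypes are pseudo-haploid: one sequencing-read allele per
individual per SNP. For a pair of individuals the observable is the
pairwise mismatch rate (PMR), the fraction of jointly covered sites at
which their calls differ. Writing *p₀* for the PMR between unrelated
members of the population, and conditioning on the IBD state *s* at a
site, a mismatch occurs at rate *p₀* (s = 0), 0.75 *p₀* (s = 1) or
0.5 *p₀* (s = 2): drawing one random allele from each of two diploids
that share s haplotypes identical by descent halves the mismatch deficit
per shared haplotype. Averaging IBD proportions over a relationship of
degree *d* gives

    p_d = p0 · (1 − 2^−(d+1)),

the geometric approach to the background that underlies all
allele-sharing kinship estimators for ancient DNA. These factors are
exact only for error-free calls: a symmetric per-read error ε moves every
rate toward ½ by p → p(1−q) + (1−p)q with q = 2ε(1−ε). Because the
background is estimated from the same data, normalized rates are only
mildly distorted (at ε = 0.01 a true first-degree pair sits near 0.768
rather than 0.750), which is why the analytic 0.5/0.75/0.875 checks in
the validation suite run at ε = 0 while the classification experiments
keep ε = 0.01.

### Background rate p₀

Relatedness can only lower the PMR, so the top of the pairwise PMR
distribution is formed by genuinely unrelated pairs. The estimator
initializes at the 0.95 quantile of all pair PMRs, then iterates: drop
pairs below 0.953125x the current estimate (halfway, in normalized PMR,
between the third- and fourth-degree expectations) and re-take the median
of the rest, until the retained set stabilizes (at most 10 rounds).

The initialization and trim level matter in pedigree-dense cohorts. A
median start with a trim halfway between second degree and unrelated
(0.90625) retains third-degree pairs, and in a community where most pairs
are relatives this biases p₀ several percent low — enough to push
first-degree pairs (normalized 0.75–0.77) across the first/second-degree
boundary at 0.8125. The high-quantile start plus the tighter trim keeps
the estimate anchored in the unrelated cluster while remaining exactly
unbiased when all pairs are unrelated. The approach still requires *some*
unrelated pairs: a cohort that is one pure patriline with no sampled
in-migrating mothers leaves p₀ unidentifiable from internal data (a
known limitation; an external panel can be supplied via the `background`
argument).

### Degree classification

The mismatch count is modelled k ~ Binomial(n, p_d) for each class
d ∈ {0, 1, 2, UNRELATED}; class posteriors combine the log binomial
pmf (scipy, log-gamma based) with a uniform prior by default. Classes
deeper than 2 are deliberately absent from the default set: the
third-degree expectation 0.9375 lies exactly between the second-degree
and unrelated rates, so such pairs split between those calls and any
claimed third-degree call would be low-confidence. An extended class set
{0..5, UNRELATED} exists behind a flag. Exact posterior ties break toward
the more distant class — conservative against false kin claims. Pairs
with fewer than 5,000 overlapping sites are flagged LOW_OVERLAP and not
classified (the per-individual hard QC is 20,000 covered sites; the
per-pair threshold is this package's choice).

### Parent-offspring vs siblings

Both are first degree. The genome is tiled into fixed 20-cM windows
(windows with < 50 jointly covered sites are excluded; fewer than 10
usable windows yields INDETERMINATE). Two marginal likelihoods are
summed over windows: parent-offspring, k_w ~ Bin(n_w, 0.75 p₀); sibling,
a ¼:½:¼ mixture of Bin(n_w, p₀ / 0.75 p₀ / 0.5 p₀). The decision is the
sign of the summed log ratio and its magnitude is reported as a
log-Bayes-factor. Windows are treated as independent — no HMM over IBD
segments is fitted — so the sibling model ignores the spatial coherence
of IBD tracts; this loses some power per window but is unbiased as a
detector of profile heterogeneity, and at 100k–500k SNPs discrimination
is essentially perfect in simulation.

## Pedigree assembly

Inputs: the classified pair table plus per-individual sex, age class and
uniparental haplogroups. The rules, applied in deterministic
(lexicographic) order:

1. **Sibling sets** are the transitive closure of SIBLING calls; pairs
   inside a set called anything other than first degree are flagged as
   closure conflicts.
2. **Orientation of parent-offspring duos** uses, in order of authority:
   haplogroup transmission (an XX candidate whose mt label differs from
   the other member's cannot be the mother; father→son requires matching
   Y labels), age class (a subadult cannot be anyone's parent), and
   sibship lifting (an individual with parent-offspring calls to two
   members of a sibship is their shared parent; one with a single
   parent-offspring call into a sibship plus second-degree calls to the
   rest is that member's child).
3. **Triangulation** resolves duos that survive step 2 (typically
   adult father–adult son pairs): a filled parent slot forces the other
   direction; a second-degree call between the candidate and an
   established parent of the other member indicates a grandparent
   pattern; an unrelated call to that parent indicates the candidate is
   the other partner; sibling/second-degree calls to an established
   child disambiguate likewise. Iterated to a fixpoint; leftovers are
   flagged AMBIGUOUS and create no edge.
4. **Commit with vetoes.** Edges are added in sorted order; an edge is
   rejected if it would create a cycle or imply, for any called pair, a
   degree more than one step *closer* than its call — and only when the
   implied degree is within the classifier's trusted range (≤ 2), since
   an UNRELATED call is fully consistent with a true third-plus-degree
   relationship. Implied degrees come from the kinship coefficient
   computed on the partial graph.
5. **Placeholders.** Sibling sets missing a sampled parent receive
   placeholder parents (always as a mother-father pair); a lone sampled
   parent receives a placeholder partner. Placeholders are never created
   for isolated individuals, so they cannot inflate recovery scores.

Second-degree calls never create edges: grandparent / avuncular /
half-sibling disambiguation beyond the triangulation above would need
IBD-segment lineality, which is out of scope; such pairs remain recorded
constraints.

Scoring against truth matches placeholders to unsampled true parents by
largest child-set overlap (greedy over sorted candidates; child sets are
tiny, so greedy matching is effectively optimal). An empty inference
reports precision 1.0 with a zero-edge flag.

## Demography

* **Sex ratios**: exact Clopper–Pearson intervals from Beta quantiles.
  The method is fixed to Clopper–Pearson because it reproduces both
  published intervals (64.5–93% from 27/33; 34.4–68.1% from 19/37) at
  printed precision, which Wilson and Jeffreys intervals do not.
* **Occupation duration**: generations x 28 years per generation,
  applied to the reproductive generations (total span minus the founding
  and migrating generations).
* **Grave-distance categories**: the statistic is the mean Euclidean
  distance over a category's pairs; the null permutes which individual
  occupies which grave while keeping the pair structure; p = (1 + #{null
  ≤ observed}) / (1 + n_perm), one-sided for proximity, default 9,999
  permutations (exact-valid by the +1 convention).
* **Mantel test**: Pearson correlation of upper-triangle entries, null
  by joint row/column permutation of the second matrix, one-sided
  (positive) by default. The genetic distance matrix defaults to
  pair-level normalized PMR; which individuals enter is configurable and
  defaults to everyone with both coordinates and genotypes.
* **Haplogroup summaries**: distinct mt/Y label counts and, per mt
  label, the longest observed mother→child transmission chain within
  assembled pedigrees.

## The synthetic-data generator

The generator emulates the study design the analysis assumes: a
patrilocal, patrilineal community with female exogamy.

* **Pedigree**: founder couples start generation 1 (default 1 couple;
  the analysis drivers use 2 to emulate a two-pedigree community).
  Children per union ~ Poisson(λ = 3). Sons stay and, if adult, form a
  union with a newly created unrelated immigrant mother carrying a fresh
  mt haplogroup (sampled with probability 0.7 — most partners are buried
  at the site, some are not). Daughters out-migrate with probability 0.8
  (present in the pedigree, absent from the burial record); those who
  stay are childless at the site. A child dies before adulthood with
  probability 0.2 and is buried as a subadult. mt labels follow mothers,
  Y labels follow fathers, so a single Y lineage runs through each
  patriline while mt lineages stop after one transmission — the
  uniparental signature of female exogamy.
* **Genomes**: founder ALT frequencies ~ Beta(0.5, 0.5) truncated to
  [0.05, 0.95] (an ascertained-SNP-like U-shape without near-fixed
  sites); founder haplotypes site-wise Bernoulli; children inherit one
  recombined gamete per parent with Poisson(genetic length) crossovers,
  breakpoints uniform on the map, no interference (Haldane). Ancestry
  labels (which founder haplotype every position descends from) ride
  along and provide exact IBD truth.
* **Panel**: 22 chromosomes of 1.5 Morgans / 130 Mb each, sites uniform
  in physical position with a linear genetic map; 50,000 SNPs by default
  (100,000–500,000 in the experiments that need the resolution). This is
  a scaled-down stand-in for a 1.24M-site capture panel chosen so the
  whole pipeline runs on a desk machine; per-pair overlaps (~40% of the
  panel at coverage 1) remain far above every classification threshold.
* **Degradation**: per-site read depth ~ Poisson(1.0); depth 0 is
  missing; otherwise one chromosome copy is drawn uniformly and misread
  with probability 0.01.
* **Graves**: each patriline is a Gaussian cluster (σ = 3 m) around a
  centre on a ring with 15 m spacing; subadult sons are drawn around
  their father with σ shrunk by 0.3. This is a test harness for the
  spatial statistics, not a model of any real necropolis plan — no
  published quantitative grave-layout model exists to emulate.

What the generator does *not* emulate, hence what passing tests do not
show: background relatedness between founders (real in-migrating mothers
may share distant ancestry), post-mortem damage beyond symmetric error,
reference bias, contamination, population structure in allele
frequencies, and half-sibling unions (every union is monogamous). Real
data also violate the uniform-coverage assumption across sites.

## Numerical and design choices

* All likelihoods in log space; posteriors normalized by logsumexp.
* Cohort-size control: offspring counts are Poisson, so experiments
  specified for a cohort of ~20 or ~30 individuals redraw the pedigree
  (advancing the seed deterministically) until the sampled count falls
  in the target window (18–30 and 24–36 respectively).
* Experiment sizes: degree recovery at 100k SNPs / ~20 individuals;
  parent-offspring vs sibling at 500k SNPs / 50 + 50 pairs; assembly at
  100k SNPs / ~30 individuals over three generations; calibration with
  500 replicates of 199 permutations. These sizes give every check a
  comfortable statistical margin while keeping the full suite in the
  low minutes on one CPU.
* Seeds: a single global seed fans out per stage through
  `numpy.random.SeedSequence` spawn keys (all derived seeds < 2³¹), so
  any stage rerun alone is reproducible.
* EIGENSTRAT digits map 2→REF, 0→ALT, 9→missing; a genuine heterozygote
  digit 1 violates the pseudo-haploid contract and is rejected unless
  explicitly resolved to a random allele with a logged warning.
* Sex determination normalizes reads per target base and divides by the
  autosomal per-base rate (the published thresholds, < 0.05 female and
  > 0.4 male, are quoted without a normalization formula; per-base rate
  is this package's choice and is configurable).
* The Y-ratio thresholds, the 20,000-covered-SNP exclusion, the 28-year
  generation time and the burial counts (27/6 adults, 19/18 subadults)
  are fixed constants of the study design being reproduced.

## Known limitations

* Background estimation needs unrelated pairs in the cohort (see above).
* Orientation of adult parent–adult child pairs relies on triangulation;
  an isolated such duo with no other relatives stays AMBIGUOUS rather
  than guessing.
* The windowed sibling test assumes window independence; extremely
  uneven coverage could leave fewer than 10 usable windows and an
  INDETERMINATE subcall.
* Degree calls beyond the second degree are intentionally not offered by
  default; pedigrees connect only through first-degree edges plus
  placeholder parents.
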