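# Methods

## The layered-ancestry procedure

The package targets a recurring problem in cultural evolution: deciding
whether a cultural domain shared among admixed forager populations is (a)
recently borrowed from the farming populations they admixed with, (b) old but
still circulating among the foragers, or (c) independent of demography
altogether (e.g. ecological convergence). The identifying idea is that
different compartments of an admixed genome date different epochs of contact:

* farmer-derived local-ancestry segments date from the farming expansion;
* cross-population IBD segments longer than 1 cM between foragers date
  genetic exchange within roughly the last 2,500 years (longer shared
  segments mean fewer recombination events since the common ancestor);
* hunter-gatherer-ancestry segments *without* such IBD carry structure that
  predates recent contact.

Masking is two-step. First, every genotype entry whose local-ancestry call is
not the retained class becomes missing (`ancestry-mask`); sites covered by no
call are also masked — the pipeline never invents ancestry. Second, retained
cross-population IBD segments are masked on exactly the two haplotypes named
in each record (`ibd-mask`). The four resulting layers are nested by
construction and the nesting is asserted every time a layer set is built.

IBD post-processing follows the published protocol for HMM-based callers:
blocks of the same haplotype pair merge when separated by a gap of at most
0.6 cM with at most one allele mismatch across the gap-plus-blocks region;
merging is transitive left-to-right (the protocol's merge tool does not
specify multi-block behaviour; left-to-right is the deterministic choice).
Cross-population retention is strict (> 1 cM). "Inconsistent genotype" is
interpreted at the haplotype-allele level because the merge operates on
phased data.

## Statistics

**Ancestry-specific frequencies.** Per population and site, f = a/n over
retained haplotype alleles only; any site where any population retains one or
fewer alleles is dropped for all populations (so n > 1 everywhere). An
individual's genotype frequency vector averages its two haplotypes (0, 0.5, 1);
one retained haplotype contributes its allele; none means missing — a site is
lost to an individual only when *neither* haplotype carries retained ancestry.

**Hudson's FST** uses the ratio-of-averages rule: numerator and denominator
are averaged across SNPs separately before dividing, which keeps the
multi-locus estimator consistent. The denominator implemented is
f_A(1−f_B) + f_B(1−f_A), the standard form from the estimator literature.
Estimates can be slightly negative around zero differentiation; the
matrix-valued export clips at 0 so downstream containers remain valid
dissimilarities, while scalar results are reported unclipped. The estimator
is exactly symmetric and, under Balding–Nichols divergence F of two
populations from a shared ancestor, estimates 2F-relative structure such
that two independently diverged pools at parameter F yield FST = F — the
basis of the parameter-recovery check.

**Matrix completion** (before individual-level ordination) is iterative
truncated-SVD imputation with optional soft-thresholding of singular values:
initialize missing entries at column means, alternately reconstruct from the
leading components and overwrite only the missing entries, stop at an RMS
change below 1e-5 or 100 iterations; filled values are clipped to [0, 1].
The published analysis cites an external completion method without algorithmic
detail; soft-impute is the standard deterministic baseline. By default the
rank is chosen adaptively each iteration (components with singular value at
least 5% of the leading one).

**Permutation battery.** Mantel correlation is Spearman by default (the
reported statistic is a rank correlation; Pearson is exposed); MMRR is OLS on
unfolded upper triangles with response-relabelling nulls for the t
statistics; CADM ranks each matrix's unfolded distances and measures
Kendall's W (tie-corrected), permuting every matrix independently for the
global null and only the tested matrix for a posteriori tests (Holm-adjusted,
as recommended for non-independent tests). Three conventions hold
throughout: nulls permute object labels (simultaneous row/column
permutation), never independent cells; p values use the add-one estimator
(1 + #extreme)/(1 + n_perm), so the smallest attainable p is 1/(n_perm+1);
Mantel/MMRR are two-sided (distance matrices can anti-correlate), CADM is
one-sided toward congruence. All tests take an explicit seed and are
bit-reproducible. The CADM implementation was verified against the R `ape`
reference implementation on a fixed fixture (Kendall's W, the chi-square
approximation and a posteriori mean correlations agree to 1e-6).

**Timing classification** applies alpha = 0.05 to BH-adjusted p values of the
three mandatory layer rows. The three idealized outcomes leave two of the
eight significance patterns unassigned (full+residue without cahg, and
residue patterns involving full); these are mapped by the precedence
cahg > full > residue-only, and the raw pattern is always reported alongside
the label.

**Lexicon.** Dyadic shared-word counts are numbers of cognate sets carried by
both groups of a dyad (cognate coding is expert input, not computed).
Tree distances: the Glottolog-style statistic counts internal nodes strictly
between two tips (endpoints excluded; sister tips are 1 apart); patristic
distances sum branch lengths, with languages outside the dated tree's family
assigned the maximum root-to-tip depth. Multi-language groups average their
languages' pairwise distances. Zero-inflated Poisson models (log-link count
part, logit-link zero part, same standardized predictors in both by default)
are fitted by maximum likelihood via statsmodels, with observed-information
standard errors; an all-zero response is rejected as unidentifiable.
The Wilcoxon signed-rank statistic reported is the positive-rank sum, with
exact p for ≤ 25 untied nonzero pairs and a tie-corrected normal
approximation otherwise. Spearman's rho is reported together with
S = Σd² over mid-ranks, matching the convention of reporting both.

## The synthetic cohort generator

The generator is the package's stand-in for the restricted genotype data and
defines the conditions under which every end-to-end claim is tested.

* **Genetics.** Sites carry ancestral frequencies uniform on (0.1, 0.9). Two
  ancestral pools (hunter-gatherer, farmer) diverge from them by
  Balding–Nichols F = 0.25 each, giving pool-to-pool FST ≈ 0.25 — the order
  of real forager–farmer differentiation. Hunter-gatherer demes nest in two
  regional clusters (cluster F = 0.05, within-cluster deme F = 0.015),
  echoing the western/eastern split and yielding between-deme FST of a few
  percent. Default cohort: 10 demes × 10 diploids × 3,000 SNPs on one 100 cM
  chromosome (one uniform cM-per-bp map).
* **Admixture.** One pulse t = 50 generations ago; each haplotype is a
  mosaic with exponential tract lengths of mean 100/t cM and per-tract farmer
  probability equal to the deme's admixture fraction. Default fractions
  spread evenly over 0.05–0.55 and are shuffled across demes so farmer
  contact is independent of the deep cluster structure.
* **Recent exchange.** Haplotype blocks (1 cM + Exp(1.5 cM)) are copied
  between demes at Poisson rates (default: 8 events per ordered within-cluster
  deme pair, 0.2 between clusters); copies are logged as ground-truth IBD and
  windows never overlap on a haplotype, so recorded segments are exactly
  allele-identical. The ancestry-interval table is derived from the final
  per-site truth, so interval and matrix representations agree entry for
  entry. Copying is used instead of coalescent simulation deliberately: it
  gives exact ground truth for masking tests.
* **Culture.** Each of 80 binary traits originates in a random deme and
  spreads to others with probability 0.10 + 0.80 × S, where S is the
  scenario's driver similarity: farmer-admixture similarity
  (`farmer_borrowing`), the recent-exchange network (`hg_exchange`), or biome
  similarity (`ecology`, biome composition drawn from two well-separated
  Dirichlet profiles assigned at random). Word counts come from the
  generative twin of the ZIP model.
* **Randomness.** One seed feeds named sub-streams (frequencies, tracts,
  alleles, exchange, geography, traits), so partial reruns are reproducible.

Power settings (cohort size, trait count, divergence levels, exchange rates)
were chosen so that each scenario's intended classification is recovered in
at least 80% of seeded runs at 1,000 permutations, and then frozen; they are
deliberately strong, clean signals. What passing tests show is therefore that
the *method* is sound — masks are exact, estimators unbiased, tests
calibrated, and the classification logic correct when its assumptions hold.
They do not show that real data carry signals this clean: the generator has
no phasing or local-ancestry-call error (calls are ground truth, whereas real
classification accuracy is ~85–90%), no linkage disequilibrium within pools
beyond tract structure, no SNP ascertainment, uniform recombination, and
trait evolution far simpler than real cultural transmission.

## Numerical and degenerate-input conventions

Genomic intervals are half-open, 1-based bp. cM coordinates interpolate
linearly in the genetic map with clamped endpoints. Jaccard pairs with an
empty union get distance 0 with a warning (unreachable with non-empty
repertoires). Gower variables with zero range are excluded with a warning.
PCoA/classical MDS share one implementation: double-centred squared
distances, symmetric eigendecomposition, negative eigenvalues reported but
excluded from coordinates, and k truncated with a warning when it exceeds the
positive spectrum. Monomorphic-everywhere FST is flagged undefined rather
than silently zero. IBD records are stored in canonical pair order
(lexicographic by sample id, then haplotype) so symmetric duplicates
collapse.

## Known limitations

* The IBD detector for synthetic data is an exact-match scan; probabilistic
  detection on noisy real data is consumed as an input file, never
  re-implemented.
* Local-ancestry inference, phasing, ADMIXTURE-style global clustering, and
  SpaceMix-style geo-genetic inference are out of scope; their outputs are
  inputs here.
* NeighborNet layout is not implemented; PCoA coordinates and NEXUS distance
  exports serve external plotting.
* The timing classification is a significance-pattern heuristic: it rules
  out scenarios rather than dating events in generations, and its precedence
  rule for non-idealized patterns is a convention (documented above), not an
  inference.
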