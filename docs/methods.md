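# Methods

`exsitu` infers the origin of captive animals of unknown ancestry from two
kinds of evidence: diploid multilocus microsatellite genotypes scored
against a panel of reference populations, and an mtDNA control-region
haplotype matched against a provenance database. This note describes the
statistical machinery, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the known limits of
the approach.

## Data model

Genotypes are diploid and codominant; missing data are whole-locus (both
alleles or neither, the GENEPOP convention). Allele registries are built
dataset-wide per locus — the number of allelic states `k` includes alleles
seen only in the unknown-origin animals, because captives may carry alleles
absent from every reference sample. Allele frequencies are plain counts
`n_a / n` per (population, locus); cells with no typed genotypes carry
`n = 0` and defer entirely to priors downstream.

## Null-allele screening and culling

A null (non-amplifying) allele inflates apparent homozygosity: null
homozygotes drop out as missing data and null heterozygotes are scored as
homozygotes of the visible allele. Each (population, locus) cell with at
least five typed genotypes is tested for a heterozygote deficit by
Monte-Carlo permutation: the cell's allele copies are re-paired at random
(2,000 replicates by default) and observed heterozygosity Ho is compared
against that distribution, one-sided. Because Ho in a cell of n genotypes
takes only n+1 values, the permutation distribution is coarsely discrete and
the inclusive p-value `P(Ho* <= Ho)` is conservative — it would flag
noticeably fewer than alpha of null-free cells. We therefore report the
mid-p, `P(Ho* < Ho) + 0.5 P(Ho* = Ho)`, which restores the false-flag rate
to approximately alpha (verified by simulation over hundreds of null-free
cells).

Expected heterozygosity uses the unbiased small-sample form
`He = n/(n-1) (1 - sum p_a^2)` on gene count n. The null-allele frequency is
estimated from the deficit as `r = max(0, (He - Ho)/(1 + He))`. A cell is
flagged when `p < alpha` (default 0.05) and `r > 0`, and flagged cells are
culled — set to missing — before any downstream frequency estimation. This
reduces the full MICRO-CHECKER-style battery to the single criterion that
matters for a cull-before-analysis workflow; stutter and large-allele
dropout are not modelled.

## Partial-Bayesian assignment and exclusion

An individual's genotype is scored against each reference population by its
posterior-predictive probability under a per-locus Dirichlet(1/k) prior on
allele frequencies. With `n` gene copies sampled at the locus and `n_a` of
allele a:

    P(a,b | a != b) = 2 (n_a + 1/k)(n_b + 1/k) / [(n + 1)(n + 2)]
    P(a,a)          =   (n_a + 1/k)(n_a + 1/k + 1) / [(n + 1)(n + 2)]

These sum to one over all genotypes for any counts (tested by brute-force
enumeration). The multilocus score is `-log10` of the product over typed
loci, accumulated in log space to avoid underflow; L1 and L2 are the
best and second-best populations. Ties break lexicographically by
population id and are flagged.

The exclusion test simulates genotypes (10,000 by default) from a
population's observed frequencies, scores them identically, and reports
`p = P(score_sim >= score_obs)`; the population is excluded as an origin
when `p` falls below the threshold (default 0.01). Simulated genotypes span
only the loci where the population has data, and the query is scored on the
same loci for comparability. Under the null (query truly from the
population) these p-values are approximately uniform, which the test suite
checks with a Kolmogorov-Smirnov test.

## Supervised admixture

Membership coefficients q are estimated with the admixture model with
independent allele-frequency priors, run supervised: reference individuals
are pinned to their populations, so components are anchored and label
switching cannot occur. Per sweep the Gibbs sampler draws population
frequencies from `Dirichlet(lambda + reference counts)`, each unknown allele
copy's origin `z` from `Categorical(q_i f_k(a))`, and each `q_i` from its
Dirichlet conditional.

Two deliberate choices depart from the textbook joint model:

* **Frequencies are conditioned on the reference counts only.** Feeding the
  unknowns' assigned copies back into the frequency update is correct for a
  joint model but is a trap in supervised use: a batch of query individuals
  that is large relative to the reference samples (hundreds of simulated
  hybrids against ~60 reference genes per locus) drags both populations
  toward the batch mixture and biases every q — measured on simulated F1s,
  the recurrent-parent mean fell from 0.5 to 0.37. Conditioning on the
  references keeps queries exchangeable and mutually independent given f.
* **The q-prior concentration defaults to alpha = 0.2** (lambda stays 1.0).
  An individual typed at nine loci contributes only 18 allele copies, so the
  posterior mean of q is shrunk toward uniform by roughly `K alpha /
  (K alpha + 18)`. At alpha = 1 this alone caps a purebred's q at ~0.86 (K =
  2) and biases the backcross ladder low. alpha was calibrated once against
  the known Mendelian expectations of simulated classes (parental 1, F1 0.5,
  B1 0.75, B2 0.875, B3 0.9375): alpha = 0.2 reproduces all five within a
  few hundredths; smaller values trade bias for variance.

Run-length defaults are desk-scale — 5,000 burn-in, 25,000 retained-phase
sweeps, thinning 10 — which gives 2,500 retained draws and Monte-Carlo error
on posterior means well below 0.01; study-scale lengths (500,000 / 1,000,000)
remain available through configuration. Intervals are equal-tailed order
statistics of the retained draws (90% by default). Missing loci contribute
no `z` variables. Every stage is reproducible from its seed.

The correlated-allele-frequency (F-model) refinement is intentionally not
implemented: with well-differentiated, pre-labelled references the
independent-frequencies model supports the same classification logic.

## Hybrid classes

Ancestry classes between a population pair are simulated by Mendelian
gamete-drawing from the parental frequency pools: F1 takes one allele per
locus from each pool; F2 crosses two independent F1s; Bn is the nth serial
backcross to one recurrent parental line (expected recurrent fractions 0.75,
0.875, 0.9375 for B1-B3), generated in both directions. Simulants are run
through the same supervised admixture fit as real queries, against the panel
restricted to the pair (plus an optional third population for the K = 3
triangle view) — the space in which the comparison is displayed and judged.

Classification of an observed q is deliberately two-fold: a *compatible set*
(all classes whose empirical 2.5-97.5 percentile envelopes cover q
component-wise — overlap between F1, F2 and backcrosses is real and must be
reported, not hidden) and a *point class* (nearest class median in Euclidean
distance). Barycentric coordinates `x = q2 + q3/2, y = q3 sqrt(3)/2` embed
K = 3 results for triangle plotting; no figures are rendered — coordinates
are exported as TSV.

## Relatedness, dyad nulls and parentage

Pairwise relatedness uses the variance-weighted regression estimator: for
reference individual x = (a,b) and proband y = (c,d), with S the
identity-in-state indicator and p the reference-sample frequencies of x's
alleles,

    r_locus = [p_a(S_bc + S_bd) + p_b(S_ac + S_ad) - 4 p_a p_b]
            / [(1 + S_ab)(p_a + p_b) - 4 p_a p_b]

weighted per locus by `denominator / (2 p_a p_b)`; zero-denominator loci
(e.g. both individuals heterozygous at a biallelic locus with p = 0.5) are
skipped and counted out. The two reciprocal estimates are averaged with
equal weight, making the matrix exactly symmetric. With the "leave one out"
option the frequencies for pair (x, y) are recomputed from the frequency
source minus both members; alleles thereby absent from the reduced sample
are floored at `1/(2 n_genes + 2)` rather than erroring.

Observed r values are interpreted against simulated dyad distributions
(1,000 dyads per class by default) of unrelateds, half-siblings,
full-siblings and parent-offspring, generated from the same frequencies and
estimated with the same estimator. Class means calibrate to 0 / 0.25 / 0.5 /
0.5 within a few thousandths; full-sib r is more variable than
parent-offspring r (Mendelian segregation adds variance that obligate
single-allele sharing does not). Classification reports the nearest class
mean plus every class whose 2.5-97.5 envelope contains r — full-sib vs
parent-offspring ambiguity is expected and surfaced. Second-order
relationships (grandparental, avuncular, half-sib) are not distinguishable
from r alone and are reported only as half-sib-compatible.

Parentage is screened by direct allele transmission: a candidate parent is
compatible when it shares at least one allele in state with the offspring at
every commonly typed locus. Genotyping error is not modelled (a single
mismatch excludes; a tolerance flag exists, default 0), and maternity can
additionally require an identical mtDNA haplotype when both animals are
sequenced.

## mtDNA haplotype matching

Queries and database haplotypes are same-fragment, pre-aligned sequences, so
matching reduces to minimal Hamming distance; positions where either
sequence is an N or an alignment gap are excluded pairwise, and ties return
every tied haplotype. Each haplotype carries the population(s) and island(s)
where it was sampled in the wild plus a per-population native/non-native
flag — a non-native haplotype is one phylogenetically characteristic of
another island's lineage, evidence of past translocation. De novo alignment
and phylogenetic placement are out of scope.

## Target-lineage screen

Hunting descendants of a specific (e.g. extinct) target lineage t in a
colony needs more power than the K-wide q vector provides: an F1's signal is
diluted across many populations. The screen computes, per unknown, the
exact likelihood ratio of "F1(t, c)" against "purebred of c", where c is the
individual's best non-target population by assignment score and frequencies
are 1/k-smoothed. This is the Neyman-Pearson statistic for the contrast of
interest; purebred t individuals also score high since the F1 model contains
the t pool.

Calibration is the delicate part. The no-target null is the LR distribution
of pure-c individuals, estimated two ways and combined as the maximum:
a parametric bootstrap (5,000 simulants from Dirichlet-posterior frequency
draws, 99.5th percentile on the query's typed loci) and the second-largest
leave-one-out LR among c's real reference individuals. The parametric null
alone is slightly light-tailed (real genotypes carry rare alleles the
observed counts miss); the empirical term anchors it, and taking the
second-largest rather than the maximum keeps one aberrant reference
individual from inflating the cutoff for its whole population. An unknown is
called a target-lineage member when its L1 population is the target, its
K-wide q for the target exceeds 0.35, or its LR exceeds the calibrated
cutoff.

With nine microsatellites at FST ~ 0.2 this operates near the information
ceiling: occasional purebreds genuinely resemble F1s and vice versa, so on
the order of one colony in six a 51-animal negative set yields three false
flags instead of two, or one true F1 in nine is missed. More loci, not
better thresholds, is the remedy.

## The synthetic archipelago

The generator emulates the study conditions end to end: 17 reference
populations genotyped at 9 loci with 10 allelic states each, 30 animals per
population, ~2.8% missing data, moderate differentiation, and captive pens
mixing purebred, F1/F2/backcross and pedigree-related individuals with
maternally inherited mtDNA haplotypes. Population frequencies are drawn from
a symmetric Dirichlet around a shared ancestral vector; a single
concentration scalar c controls divergence with expected FST roughly
1/(1 + c) (default c = 4, realised multilocus FST ~ 0.18-0.20, measured by
variance partition on the true frequencies). Hidden null alleles can be
planted per (population, locus) under the standard artifact model. Every
individual's true ancestry fractions, recorded parents and haplotype are
kept in a truth table, and seeded runs are bit-reproducible.

What it does not emulate — and what passing tests therefore do not
demonstrate about real data: no mutation model (no stepwise mutation, so no
size homoplasy), no linkage between loci, no genotyping error or allelic
dropout beyond the explicit null-allele model, island-free random mating
within populations (no inbreeding, no within-population structure), and
haplotype databases without the real system's deep phylogeographic
structure. Results on synthetic data bound what the methods can do when
their assumptions hold; they do not certify performance on noisy archival
genotypes.

## Numerical and engineering choices

Genotype probabilities are accumulated as log10 sums; Dirichlet draws use
gamma variates with invalid registry slots masked; q draws live on the
simplex to within 1e-9 by construction. The pipeline fixes the stage order
QC -> frequencies -> mtDNA -> assignment -> admixture -> target screen ->
hybrid classes -> relatedness, derives one child seed per stage from the
global seed, and emits a manifest (version, seed, parameter hash, record
counts) sufficient to reproduce every output bit-for-bit. Degenerate inputs
fail loudly with the stage and record named: all-missing individuals are
excluded from admixture with a warning, pairs with no common typed loci are
"not assessable", and GENEPOP parse errors carry line numbers.

## Known limitations

Nine loci cannot separate F1s from F2s or early backcrosses individual by
individual — compatible sets overlap by design, and the class machinery
reports that honestly. The relatedness estimator is unbiased but noisy at 9
loci (the simulated-dyad envelopes are wide); pedigree-grade conclusions
need the parentage screen's hard Mendelian evidence or more markers. The
native/non-native mtDNA flag is metadata passthrough, not a phylogenetic
inference. Haploid or polyploid data, Arlequin/STRUCTURE file dialects, and
likelihood-based pedigree reconstruction are out of scope.
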