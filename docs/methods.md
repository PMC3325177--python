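# Methods

## The statistical question

Given a set of k risk alleles for one disease and per-population allele
frequencies from a multi-population reference panel, we ask whether the set
shifts in frequency *consistently in one direction* between continental
regions — more so than (a) genomic alleles matched on European frequency and
(b) the risk alleles of other diseases — and whether the per-individual
genetic risk implied by those alleles is unusually differentiated between
population groups. Directionality is the point: F<sub>ST</sub> measures the
magnitude of differentiation but is blind to sign, so an ensemble whose
alleles all drift the same way is indistinguishable, by F<sub>ST</sub> alone,
from one whose alleles drift in random directions.

## Frequency model and notation

A SNP is two alleles (a, b) with per-population frequency f of allele a;
the risk-allele frequency (RAF) is f or 1−f depending on which allele plays
the risk role. Populations pool into regions by an allele-count-weighted
mean when chromosome counts are known (equivalent to pooling genotypes) and
an unweighted mean otherwise; which was used is recorded. Regional contrasts
are written Δ = RAF_region − RAF_ref with the European pool as the reference
throughout.

## Frequency matching

The empirical nulls all rest on *matching controls by reference-region
frequency*. Matching is allele-level: for a target RAF t, every other SNP
contributes the allele (either orientation) whose pooled reference frequency
lies within t ± tol; if both orientations match (possible only near 0.5) the
closer one is used. SNP-level (minor-allele) matching is available as an
option. Two tolerances are used, both closed intervals: ±0.01 for the
per-SNP joint-tail test and ±0.05 for the ensemble and permutation nulls.
A pool smaller than `min_pool` (default 50 for the per-SNP test) is an
error that advises widening the tolerance rather than silently testing
against a noisy null.

## The three differentiation statistics

**Per-SNP joint tail.** p = #{matched alleles with strictly higher
high-region frequency AND strictly lower low-region frequency than
observed} / pool size. Strict inequalities implement "both higher … and
lower"; a zero count is floored at 1/(pool+1) so p is never 0. The
implementation is an exact enumeration over the pool (vectorized), and the
test suite checks it against an independent brute-force loop, including on a
pool above 10⁴ alleles.

**Ensemble resampling.** The observed statistic is the mean Δ over the k
usable risk alleles (alleles lacking a frequency in either region are
dropped with a named warning; at least two must remain). Each of n
resamples draws one member per target's matched pool, independently across
targets and with replacement across resamples, and records the members' mean
of their own Δ. The two-sided p doubles the smaller continuity-corrected
tail: p = 2·min(#{null ≥ obs}+1, #{null ≤ obs}+1)/(n+1), capped at 1. The
doubling rule keeps the test applicable to a new disease with no prior on
the sign of Δ; the +1 continuity makes p positive and slightly conservative
at the resolution of n. The "other diseases" null replaces the genome pool
with a supplied list of (rsid, risk allele) pairs, matched with their stated
orientation fixed.

**F<sub>ST</sub>.** Nei's G<sub>ST</sub> on pooled regions:
H_T = 2p̄(1−p̄) with p̄ the count-weighted mean, H_S the count-weighted mean
of 2pᵢ(1−pᵢ), FST = (H_T − H_S)/H_T, defined as 0 when H_T = 0 and clamped
to [0, 1]. This estimator matches the pooled-frequency inputs. A
Weir–Cockerham θ is offered as an option; because only pooled frequencies
are available, its observed-heterozygosity term is taken at the HWE
expectation 2p(1−p), and unknown chromosome counts default to 100 per pool
— it is a convenience cross-check, not the primary estimator. For the
genome comparison, SNPs are binned by the minor-allele frequency of the
pooled European frequency into ten 5%-wide half-open bins (MAF = 0.5 joins
the top bin); disease SNPs get empirical percentiles within their bin, and a
one-sided Mann–Whitney U test compares bin-normalized
((FST − bin mean)/bin SD) disease values against the genome, per contrast
(global + three pairwise). Bins with zero FST variance cannot be
normalized; affected disease SNPs are excluded with a warning.

## Catalog curation

Cross-ethnic selection requires, for a consistent risk allele, one
association at p &lt; 10⁻⁶ and significant support (p &lt; 10⁻⁶ for GWAS,
p &lt; 0.01 for candidate studies) in ≥ 5 *distinct* populations; replicated
selection requires p &lt; 5×10⁻⁸ in ≥ 2 distinct papers. Requiring the same
risk allele across supporting studies is a deliberate choice — a locus
"replicated" with opposite alleles is evidence of strand confusion, not
replication. Evidence ranks by (#studies, total n, #populations), with
rsid as the final lexicographic tie-break so the order is total.
LD pruning scans that ranking greedily, keeping a SNP unless its R² with an
already-kept SNP violates the threshold (strict &gt; at 0.7 for catalog
pruning; inclusive ≥ at 0.3 for risk-score pruning — the comparator is a
parameter); absent pairs count as unlinked, since only known-linked pairs
are pruned. Strand harmonization resolves non-palindromic SNPs by set
comparison against the reference alleles (complementing both alleles when
needed); palindromic A/T and C/G SNPs are always flagged ambiguous and
re-oriented only when the study's control risk-allele frequency separates
the two readings by more than 0.1. Between-study heterogeneity is
fixed-effect Cochran's Q on ln OR with inverse-variance weights
(SE from the 95% CI when present, else Woolf's formula on the 2×2 allele
counts with +0.5 on every cell if any is zero), I² = max(0, (Q−df)/Q)·100.

## Genetic risk

Per-locus genotype likelihood ratios LR(g) = Pr(g|case)/Pr(g|control) come
from published case/control genotype counts, with +0.5 added to all six
cells whenever any cell is zero (correcting all cells, not only the zero
one, keeps the three LRs order-consistent). Studies lacking counts fall
back to a model: control genotype frequencies by HWE at the control RAF and
case frequencies by the multiplicative allelic model case(g) ∝
control(g)·ORᵍ, renormalized; such models are flagged `fallback`. Study
LRs combine as a √n-weighted mean per genotype. log PGR sums ln LR over
LD-independent loci (dosage 2 → hom-risk, 1 → het, 0 → hom-other); a
missing dosage skips the locus for that individual, and an individual with
no usable locus is an error rather than a silent zero. GRS is
Σ dosage·ln OR with the same missing-dosage rule.

The permutation test asks whether the observed group contrasts (mean log
PGR in a group minus the mean over all other individuals) exceed what
frequency-matched genome SNPs produce. "Global frequency" is the unweighted
mean across the populations present in the genotype matrix, matched at
±0.05. Each permutation draws, per risk locus, one matched genome locus and
then redraws every individual's genotype from that locus's
population-specific frequency under HWE, keeping the original LRs. Redrawing
(rather than permuting real genotype columns) is required because the
control loci must carry their own population structure into the null;
real-column replacement is possible when a full genome matrix is supplied.
Control loci are drawn independently per permutation (no LD among controls).
p-values use the same doubled continuity-corrected tail as the ensemble
test.

## The synthetic corpus

The generator emulates the statistical structure the analysis assumes, not
any particular panel. Ancestral frequencies are Uniform(0.05, 0.95); each
population's frequency is Beta-distributed with the Balding–Nichols
parameterization (shape (1−F)/F · (p, 1−p)), fixation absorbing. By default
every population drifts independently from the ancestral frequency (star
topology), under which the panel-wide Nei FST estimates F directly —
E[G_ST] ≈ F(1−1/K) ≈ 0.09 at F = 0.1 with K = 11 — which is what the
parameter-recovery checks exploit. A serial-founder option chains each
population off its predecessor instead, accumulating differentiation along
the list to mimic a migration cline; it is opt-in because it deliberately
breaks the FST↔F correspondence. The directional signal is injected
explicitly: delta_high (default +0.10) is added to every high-region
population frequency and delta_low (default −0.10) to every low-region
frequency at the designated risk loci, clamped to [0.01, 0.99] (a warning
fires when clamping touches more than 10% of the loci — routine at the
default deltas, since ancestral frequencies near the edges leave no
headroom); reference-region frequencies are untouched so frequency matching
stays valid. Genotypes are Binomial(2, population RAF), i.e. HWE and
linkage equilibrium. Case/control studies draw multinomial genotype counts
from HWE controls and multiplicative-model cases at a stated OR, and report
the chi-square allele-table p and the count-recomputed OR with a Woolf CI.
The generated catalog plants construction-guaranteed positives
(n_studies_per_snp studies in distinct populations at reported p = 10⁻⁸)
and one decoy per exclusion rule (4 populations; weak p; single paper),
plus an LD pair at R² = 0.9 (one member must be pruned) and an independent
pair at R² = 0.512 (both must survive).

What the generator does **not** emulate: realistic LD structure (loci are
exchangeable and unlinked except planted pairs), ascertainment bias of
genotyping arrays, admixture within populations, imputation error, and
shared drift between regions. Passing calibration and power tests therefore
shows the *statistics* behave as designed under their own assumptions — not
that real panels satisfy those assumptions.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| p_discovery / p_gwas | 10⁻⁶ | discovery and per-GWAS-study significance |
| p_candidate | 0.01 | per-candidate-study significance |
| min_populations | 5 | distinct populations for cross-ethnic status |
| p_threshold / min_papers | 5×10⁻⁸ / 2 | replicated-SNP rule |
| catalog LD prune | R² &gt; 0.7 (CEU-like panel) | greedy, strongest-first |
| risk-score LD prune | R² ≥ 0.3 | per population-group panel |
| per-SNP match tolerance | ±0.01 | European-frequency matching |
| ensemble/permutation tolerance | ±0.05 | matching for resampling nulls |
| n_resamples | 10,000 | ensemble null size |
| n_perm | 100,000 | permutation null size |
| f_drift | 0.05 | per-population Balding–Nichols F |
| delta_high / delta_low | +0.10 / −0.10 | injected cline at risk loci |
| or_range | [1.1, 1.5] | risk-locus odds ratios |
| n_case / n_control | 2,000 / 2,000 | simulated study arms |

Every stochastic operation takes an explicit integer seed, recorded in the
result/provenance objects; equal seeds give identical outputs, and the
synthetic corpus is a pure function of its configuration (byte-identical
files).

## Problem sizes in the test suite and acceptance script

Calibration and power are measured at sizes that keep the whole suite in
the minutes range on one CPU, as the package's own verification scale:
ensemble type-I error over 500 seeded null corpora (3,000 genome SNPs, 10
targets, 2,000 resamples; observed ≈ 0.066 against the 0.05 ± 0.02 band);
permutation type-I error over 200 seeds (1,500 SNPs, 10 loci, 550
individuals, 2,000 permutations; ≈ 0.053, averaged over the three group
contrasts); power over 100 seeds at 20,000 genome SNPs, F = 0.05, ±0.10
cline (≥ 90/100 required). The acceptance script uses 10,000
resamples/permutations for its single-corpus runs and slightly smaller seed
counts for the rate estimates. The brute-force oracle for the per-SNP test
runs at a pool above 10⁴ alleles with exact-equality assertions.

## Known limitations

- The joint-tail and ensemble tests condition on the *pooled* European
  frequency; per-population averaging (the alternative reading of
  "average frequencies") would shift pool membership slightly near the
  tolerance boundary.
- The two-sided doubling rule is conservative when the resampling null is
  strongly skewed (it can only overstate p, never understate it).
- Palindromic SNPs without control genotype counts cannot be strand-resolved
  and are flagged for exclusion from frequency-based analyses.
- The Weir–Cockerham option approximates heterozygosity by its HWE
  expectation; with genotype-level data a proper θ̂ would differ for loci
  out of HWE.
- Permutation nulls draw control loci independently; if real control loci
  were in strong LD the null would be slightly under-dispersed.
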