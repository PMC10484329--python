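# Methods

This note documents the models, estimators and numerical conventions behind
`apiscan`, the assumptions of the synthetic-data generator, and the design
choices made where more than one reading was defensible.

## Statistical estimators

**Weir & Cockerham (1984) F_ST.** Per-SNP two-population variance
components are computed from per-site called sample sizes, allele
frequencies and observed heterozygote fractions; haploid samples contribute
one allele copy with heterozygosity zero and count as half an individual in
the moment equations. The per-SNP estimate is a/(a+b+c) and is left
undefined when the denominator is zero (monomorphic across both
populations). Windowed and gene-wise values are ratio-of-sums (the
"weighted" estimator): Σa / Σ(a+b+c) over member SNPs, which weights SNPs
by their information content and makes negative per-SNP components cancel
rather than being clamped. Windows are 1-based inclusive tiles
[k·w+1, (k+1)·w] starting at position 1 of each chromosome; BED output is
converted to 0-based half-open coordinates.

**Reynolds, Weir & Cockerham (1983) F_ST.** The genome-wide coancestry
estimator is a ratio of per-locus numerator and denominator sums, with the
within-population gene diversity term made unbiased by the 2n/(2n−1)
factor. Identical populations give an estimate within Monte-Carlo noise of
zero, a fixed difference exactly 1, and on a simulated two-deme panel at
split time 0.0301 (4N units) the estimator recovers the design value
1 − e^(−0.0602) ≈ 0.058.

**Diversity.** Per-site π is the unbiased pairwise heterozygosity
2p(1−p)·n/(n−1) over called allele copies (pairwise-complete n per site,
since missingness is population-specific); window π divides the sum over
SNPs by the window length in bp and the genome value is the unweighted mean
over windows with at least one called site. θ_W = S/(a_n·L) with a_n the
harmonic number over sampled allele copies minus one.

**Kinship.** KING-robust within-pair form,
φ = (N_het,het − 2·N_opposite-hom)/(N_het(i) + N_het(j)), over shared
called sites; φ > 0.044 — the smallest value implying any degree of
relatedness — flags a pair. A sample against itself gives exactly 0.5.

**Inbreeding.** The homozygosity-excess method-of-moments estimator
F = (O − E)/(N − E), with E the sum over usable sites of
1 − 2p(1−p)·n/(n−1); this is the per-sample quantity conventionally used to
flag unreliable drones (a true haploid coded diploid approaches F = 1).

## Filter cascade

Order: caller hard filters → site filters → drone heterozygote handling →
MAC. Boundary semantics follow the printed comparators: hard-filter rules
fire only strictly beyond their thresholds; QUAL must strictly exceed 100;
mean depth exactly 20 is retained ("maximum of 20"); missingness of 30% or
more in any one of the five populations removes the site. Missing
hard-filter annotations never fail a site — joint callers omit
rank-sum annotations at sites without heterozygotes, and absence is not
evidence of failure. Mean depth uses the per-sample FORMAT DP average
(sites lacking all DP skip the rule); an alternative INFO-DP path would be
trivial to add but the FORMAT mean is the default. Sites with exactly one
heterozygous drone have that genotype set missing; two or more remove the
site. Thinning is greedy left-to-right per chromosome, which guarantees
every retained pair is at least the minimum distance apart. Re-running the
cascade on its own output is a no-op, and removal counts plus output sites
always equal input sites.

## Pericentromere detection

GC content is computed in 10-kbp windows with N bases excluded from
numerator and denominator; all-N windows are undefined and score 0. Windows
score +1 below the genome-wide mean GC, −1 above, 0 at equality. "Highest
increase in the cumulative score" is read as the maximum net score sum over
a sliding 50-window (0.5-Mb) span — the only reading consistent with a
prefix-sum track — with ties broken leftmost. The seed extends outward by
10-window blocks while a full block contributes net score ≥ +5 (partial
blocks at chromosome edges are not absorbed), then by single windows while
each scores +1. Block extension does not re-check any whole-region
criterion, exactly as stated by the procedure it implements; chromosomes
whose best span has non-positive gain yield no region. The detector is
verified equivalent to an exhaustive enumerate-and-simulate oracle on
random tracks up to 500 windows.

## Peak calling

Seeds are maximal runs of windows at or above the 0.998 quantile of all
defined window values (adjacent seed windows merge; gaps are never
jumped). Extension proceeds one window at a time, alternating sides
starting left — the source procedure does not fix an order, so one is fixed
deterministically and mirrored in the brute-force oracle — and a window is
accepted iff its own value is ≥ the 0.98 quantile and the resulting peak's
SNP-weighted mean (ratio of summed components) stays ≥ the 0.99 quantile,
checked after every single acceptance (the stricter of the two possible
readings). Quantiles use the linear-interpolation (type-7) definition.
Peaks overlapping detected pericentromeric regions are flagged, not
removed. A gene is annotated to a peak iff at least 30% of its exons
overlap the peak by at least 50% of the exon's length; gene-wise F_ST uses
transcript bounds including introns (the simplest reading of "gene
coordinates"). Term enrichment is the upper-tail hypergeometric
P(X ≥ k) with Benjamini–Hochberg correction across terms.

## Coalescent null

The null is a clean split: an ancestral panmictic population divides into
two demes of unchanged, equal size with no subsequent migration. Time is in
units of 4N generations, matching the `ms` convention in which k lineages
coalesce at total rate k(k−1) per unit time. The scaled divergence
T = −ln(1 − F_ST)/2 is in 2N units, so the simulation input is T/2
(0.0584 → T = 0.0301 → 0.0150). Each locus carries exactly one mutation
placed uniformly along the genealogy's total branch length (the root branch
has length zero), so every simulated SNP segregates; per-SNP F_ST uses the
haploid Weir–Cockerham form on per-deme derived counts. With one
conditioned segregating site the locus mutation rate θ does not affect the
exported SNP's distribution; it is retained in the model for interface
parity and logged. The production path is a numba kernel looping over
loci; a pure-Python genealogy path (`simulate_genealogy` +
`drop_single_mutation`) implements the identical process for inspection and
testing, and the kernel's F_ST distribution is verified indistinguishable
(Kolmogorov–Smirnov, α = 0.01, n = 10⁴) from msprime run with matched
scaling (haploid samples, population size 0.5).

Two numerical facts about this conditioning are worth recording. First,
placing exactly one mutation per genealogy weights each tree by the inverse
of its total length, so the site-frequency spectrum is E[L_i/L], not the
classical E[L_i]/E[L] ∝ 1/i; the tests therefore check the branch-length
spectrum (exactly ∝ 1/i) and the SFS only qualitatively. Second, the
per-SNP F_ST distribution at this shallow divergence is dominated by rare
variants: its plain mean (negative estimates included) is ≈ 0.019 and its
ratio-of-sums ≈ 0.029 (the parametric value 1 − e^(−0.03)), while the mean
over positively differentiated SNPs is ≈ 0.052. The panel summary exposes
all three; the positive-part mean is the one quoted as the panel's average
divergence, being the only summary jointly consistent with the
outlier-count behaviour of the distribution at these parameters. The
enrichment test counts SNPs above the threshold (default 0.255) in the
empirical and simulated distributions and reports their ratio after scaling
to equal totals.

## Ancestry statistics

p(A) = p(AA) + (p(MA) + p(CA))/2, with the analogous reductions for p(C)
and p(M) summing to one. Population tracks average individual p(A) per SNP;
Δ = lowland − highland. The Spearman correlation between windowed F_ST and
Δ uses window-averaged Δ (the windowed F_ST has no per-SNP resolution; the
alternative per-SNP pairing would duplicate window values). The
dependent-correlation comparison is Dunn & Clark's z with the covariance
evaluated at the backtransformed average of the two Fisher transforms
(Hittner, May & Silver 2003). n is the number of SNPs in the intersection;
SNP autocorrelation is ignored, exactly as in the analysis this
reimplements, so the printed p-values are anti-conservative in the same
way — the classification test downstream depends only on a significance
cut, for which both the 0.001 and 0.0001 conventions are supported
(default 0.001). The climate-class test builds the 2×2 table of (external
population's ancestry class) × (significantly higher correlation with the
highland population) and applies a two-sided Fisher exact test, verified
against full hypergeometric enumeration for all margins ≤ 30.

## Synthetic-data generator

The generator emulates the study design rather than honey-bee biology in
full. Its defaults are the study constants: sample sizes 15 lowland + 14
highland admixed workers, 19 A and 9 C diploid references, 85 haploid M
drones; mean A ancestry 0.847 (lowland) and 0.686 (highland); C
contribution 0.001; drone heterozygote injection at 2.5% of sites with one
het drone and 0.5% with two.

*Frequencies.* Shared SNPs draw per-lineage frequencies from a
Balding–Nichols Beta around a common ancestral frequency p ~ U(0.05, 0.95);
the drift parameters (A 0.12, C 0.32, M 0.28) are set so A–M
differentiation is strong, as between the real lineages, while A remains
the most diverse. Lineage-private SNPs (weights 0.30 A, 0.12 M, 0.08 C;
frequency U(0.05, 0.30) in the owning lineage, absent elsewhere) emulate
the large excess of A-segregating sites in real panels. The admixed gene
pool carries additional founder drift (F = 0.06, one shared introduction
event) — without it, admixture's between-lineage variance would make the
hybrids more diverse than the A reference, inverting the diversity ranking
the real data show. Together these give π(A) > π(admixed) > π(M) > π(C)
with stable margins.

*Genotypes and selection.* Each allele copy draws its ancestry
independently (no linkage tracts: the per-SNP statistics in scope do not
require realistic tract lengths), then its allele from the chosen lineage's
founder frequency. Selection targets are contiguous regions spanning whole
analysis windows (default one region of two 10-kbp windows per panel —
0.2% of windows, matching the outlier fraction a 0.998-quantile scan can
seed on); within them the highland A proportion drops by the configured
shift (default 0.5). Region boundaries are aligned to the window grid so
recovery metrics are unambiguous.

*Files.* The VCF codes drones as diploid homozygotes (as a joint caller
would) with injected heterozygous drone calls, caller-style INFO fields
drawn inside the pass region, and optional engineered failures per rule.
The FASTA has background GC 0.37 with the configured depression inside
truth centromere intervals; the recombination map reduces rates fivefold in
centromeres. Posteriors are Dirichlet draws centred on the true diplotype
(concentration 50 by default); cline steepness is generated at a
configurable correlation with the true ancestry-shift vector.

*What passing tests do and do not show.* The generator has no linkage
disequilibrium, no mutation-spectrum structure, no depth-genotype error
coupling, and drone heterozygosity is injected uniformly (its
allele-frequency dependence in real callers is unknown). Recovery results
therefore demonstrate the correctness and calibration of the estimators
and callers under the declared model, not robustness to real-data
artefacts such as mapping bias or tract-length autocorrelation.

## Problem sizes

Default synthetic panels are 30,000 SNPs on three chromosomes totalling
10 Mbp (1,000 analysis windows) with 142 samples — a scale chosen so the
full 20-seed recovery suite and the end-to-end pipeline each complete in
about a minute while every quantile, window and sample-size convention
matches the full-scale analysis. The coalescent null runs at the full
published size (248,598 loci) in seconds.

## Known limitations

- The split-model null ignores recombination within loci, migration and
  population-size change; these are the stated simplifications of the
  analysis it reproduces.
- Windowed F_ST uses the weighted (ratio-of-sums) value; the mean-of-ratios
  alternative would change quantile thresholds slightly.
- The dependent-correlation p-values inherit the SNP-independence
  assumption of the source analysis.
- Real peak coordinates and gene lists require the original sequence data
  and are out of scope; the synthetic panels recover configured targets
  instead.
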