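# Methods

`domestiscan` re-implements, as a tested library, the statistical core of a
candidate-gene domestication study: a cis-regulatory region upstream of a
panicle-architecture gene is scanned for variants across a wild/cultivated
accession panel, the causal variant is identified by exact-test association
and confirmed by a selective-sweep diversity contrast, the locus itself is
fine-mapped in F2 populations, and the regulatory consequence is examined
through promoter methylation and relative expression. This note documents
the models, the defaults and the numerical choices.

## Accession panel and coordinates

A panel is a gapped alignment of one upstream region over inbred accessions
(rice lines are effectively homozygous, so each accession contributes one
haploid sequence). All reported positions are "bp upstream of the
translation start": alignment column 0 maps to a user-supplied anchor (the
distal edge of the region) and positions decrease toward the gene. The
anchor is a required parameter because the distal edge's absolute position
depends on how the region was excised from its chromosome. Symbols outside
{A, C, G, T, -} are masked to N and excluded from every downstream count.

VCF export uses a synthetic forward contig running distal → proximal, so
POS = column + 1 ascends toward the ATG and indels can be left-anchored
with one base of context in the usual way; the upstream coordinate is kept
in INFO/UPS.

## Variants and haplotypes

A SNP is any gap-free column with ≥ 2 distinct non-N symbols. Multi-base
indels are merged into single events: a maximal run of consecutive
gap-bearing columns with an identical gap-membership pattern across
accessions is one INDEL whose alleles are the substrings over the run; the
run splits where the membership changes. The reference allele is the
majority allele among wild accessions (the progenitor population carries
the ancestral state), ties to the lexicographically smaller allele.
Haplotypes are exact allele-vector equivalence classes; a missing call
never equals a concrete allele, and accessions missing > 50 % of calls are
dropped with a warning. Labels H1, H2, … follow descending carrier count.

## Association and LD

Fisher's exact test is computed by direct hypergeometric enumeration in
log space (log-gamma factorials + log-sum-exp): with margins fixed, the
two-sided p is the sum of point probabilities ≤ the observed one, with the
standard 1 + 1e−7 relative guard for floating-point ties. Units are
accessions (haploid inbred lines). Rows are the phenotype classes
(spread/compact), columns reference vs pooled-alternate allele;
multiallelic sites are biallelized the same way for LD. For a
completely separating site in a 21 vs 158 panel the p-value is
1/C(179, 21) ≈ 8.5 × 10⁻²⁸. No multiple-testing correction is applied to
the reported p (a Bonferroni column is emitted for reference). The top
hit is the minimal p; ties resolve to the most distal position.

r² and D′ use haplotype frequencies over accessions complete at both
sites, with the textbook D_max branch on the sign of D. Sites monomorphic
after filtering yield missing values rather than errors.

## Diversity contrast

π is the Nei–Li mean pairwise difference per site with pairwise deletion
(columns with gap or N in either member of a pair are skipped); the
effective length is the mean number of compared sites over pairs, so
π = Σ diffs / Σ compared. Indel gaps therefore never contribute
differences — diversity is SNP-only. Watterson's θ_w = S/(a₁·L_eff) uses
complete deletion (columns with a concrete base in every sequence).
Sliding windows default to 500/100 bp (window/step, configurable); the
final partial window is kept when it spans at least half a window. The
sweep signature is the per-window ratio π_cultivated/π_wild; because no
parametric test is defined for this contrast, the package reports the
ratio with a seeded bootstrap CI over windows (1,000 replicates by
default) instead of a p-value.

## F2 fine mapping

Under single-locus dominance, only compact (recessive-class) plants have a
certain genotype (A/A) at the functional mutation, so only they constrain
the interval; a spread plant enters the recombinant count only via the
lower-bound rule (a marker-A call certifies ≥ 1 recombinant gamete).
Graphical genotyping places breakpoints at midpoints between adjacent
genotyped markers with differing A/non-A status; the region beyond the
outermost genotyped markers is left unconstrained, since a breakpoint
distal to the outermost marker cannot be excluded. The FM interval is the
intersection of the allowed regions over all informative plants, snapped
outward to the nearest flanking markers. Double recombinants within a
marker interval are assumed absent; when a real (simulated) double
recombinant violates that assumption the intersection can be empty, which
raises an inconsistency error by design. The 3:1 segregation test is a
1-df χ² goodness of fit without continuity correction.

## Bisulfite methylation

Only the converted top strand is modeled (clone Sanger sequencing of one
PCR fragment, gapless alignment to the reference). At each reference C,
clone C → methylated, T → unmethylated, anything else → ambiguous and
excluded from the percent. Context is assigned from the reference
trinucleotide (CG → CpG, C-H-G → CHG, else CHH; truncated contexts at the
reference end default to CHH). Calling never corrects for incomplete
conversion; instead a per-clone non-CpG methylation rate is reported as a
conversion QC. A warning is issued below 30 clones, the conventional
minimum for stable site percentages.

## Relative expression (2^−ΔΔCT)

Amplification efficiency is fixed at 2.0. Replicates are paired by index
(technical runs); per replicate, ΔCT = CT_target − CT_reference, ΔΔCT
subtracts the calibrator's ΔCT, and the fold change is 2^−ΔΔCT, summarized
by mean and n−1 SD. An unpaired mode (mean-ΔCT with propagated SE) is
available behind a flag for designs without run pairing.

## Phylogeny

Distances over protein alignments are p-distances with pairwise gap
deletion or Poisson-corrected −ln(1 − p) (the default, the common
amino-acid setting for distance trees; the correction is undefined at
p ≥ 1 and raises). Neighbor joining follows Studier–Keppler; ties in Q
break toward the smallest pair in input label order, making the topology
deterministic. Negative branch lengths are clipped to zero with the
deficit moved to the sibling branch, preserving the joined pair's
distance; this affects printed lengths only, never topology. NJ is exact
on additive matrices, which the tree simulator exploits for exact
recovery tests. No bootstrap is run by default.

## Synthetic data: what it emulates and what it does not

The panel generator uses a star genealogy (independent per-site tip
mutations from a shared ancestor) rather than a coalescent: it trades
realism for closed-form expectations, E[π] ≈ 2μ per site, which the test
suite checks exactly. Defaults mirror the study conditions: 21 wild /
158 cultivated accessions, a 3.3-kb region anchored 13.3 kb upstream, a
causal column at 11 kb upstream with guaranteed complete wild/cultivar
separation, three linked cultivar-fixed sites and a 6-bp deletion — both
seeded at low frequency (default 0.1 per wild accession, at least one
carrier) in the wild group so their LD with the causal site is high but
below 1, leaving the causal site the unique strongest signal. Background
rates default to μ_wild = 5 × 10⁻³ and μ_cult = 2 × 10⁻⁴ per site, giving
the near-zero cultivated diversity of a hard sweep. The `paper_like`
preset instead plants polymorphism at exactly 13 sites (12 SNPs + the
indel) and splits the 158 cultivars 150/8 across two haplotypes,
reproducing the published haplotype structure at desk scale.

The F2 generator draws two independent gametes per plant as Markov walks
along the marker map with Haldane recombination fractions (no
interference); the phenotype is determined by dominance at the FM. The
bisulfite generator draws per-clone methylation states independently per
site with a conversion-efficiency parameter (default 0.995 in realistic
use; 1.0 in the exact-recovery checks). The CT generator adds Gaussian
noise (default SD 0.2 cycles) to a base CT of 20.

Because wild accessions are unstructured star tips, the generators do not
reproduce population structure, linkage blocks within the wild group,
recombination between panel haplotypes, crossover interference, or
sequencing error beyond conversion efficiency — so passing tests certify
the estimators and the pipeline logic, not robustness to those real-data
features.

## Problem sizes in the checks

The bundled end-to-end checks run at the sizes the statistics need rather
than production scale: exhaustive Fisher validation over all 2×2 tables
with n ≤ 30 against an independent enumeration oracle; 500 random panels
(n ≤ 8, L ≤ 50) against a brute-force π/θ oracle; 200 star-panel seeds for
the 2μ limit; 500 simulated 2,000-plant F2 populations for interval
recovery plus 1,000 replicates of the 285-plant segregation design for
type-I control; 200 random additive matrices (≤ 12 leaves) for NJ
exactness; and 1,000-clone bisulfite sets for methylation recovery at the
published 83 % / 40 % / 16 % rates.
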